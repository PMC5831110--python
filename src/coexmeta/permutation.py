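"""Multivariate permutation control of the false discovery proportion.

The null model shuffles the seed profile independently within every batch —
destroying any seed-gene association while preserving batch structure and the
gene-gene covariance — and recomputes the full meta statistic for all
features. A statistic threshold t* is then chosen so that, with the stated
confidence, the number of null features exceeding t* is at most the target
FDR fraction of the selections: over candidate thresholds t (the sorted
observed statistics), V_b(t) counts null statistics >= t in permutation b,
V*(t) is the ceil(confidence * B)-th order statistic of {V_b(t)}, and t* is
the smallest t with V*(t) <= gamma * R(t) where R(t) counts observed
statistics >= t.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ExpressionBatch

__all__ = ["PermutationNull", "FDRSelection", "permute_null",
           "select_significant", "PermutationFDRSelector"]

_CLIP = 1.0 - 1e-12


@dataclass
class PermutationNull:
    """B x G matrix of meta statistics under within-batch seed permutation."""

    statistics: np.ndarray  # shape (B, G)
    features: pd.Index
    rng_seed: int

    @property
    def n_permutations(self) -> int:
        return self.statistics.shape[0]


@dataclass
class FDRSelection:
    """Result of the permutation threshold search."""

    threshold: float
    selected: list[str]
    fdr: float
    confidence: float
    n_permutations: int
    table: pd.DataFrame  # candidate threshold t, R(t), V*(t), qualifies

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def permute_null(batches: Sequence[ExpressionBatch],
                 seed_profiles: Mapping[str, pd.Series],
                 n_permutations: int,
                 rng_seed: int,
                 features: pd.Index | None = None,
                 exclude: set[str] | None = None) -> PermutationNull:
    """Recompute the meta statistic for every feature under B seed shuffles.

    Each permutation draws an independent within-batch rearrangement of the
    seed values; per-batch Fisher-z correlations are pooled with the same
    inverse-variance weights (n - 3) as the observed analysis. Features listed
    in ``exclude`` (e.g. the seed's own probes) are dropped.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not batches:
        raise ValueError("no batches provided")
    rng = np.random.default_rng(rng_seed)

    if features is None:
        features = pd.Index(sorted(set().union(*(b.data.index for b in batches))))
    if exclude:
        features = features[~features.isin(exclude)]
    G = len(features)
    B = n_permutations

    num = np.zeros((G, B))
    den = np.zeros(G)
    for batch in batches:
        n = batch.n_samples
        if n < 4:
            raise ValueError(f"batch {batch.batch_id!r} has n={n} < 4 samples")
        data = batch.data.reindex(features)
        X = data.to_numpy(dtype=float)
        present = ~np.isnan(X).any(axis=1)

        Xc = X[present] - np.nanmean(X[present], axis=1, keepdims=True)
        norms = np.sqrt((Xc**2).sum(axis=1))
        good = norms > 0
        Xs = np.zeros_like(Xc)
        Xs[good] = Xc[good] / norms[good][:, None]

        s = seed_profiles[batch.batch_id].reindex(batch.sample_ids).to_numpy(dtype=float)
        sc = s - s.mean()
        s_norm = np.sqrt(sc @ sc)
        if s_norm == 0:
            raise ValueError(f"seed profile constant in batch {batch.batch_id!r}")
        ss = sc / s_norm

        perms = np.empty((n, B))
        for b in range(B):
            perms[:, b] = ss[rng.permutation(n)]

        r = np.clip(Xs @ perms, -_CLIP, _CLIP)  # (present, B)
        z = np.arctanh(r)
        w = float(n - 3)

        idx = np.where(present)[0][good]
        num[idx] += w * z[good]
        den[idx] += w

    with np.errstate(divide="ignore", invalid="ignore"):
        stats = (num / np.sqrt(den)[:, None]).T  # (B, G); den==0 -> nan
    return PermutationNull(statistics=stats, features=features, rng_seed=rng_seed)


def select_significant(observed: pd.Series, null: PermutationNull,
                       fdr: float = 0.01, confidence: float = 0.99,
                       two_sided: bool = False) -> FDRSelection:
    """Pick the smallest statistic threshold meeting the FDR bound.

    ``observed`` must be indexed by the same feature universe the null was
    computed on. With ``two_sided`` the search ranks on absolute statistics.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    if set(observed.index) != set(null.features):
        raise ValueError("observed statistics and permutation null cover "
                         "different feature universes")

    obs = observed.reindex(null.features).to_numpy(dtype=float)
    nul = null.statistics
    if two_sided:
        obs = np.abs(obs)
        nul = np.abs(nul)
    finite = np.isfinite(obs)
    obs_f = obs[finite]

    ts = np.sort(obs_f)  # candidate thresholds, ascending
    n_obs = len(ts)
    R = n_obs - np.searchsorted(ts, ts, side="left")  # observed count >= t

    B = nul.shape[0]
    V = np.empty((B, n_obs), dtype=np.int64)
    for b in range(B):
        row = np.sort(nul[b][np.isfinite(nul[b])])
        V[b] = len(row) - np.searchsorted(row, ts, side="left")
    order_idx = math.ceil(confidence * B) - 1  # 0-based order statistic
    Vstar = np.sort(V, axis=0)[order_idx]

    qualifies = Vstar <= fdr * R
    table = pd.DataFrame({"t": ts, "R": R, "V_star": Vstar, "qualifies": qualifies})
    if qualifies.any():
        tstar = float(ts[qualifies][0])  # smallest qualifying threshold
        mask = np.isfinite(obs) & (obs >= tstar)
        selected = list(observed.index[mask])
    else:
        tstar = float("inf")
        selected = []
    return FDRSelection(threshold=tstar, selected=selected, fdr=fdr,
                        confidence=confidence, n_permutations=B, table=table)


class PermutationFDRSelector:
    """Select seed-associated features at a permutation-calibrated threshold.

    Fit on a fitted :class:`~coexmeta.association.SeedAssociationMeta`: the
    selector reuses its batches and seed profiles to build the within-batch
    permutation null, then thresholds the observed meta statistics so that the
    false discovery proportion is bounded by ``fdr`` with the stated
    ``confidence``. Seed-gene probes are excluded from the tested universe.

    Attributes (after fit)
    ----------------------
    null_ : PermutationNull
    selection_ : FDRSelection
    threshold_ : float
    selected_ : list of selected feature ids
    """

    def __init__(self, n_permutations: int = 1000, fdr: float = 0.01,
                 confidence: float = 0.99, two_sided: bool = False,
                 random_state: int = 0):
        self.n_permutations = n_permutations
        self.fdr = fdr
        self.confidence = confidence
        self.two_sided = two_sided
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_permutations": self.n_permutations, "fdr": self.fdr,
            "confidence": self.confidence, "two_sided": self.two_sided,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "PermutationFDRSelector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, meta, y=None) -> "PermutationFDRSelector":
        observed = meta.observed_statistics_
        seed_features = set(meta.table_.loc[meta.table_["is_seed"], "probe_id"])
        self.null_ = permute_null(
            meta.batches_, meta.seed_profiles_, self.n_permutations,
            rng_seed=self.random_state, exclude=seed_features,
        )
        self.selection_ = select_significant(
            observed, self.null_, fdr=self.fdr, confidence=self.confidence,
            two_sided=self.two_sided,
        )
        self.threshold_ = self.selection_.threshold
        self.selected_ = self.selection_.selected
        return self
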