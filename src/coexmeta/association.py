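"""Seed-gene association and fixed-effect meta-analysis.

Within each batch the association of every probe (or gene) with the seed
gene's collapsed profile is a Pearson correlation; correlations are taken to
the variance-stabilizing Fisher z scale (SE = 1/sqrt(n - 3)) and pooled
across batches by the generic inverse-variance method under a fixed-effect
model. The pooled z over its pooled SE is the meta statistic used for
ranking and downstream permutation-based selection.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ExpressionBatch

__all__ = [
    "collapse_probes",
    "seed_profile",
    "batch_correlations",
    "fisher_z",
    "meta_fixed_effect",
    "rank_genes",
    "SeedAssociationMeta",
]

_CLIP = 1.0 - 1e-12


def collapse_probes(data: pd.DataFrame, probe_map: pd.DataFrame,
                    genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Collapse probe rows to gene rows by the arithmetic mean.

    ``probe_map`` needs columns ``probe_id`` and ``gene_symbol``. When
    ``genes`` is given, every requested gene must have at least one mapped
    probe present in ``data``.
    """
    pm = probe_map.set_index("probe_id")["gene_symbol"]
    present = data.index.intersection(pm.index)
    if genes is not None:
        available = set(pm.loc[present])
        for g in genes:
            if g not in available:
                raise KeyError(f"gene {g!r} has no probes in the matrix")
    sub = data.loc[present]
    collapsed = sub.groupby(pm.loc[present].to_numpy()).mean()
    collapsed.index.name = "gene_symbol"
    if genes is not None:
        collapsed = collapsed.loc[list(genes)] if len(genes) > 1 else collapsed.loc[[genes[0]]]
    return collapsed


def seed_profile(batch: ExpressionBatch, probe_map: pd.DataFrame,
                 seed_gene: str) -> pd.Series:
    """Per-sample seed profile: mean over the seed gene's probes in this batch."""
    collapsed = collapse_probes(batch.data, probe_map, [seed_gene])
    return collapsed.loc[seed_gene]


def _rowwise_pearson(X: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X with s; zero-variance rows give NaN."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    s_norm = np.sqrt(sc @ sc)
    if s_norm == 0:
        raise ValueError("seed profile has zero variance")
    row_norm = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ sc) / (row_norm * s_norm)
    r[row_norm == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def batch_correlations(batch: ExpressionBatch, seed: pd.Series) -> pd.DataFrame:
    """Per-probe Pearson r with the seed profile, with Fisher z and SE.

    Returns a frame indexed by probe with columns ``r``, ``n``, ``z``, ``se``.
    Probes with zero within-batch variance get NaN (missing in this batch).
    """
    n = batch.n_samples
    if n < 4:
        raise ValueError(f"batch {batch.batch_id!r} has n={n} < 4 samples")
    s = seed.reindex(batch.sample_ids)
    if s.isna().any():
        raise ValueError("seed profile is not aligned to the batch samples")
    r = _rowwise_pearson(batch.data.to_numpy(dtype=float), s.to_numpy(dtype=float))
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    se = 1.0 / np.sqrt(n - 3)
    return pd.DataFrame(
        {"r": r, "n": n, "z": z, "se": np.where(np.isnan(r), np.nan, se)},
        index=batch.data.index,
    )


def fisher_z(r: float, n: int) -> tuple[float, float]:
    """Fisher transform of a Pearson correlation: z = atanh(r), SE = 1/sqrt(n-3)."""
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if n < 4:
        raise ValueError("need n >= 4 for a finite standard error")
    z = float(np.arctanh(np.clip(r, -_CLIP, _CLIP)))
    return z, 1.0 / np.sqrt(n - 3)


def meta_fixed_effect(pairs: Sequence[tuple[float, float]]
                      ) -> tuple[float, float, float, float]:
    """Inverse-variance fixed-effect pooling of (z, se) pairs.

    Returns ``(z_pooled, se_pooled, statistic, two-sided p)`` with weights
    ``w_i = 1/se_i^2``; the statistic is z_pooled / se_pooled, referred to the
    standard normal.
    """
    pairs = [(z, se) for z, se in pairs if np.isfinite(z) and np.isfinite(se)]
    if not pairs:
        raise ValueError("no batches with finite effect estimates")
    z = np.array([p[0] for p in pairs])
    se = np.array([p[1] for p in pairs])
    w = 1.0 / se**2
    zbar = float((w * z).sum() / w.sum())
    se_pooled = float(1.0 / np.sqrt(w.sum()))
    stat = zbar / se_pooled
    p = float(2.0 * stats.norm.sf(abs(stat)))
    return zbar, se_pooled, stat, max(p, np.finfo(float).tiny)


def rank_genes(table: pd.DataFrame, k: int,
               exclude_seed: bool = True) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Rank the meta table by statistic (descending) and slice the top k.

    Ties break lexicographically on gene symbol then probe id so ranking is
    deterministic. Seed-gene probes (``is_seed``) are ranked but left out of
    the top-k slice by default, since their self-correlation is trivially 1.
    Returns (ranked table, top-k slice, distinct gene symbols in the slice).
    """
    if table.empty:
        raise ValueError("empty association table")
    ranked = table.sort_values(
        by=["statistic", "gene_symbol", "probe_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    pool = ranked[~ranked["is_seed"]] if exclude_seed else ranked
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the {len(pool)} rankable probes")
    top = pool.head(k).copy()
    return ranked, top, int(top["gene_symbol"].nunique())


class SeedAssociationMeta:
    """Guilt-by-association meta-analysis of a multi-batch compendium.

    Collapses the seed gene's probes by the mean within each batch, computes
    per-batch Pearson correlations of every probe (or collapsed gene) with
    that profile, Fisher-transforms them, and pools across batches by
    inverse-variance fixed-effect weighting. Probes absent or degenerate in a
    batch simply contribute nothing to that batch's sums (complete-case
    pooling), which accommodates platforms with different probe content.

    Parameters
    ----------
    seed_gene : str
        Symbol of the seed gene (collapsed by the mean over its probes).
    top_k : int
        Size of the reported top slice (default 500).
    level : str
        "probe" (default) correlates individual probes against the collapsed
        seed; "gene" collapses all genes first.

    Attributes (after fit)
    ----------------------
    table_ : pd.DataFrame
        Ranked meta table: probe_id, gene_symbol, per-batch r_<batch> and
        n_<batch>, z_pooled, se_pooled, statistic, p, r_pooled, rank, is_seed.
    top_ : pd.DataFrame, the top_k slice (seed probes excluded).
    n_unique_genes_ : int, distinct gene symbols in the top slice.
    seed_profiles_ : dict of batch id -> per-sample seed profile.
    """

    def __init__(self, seed_gene: str = "MS4A1", top_k: int = 500,
                 level: str = "probe"):
        self.seed_gene = seed_gene
        self.top_k = top_k
        self.level = level

    def get_params(self, deep: bool = True) -> dict:
        return {"seed_gene": self.seed_gene, "top_k": self.top_k, "level": self.level}

    def set_params(self, **params) -> "SeedAssociationMeta":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _feature_batches(self, batches: Sequence[ExpressionBatch],
                         probe_map: pd.DataFrame) -> list[ExpressionBatch]:
        if self.level == "probe":
            return list(batches)
        if self.level == "gene":
            out = []
            for b in batches:
                collapsed = collapse_probes(b.data, probe_map)
                out.append(ExpressionBatch(b.batch_id, collapsed))
            return out
        raise ValueError(f"unknown level {self.level!r}")

    def fit(self, batches: Sequence[ExpressionBatch], probe_map: pd.DataFrame,
            y=None) -> "SeedAssociationMeta":
        if not batches:
            raise ValueError("no batches provided")
        pm = probe_map
        self.seed_profiles_ = {
            b.batch_id: seed_profile(b, pm, self.seed_gene) for b in batches
        }
        feats = self._feature_batches(batches, pm)

        per_batch = {
            b.batch_id: batch_correlations(b, self.seed_profiles_[b.batch_id])
            for b in feats
        }
        features = pd.Index(sorted(set().union(*(t.index for t in per_batch.values()))))

        num = pd.Series(0.0, index=features)
        den = pd.Series(0.0, index=features)
        cols: dict[str, pd.Series] = {}
        for bid, t in per_batch.items():
            t = t.reindex(features)
            w = 1.0 / t["se"] ** 2
            contrib = (w * t["z"]).fillna(0.0)
            num += contrib
            den += w.fillna(0.0)
            cols[f"r_{bid}"] = t["r"]
            cols[f"n_{bid}"] = t["n"]

        ok = den > 0
        zbar = num[ok] / den[ok]
        se_pooled = 1.0 / np.sqrt(den[ok])
        statistic = zbar / se_pooled
        p = 2.0 * stats.norm.sf(np.abs(statistic))
        p = np.maximum(p, np.finfo(float).tiny)

        if self.level == "probe":
            gene_of = pm.set_index("probe_id")["gene_symbol"]
            gene_symbol = gene_of.reindex(features[ok]).fillna("").to_numpy()
            probe_id = features[ok].to_numpy()
        else:
            gene_symbol = features[ok].to_numpy()
            probe_id = features[ok].to_numpy()

        table = pd.DataFrame({
            "probe_id": probe_id,
            "gene_symbol": gene_symbol,
            "z_pooled": zbar.to_numpy(),
            "se_pooled": se_pooled.to_numpy(),
            "statistic": statistic.to_numpy(),
            "p": p,
            "r_pooled": np.tanh(zbar.to_numpy()),
            "is_seed": gene_symbol == self.seed_gene,
        })
        for name, col in cols.items():
            table[name] = col[ok].to_numpy()

        k = min(self.top_k, int((~table["is_seed"]).sum()))
        self.table_, self.top_, self.n_unique_genes_ = rank_genes(table, k)
        self.per_batch_ = per_batch
        self.batches_ = feats  # feature-level batches, reused by the permutation null
        return self

    @property
    def observed_statistics_(self) -> pd.Series:
        """Meta statistics of non-seed probes, indexed by probe id."""
        t = self.table_[~self.table_["is_seed"]]
        return pd.Series(t["statistic"].to_numpy(), index=t["probe_id"].to_numpy())
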