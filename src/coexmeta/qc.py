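"""Sample-level quality control.

Two filters, applied per batch: removal of duplicate samples by content
hashing of the expression vector, and removal of low-quality arrays by their
correlation with the first principal component (PCqc) of the sample
correlation matrix. On well-behaved arrays PCqc describes a near-constant
pattern dominating the data; arrays whose profile correlates with it below a
threshold (default 0.8) are discarded.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ExpressionBatch

__all__ = [
    "QCReport",
    "PCOutlierFilter",
    "content_digest",
    "deduplicate",
    "sample_correlation_matrix",
    "pcqc_scores",
    "filter_outliers",
    "run_batch_qc",
]

DEFAULT_THRESHOLD = 0.8
_EPS = 1e-12


@dataclass
class QCReport:
    """Per-sample QC outcome for one batch."""

    batch_id: str
    table: pd.DataFrame  # sample_id, digest, duplicate_of, pcqc_correlation, kept
    pc1_variance_fraction: float
    threshold: float

    @property
    def kept_samples(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "sample_id"])

    @property
    def removed_samples(self) -> list[str]:
        return list(self.table.loc[~self.table["kept"], "sample_id"])


def content_digest(values: np.ndarray, decimals: int = 6) -> str:
    """MD5 digest of a canonical fixed-decimal serialization of the profile.

    Fixed-precision formatting makes the fingerprint stable across re-parsing
    of text matrices while still distinguishing any numerically distinct
    profiles at the stated precision.
    """
    vec = np.asarray(values, dtype=float).ravel()
    text = ",".join(f"{v:.{decimals}f}" for v in vec)
    return hashlib.md5(text.encode()).hexdigest()


def deduplicate(batch: ExpressionBatch) -> tuple[ExpressionBatch, pd.DataFrame]:
    """Drop samples whose expression content hashes identically.

    Among samples sharing a digest the first in column order is kept. Returns
    the deduplicated batch and a report with columns ``sample_id``,
    ``digest``, ``duplicate_of`` (empty for kept samples) and ``kept``.
    """
    data = batch.data
    if data.isna().any().any():
        bad = data.columns[data.isna().any(axis=0)][0]
        raise ValueError(f"sample {bad!r} has unreadable (NaN) content")
    digests = {s: content_digest(data[s].to_numpy()) for s in data.columns}
    first_seen: dict[str, str] = {}
    rows = []
    kept_cols = []
    for s in data.columns:
        d = digests[s]
        rep = first_seen.setdefault(d, s)
        kept = rep == s
        if kept:
            kept_cols.append(s)
        rows.append((s, d, "" if kept else rep, kept))
    report = pd.DataFrame(rows, columns=["sample_id", "digest", "duplicate_of", "kept"])
    return ExpressionBatch(batch.batch_id, data[kept_cols]), report


def sample_correlation_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of sample columns."""
    if data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 samples and 2 probes")
    sds = data.std(axis=0, ddof=0)
    zero = sds.index[sds.to_numpy() <= 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero variance")
    corr = np.corrcoef(data.to_numpy(), rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=data.columns, columns=data.columns)


def _colwise_pearson(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every column of M with y, degenerate-safe.

    When both a column and y are constant the pair is perfectly redundant and
    scores 1.0 (a fully homogeneous batch); a constant column against a
    varying y scores 0.0.
    """
    Mc = M - M.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    col_norm = np.sqrt((Mc**2).sum(axis=0))
    y_norm = np.sqrt(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Mc.T @ yc) / (col_norm * y_norm)
    degenerate = col_norm < _EPS
    if degenerate.any() or y_norm < _EPS:
        fill = 1.0 if y_norm < _EPS else 0.0
        r = np.where(col_norm < _EPS, fill, r)
        if y_norm < _EPS:
            r = np.where(col_norm < _EPS, 1.0, 0.0)
    return np.asarray(r, dtype=float)


def pcqc_scores(corr: pd.DataFrame, profiles: pd.DataFrame | None = None,
                score_mode: str = "corr-rows") -> tuple[pd.Series, float]:
    """Correlation of each sample with PCqc, plus PC1's variance fraction.

    PCqc is the leading eigenvector of the sample correlation matrix, with its
    sign fixed so the mean loading is nonnegative. Under ``score_mode
    "profiles"`` (the operational default in :class:`PCOutlierFilter`) the raw
    expression profile is correlated with the PC1 metagene (the
    PCqc-weighted combination of samples; requires ``profiles``); under
    ``"corr-rows"`` each sample's score is the Pearson correlation of its row
    of the correlation matrix with PCqc. The corr-rows score degenerates on
    large homogeneous batches — the rows and the eigenvector both become
    near-constant, so their correlation is driven by noise — hence the
    profile-based score is preferred for filtering. The variance fraction is
    the leading eigenvalue over the trace.
    """
    c = corr.to_numpy(dtype=float)
    evals, evecs = np.linalg.eigh(c)
    lead = evals[-1]
    v = evecs[:, -1]
    if v.mean() < 0:
        v = -v
    frac = float(lead / np.trace(c))

    if score_mode == "corr-rows":
        scores = _colwise_pearson(c, v)  # symmetric: columns are rows
    elif score_mode == "profiles":
        if profiles is None:
            raise ValueError("score_mode 'profiles' requires the expression matrix")
        metagene = profiles.to_numpy() @ v
        scores = _colwise_pearson(profiles.to_numpy(), metagene)
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")
    return pd.Series(scores, index=corr.index, name="pcqc_correlation"), frac


def filter_outliers(scores: pd.Series, threshold: float = DEFAULT_THRESHOLD
                    ) -> tuple[list[str], list[str]]:
    """Partition samples into (kept, removed); removal is strict ``< threshold``."""
    s = scores.to_numpy(dtype=float)
    if (np.abs(s) > 1 + 1e-9).any():
        raise ValueError("scores must lie in [-1, 1]")
    kept = list(scores.index[s >= threshold])
    removed = list(scores.index[s < threshold])
    return kept, removed


class PCOutlierFilter:
    """Outlier-array filter: fit PCqc on a batch, drop low-correlation samples.

    Parameters
    ----------
    threshold : float
        Samples with PCqc correlation strictly below this are removed.
    score_mode : str
        "corr-rows" (score against rows of the correlation matrix) or
        "profiles" (score the raw expression profile against the PC1
        metagene).

    Attributes (after fit)
    ----------------------
    scores_ : pd.Series, per-sample PCqc correlation
    pc1_variance_fraction_ : float
    kept_ : list of kept sample ids
    removed_ : list of removed sample ids
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD,
                 score_mode: str = "profiles"):
        self.threshold = threshold
        self.score_mode = score_mode

    # minimal sklearn-style parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold, "score_mode": self.score_mode}

    def set_params(self, **params) -> "PCOutlierFilter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, data: pd.DataFrame, y=None) -> "PCOutlierFilter":
        corr = sample_correlation_matrix(data)
        self.scores_, self.pc1_variance_fraction_ = pcqc_scores(
            corr, profiles=data, score_mode=self.score_mode
        )
        self.kept_, self.removed_ = filter_outliers(self.scores_, self.threshold)
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        return data[[s for s in data.columns if s in set(self.kept_)]]

    def fit_transform(self, data: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(data).transform(data)


def run_batch_qc(batch: ExpressionBatch, threshold: float = DEFAULT_THRESHOLD,
                 score_mode: str = "profiles") -> tuple[ExpressionBatch, QCReport]:
    """Deduplicate then PCqc-filter one batch; returns the clean batch + report."""
    dedup, dup_report = deduplicate(batch)
    filt = PCOutlierFilter(threshold=threshold, score_mode=score_mode).fit(dedup.data)
    clean = ExpressionBatch(batch.batch_id, filt.transform(dedup.data))

    digests = dict(zip(dup_report["sample_id"], dup_report["digest"]))
    dup_of = dict(zip(dup_report["sample_id"], dup_report["duplicate_of"]))
    rows = []
    for s in batch.sample_ids:
        if dup_of[s]:
            rows.append((s, digests[s], dup_of[s], np.nan, False))
        else:
            score = float(filt.scores_[s])
            rows.append((s, digests[s], "", score, score >= threshold))
    table = pd.DataFrame(
        rows, columns=["sample_id", "digest", "duplicate_of", "pcqc_correlation", "kept"]
    )
    report = QCReport(batch.batch_id, table, filt.pc1_variance_fraction_, threshold)
    return clean, report
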