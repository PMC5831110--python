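"""Cohort summaries and expression-stratified survival comparisons.

Covers the downstream clinical questions asked of a prioritized target:
does its expression differ across disease subtypes (Kruskal-Wallis), and
does a high/low expression split stratify overall survival within a
treatment arm (Kaplan-Meier curves, log-rank test, O/E hazard ratio)?
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "percent",
    "summarize_cohort",
    "kruskal_wallis",
    "dichotomize_expression",
    "km_estimator",
    "logrank_hr",
    "SurvivalComparison",
    "KMCurve",
]


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage with round-half-up at the given number of decimals."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) / Decimal(total) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


def summarize_cohort(table: pd.DataFrame,
                     fields: Sequence[str] = ("arm", "coo")) -> pd.DataFrame:
    """Availability and composition summary of categorical clinical fields.

    For each field: the count and percentage of the cohort with a non-missing
    value, then per level the count and percentage of the available records.
    Percentages are rounded half-up to one decimal; an integer-rounded form is
    included for prose-style reporting.
    """
    total = len(table)
    rows = []
    for fieldname in fields:
        if fieldname in table.columns:
            col = table[fieldname]
            avail = col.notna() & (col.astype(str).str.strip() != "")
        else:
            avail = pd.Series(False, index=table.index)
        n_avail = int(avail.sum())
        rows.append((fieldname, "<available>", n_avail,
                     percent(n_avail, total), percent(n_avail, total, 0)))
        if n_avail:
            counts = table.loc[avail, fieldname].value_counts()
            for level, n in counts.items():
                rows.append((fieldname, str(level), int(n),
                             percent(int(n), n_avail), percent(int(n), n_avail, 0)))
    return pd.DataFrame(rows, columns=["field", "level", "n", "pct", "pct_int"])


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]
                   ) -> tuple[float, float]:
    """Kruskal-Wallis H over midranks with tie correction; chi-square p."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    parts = [values[groups == lv] for lv in levels]
    for lv, part in zip(levels, parts):
        if part.size == 0:
            raise ValueError(f"group {lv!r} is empty")
    h, p = stats.kruskal(*parts)
    return float(h), float(p)


_RULES = {"median": 0.5, "tertile-top": 2.0 / 3.0}


def dichotomize_expression(values: Sequence[float],
                           rule: str | float = "median") -> np.ndarray:
    """Split expression into "high"/"low" labels at a quantile cut-point.

    The default median split labels values strictly above the median "high";
    ties at the cut-point go to "low". ``rule`` may be "median",
    "tertile-top", or a quantile in (0, 1).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.isfinite(x).all():
        raise ValueError("need >= 2 finite expression values")
    if np.ptp(x) == 0:
        raise ValueError("all expression values identical; no split possible")
    q = _RULES[rule] if isinstance(rule, str) else float(rule)
    if not 0 < q < 1:
        raise ValueError(f"quantile rule must lie in (0, 1), got {q}")
    cut = np.quantile(x, q)
    return np.where(x > cut, "high", "low")


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def km_estimator(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit survival estimate with right censoring."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("survival times must be nonnegative")
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    fitter = KaplanMeierFitter()
    fitter.fit(t, event_observed=e)
    sf = fitter.survival_function_
    return KMCurve(times=sf.index.to_numpy(dtype=float),
                   survival=sf.iloc[:, 0].to_numpy(dtype=float))


@dataclass
class SurvivalComparison:
    """Log-rank comparison of two groups with an O/E hazard ratio."""

    chi_square: float
    p: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    n: tuple[int, int]


def logrank_hr(times1: Sequence[float], events1: Sequence[int],
               times2: Sequence[float], events2: Sequence[int],
               alpha: float = 0.05) -> SurvivalComparison:
    """Two-group log-rank test and observed/expected hazard ratio.

    At every distinct event time the standard 2x2 risk-set table contributes
    observed events, expected events (hypergeometric mean) and variance; the
    chi-square is (O1 - E1)^2 / V with 1 df, the hazard ratio is
    (O1/E1) / (O2/E2) with CI exp(ln HR +- z * sqrt(1/E1 + 1/E2)). Tied event
    times are handled by simultaneous risk-set accounting.
    """
    t1 = np.asarray(times1, dtype=float)
    e1 = np.asarray(events1, dtype=int)
    t2 = np.asarray(times2, dtype=float)
    e2 = np.asarray(events2, dtype=int)
    for t in (t1, t2):
        if (t < 0).any():
            raise ValueError("survival times must be nonnegative")
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events in the pooled data")

    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O1 = float(e1.sum())
    O2 = float(e2.sum())
    E1 = E2 = V = 0.0
    for t in event_times:
        n1 = float((t1 >= t).sum())
        n2 = float((t2 >= t).sum())
        n = n1 + n2
        d1 = float(((t1 == t) & (e1 == 1)).sum())
        d2 = float(((t2 == t) & (e2 == 1)).sum())
        d = d1 + d2
        E1 += d * n1 / n
        E2 += d * n2 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)

    if E1 <= 0 or E2 <= 0:
        raise ValueError("a group has zero expected events; comparison undefined")
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    hr = (O1 / E1) / (O2 / E2)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(1.0 / E1 + 1.0 / E2)
    return SurvivalComparison(
        chi_square=float(chi2), p=p, hazard_ratio=float(hr),
        ci_low=float(hr * np.exp(-half)), ci_high=float(hr * np.exp(half)),
        observed=(O1, O2), expected=(float(E1), float(E2)),
        n=(len(t1), len(t2)),
    )


def survival_by_group(clinical: pd.DataFrame, group_col: str = "group",
                      arm_col: str = "arm", coo_col: str = "coo"
                      ) -> pd.DataFrame:
    """Log-rank HR of group "high" vs "low" within each arm x subtype stratum."""
    rows = []
    for (arm, coo), sub in clinical.groupby([arm_col, coo_col]):
        hi = sub[sub[group_col] == "high"]
        lo = sub[sub[group_col] == "low"]
        if len(hi) < 2 or len(lo) < 2:
            continue
        try:
            cmp = logrank_hr(hi["time"], hi["event"], lo["time"], lo["event"])
        except ValueError:
            continue
        rows.append((arm, coo, len(hi), len(lo), cmp.observed[0], cmp.expected[0],
                     cmp.observed[1], cmp.expected[1], cmp.hazard_ratio,
                     cmp.ci_low, cmp.ci_high, cmp.p))
    return pd.DataFrame(rows, columns=[
        "arm", "coo", "n_high", "n_low", "O_high", "E_high", "O_low", "E_low",
        "HR", "CI_low", "CI_high", "p",
    ])
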