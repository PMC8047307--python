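"""Inter-structure variability and association statistics.

Covers the descriptive layer of the analysis: coefficients of variation of
contoured volumes, paired comparisons of covering doses between half-brain
and temporal lobe (with per-case percent reductions), Pearson correlation
among dosimetric metrics, and chi-square association tests for clinical
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dvh import evaluate_metric

__all__ = [
    "PairedComparison",
    "coefficient_of_variation",
    "paired_t_test",
    "reduction_table",
    "pearson_matrix",
    "chi_square_association",
]


@dataclass
class PairedComparison:
    """Paired half-brain vs temporal-lobe comparison of one metric."""

    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_difference: float
    sd_difference: float
    mean_percent_reduction: float
    sd_percent_reduction: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    n: int
    n_excluded_zero_reference: int = 0
    degenerate: bool = False


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean.

    Requires at least two values and a positive mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("coefficient of variation requires n >= 2")
    mean = x.mean()
    if mean <= 0:
        raise ValueError(f"coefficient of variation requires a positive mean, got {mean}")
    return float(100.0 * x.std(ddof=1) / mean)


def paired_t_test(x: Sequence[float], y: Sequence[float]):
    """Two-sided paired t-test: t = mean(x-y) / (sd(x-y)/sqrt(n)), df = n-1.

    Zero-variance differences yield a degenerate flagged result (t and p NaN)
    rather than an exception.

    Returns ``(t, df, p, degenerate)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        return np.nan, n - 1, np.nan, True
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(p), False


def reduction_table(cohort, metrics: Sequence[str], unit: str = "side") -> pd.DataFrame:
    """Half-brain vs temporal-lobe comparison table across a cohort.

    For each metric, every analysis unit pairs the half-brain covering dose
    with the temporal-lobe one; the per-case percent reduction is
    ``100 * (HB - TL) / HB``.  ``unit='side'`` treats each side as a unit
    (two per patient); ``unit='patient'`` averages the two sides first.
    Cases with a zero half-brain reference are excluded from the
    percent-reduction averages and counted.
    """
    if len(cohort) == 0:
        raise ValueError("reduction_table requires a non-empty cohort")
    if unit not in ("side", "patient"):
        raise ValueError(f"unit must be 'side' or 'patient', got {unit!r}")
    rows = []
    for metric in metrics:
        hb, tl = [], []
        for rec in cohort:
            pair_hb = [evaluate_metric(rec.curves[f"half_brain_{s}"], metric) for s in "LR"]
            pair_tl = [evaluate_metric(rec.curves[f"temporal_{s}"], metric) for s in "LR"]
            if unit == "side":
                hb.extend(pair_hb)
                tl.extend(pair_tl)
            else:
                hb.append(np.mean(pair_hb))
                tl.append(np.mean(pair_tl))
        hb = np.asarray(hb)
        tl = np.asarray(tl)
        diff = hb - tl
        nonzero = hb > 0
        pct = 100.0 * diff[nonzero] / hb[nonzero]
        t, df, p, degenerate = paired_t_test(hb, tl)
        rows.append(
            PairedComparison(
                metric=metric,
                mean_a=float(hb.mean()),
                sd_a=float(hb.std(ddof=1)) if hb.size > 1 else np.nan,
                mean_b=float(tl.mean()),
                sd_b=float(tl.std(ddof=1)) if tl.size > 1 else np.nan,
                mean_difference=float(diff.mean()),
                sd_difference=float(diff.std(ddof=1)) if diff.size > 1 else np.nan,
                mean_percent_reduction=float(pct.mean()) if pct.size else np.nan,
                sd_percent_reduction=float(pct.std(ddof=1)) if pct.size > 1 else np.nan,
                t_statistic=t,
                degrees_of_freedom=df,
                p_value=p,
                n=int(hb.size),
                n_excluded_zero_reference=int((~nonzero).sum()),
                degenerate=degenerate,
            )
        )
    return pd.DataFrame([vars(r) for r in rows])


def pearson_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values (t transform, n-2 df).

    ``values`` is a DataFrame with one column per metric and one row per
    observation, or an iterable of :class:`~dvhtox.dvh.DosimetricVector`.
    Zero-variance metrics yield NaN entries (correlation undefined).
    """
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame([v.metrics for v in values])
    if len(values) < 3:
        raise ValueError("pearson_matrix requires at least 3 observations")
    cols = list(values.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    arr = values.to_numpy(dtype=float)
    sds = arr.std(axis=0)
    n = arr.shape[0]
    for i in range(k):
        if sds[i] == 0:
            continue
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            if sds[j] == 0:
                continue
            rij, pij = sps.pearsonr(arr[:, i], arr[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def chi_square_association(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2 x k table, no continuity
    correction; returns ``(chi2, df, p)``."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("contingency table must hold non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
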