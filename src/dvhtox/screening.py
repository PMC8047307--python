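"""ROC screening of dosimetric metrics for toxicity prediction.

Every candidate metric (D_V over a volume grid, V_D over a dose grid) is
scored against the injury labels: empirical AUC with a DeLong 95% interval,
and the Youden-optimal cutoff (maximising sensitivity + specificity - 1).
Sweeping the grids produces AUC profiles whose peak identifies the most
predictive covering volume / dose for each structure.

The risk direction is fixed a priori: a higher dose or hot volume means a
higher injury risk (scores are never auto-flipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dvh import DEFAULT_DOSE_GRID_GY, DEFAULT_VOLUME_GRID_CC, evaluate_metric, metric_name_d, metric_name_v

__all__ = [
    "ROCResult",
    "AUCProfile",
    "auc",
    "auc_ci",
    "youden_best_cutoff",
    "youden_index",
    "roc_result",
    "sweep_profiles",
    "best_cutoff_table",
    "metric_values",
]

Z_95 = 1.959963984540054


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


@dataclass
class ROCResult:
    """Empirical ROC summary for one metric: AUC, DeLong CI, Youden cutoff."""

    metric: str
    auc: float
    ci_low: float
    ci_high: float
    best_cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    n_pos: int
    n_neg: int
    roc_points: np.ndarray = field(repr=False, default=None)  # (1-Sp, Se) pairs
    degenerate_ci: bool = False
    ci_method: str = "delong"


@dataclass
class AUCProfile:
    """AUC as a function of the metric grid for one structure."""

    structure: str
    kind: str  # "D_V" (axis in cc) or "V_D" (axis in Gy)
    axis: np.ndarray
    auc_values: np.ndarray
    unit: str

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.auc_values))

    @property
    def peak_point(self) -> float:
        return float(self.axis[self.peak_index])

    @property
    def peak_auc(self) -> float:
        return float(self.auc_values[self.peak_index])


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    return pos, neg


def auc(scores, labels) -> float:
    """Empirical AUC: fraction of (positive, negative) pairs with a higher
    positive score, ties counted one half — the trapezoidal area under the
    empirical ROC, computed by the rank formula."""
    pos, neg = _split(scores, labels)
    m, n = pos.size, neg.size
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_components(pos, neg):
    m, n = pos.size, neg.size
    ranks_all = rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - rankdata(neg)) / m
    a = v10.mean()
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    return a, var


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong structural-components normal interval for the AUC, truncated to
    [0, 1].  A degenerate variance collapses the interval to the estimate."""
    pos, neg = _split(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("auc_ci requires at least two units per class")
    from scipy.stats import norm

    a, var = _delong_components(pos, neg)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, a - half)), float(min(1.0, a + half))


def youden_best_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """Scan all midpoints between consecutive distinct scores for the cutoff
    maximising the Youden index (classify positive when score >= cutoff).

    Ties are broken toward higher sensitivity, then toward the lower cutoff.
    Returns ``(cutoff, sensitivity, specificity, youden)``.
    """
    pos, neg = _split(scores, labels)
    u = np.unique(np.concatenate([pos, neg]))
    if u.size == 1:
        # single distinct score: any midpoint is undefined; cutoff at the value
        return float(u[0]), 1.0, 0.0, 0.0
    cuts = 0.5 * (u[:-1] + u[1:])
    m, n = pos.size, neg.size
    # integer counts keep exactly tied Youden values exactly tied
    tp = m - np.searchsorted(np.sort(pos), cuts, side="left")
    tn = np.searchsorted(np.sort(neg), cuts, side="left")
    j_scaled = tp * n + tn * m - m * n  # Youden * (m*n)
    # lexsort: last key is primary; prefer high J, then high Se, then low cutoff
    order = np.lexsort((cuts, -tp, -j_scaled))
    best = order[0]
    return (float(cuts[best]), float(tp[best] / m), float(tn[best] / n),
            float(j_scaled[best] / (m * n)))


def roc_result(scores, labels, metric: str = "") -> ROCResult:
    """Full ROC summary of one metric (AUC, DeLong CI, Youden cutoff, curve)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    a = auc(scores, labels)
    pos, neg = _split(scores, labels)
    _, var = _delong_components(pos, neg)
    degenerate = var == 0.0
    if degenerate:
        lo = hi = a
    else:
        lo, hi = auc_ci(scores, labels)
    cutoff, se, sp, j = youden_best_cutoff(scores, labels)
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    return ROCResult(
        metric=metric,
        auc=a,
        ci_low=lo,
        ci_high=hi,
        best_cutoff=cutoff,
        sensitivity=se,
        specificity=sp,
        youden=j,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        roc_points=np.column_stack([fpr, tpr]),
        degenerate_ci=bool(degenerate),
    )


def metric_values(cohort, structure: str, metric: str, unit: str = "side",
                  scheme=None) -> tuple[np.ndarray, np.ndarray]:
    """Metric values and injury labels per analysis unit.

    ``structure`` is 'half_brain', 'temporal' or 'brain'.  With
    ``unit='side'`` each side of a lateral structure is one unit, paired with
    that side's label; with ``unit='patient'`` (forced for the brain) the
    per-patient maximum of the two sides is paired with the any-side label.
    """
    if structure == "brain":
        unit = "patient"
    vals, labels = [], []
    for rec in cohort:
        if structure == "brain":
            vals.append(evaluate_metric(rec.curves["brain"], metric, scheme))
            labels.append(rec.any_injury)
        elif unit == "side":
            for side in "LR":
                vals.append(evaluate_metric(rec.curves[f"{structure}_{side}"], metric, scheme))
                labels.append(rec.injury(side))
        elif unit == "patient":
            vals.append(
                max(evaluate_metric(rec.curves[f"{structure}_{s}"], metric, scheme) for s in "LR")
            )
            labels.append(rec.any_injury)
        else:
            raise ValueError(f"unit must be 'side' or 'patient', got {unit!r}")
    return np.asarray(vals), np.asarray(labels, dtype=bool)


def sweep_profiles(
    cohort,
    structure: str,
    volume_grid_cc: Sequence[float] = DEFAULT_VOLUME_GRID_CC,
    dose_grid_gy: Sequence[float] = DEFAULT_DOSE_GRID_GY,
    unit: str = "side",
    scheme=None,
) -> tuple[AUCProfile, AUCProfile]:
    """AUC of every D_V and V_D grid point for one structure.

    Returns the pair of profiles (D_V over the volume grid, V_D over the dose
    grid), each carrying its peak.
    """
    if len(cohort) == 0:
        raise ValueError("sweep_profiles requires a non-empty cohort")
    if structure == "brain":
        unit = "patient"
    dv = np.array(
        [auc(*metric_values(cohort, structure, metric_name_d(v), unit, scheme))
         for v in volume_grid_cc]
    )
    vd = np.array(
        [auc(*metric_values(cohort, structure, metric_name_v(d), unit, scheme))
         for d in dose_grid_gy]
    )
    return (
        AUCProfile(structure, "D_V", np.asarray(volume_grid_cc, dtype=float), dv, unit),
        AUCProfile(structure, "V_D", np.asarray(dose_grid_gy, dtype=float), vd, unit),
    )


def best_cutoff_table(cohort, structures: Sequence[str], selected_metrics: Sequence[str],
                      unit: str = "side", scheme=None) -> pd.DataFrame:
    """One ROC summary row per (structure, metric) pair."""
    rows = []
    for structure in structures:
        for metric in selected_metrics:
            vals, labels = metric_values(cohort, structure, metric, unit, scheme)
            res = roc_result(vals, labels, metric)
            rows.append(
                {
                    "structure": structure,
                    "metric": metric,
                    "AUC": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "cutoff": res.best_cutoff,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "youden": res.youden,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                }
            )
    return pd.DataFrame(rows)
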