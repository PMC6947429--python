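"""Opt-out decision-curve analysis with standardized net benefit.

A prediction rule estimates each patient's risk of being in the
low-clearance state (urea clearance below the guideline cutoff).  Under
the opt-out framing, patients whose predicted risk falls below a
threshold R may opt out of the thrice-weekly dialysis standard.  The
threshold encodes the cost-benefit valuation R = C / (C + B), and the
standardized net benefit at that threshold discounts the true-negative
rate by the prevalence-weighted false-negative rate:

    SNB = TNR - prevalence / (1 - prevalence) * (B/C) * FNR

The standard of care (nobody opts out) has TNR = FNR = SNB = 0; a perfect
rule attains SNB = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "DecisionCurvePoint",
    "threshold_from_cost_benefit",
    "benefit_cost_from_threshold",
    "confusion_at_threshold",
    "snb_opt_out",
    "decision_curve",
    "prevalence_sensitivity",
    "DEFAULT_PREVALENCE_SET",
]

DEFAULT_PREVALENCE_SET = (0.1, 0.3, 0.5, 0.7, 0.9)
CURVE_COLUMNS = ["threshold", "bc_ratio", "tnr", "fnr", "snb", "prevalence"]


@dataclass(frozen=True)
class DecisionCurvePoint:
    """One point of an opt-out decision curve."""

    threshold: float
    benefit_cost: float
    prevalence: float
    tnr: float
    fnr: float
    snb: float


def threshold_from_cost_benefit(cost: float, benefit: float) -> float:
    """Optimal risk threshold R = C / (C + B) for a cost-benefit pair."""
    if cost < 0 or benefit < 0:
        raise ValueError("cost and benefit must be non-negative")
    if cost + benefit == 0:
        raise ValueError("cost + benefit must be positive")
    return cost / (cost + benefit)


def benefit_cost_from_threshold(threshold: float) -> float:
    """Benefit:cost ratio implied by a risk threshold, (1 - R) / R."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    return (1.0 - threshold) / threshold


def confusion_at_threshold(risk_of_low_clearance, true_low_clearance_labels,
                           threshold: float) -> tuple[float, float]:
    """(TNR, FNR) of the opt-out rule at a risk threshold.

    A patient opts out (is labeled as having preserved clearance) when
    the predicted risk of the low-clearance state is strictly below the
    threshold; ties go to no opt-out.  TNR is the fraction of truly
    high-clearance patients who opt out; FNR the fraction of truly
    low-clearance patients who (incorrectly) opt out.
    """
    r = np.asarray(risk_of_low_clearance, dtype=float)
    y = np.asarray(true_low_clearance_labels).astype(int)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risks must lie in [0, 1]")
    opt_out = r < threshold
    n_high = int((y == 0).sum())
    if n_high == 0:
        raise ValueError("TNR undefined: no truly high-clearance patients")
    tnr = float(opt_out[y == 0].mean())
    fnr = float(opt_out[y == 1].mean()) if (y == 1).any() else 0.0
    return tnr, fnr


def snb_opt_out(tnr: float, fnr: float, prevalence: float,
                benefit_cost: float) -> float:
    """Standardized net benefit of an opt-out rule.

    ``prevalence`` is the prevalence of the low-clearance ("case") state;
    ``benefit_cost`` the benefit:cost ratio B/C.
    """
    if not 0.0 <= prevalence < 1.0:
        raise ValueError("prevalence must lie in [0, 1)")
    if benefit_cost <= 0:
        raise ValueError("benefit_cost must be positive")
    if not (0.0 <= tnr <= 1.0 and 0.0 <= fnr <= 1.0):
        raise ValueError("TNR and FNR must lie in [0, 1]")
    return tnr - prevalence / (1.0 - prevalence) * benefit_cost * fnr


def decision_curve(risks, labels, threshold_grid=None,
                   prevalence: float | None = None,
                   smooth: bool = False, smooth_span: float = 0.3,
                   ) -> pd.DataFrame:
    """Opt-out decision curve over a grid of risk thresholds.

    The benefit:cost ratio at each threshold follows from inverting
    R = C/(C+B).  ``prevalence`` defaults to the empirical prevalence of
    the low-clearance label; override it for sensitivity analyses (TNR
    and FNR are class-conditional, so they are reused unchanged).  With
    ``smooth=True`` a loess-smoothed SNB column ``snb_smooth`` is added
    for display; the raw points are always retained.
    """
    if threshold_grid is None:
        threshold_grid = np.linspace(0.01, 0.99, 99)
    grid = np.asarray(threshold_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    y = np.asarray(labels).astype(int)
    prev = float(y.mean()) if prevalence is None else float(prevalence)
    rows = []
    for t in grid:
        tnr, fnr = confusion_at_threshold(risks, y, t)
        bc = benefit_cost_from_threshold(t)
        rows.append((t, bc, tnr, fnr, snb_opt_out(tnr, fnr, prev, bc), prev))
    out = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    if smooth and len(out) >= 5:
        out["snb_smooth"] = lowess(out["snb"], out["threshold"],
                                   frac=smooth_span, return_sorted=False)
    return out


def prevalence_sensitivity(risks, labels, threshold_grid=None,
                           prevalence_set=DEFAULT_PREVALENCE_SET,
                           ) -> pd.DataFrame:
    """Decision curves recomputed under assumed case prevalences.

    TNR and FNR are estimated once from the data (they are conditional on
    the true class); only the prevalence weight in the SNB changes.
    Returns the concatenated curves with a ``prevalence`` column.
    """
    for p in prevalence_set:
        if not 0.0 < p < 1.0:
            raise ValueError("prevalences must lie strictly in (0, 1)")
    curves = [decision_curve(risks, labels, threshold_grid, prevalence=p)
              for p in prevalence_set]
    return pd.concat(curves, ignore_index=True)
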