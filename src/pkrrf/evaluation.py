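"""Discrimination, calibration and error metrics for RRF predictions.

Covers rank-based AUC, linear/logistic calibration regressions
(calibration-in-the-large and calibration slope), probability calibration
metrics (Brier score, Spiegelhalter test, Somers' D, unreliability index)
and the bias/spread/precision summaries used for continuous clearance
predictions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "roc_auc",
    "calibration_linear",
    "binary_calibration_metrics",
    "continuous_error_metrics",
    "somers_d",
]


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2 or not set(classes) <= {0, 1, False, True}:
        raise ValueError("labels must contain both classes, coded 0/1")
    return y.astype(int)


def roc_auc(scores, binary_labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) statistic.

    Ties in the scores are handled with midranks, so the value equals the
    probability that a random positive outranks a random negative, with
    ties counted as half.
    """
    y = _check_binary(binary_labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be the same length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def somers_d(scores, binary_labels) -> float:
    """Somers' rank correlation D_xy = 2 AUC - 1."""
    return 2.0 * roc_auc(scores, binary_labels) - 1.0


def calibration_linear(predictions, observations, *, binary: bool | None = None,
                       ) -> tuple[float, float]:
    """Calibration intercept and slope of observed against predicted.

    For continuous observations this is the OLS regression of the
    observed values on the predictions (ideal: intercept 0, slope 1).
    For binary observations (detected automatically, or forced with
    ``binary=``) a logistic recalibration regression is fitted with the
    prediction's logit as the covariate.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 points")
    if np.var(p) == 0:
        raise ValueError("slope unidentifiable: constant predictions")
    if binary is None:
        binary = set(np.unique(o)) <= {0.0, 1.0}
    if binary:
        lp = _logit(np.clip(p, 1e-12, 1 - 1e-12))
        model = sm.GLM(o, sm.add_constant(lp), family=sm.families.Binomial())
        res = model.fit()
        return float(res.params[0]), float(res.params[1])
    res = sm.OLS(o, sm.add_constant(p)).fit()
    return float(res.params[0]), float(res.params[1])


def _logit(p):
    return np.log(p / (1.0 - p))


def binary_calibration_metrics(probabilities, outcomes) -> dict:
    """Probability-calibration summary for a binary prediction rule.

    Returns the Brier score (mean squared error of the probabilities),
    the Spiegelhalter z statistic and two-sided p-value, Somers' D
    (2 AUC - 1) and the unreliability index: the likelihood-ratio
    statistic (with its chi-square 2-df p-value) for the joint hypothesis
    that the logistic recalibration regression has intercept 0 and
    slope 1.
    """
    p = np.asarray(probabilities, dtype=float)
    y = _check_binary(outcomes).astype(float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    brier = float(np.mean((y - p) ** 2))

    var_terms = (1 - 2 * p) ** 2 * p * (1 - p)
    keep = var_terms > 0
    if not keep.all():
        warnings.warn("dropping predictions with p(1-p)=0 from the "
                      "Spiegelhalter statistic", stacklevel=2)
    num = float(np.sum((y - p) * (1 - 2 * p)))
    den = float(np.sqrt(np.sum(var_terms[keep])))
    z = num / den if den > 0 else np.nan
    p_spieg = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan

    pc = np.clip(p, 1e-12, 1 - 1e-12)
    lp = _logit(pc)
    free = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    # null model: intercept 0, slope 1 (pure offset)
    ll_null = float(np.sum(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    lr = 2 * (free.llf - ll_null)
    return {
        "brier": brier,
        "spiegelhalter_z": float(z),
        "spiegelhalter_p": float(p_spieg),
        "somers_d": somers_d(p, y.astype(int)),
        "unreliability_lr": float(lr),
        "unreliability_p": float(stats.chi2.sf(max(lr, 0.0), df=2)),
    }


def continuous_error_metrics(predictions, observations,
                             within=(0.5, 1.0, 2.0)) -> dict:
    """Bias, spread and precision of continuous clearance predictions.

    Errors are prediction minus observation (mL/min).  Quantiles use
    linear interpolation so the IQR is reproducible across platforms.
    ``within`` lists the absolute-agreement windows reported as
    proportions.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if len(p) == 0 or len(p) != len(o):
        raise ValueError("predictions and observations must be equal-length "
                         "and non-empty")
    err = p - o
    q75, q25 = np.percentile(err, [75, 25], method="linear")
    out = {
        "median_error": float(np.median(err)),
        "mae": float(np.mean(np.abs(err))),
        "iqr": float(q75 - q25),
        "rmse": float(np.sqrt(np.mean(err ** 2))),
    }
    for d in within:
        out[f"within_{d}"] = float(np.mean(np.abs(err) <= d))
    return out
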