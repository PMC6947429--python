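"""Dialytic B2M clearance from session observables.

Two estimators are provided: the classical single-pool variable-volume
closed form (the Leypoldt approach — treatment duration, ultrafiltration
volume, body weight and the pre/post concentration ratio), and a Matérn
Gaussian-process emulator trained on simulated cohorts where the true
dialyzer clearance is known.  The closed form neglects generation,
non-dialytic clearance and the second pool, so it is biased in realistic
two-pool patients; the emulator learns those corrections from the
simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = [
    "leypoldt_clearance",
    "ClearanceEmulator",
    "ClearanceEmulatorResults",
    "fit_clearance_emulator",
    "CLEARANCE_FEATURES",
]

CLEARANCE_FEATURES = ["pre_b2m", "post_b2m", "weight", "duration", "uf_volume"]


def leypoldt_clearance(pre_b2m, post_b2m, weight, uf_volume, duration,
                       volume_fraction: float = 0.2):
    """Single-pool variable-volume estimate of dialyzer clearance, mL/min.

    The postdialysis distribution volume is taken as
    ``volume_fraction * weight`` (liters; default 0.2, the conventional
    extracellular-distribution assumption for B2M), the predialysis
    volume adds the ultrafiltration volume, and the clearance solves the
    one-compartment mass balance with generation and non-dialytic removal
    neglected:

        K = Q_UF * [1 + ln(pre/post) / ln(V_pre/V_post)]

    with the continuous limit K = (V/duration) * ln(pre/post) as
    Q_UF -> 0.  Accepts scalars or aligned arrays.
    """
    pre = np.asarray(pre_b2m, dtype=float)
    post = np.asarray(post_b2m, dtype=float)
    w = np.asarray(weight, dtype=float)
    uf = np.asarray(uf_volume, dtype=float)
    td = np.asarray(duration, dtype=float)
    if np.any(post <= 0) or np.any(pre <= 0):
        raise ValueError("B2M concentrations must be positive")
    if np.any(td <= 0):
        raise ValueError("duration must be positive")
    if np.any(uf < 0):
        raise ValueError("uf_volume must be non-negative")
    scalar = pre.ndim == 0
    pre, post, w, uf, td = np.atleast_1d(pre, post, w, uf, td)
    pre, post, w, uf, td = np.broadcast_arrays(pre, post, w, uf, td)

    v_post = volume_fraction * w
    v_pre = v_post + uf
    q_uf = uf / td
    ratio = np.log(pre / post)

    out = np.empty_like(pre, dtype=float)
    has_uf = uf > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[has_uf] = (q_uf * (1.0 + ratio / np.log(v_pre / v_post)))[has_uf]
    out[~has_uf] = (v_post / td * ratio)[~has_uf]

    neg = ratio < 0
    if np.any(neg & ~has_uf):
        warnings.warn("postdialysis B2M >= predialysis with no ultrafiltration; "
                      "returning 0 clearance", stacklevel=2)
        out[neg & ~has_uf] = 0.0
    out *= 1000.0  # L/min -> mL/min
    return float(out[0]) if scalar else out


@dataclass
class ClearanceEmulatorResults:
    """Fitted clearance emulator with hold-out diagnostics.

    ``diagnostics`` (median_bias, mean_bias, iqr, sd of prediction - truth,
    mL/min) are computed on the hold-out split when one was requested.
    """

    model: "ClearanceEmulator"
    gp: GaussianProcessRegressor
    diagnostics: dict | None

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Predicted dialyzer clearance, mL/min, clipped at 0."""
        X = self.model._design(records)
        return np.clip(self.gp.predict(X), 0.0, None)


class ClearanceEmulator:
    """Matérn-3/2 Gaussian-process emulator of dialyzer clearance.

    Inputs are the session observables (B2M concentrations on the log
    scale, weight, duration, ultrafiltration volume), standardized to the
    training span.  Above ``subset_cap`` rows a reproducible subset of
    the training data is used (subset-of-data sparse approximation);
    kernel hyperparameters start at unit length scales on the
    standardized scale and are refined by marginal-likelihood
    optimization.
    """

    def __init__(self, train: pd.DataFrame, features=None, *,
                 subset_cap: int = 1500, seed: int = 0,
                 optimize_hyperparameters: bool = True):
        features = list(features) if features is not None else list(CLEARANCE_FEATURES)
        missing = [c for c in features + ["kd_true"] if c not in train.columns]
        if missing:
            raise ValueError(f"training table is missing columns: {missing}")
        self.features = features
        self.train = train.reset_index(drop=True)
        self.subset_cap = subset_cap
        self.seed = seed
        self.optimize_hyperparameters = optimize_hyperparameters
        self._mu = None
        self._sd = None

    def _raw_design(self, records: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in self.features:
            x = records[c].to_numpy(dtype=float)
            if c in ("pre_b2m", "post_b2m"):
                x = np.log(x)
            cols.append(x)
        return np.column_stack(cols)

    def _design(self, records: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.features if c not in records.columns]
        if missing:
            raise ValueError(f"records are missing columns: {missing}")
        X = self._raw_design(records)
        return (X - self._mu) / self._sd

    def fit(self) -> ClearanceEmulatorResults:
        df = self.train
        rng = np.random.default_rng(self.seed)
        if len(df) > self.subset_cap:
            idx = np.sort(rng.choice(len(df), self.subset_cap, replace=False))
            df_fit = df.iloc[idx]
        else:
            df_fit = df
        Xr = self._raw_design(df_fit)
        self._mu = Xr.mean(axis=0)
        self._sd = np.where(Xr.std(axis=0) > 0, Xr.std(axis=0), 1.0)
        X = (Xr - self._mu) / self._sd
        y = df_fit["kd_true"].to_numpy(dtype=float)

        kernel = (ConstantKernel(1.0, (1e-3, 1e4))
                  * Matern(length_scale=2.0 * np.ones(X.shape[1]),
                           length_scale_bounds=(1e-2, 1e2), nu=1.5)
                  + WhiteKernel(0.1, (1e-8, 1e2)))
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True,
            optimizer="fmin_l_bfgs_b" if self.optimize_hyperparameters else None,
            n_restarts_optimizer=3 if self.optimize_hyperparameters else 0,
            random_state=self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(X, y)
        return ClearanceEmulatorResults(model=self, gp=gp, diagnostics=None)


def clearance_error_summary(predicted, truth) -> dict:
    """Bias/spread summary of clearance errors (predicted - truth), mL/min."""
    err = np.asarray(predicted, dtype=float) - np.asarray(truth, dtype=float)
    q75, q25 = np.percentile(err, [75, 25])
    return {
        "median_bias": float(np.median(err)),
        "mean_bias": float(np.mean(err)),
        "iqr": float(q75 - q25),
        "sd": float(np.std(err, ddof=1)),
    }


def fit_clearance_emulator(train: pd.DataFrame, test: pd.DataFrame | None = None,
                           **kwargs) -> ClearanceEmulatorResults:
    """Fit the GP emulator; if ``test`` is given, attach hold-out diagnostics."""
    res = ClearanceEmulator(train, **kwargs).fit()
    if test is not None:
        res.diagnostics = clearance_error_summary(res.predict(test),
                                                  test["kd_true"].to_numpy())
    return res
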