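"""PK-RRF estimating equations fitted to simulated cohorts.

Two feature sets are supported: a *basic* equation using only the
predialysis B2M concentration, and a *clearance-based* equation that
additionally feeds the raw session observables (postdialysis B2M, body
weight, treatment duration, ultrafiltration volume) to a multi-input
Matérn Gaussian process, letting the smoother account for dialytic
removal without computing an explicit clearance first.  Each feature set
comes in a logistic flavour (probability that residual renal clearance is
at or above a cutoff — by default the RRF-scale image 2/0.751 ~ 2.66
mL/min of the 2 mL/min urea-clearance guideline threshold) and a
continuous flavour (RRF in mL/min, clipped at zero, convertible to the
urea-clearance scale).

B2M concentrations enter all smoothers on the log scale (they are
right-skewed).  The development protocol splits the simulated cohort
2/3 train : 1/3 test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam
from sklearn.gaussian_process import (GaussianProcessClassifier,
                                      GaussianProcessRegressor)
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .gfr_link import DEFAULT_URCL_SLOPE, rrf_to_urcl, urcl_cutoff_to_rrf

__all__ = [
    "SmootherSpec",
    "PKRRF",
    "PKRRFResults",
    "split_train_test",
    "fit_pkrrf",
    "predict_rrf",
    "BASIC_FEATURES",
    "CLEARANCE_FEATURES",
    "DEFAULT_RRF_CUTOFF",
]

BASIC_FEATURES = ["pre_b2m"]
CLEARANCE_FEATURES = ["pre_b2m", "post_b2m", "weight", "duration", "uf_volume"]
DEFAULT_RRF_CUTOFF = float(urcl_cutoff_to_rrf(2.0))  # ~2.66 mL/min
_LOG_COLS = ("pre_b2m", "post_b2m")


@dataclass(frozen=True)
class SmootherSpec:
    """Configuration of the flexible smoother behind a PK-RRF equation.

    ``kind`` is ``"spline"`` (penalized B-spline additive model) or
    ``"matern-gp"``.  ``basis_dim`` is the spline basis dimension per
    covariate; GP hyperparameters are a unit-amplitude Matérn 3/2 kernel
    with the given ``length_scale`` on standardized covariates.
    """

    kind: str = "spline"
    covariates: tuple[str, ...] = ("pre_b2m",)
    basis_dim: int = 20
    length_scale: float = 2.0
    link: str = "logit"

    def __post_init__(self):
        if self.kind not in ("spline", "matern-gp"):
            raise ValueError("kind must be 'spline' or 'matern-gp'")
        if self.basis_dim < 3:
            raise ValueError("basis_dim must be >= 3")
        if self.link not in ("logit", "identity"):
            raise ValueError("link must be 'logit' or 'identity'")


def split_train_test(table: pd.DataFrame, train_fraction: float = 2.0 / 3.0,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random partition into training and test subsets.

    The training size is the floor of ``train_fraction * n``; the two
    parts are disjoint and exhaustive.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    if len(table) < 10:
        raise ValueError("table must have at least 10 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    n_train = int(np.floor(train_fraction * len(table)))
    return (table.iloc[perm[:n_train]].reset_index(drop=True),
            table.iloc[perm[n_train:]].reset_index(drop=True))


def _design(records: pd.DataFrame, covariates) -> np.ndarray:
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing covariates: {missing}")
    cols = []
    for c in covariates:
        x = records[c].to_numpy(dtype=float)
        if c in _LOG_COLS:
            x = np.log(x)
        cols.append(x)
    return np.column_stack(cols)


class PKRRF:
    """Population-kinetic RRF estimating equation (model object).

    Parameters
    ----------
    train : DataFrame
        Simulated cohort records with ``rrf_true`` and the feature
        columns of the chosen feature set.
    feature_set : {"basic", "clearance"}
        ``"basic"`` uses predialysis B2M only; ``"clearance"`` adds the
        session observables.
    outcome : {"logistic", "continuous"}
        Binary preserved-RRF outcome (``rrf_true >= rrf_cutoff``) or the
        continuous RRF value.
    rrf_cutoff : float
        Cutoff on the RRF scale for the logistic outcome, mL/min.
    spec : SmootherSpec, optional
        Override the default smoother (spline for the basic set,
        Matérn GP for the clearance set).
    """

    def __init__(self, train: pd.DataFrame, feature_set: str = "basic",
                 outcome: str = "logistic",
                 rrf_cutoff: float = DEFAULT_RRF_CUTOFF,
                 spec: SmootherSpec | None = None, *,
                 seed: int = 0, subset_cap: int = 1200):
        if feature_set not in ("basic", "clearance"):
            raise ValueError("feature_set must be 'basic' or 'clearance'")
        if outcome not in ("logistic", "continuous"):
            raise ValueError("outcome must be 'logistic' or 'continuous'")
        covs = BASIC_FEATURES if feature_set == "basic" else CLEARANCE_FEATURES
        if spec is None:
            spec = SmootherSpec(
                kind="spline" if feature_set == "basic" else "matern-gp",
                covariates=tuple(covs),
                link="logit" if outcome == "logistic" else "identity")
        missing = [c for c in spec.covariates if c not in train.columns]
        if missing:
            raise ValueError(f"training table lacks covariates: {missing}")
        if "rrf_true" not in train.columns:
            raise ValueError("training table lacks 'rrf_true'")
        self.train = train.reset_index(drop=True)
        self.feature_set = feature_set
        self.outcome = outcome
        self.rrf_cutoff = float(rrf_cutoff)
        self.spec = spec
        self.seed = seed
        self.subset_cap = subset_cap

    def _target(self) -> np.ndarray:
        rrf = self.train["rrf_true"].to_numpy(dtype=float)
        if self.outcome == "logistic":
            y = (rrf >= self.rrf_cutoff).astype(int)
            if len(np.unique(y)) < 2:
                raise ValueError("degenerate outcome: a single class after "
                                 f"applying the {self.rrf_cutoff} cutoff")
            return y
        return rrf

    def fit(self) -> "PKRRFResults":
        y = self._target()
        X = _design(self.train, self.spec.covariates)
        rng = np.random.default_rng(self.seed)
        if len(X) > self.subset_cap and self.spec.kind == "matern-gp":
            idx = np.sort(rng.choice(len(X), self.subset_cap, replace=False))
            X, y = X[idx], y[idx]

        if self.spec.kind == "spline":
            df = min(self.spec.basis_dim, max(4, len(X) // 10))
            bs = BSplines(X, df=[df] * X.shape[1], degree=[3] * X.shape[1])
            family = (sm.families.Binomial() if self.outcome == "logistic"
                      else sm.families.Gaussian())
            alpha = np.ones(X.shape[1])
            gam = GLMGam(y, np.ones((len(X), 1)), smoother=bs, alpha=alpha,
                         family=family)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    alpha = gam.select_penweight()[0]
                    gam = GLMGam(y, np.ones((len(X), 1)), smoother=bs,
                                 alpha=alpha, family=family)
                except Exception:
                    pass
                fitted = gam.fit()
            span = (X.min(axis=0), X.max(axis=0))
            state = ("spline", bs, fitted, span)
        else:
            mu = X.mean(axis=0)
            sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
            Xs = (X - mu) / sd
            if self.outcome == "logistic":
                kernel = ConstantKernel(3.0, (1e-2, 1e3)) * Matern(
                    length_scale=self.spec.length_scale * np.ones(X.shape[1]),
                    length_scale_bounds=(1e-1, 1e2), nu=1.5)
                est = GaussianProcessClassifier(kernel=kernel,
                                                random_state=self.seed)
            else:
                kernel = (ConstantKernel(1.0, (1e-3, 1e4))
                          * Matern(length_scale=self.spec.length_scale
                                   * np.ones(X.shape[1]),
                                   length_scale_bounds=(1e-2, 1e2), nu=1.5)
                          + WhiteKernel(0.1, (1e-8, 1e2)))
                est = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                               n_restarts_optimizer=2,
                                               random_state=self.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xs, y)
            state = ("gp", (mu, sd), est)

        fitted_vals = self._predict_state(state, self.train)
        return PKRRFResults(model=self, state=state,
                            fitted_values=fitted_vals,
                            meta={"seed": self.seed, "n": len(self.train),
                                  "n_fit": len(X),
                                  "feature_set": self.feature_set,
                                  "outcome": self.outcome,
                                  "rrf_cutoff": self.rrf_cutoff})

    def _predict_state(self, state, records: pd.DataFrame) -> np.ndarray:
        X = _design(records, self.spec.covariates)
        kind = state[0]
        if kind == "spline":
            # B-spline bases are undefined outside the training knots;
            # covariates are clamped to the training span (flat
            # extrapolation at the boundaries)
            _, bs, fitted, (lo, hi) = state
            X = np.clip(X, lo, hi)
            exog = np.column_stack(
                [np.ones(len(X))]
                + [bs.smoothers[i].transform(X[:, [i]])
                   for i in range(X.shape[1])])
            out = fitted.model.family.link.inverse(exog @ fitted.params)
        else:
            _, (mu, sd), est = state
            Xs = (X - mu) / sd
            if self.outcome == "logistic":
                out = est.predict_proba(Xs)[:, 1]
            else:
                out = est.predict(Xs)
        if self.outcome == "continuous":
            out = np.clip(out, 0.0, None)
        return np.asarray(out, dtype=float)


@dataclass
class PKRRFResults:
    """A fitted PK-RRF equation.

    ``fitted_values`` are in-sample predictions on the training rows
    (probabilities of preserved RRF for the logistic outcome, RRF in
    mL/min for the continuous one).
    """

    model: PKRRF
    state: tuple
    fitted_values: np.ndarray
    meta: dict = field(default_factory=dict)

    def predict(self, records: pd.DataFrame, scale: str = "rrf") -> np.ndarray:
        """Predict for new records.

        Logistic models return the probability of preserved RRF
        regardless of ``scale``.  Continuous models return RRF in mL/min
        (``scale="rrf"``, clipped at zero) or the urea-clearance image
        (``scale="urcl"``, multiplied by the link slope).
        """
        out = self.model._predict_state(self.state, records)
        if self.model.outcome == "continuous" and scale == "urcl":
            out = rrf_to_urcl(out)
        elif scale not in ("rrf", "urcl"):
            raise ValueError("scale must be 'rrf' or 'urcl'")
        return out

    def predict_risk_low(self, records: pd.DataFrame) -> np.ndarray:
        """Predicted risk of the low-clearance state (1 - P(preserved))."""
        if self.model.outcome != "logistic":
            raise ValueError("risk predictions require a logistic model")
        return 1.0 - self.predict(records)

    def summary(self) -> str:
        m = self.meta
        lines = [
            f"PK-RRF equation ({m['feature_set']} features, {m['outcome']} outcome)",
            "=" * 60,
            f"smoother: {self.model.spec.kind}  covariates: "
            f"{', '.join(self.model.spec.covariates)}",
            f"training rows: {m['n']} (fitted on {m['n_fit']})  seed: {m['seed']}",
        ]
        if m["outcome"] == "logistic":
            lines.append(f"RRF cutoff: {m['rrf_cutoff']:.3f} mL/min "
                         f"(urea-clearance image of 2 mL/min)")
        return "\n".join(lines)


def fit_pkrrf(train: pd.DataFrame, feature_set: str = "basic",
              outcome: str = "logistic",
              spec: SmootherSpec | None = None, **kwargs) -> PKRRFResults:
    """Fit a PK-RRF equation (functional wrapper around :class:`PKRRF`)."""
    return PKRRF(train, feature_set, outcome, spec=spec, **kwargs).fit()


def predict_rrf(results: PKRRFResults, records: pd.DataFrame,
                scale: str = "rrf") -> np.ndarray:
    """Predict with a fitted PK-RRF equation (functional wrapper)."""
    return results.predict(records, scale=scale)
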