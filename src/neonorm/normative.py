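"""Gaussian-process normative models of volumetric development.

For every measure (an absolute segment volume in cm**3 or a relative volume)
a GP regression is fitted on the control cohort over three covariates: sex
(female = 0, male = 1), postmenstrual age at scan (weeks) and age from birth
(weeks).  The posterior supplies, at any covariate point, a predictive mean
and a predictive SD; an individual's deviation is

    z = (observed - predicted_mean) / predicted_sd

in SD units, with |z| >= 2.6 flagged as an extreme deviation (the top and
bottom ~0.5% of a standard normal).

Kernel: RBF with per-dimension length scales (local nonlinearity) + a linear
kernel (monotone growth trend) + independent Gaussian noise.  The predictive
SD deliberately includes the noise variance: z-scores of held-out controls
then have unit SD rather than SD > 1.  Covariates are standardized
internally; the target is centred/scaled by the regressor, which makes the
whole model equivariant under positive rescaling of the measure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, DotProduct, WhiteKernel

__all__ = [
    "COVARIATES",
    "EXTREME_Z",
    "FitError",
    "NotFittedError",
    "NormativeModel",
    "fit_normative",
    "zscore",
    "calibration_report",
]

COVARIATES = ("sex", "pma_scan", "age_from_birth")
EXTREME_Z = 2.6
_JITTER = 1e-8


class FitError(ValueError):
    """Raised when a normative fit is impossible on the given controls."""


class NotFittedError(RuntimeError):
    pass


def _design_matrix(demo: pd.DataFrame) -> np.ndarray:
    for c in ("sex", "pma_scan"):
        if c not in demo.columns:
            raise FitError(f"demographics table lacks required column {c!r}")
    sex = demo["sex"]
    if sex.dtype == object:
        sex01 = sex.map({"female": 0.0, "male": 1.0})
        if sex01.isna().any():
            raise FitError("sex must be 'female' or 'male'")
    else:
        sex01 = sex.astype(float)
    if "age_from_birth" in demo.columns:
        age = demo["age_from_birth"].astype(float)
    else:
        age = demo["pma_scan"].astype(float) - demo["ga_birth"].astype(float)
    X = np.column_stack([sex01.to_numpy(float),
                         demo["pma_scan"].to_numpy(float),
                         age.to_numpy(float)])
    if not np.all(np.isfinite(X)):
        raise FitError("missing or non-finite covariates")
    return X


def _default_kernel():
    return (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=[1.0, 1.0, 1.0], length_scale_bounds=(1e-2, 1e3))
        + ConstantKernel(0.1, (1e-4, 1e3)) * DotProduct(sigma_0=1.0, sigma_0_bounds=(1e-3, 1e3))
        + WhiteKernel(0.1, (1e-8, 1e1))
    )


@dataclass
class NormativeModel:
    """Fitted per-measure GP normative model.

    Use :func:`fit_normative` to construct; :meth:`predict` returns the
    predictive mean and SD (noise-inclusive) for new subjects.
    """

    measure_name: str
    _gp: GaussianProcessRegressor | None = None
    _x_mean: np.ndarray | None = None
    _x_sd: np.ndarray | None = None
    _train_range: dict | None = None
    _train_index: tuple | None = None
    n_train: int = 0

    # -- fitting -----------------------------------------------------------

    def fit(self, demo: pd.DataFrame, y, *, seed: int = 0, n_restarts: int = 5,
            optimize: bool = True, min_controls: int = 30,
            kernel=None) -> "NormativeModel":
        y = np.asarray(y, dtype=float)
        X = _design_matrix(demo)
        if len(y) != len(X):
            raise FitError("covariates and measure values differ in length")
        if len(y) < min_controls:
            raise FitError(f"need at least {min_controls} controls, got {len(y)}")
        if not np.all(np.isfinite(y)):
            raise FitError("measure values must be finite")
        if len(y) > 1 and np.ptp(y) == 0:
            raise FitError(f"degenerate measure {self.measure_name!r}: zero variance")
        self._x_mean = X.mean(axis=0)
        self._x_sd = X.std(axis=0)
        self._x_sd[self._x_sd == 0] = 1.0
        Xs = (X - self._x_mean) / self._x_sd
        self._gp = GaussianProcessRegressor(
            kernel=kernel if kernel is not None else _default_kernel(),
            alpha=_JITTER,
            normalize_y=True,
            n_restarts_optimizer=n_restarts if optimize else 0,
            optimizer="fmin_l_bfgs_b" if optimize else None,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter
            self._gp.fit(Xs, y)
        self._train_range = {
            "pma_scan": (float(X[:, 1].min()), float(X[:, 1].max())),
            "age_from_birth": (float(X[:, 2].min()), float(X[:, 2].max())),
        }
        self._train_index = tuple(map(str, demo.index))
        self.n_train = len(y)
        return self

    @property
    def fitted(self) -> bool:
        return self._gp is not None

    @property
    def kernel_hyperparams(self) -> dict[str, float]:
        if not self.fitted:
            raise NotFittedError("model not fitted")
        k = self._gp.kernel_
        return dict(zip(k.hyperparameters and [h.name for h in k.hyperparameters],
                        np.exp(k.theta)))

    # -- prediction --------------------------------------------------------

    def predict(self, demo: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and SD (including observation noise) per subject."""
        if not self.fitted:
            raise NotFittedError(f"normative model {self.measure_name!r} is not fitted")
        X = _design_matrix(demo)
        for j, name in ((1, "pma_scan"), (2, "age_from_birth")):
            lo, hi = self._train_range[name]
            out = (X[:, j] < lo - 2.0) | (X[:, j] > hi + 2.0)
            if out.any():
                warnings.warn(
                    f"{self.measure_name}: {int(out.sum())} subject(s) have {name} "
                    f"more than 2 weeks outside the training range [{lo:.2f}, {hi:.2f}]",
                    stacklevel=2)
        Xs = (X - self._x_mean) / self._x_sd
        mean, sd = self._gp.predict(Xs, return_std=True)
        return mean, sd

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        if not self.fitted:
            raise NotFittedError("cannot serialize an unfitted model")
        gp = self._gp
        state = {
            "measure_name": self.measure_name,
            "theta": gp.kernel_.theta.tolist(),
            "x_mean": self._x_mean.tolist(),
            "x_sd": self._x_sd.tolist(),
            "train_range": self._train_range,
            "train_index": list(self._train_index),
            "X_train": gp.X_train_.tolist(),
            "y_train": (gp.y_train_ * gp._y_train_std + gp._y_train_mean).tolist(),
        }
        return json.dumps(state)

    @classmethod
    def from_json(cls, text: str) -> "NormativeModel":
        state = json.loads(text)
        model = cls(measure_name=state["measure_name"])
        kernel = _default_kernel()
        kernel.theta = np.asarray(state["theta"])
        gp = GaussianProcessRegressor(kernel=kernel, alpha=_JITTER,
                                      normalize_y=True, optimizer=None)
        gp.fit(np.asarray(state["X_train"]), np.asarray(state["y_train"]))
        model._gp = gp
        model._x_mean = np.asarray(state["x_mean"])
        model._x_sd = np.asarray(state["x_sd"])
        model._train_range = {k: tuple(v) for k, v in state["train_range"].items()}
        model._train_index = tuple(state["train_index"])
        model.n_train = len(state["y_train"])
        return model


def fit_normative(demo: pd.DataFrame, y, measure_name: str, *, seed: int = 0,
                  n_restarts: int = 5, optimize: bool = True,
                  min_controls: int = 30, kernel=None) -> NormativeModel:
    """Fit a GP normative model of ``measure_name`` on control subjects.

    ``demo`` holds the covariates (sex, pma_scan and age_from_birth or
    ga_birth); ``y`` the per-subject measure values.  Hyperparameters maximize
    the GP marginal likelihood from ``n_restarts`` seeded restarts; identical
    inputs and seed give bit-identical models.
    """
    return NormativeModel(measure_name=measure_name).fit(
        demo, y, seed=seed, n_restarts=n_restarts, optimize=optimize,
        min_controls=min_controls, kernel=kernel)


def zscore(model: NormativeModel, demo: pd.DataFrame, observed,
           threshold: float = EXTREME_Z) -> pd.DataFrame:
    """Deviation z-scores for subjects given a fitted model.

    Returns a DataFrame (index = subjects) with columns ``measure, observed,
    mean, sd, z, extreme``; ``extreme`` uses the inclusive |z| >= threshold
    rule.
    """
    observed = np.asarray(observed, dtype=float)
    mean, sd = model.predict(demo)
    z = (observed - mean) / sd
    return pd.DataFrame(
        {"measure": model.measure_name, "observed": observed, "mean": mean,
         "sd": sd, "z": z, "extreme": np.abs(z) >= threshold},
        index=demo.index)


def calibration_report(model: NormativeModel, demo: pd.DataFrame, observed) -> dict:
    """Summary of held-out control z-scores: a calibrated model gives mean ~ 0,
    SD ~ 1 and a small fraction of extreme deviations.

    The held-out subjects must be disjoint from the training set.
    """
    if len(demo) == 0:
        raise ValueError("empty held-out set")
    overlap = set(map(str, demo.index)) & set(model._train_index or ())
    if overlap:
        raise ValueError(f"held-out set overlaps training set: {sorted(overlap)[:3]}...")
    scores = zscore(model, demo, observed)
    z = scores["z"].to_numpy()
    return {
        "mean_z": float(z.mean()),
        "sd_z": float(z.std(ddof=1)) if len(z) > 1 else 0.0,
        "fraction_extreme": float(scores["extreme"].mean()),
        "z": z,
    }
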