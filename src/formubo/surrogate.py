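"""Per-objective Gaussian-process surrogates.

One independent GP per objective (Tm, kD, retained monomer), Matern 5/2
kernel with per-dimension length scales on the unit hypercube, targets
standardized to zero mean and unit variance, hyperparameters by
multi-restart maximum marginal likelihood.  A learned white-noise term
absorbs replicate scatter.  Predictions are returned in raw objective
units.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.utils.validation import check_is_fitted

__all__ = ["ObjectiveGP", "fit_objective_model", "predict_mean_sd", "augment_with_fantasy"]

_SD_FLOOR = 1e-8


class ObjectiveGP(RegressorMixin, BaseEstimator):
    """Gaussian-process regressor for one formulation objective.

    Parameters
    ----------
    name : str
        Objective label (bookkeeping only).
    length_scale_bounds : tuple
        MLE search bounds for the per-dimension Matern length scales,
        in unit-cube coordinates.
    noise_bounds : tuple
        Bounds for the white-noise variance (standardized-target units);
        the lower bound acts as the noise floor.
    n_restarts : int
        Extra random restarts for the marginal-likelihood optimizer.
    optimize : bool
        If False, hyperparameters are frozen at ``length_scale``,
        ``output_variance`` and ``noise_variance`` (closed-form posterior
        mode, used for testing and fantasy bookkeeping).
    random_state : int or None
        Seed for the restart draws; fits are deterministic given it.
    """

    def __init__(
        self,
        name: str = "objective",
        length_scale_bounds: tuple[float, float] = (1e-2, 1e2),
        noise_bounds: tuple[float, float] = (_SD_FLOOR, 1e1),
        n_restarts: int = 9,
        optimize: bool = True,
        length_scale: float | np.ndarray = 1.0,
        output_variance: float = 1.0,
        noise_variance: float = 1e-6,
        random_state: int | None = None,
    ) -> None:
        self.name = name
        self.length_scale_bounds = length_scale_bounds
        self.noise_bounds = noise_bounds
        self.n_restarts = n_restarts
        self.optimize = optimize
        self.length_scale = length_scale
        self.output_variance = output_variance
        self.noise_variance = noise_variance
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ObjectiveGP":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(y) < 2:
            raise ValueError("need at least 2 observations to fit a surrogate")
        self.y_mean_ = float(np.mean(y))
        sd = float(np.std(y))
        if sd < _SD_FLOOR:
            warnings.warn(
                f"objective '{self.name}' has (near-)constant targets; "
                "standardization floored",
                stacklevel=2,
            )
            sd = _SD_FLOOR
        self.y_sd_ = sd
        z = (y - self.y_mean_) / self.y_sd_

        d = X.shape[1]
        ls = np.broadcast_to(np.asarray(self.length_scale, dtype=float), (d,)).copy()
        if self.optimize:
            kernel = (
                ConstantKernel(1.0, (1e-3, 1e3))
                * Matern(length_scale=ls, length_scale_bounds=self.length_scale_bounds, nu=2.5)
                + WhiteKernel(1e-2, self.noise_bounds)
            )
            gp = GaussianProcessRegressor(
                kernel=kernel,
                alpha=1e-10,
                normalize_y=False,
                n_restarts_optimizer=self.n_restarts,
                random_state=self.random_state,
            )
        else:
            kernel = (
                ConstantKernel(self.output_variance, "fixed")
                * Matern(length_scale=ls, length_scale_bounds="fixed", nu=2.5)
                + WhiteKernel(self.noise_variance, "fixed")
            )
            gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-10, normalize_y=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, z)
        self.gp_ = gp
        self.X_train_ = X
        self.y_train_ = y
        self.log_marginal_likelihood_ = float(gp.log_marginal_likelihood_value_)
        k = gp.kernel_
        self.length_scale_ = np.atleast_1d(k.k1.k2.length_scale).astype(float)
        self.output_variance_ = float(k.k1.k1.constant_value)
        self.noise_variance_ = float(k.k2.noise_level)
        return self

    def predict(self, X: np.ndarray, return_std: bool = False):
        """Posterior mean (and sd) in raw objective units."""
        check_is_fitted(self, "gp_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if return_std:
            mean, sd = self.gp_.predict(X, return_std=True)
            return mean * self.y_sd_ + self.y_mean_, sd * self.y_sd_
        return self.gp_.predict(X) * self.y_sd_ + self.y_mean_

    def fantasize(self, x: np.ndarray) -> "ObjectiveGP":
        """Kriging-believer augmentation: refit on the training set plus
        (x, posterior mean at x).  Hyperparameters are re-estimated."""
        check_is_fitted(self, "gp_")
        x = np.asarray(x, dtype=float).reshape(1, -1)
        y_f = self.predict(x)
        clone = ObjectiveGP(**self.get_params())
        return clone.fit(
            np.vstack([self.X_train_, x]), np.concatenate([self.y_train_, y_f])
        )

    def to_record(self) -> dict:
        """Plain-serializable snapshot (hyperparameters + training data)."""
        check_is_fitted(self, "gp_")
        return {
            "name": self.name,
            "X": self.X_train_.tolist(),
            "y": self.y_train_.tolist(),
            "length_scale": self.length_scale_.tolist(),
            "output_variance": self.output_variance_,
            "noise_variance": self.noise_variance_,
            "y_mean": self.y_mean_,
            "y_sd": self.y_sd_,
        }

    @classmethod
    def from_record(cls, record: dict) -> "ObjectiveGP":
        model = cls(
            name=record["name"],
            optimize=False,
            length_scale=np.asarray(record["length_scale"]),
            output_variance=record["output_variance"],
            noise_variance=record["noise_variance"],
        )
        return model.fit(np.asarray(record["X"]), np.asarray(record["y"]))


def fit_objective_model(
    X: np.ndarray, y: np.ndarray, name: str = "objective", random_state: int | None = None, **kwargs
) -> ObjectiveGP:
    """Fit one objective surrogate on unit-cube inputs and raw targets."""
    return ObjectiveGP(name=name, random_state=random_state, **kwargs).fit(X, y)


def predict_mean_sd(model: ObjectiveGP, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(X, return_std=True)


def augment_with_fantasy(model: ObjectiveGP, x: np.ndarray) -> ObjectiveGP:
    return model.fantasize(x)
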