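"""Machine-learning torque regressors behind a uniform contract.

Three nonlinear regressors complement the physiological and linear
models:

* ``svr`` — epsilon support vector regression with a Gaussian kernel;
  C, gamma and epsilon are chosen by grid search with 8-fold
  cross-validation (the target is standardized internally so the
  epsilon grid is scale-free);
* ``ann`` — a feed-forward network with two tanh hidden layers trained
  by quasi-Newton (L-BFGS) with l2 regularization; the best of ten
  seeded restarts is kept;
* ``lwpr`` — locally weighted regression with radial-basis receptive
  fields. No locally-weighted-projection-regression library is
  available, so this is a batch receptive-field weighted *linear*
  model: greedily placed Gaussian receptive fields, each carrying a
  weighted ridge-regression local model, with the initial distance
  metric picked by 8-fold cross-validated grid search. The fitted
  metadata records the substitution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .exceptions import InvalidInputError, InvalidParameterError
from .linear import RegressionProblem


@dataclass
class SVRConfig:
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    epsilon_grid: tuple[float, ...] = (0.001, 0.01, 0.1)
    folds: int = 8


@dataclass
class ANNConfig:
    hidden_sizes: tuple[int, int] = (10, 5)
    max_epochs: int = 500
    alpha: float = 1e-3  # l2 regularization strength
    restarts: int = 10
    validation_fraction: float = 0.15
    patience: int = 20


@dataclass
class LWPRConfig:
    init_distance_grid: tuple[float, ...] = (1.0, 5.0, 25.0, 125.0)
    folds: int = 8
    activation_threshold: float = 0.3  # spawn a new RF below this
    ridge: float = 1e-6


@dataclass
class EstimatorConfig:
    kind: str = "svr"
    seed: int = 0
    svr: SVRConfig = field(default_factory=SVRConfig)
    ann: ANNConfig = field(default_factory=ANNConfig)
    lwpr: LWPRConfig = field(default_factory=LWPRConfig)

    def __post_init__(self) -> None:
        if self.kind not in ("svr", "ann", "lwpr"):
            raise InvalidParameterError(f"unknown estimator kind {self.kind!r}")


@dataclass
class FittedEstimator:
    kind: str
    model: Any
    hyperparameters: dict
    cv_score: float | None
    y_offset: float = 0.0
    y_scale: float = 1.0
    n_features: int = 0
    metadata: dict = field(default_factory=dict)


class ReceptiveFieldRegressor(BaseEstimator, RegressorMixin):
    """Batch receptive-field weighted linear model (LWPR stand-in).

    Receptive fields are Gaussian kernels w = exp(-0.5 * D * ||x - c||^2)
    with a shared scalar distance metric D; a field is spawned at any
    training point whose maximum activation falls below the threshold.
    Each field fits a weighted ridge local linear model; prediction is
    the activation-weighted blend, falling back to a global linear model
    where no field responds.
    """

    def __init__(self, init_distance=25.0, activation_threshold=0.3,
                 ridge=1e-6):
        self.init_distance = init_distance
        self.activation_threshold = activation_threshold
        self.ridge = ridge

    def _activations(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.centers_[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-0.5 * self.init_distance * d2)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        centers = [X[0]]
        for x in X[1:]:
            w = np.exp(
                -0.5 * self.init_distance
                * ((np.asarray(centers) - x) ** 2).sum(axis=1)
            )
            if w.max() < self.activation_threshold:
                centers.append(x)
        self.centers_ = np.asarray(centers)
        W = self._activations(X)
        Xa = np.column_stack([X, np.ones(len(X))])
        self.local_models_ = []
        eye = self.ridge * np.eye(Xa.shape[1])
        for k in range(self.centers_.shape[0]):
            sw = np.sqrt(W[:, k])
            A = Xa * sw[:, None]
            b = y * sw
            coef = np.linalg.solve(A.T @ A + eye, A.T @ b)
            self.local_models_.append(coef)
        self.local_models_ = np.asarray(self.local_models_)
        self.global_coef_, *_ = np.linalg.lstsq(Xa, y, rcond=None)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Xa = np.column_stack([X, np.ones(len(X))])
        W = self._activations(X)
        local = Xa @ self.local_models_.T  # (n, n_rf)
        total = W.sum(axis=1)
        blended = (W * local).sum(axis=1) / np.where(total > 1e-12, total, 1.0)
        fallback = Xa @ self.global_coef_
        return np.where(total > 1e-12, blended, fallback)


def _standardize_y(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    offset = float(y.mean())
    scale = float(y.std())
    if scale == 0:
        scale = 1.0
    return (y - offset) / scale, offset, scale


def fit_estimator(
    problem: RegressionProblem, config: EstimatorConfig
) -> FittedEstimator:
    """Fit one ML regressor with its model-selection protocol."""
    X, y = problem.design, problem.response
    n = X.shape[0]
    ys, off, scale = _standardize_y(y)

    if config.kind == "svr":
        cfg = config.svr
        if not (cfg.C_grid and cfg.gamma_grid and cfg.epsilon_grid):
            raise InvalidParameterError("empty SVR hyperparameter grid")
        if n < cfg.folds:
            raise InvalidParameterError(
                f"{n} samples cannot be split into {cfg.folds} folds"
            )
        cv = KFold(n_splits=cfg.folds, shuffle=True, random_state=config.seed)
        search = GridSearchCV(
            SVR(kernel="rbf"),
            {"C": list(cfg.C_grid), "gamma": list(cfg.gamma_grid),
             "epsilon": list(cfg.epsilon_grid)},
            cv=cv, scoring="neg_mean_squared_error", n_jobs=1,
        )
        search.fit(X, ys)
        return FittedEstimator(
            kind="svr", model=search.best_estimator_,
            hyperparameters=dict(search.best_params_),
            cv_score=float(search.best_score_),
            y_offset=off, y_scale=scale, n_features=X.shape[1],
        )

    if config.kind == "ann":
        cfg = config.ann
        if cfg.restarts < 1:
            raise InvalidParameterError("need at least one training restart")
        best, best_loss, best_seed = None, np.inf, None
        for r in range(cfg.restarts):
            net = MLPRegressor(
                hidden_layer_sizes=cfg.hidden_sizes, activation="tanh",
                solver="lbfgs", alpha=cfg.alpha, max_iter=cfg.max_epochs,
                random_state=config.seed + r,
            )
            with warnings.catch_warnings():
                # stopping at the epoch cap is the intended behaviour
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                net.fit(X, ys)
            if net.loss_ < best_loss:
                best, best_loss, best_seed = net, net.loss_, config.seed + r
        return FittedEstimator(
            kind="ann", model=best,
            hyperparameters={"hidden_sizes": cfg.hidden_sizes,
                             "alpha": cfg.alpha, "restart_seed": best_seed},
            cv_score=float(-best_loss),
            y_offset=off, y_scale=scale, n_features=X.shape[1],
            metadata={"restarts": cfg.restarts},
        )

    # lwpr stand-in
    cfg = config.lwpr
    if not cfg.init_distance_grid:
        raise InvalidParameterError("empty distance-metric grid")
    if n < cfg.folds:
        raise InvalidParameterError(
            f"{n} samples cannot be split into {cfg.folds} folds"
        )
    cv = KFold(n_splits=cfg.folds, shuffle=True, random_state=config.seed)
    best_d, best_mse = None, np.inf
    for d in cfg.init_distance_grid:
        mse = 0.0
        for tr, te in cv.split(X):
            m = ReceptiveFieldRegressor(
                init_distance=d,
                activation_threshold=cfg.activation_threshold,
                ridge=cfg.ridge,
            ).fit(X[tr], ys[tr])
            err = m.predict(X[te]) - ys[te]
            mse += float(err @ err)
        if mse < best_mse:
            best_d, best_mse = d, mse
    model = ReceptiveFieldRegressor(
        init_distance=best_d, activation_threshold=cfg.activation_threshold,
        ridge=cfg.ridge,
    ).fit(X, ys)
    return FittedEstimator(
        kind="lwpr", model=model,
        hyperparameters={"init_distance": best_d},
        cv_score=float(-best_mse / n),
        y_offset=off, y_scale=scale, n_features=X.shape[1],
        metadata={
            "implementation": "receptive-field weighted linear model "
            "(batch stand-in for LWPR)",
            "n_receptive_fields": int(model.centers_.shape[0]),
        },
    )


def estimator_predict(fitted: FittedEstimator, design: np.ndarray) -> np.ndarray:
    """Predict torque (N·m) for new envelope rows."""
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[1] != fitted.n_features:
        raise InvalidInputError(
            f"design must be 2-D with {fitted.n_features} columns"
        )
    ys = fitted.model.predict(design)
    return np.asarray(ys, dtype=float) * fitted.y_scale + fitted.y_offset
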