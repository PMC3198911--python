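"""Ordinary and l1-regularized least-squares torque regressors.

Both models regress measured torque directly on the processed SEMG
envelopes with no intercept,

    tau = SEMG @ beta + eps,

OLS solving the normal equations and RLS minimizing the lasso objective
lambda * sum|beta_i| + sum r_i^2 (default lambda = 0.01). The lasso is
solved by scikit-learn's coordinate descent with the penalty rescaled to
match this parameterization exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.01


@dataclass
class RegressionProblem:
    """Design matrix of envelopes (N x M) and measured torque (N,)."""

    design: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.design.ndim != 2:
            raise InvalidInputError("design must be 2-D")
        if self.response.shape != (self.design.shape[0],):
            raise InvalidInputError("response length must match design rows")
        if not (np.isfinite(self.design).all() and
                np.isfinite(self.response).all()):
            raise InvalidInputError("design/response contain non-finite values")


@dataclass
class LinearCoefficients:
    """Fitted coefficients (N·m per unit envelope) and the lambda used."""

    beta: np.ndarray
    lambda_used: float = 0.0
    channel_names: tuple[str, ...] | None = None
    sse: float | None = None

    def to_json(self) -> str:
        return json.dumps({
            "beta": list(map(float, self.beta)),
            "lambda": self.lambda_used,
            "channel_names": self.channel_names,
            "sse": self.sse,
        })


def ols_fit(problem: RegressionProblem) -> LinearCoefficients:
    """Least-squares fit without intercept.

    Raises on rank deficiency, naming a collinear column.
    """
    X, y = problem.design, problem.response
    if X.shape[0] < X.shape[1]:
        raise InvalidInputError(
            "need at least as many observations as channels"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a column linearly dependent on its predecessors
        culprit = X.shape[1] - 1
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                culprit = j - 1
                break
        raise InvalidInputError(
            f"design is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"column {culprit} is collinear with earlier columns"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    _warn_if_biased(resid, y)
    return LinearCoefficients(beta=beta, lambda_used=0.0,
                              sse=float(resid @ resid))


def rls_fit(
    problem: RegressionProblem, lam: float = DEFAULT_LAMBDA
) -> LinearCoefficients:
    """l1-regularized fit minimizing lam * sum|beta| + sum r^2.

    scikit-learn's Lasso minimizes ||r||^2 / (2n) + alpha * sum|beta|,
    so alpha = lam / (2n) reproduces this objective.
    """
    if lam < 0:
        raise InvalidInputError("lambda must be nonnegative")
    X, y = problem.design, problem.response
    if lam == 0:
        return ols_fit(problem)
    n = X.shape[0]
    model = Lasso(
        alpha=lam / (2.0 * n), fit_intercept=False,
        max_iter=100_000, tol=1e-10,
    )
    model.fit(X, y)
    beta = np.asarray(model.coef_, dtype=float)
    resid = y - X @ beta
    _warn_if_biased(resid, y)
    return LinearCoefficients(beta=beta, lambda_used=lam,
                              sse=float(resid @ resid))


def linear_predict(
    coefs: LinearCoefficients, design: np.ndarray
) -> np.ndarray:
    """tau_e = design @ beta."""
    design = np.asarray(design, dtype=float)
    if design.shape[1] != coefs.beta.shape[0]:
        raise InvalidInputError(
            f"design has {design.shape[1]} columns but "
            f"{coefs.beta.shape[0]} coefficients were fitted"
        )
    return design @ coefs.beta


def _warn_if_biased(resid: np.ndarray, y: np.ndarray) -> None:
    # no intercept is fitted, so flag a fit whose residual mean is large
    rng = np.ptp(y)
    if rng > 0 and abs(resid.mean()) > 0.05 * rng:
        logger.info(
            "residual mean %.3g exceeds 5%% of the torque range %.3g "
            "(no-intercept model)", resid.mean(), rng,
        )
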