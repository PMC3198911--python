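"""Accuracy metrics and cohort reporting arithmetic.

NRMSE divides the root-mean-squared torque error by the measured range
(maximum flexion torque plus the magnitude of the maximum extension
torque); R^2 is the ordinary coefficient of determination and Ra^2 its
adjustment for the number of SEMG channels k:

    Ra^2 = 1 - (n - 1)/(n - k - 1) * (1 - R^2).

Relative changes are reported the way the source tables print them:
percent changes rounded half-away-from-zero to integers, fold changes to
two decimals. Model comparison uses classical one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidInputError, UndefinedMetricError


@dataclass
class EvaluationResult:
    """NRMSE / R^2 / Ra^2 of one model under one condition."""

    nrmse: float
    r2: float
    ra2: float
    n: int
    k: int
    tau_flex_max: float
    tau_ext_max: float


def _as_series(estimated, measured) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if est.shape != mea.shape or est.ndim != 1 or est.size == 0:
        raise InvalidInputError("series must be equal-length, nonempty 1-D")
    return est, mea


def torque_range(measured: np.ndarray) -> tuple[float, float]:
    """(max flexion torque, max extension torque) with signs preserved."""
    measured = np.asarray(measured, dtype=float)
    return float(max(measured.max(), 0.0)), float(min(measured.min(), 0.0))


def nrmse(estimated, measured) -> float:
    """RMSE over (tau_flex_max + |tau_ext_max|) of the measured series."""
    est, mea = _as_series(estimated, measured)
    flex, ext = torque_range(mea)
    denom = flex + abs(ext)
    if denom == 0:
        raise UndefinedMetricError("measured torque range is zero")
    return float(np.sqrt(np.mean((est - mea) ** 2)) / denom)


def r_squared(estimated, measured) -> float:
    """1 - SSE/SST; negative when the fit is worse than the mean."""
    est, mea = _as_series(estimated, measured)
    sst = float(np.sum((mea - mea.mean()) ** 2))
    if sst == 0:
        raise UndefinedMetricError("measured series is constant")
    sse = float(np.sum((est - mea) ** 2))
    return 1.0 - sse / sst


def adjusted_r_squared(r2: float, n: int, k: int) -> float:
    """Penalize R^2 for the number of SEMG channels k."""
    if n <= k + 1:
        raise UndefinedMetricError(
            f"adjusted R^2 needs n > k + 1 (got n={n}, k={k})"
        )
    return 1.0 - (n - 1) / (n - k - 1) * (1.0 - r2)


def evaluate(estimated, measured, k: int) -> EvaluationResult:
    """All metrics for one prediction against measured torque."""
    est, mea = _as_series(estimated, measured)
    flex, ext = torque_range(mea)
    r2 = r_squared(est, mea)
    return EvaluationResult(
        nrmse=nrmse(est, mea),
        r2=r2,
        ra2=adjusted_r_squared(r2, est.size, k),
        n=est.size,
        k=k,
        tau_flex_max=flex,
        tau_ext_max=ext,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def relative_change(before: float, after: float, mode: str = "percent"):
    """(after - before)/before, reported at table granularity.

    percent mode returns an integer percentage (half-away-from-zero);
    fold mode returns the ratio change rounded to 2 decimals.
    """
    if before == 0:
        raise UndefinedMetricError("relative change undefined for before=0")
    ratio = (after - before) / before
    if mode == "percent":
        return _round_half_away(100.0 * ratio)
    if mode == "fold":
        return round(ratio, 2)
    raise InvalidInputError(f"unknown mode {mode!r}")


def one_way_anova(groups) -> dict:
    """Classical one-way ANOVA across per-subject metric vectors."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise InvalidInputError(
            "ANOVA needs >= 2 groups with >= 2 values each"
        )
    f, p = stats.f_oneway(*groups)
    return {"F": float(f), "p": float(p)}
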