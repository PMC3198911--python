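"""Physiological (neuromusculoskeletal) wrist-torque model.

The forward chain maps each channel's normalized SEMG envelope e_j(t) to
joint torque:

1. activation dynamics — a critically-damped twitch response discretized
   as a second-order recursive filter,
       u(t) = alpha * e(t - d) - beta1 * u(t-1) - beta2 * u(t-2),
   with beta1 = C1 + C2, beta2 = C1 * C2 (poles at -C1, -C2; stable for
   |C1|, |C2| < 1) and alpha = 1 + beta1 + beta2 so the DC gain is
   exactly 1; d is the electromechanical delay (10-100 ms);
2. activation nonlinearity a = (exp(A u) - 1) / (exp(A) - 1), with shape
   factor A in [-3, 0] (A = 0 is the linear limit a = u);
3. torque summation tau = sum_j (sigmaPCSA_j / PCSA_j) Fmax_j MA_j a_j,
   flexors contributing positive torque and extensors negative.

Calibration tunes x = {A, C1, C2, d, Fmax_1..M, MA_1..M} (activation
parameters shared across muscles, per-muscle forces and moment arms
box-bounded to +-1 SD of literature values) by minimizing the summed
squared torque residual with a seeded genetic algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import signal as sps

from .exceptions import InvalidInputError, InvalidParameterError
from .muscles import MusclePhysiology, build_muscles
from .processing import ProcessedRecording, resample_indices

DELAY_BOUNDS_MS = (10.0, 100.0)
SHAPE_BOUNDS = (-3.0, 0.0)
RECURSIVE_BOUNDS = (-0.95, 0.95)  # |C1|, |C2| < 1 with a stability margin


@dataclass
class ActivationParams:
    """Shared activation-dynamics parameters (A, C1, C2, delay)."""

    A: float = -1.0
    C1: float = 0.0
    C2: float = 0.0
    d_ms: float = 40.0

    def __post_init__(self) -> None:
        if not (abs(self.C1) < 1 and abs(self.C2) < 1):
            raise InvalidParameterError(
                "recursive coefficients must satisfy |C1| < 1 and |C2| < 1"
            )
        if not SHAPE_BOUNDS[0] <= self.A <= SHAPE_BOUNDS[1]:
            raise InvalidParameterError("shape factor A must lie in [-3, 0]")
        if not DELAY_BOUNDS_MS[0] <= self.d_ms <= DELAY_BOUNDS_MS[1]:
            raise InvalidParameterError(
                "electromechanical delay must lie in [10, 100] ms"
            )

    @property
    def beta1(self) -> float:
        return self.C1 + self.C2

    @property
    def beta2(self) -> float:
        return self.C1 * self.C2

    @property
    def alpha(self) -> float:
        # alpha - beta1 - beta2 = 1 pins the recursion's DC gain at 1
        return 1.0 + self.beta1 + self.beta2

    def delay_samples(self, sample_rate_hz: float) -> int:
        return int(round(self.d_ms * sample_rate_hz / 1000.0))


@dataclass
class PBMParameters:
    """Activation dynamics plus one :class:`MusclePhysiology` per channel."""

    activation: ActivationParams
    muscles: list[MusclePhysiology]

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)

    def torque_weights(self) -> np.ndarray:
        """Signed per-channel torque gains (sigmaPCSA/PCSA) * Fmax * MA."""
        return np.array(
            [m.pcsa_weight * m.fmax_N * m.ma_m for m in self.muscles]
        )


def default_parameters(channels=None, table=None) -> PBMParameters:
    """Mean-valued parameters for a channel subset (the GA start point)."""
    from .processing import CHANNEL_NAMES

    channels = tuple(channels) if channels is not None else CHANNEL_NAMES
    return PBMParameters(
        activation=ActivationParams(), muscles=build_muscles(channels, table)
    )


def recursive_filter(
    e: np.ndarray, params: ActivationParams, sample_rate_hz: float
) -> np.ndarray:
    """Apply the activation-dynamics recursion to one or more envelopes.

    Implemented as an order-2 IIR filter on the delayed envelope; u(t) is
    zero before the first delayed sample.
    """
    e = np.asarray(e, dtype=float)
    d = params.delay_samples(sample_rate_hz)
    delayed = np.zeros_like(e)
    if d < e.shape[0]:
        delayed[d:] = e[: e.shape[0] - d]
    b = [params.alpha]
    a = [1.0, params.beta1, params.beta2]
    return sps.lfilter(b, a, delayed, axis=0)


def activation_nonlinearity(u: np.ndarray, A: float) -> np.ndarray:
    """Exponential firing-rate shaping, a = (e^{Au} - 1)/(e^A - 1).

    A = 0 is handled as its analytic limit a = u. Monotone bijection of
    [0, 1] onto itself for every A in [-3, 0].
    """
    if not SHAPE_BOUNDS[0] <= A <= SHAPE_BOUNDS[1]:
        raise InvalidParameterError("shape factor A must lie in [-3, 0]")
    u = np.asarray(u, dtype=float)
    if abs(A) < 1e-12:
        return u.copy()
    return np.expm1(A * u) / np.expm1(A)


def joint_torque(a: np.ndarray, params: PBMParameters) -> np.ndarray:
    """PCSA-weighted sum of per-channel isometric torques.

    ``a`` is (N, M) activation; returns the (N,) wrist torque in N·m.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape[1] != len(params.muscles):
        raise InvalidInputError(
            f"{a.shape[1]} activation channels but "
            f"{len(params.muscles)} muscle definitions"
        )
    return a @ params.torque_weights()


def two_channel_torque(
    a_flexor: np.ndarray,
    a_extensor: np.ndarray,
    params: PBMParameters,
) -> np.ndarray:
    """Torque from one flexor + one extensor channel.

    ``params.muscles`` must contain exactly one flexor and one extensor
    whose sigma PCSA already carries the full PCSA of its role group
    (see :func:`semgtorque.muscles.build_muscles` on a 2-channel subset).
    """
    roles = [m.role for m in params.muscles]
    if sorted(roles) != ["extensor", "flexor"]:
        raise InvalidInputError(
            "two-channel model requires exactly one flexor and one extensor"
        )
    a = np.column_stack([
        np.asarray(a_flexor, dtype=float)
        if roles[0] == "flexor" else np.asarray(a_extensor, dtype=float),
        np.asarray(a_extensor, dtype=float)
        if roles[1] == "extensor" else np.asarray(a_flexor, dtype=float),
    ])
    return joint_torque(a, params)


def forward_pbm(
    processed: ProcessedRecording | np.ndarray,
    params: PBMParameters,
    sample_rate_hz: float | None = None,
) -> np.ndarray:
    """Full forward model: recursion -> nonlinearity -> torque summation.

    Accepts a :class:`ProcessedRecording` or a plain (N, M) envelope
    array (then ``sample_rate_hz`` is required). The recursion can
    transiently overshoot [0, 1]; u is clipped before the nonlinearity.
    """
    if isinstance(processed, ProcessedRecording):
        env = processed.envelopes
        fs = processed.sample_rate_hz
    else:
        env = np.asarray(processed, dtype=float)
        if sample_rate_hz is None:
            raise InvalidInputError(
                "sample_rate_hz required with a plain envelope array"
            )
        fs = sample_rate_hz
    u = recursive_filter(env, params.activation, fs)
    np.clip(u, 0.0, 1.0, out=u)
    a = activation_nonlinearity(u, params.activation.A)
    return joint_torque(a, params)


# ---------------------------------------------------------------------------
# Genetic-algorithm calibration
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    """Genetic-algorithm settings for model calibration.

    Tournament selection, blend (BLX-alpha) crossover and bounds-clipped
    Gaussian mutation with two elites; the delay bound keeps d in
    [10, 100] ms. ``resample_k`` decimates the objective to every k-th
    sample (the forward model still runs at the full rate so the delay
    stays resolvable).
    """

    seed: int = 0
    population: int = 50
    generations: int = 100
    tournament: int = 3
    crossover_rate: float = 0.9
    blend_alpha: float = 0.5
    mutation_rate: float = 0.15
    mutation_sigma: float = 0.12  # fraction of each gene's range
    elites: int = 2
    resample_k: int = 100
    stall_generations: int = 25
    stall_tol: float = 1e-10

    @classmethod
    def from_yaml(cls, path) -> "GAConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class GAResult:
    x: np.ndarray
    fun: float
    n_generations: int
    converged: bool
    history: np.ndarray = field(repr=False, default=None)


def minimize_ga(
    objective,
    lower: np.ndarray,
    upper: np.ndarray,
    config: GAConfig,
    x0: np.ndarray | None = None,
) -> GAResult:
    """Box-constrained GA minimization; fully seeded and deterministic."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or np.any(lower > upper):
        raise InvalidParameterError("infeasible bounds")
    rng = np.random.default_rng(config.seed)
    dim = lower.size
    span = upper - lower
    pop = lower + rng.random((config.population, dim)) * span
    if x0 is not None:
        pop[0] = np.clip(np.asarray(x0, dtype=float), lower, upper)
    fit = np.array([objective(ind) for ind in pop])
    order = np.argsort(fit)
    pop, fit = pop[order], fit[order]
    best_hist = [fit[0]]

    gens_run = 0
    for gen in range(config.generations):
        gens_run = gen + 1
        children = [pop[i].copy() for i in range(config.elites)]
        while len(children) < config.population:
            picks = rng.integers(0, config.population, (2, config.tournament))
            p1 = pop[picks[0][np.argmin(fit[picks[0]])]]
            p2 = pop[picks[1][np.argmin(fit[picks[1]])]]
            if rng.random() < config.crossover_rate:
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                d = (hi - lo) * config.blend_alpha
                child = lo - d + rng.random(dim) * (hi - lo + 2 * d)
            else:
                child = p1.copy()
            mutate = rng.random(dim) < config.mutation_rate
            child = np.where(
                mutate,
                child + rng.normal(0.0, config.mutation_sigma, dim) * span,
                child,
            )
            children.append(np.clip(child, lower, upper))
        pop = np.asarray(children)
        fit = np.array([objective(ind) for ind in pop])
        order = np.argsort(fit)
        pop, fit = pop[order], fit[order]
        best_hist.append(fit[0])
        if (
            gen + 1 >= config.stall_generations
            and best_hist[-config.stall_generations] - best_hist[-1]
            <= config.stall_tol
        ):
            break
    converged = (
        len(best_hist) > config.stall_generations
        and best_hist[-config.stall_generations] - best_hist[-1]
        <= max(config.stall_tol, 1e-8 * abs(best_hist[-1]))
    )
    return GAResult(
        x=pop[0], fun=fit[0], n_generations=gens_run,
        converged=converged, history=np.asarray(best_hist),
    )


def _pack_bounds(params: PBMParameters) -> tuple[np.ndarray, np.ndarray]:
    lo = [SHAPE_BOUNDS[0], RECURSIVE_BOUNDS[0], RECURSIVE_BOUNDS[0],
          DELAY_BOUNDS_MS[0]]
    hi = [SHAPE_BOUNDS[1], RECURSIVE_BOUNDS[1], RECURSIVE_BOUNDS[1],
          DELAY_BOUNDS_MS[1]]
    for m in params.muscles:
        lo.append(m.fmax_bounds_N[0])
        hi.append(m.fmax_bounds_N[1])
    for m in params.muscles:
        lo.append(m.ma_bounds_m[0])
        hi.append(m.ma_bounds_m[1])
    return np.asarray(lo), np.asarray(hi)


def _unpack(x: np.ndarray, template: PBMParameters) -> PBMParameters:
    m = len(template.muscles)
    act = ActivationParams(A=x[0], C1=x[1], C2=x[2], d_ms=x[3])
    muscles = []
    for j, mus in enumerate(template.muscles):
        muscles.append(
            MusclePhysiology(
                name=mus.name, role=mus.role,
                fmax_N=float(x[4 + j]), fmax_bounds_N=mus.fmax_bounds_N,
                ma_m=float(x[4 + m + j]), ma_bounds_m=mus.ma_bounds_m,
                pcsa_cm2=mus.pcsa_cm2, sigma_pcsa_cm2=mus.sigma_pcsa_cm2,
            )
        )
    return PBMParameters(activation=act, muscles=muscles)


@dataclass
class CalibrationResult:
    parameters: PBMParameters
    sse: float
    converged: bool
    n_generations: int


def calibrate_pbm(
    processed: ProcessedRecording,
    template: PBMParameters | None = None,
    ga_config: GAConfig | None = None,
    train_indices: np.ndarray | None = None,
) -> CalibrationResult:
    """Fit the physiological model to measured torque by seeded GA.

    The objective is the summed squared residual between modeled and
    measured torque at the (decimated) training indices; the forward
    model runs at the recording's full rate. The mean-valued parameter
    vector is injected into the initial population, so the returned
    objective can never exceed the objective at the physiological means.
    """
    if processed.n_samples == 0:
        raise InvalidInputError("empty training recording")
    ga_config = ga_config or GAConfig()
    template = template or default_parameters(processed.channel_names)
    if tuple(template.channel_names) != tuple(processed.channel_names):
        raise InvalidInputError(
            "muscle order must match the recording's channel order"
        )
    if train_indices is None:
        train_indices = resample_indices(
            processed.n_samples, ga_config.resample_k
        )
    env = processed.envelopes
    tau_m = processed.torque[train_indices]
    fs = processed.sample_rate_hz
    m = env.shape[1]
    weights_pcsa = np.array([mus.pcsa_weight for mus in template.muscles])
    n_use = int(train_indices[-1]) + 1

    env_head = np.asarray(env[:n_use], dtype=float)
    train_indices = np.asarray(train_indices)

    def objective(x: np.ndarray) -> float:
        # the recursion is LTI, so filtering the undelayed envelope and
        # shifting the readout indices equals filtering a delayed copy
        act = ActivationParams(A=x[0], C1=x[1], C2=x[2], d_ms=x[3])
        u_full = sps.lfilter(
            [act.alpha], [1.0, act.beta1, act.beta2], env_head, axis=0
        )
        shifted = train_indices - act.delay_samples(fs)
        u = np.where(
            shifted[:, None] >= 0, u_full[np.maximum(shifted, 0)], 0.0
        )
        np.clip(u, 0.0, 1.0, out=u)
        a = activation_nonlinearity(u, float(x[0]))
        gains = weights_pcsa * x[4:4 + m] * x[4 + m:4 + 2 * m]
        resid = a @ gains - tau_m
        return float(resid @ resid)

    lower, upper = _pack_bounds(template)
    x0 = np.concatenate([
        [template.activation.A, template.activation.C1,
         template.activation.C2, template.activation.d_ms],
        [mus.fmax_N for mus in template.muscles],
        [mus.ma_m for mus in template.muscles],
    ])
    result = minimize_ga(objective, lower, upper, ga_config, x0=x0)
    return CalibrationResult(
        parameters=_unpack(result.x, template),
        sse=result.fun,
        converged=result.converged,
        n_generations=result.n_generations,
    )
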