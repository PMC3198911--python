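"""Synthetic SEMG + wrist-torque cohort generator with known ground truth.

Real recordings from the wrist-torque protocol were never deposited, so
every pipeline stage is exercised against surrogate data built to the
same shape: eight forearm channels at 1 kHz, 33,520 samples per
recording, a protocol of one maximal flexion, one maximal extension and
three gradual ramps each to 50% and 25% MVC per direction (14 action
segments), sessions one hour and twenty-four hours later, and a
supinated repetition of session one.

The surrogate follows the standard interference-EMG model: each channel
is amplitude-modulated band-limited (20-450 Hz) Gaussian noise, where
the modulation is the crosstalk-mixed muscle excitation, plus DC offset,
sub-5 Hz motion-artifact drift and white measurement noise. Torque is
produced by the physiological forward model with parameters drawn inside
their physiological bounds, so calibration recovery is testable.

Session-to-session change combines a slow per-channel gain ramp
(electrode-gel impedance drift; a *static* gain would be removed exactly
by per-session max-normalization), a per-muscle EMG-force exponent warp
(fatigue-style), imperfect MVC repeatability (which moves the
normalization anchors) and a mild crosstalk shift from re-strapping the
forearm; the 24-hour session nests the 1-hour drift with amplified
deviations plus an electrode-replacement crosstalk displacement. Posture
change swaps in an alternative crosstalk matrix and reverses the torque
sensor sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidInputError, InvalidParameterError
from .muscles import build_muscles, load_muscle_table
from .pbm import ActivationParams, PBMParameters, forward_pbm
from .processing import CHANNEL_NAMES, ProcessedRecording, Recording

N_SAMPLES_DEFAULT = 33_520
SAMPLE_RATE_DEFAULT = 1000.0


@dataclass
class NoiseSpec:
    """SEMG carriers are millivolt-scale; offsets/artifacts are larger but
    fall below the 30 Hz high-pass, while the broadband measurement noise
    (~20 uV) sets the in-band noise floor."""

    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    measurement_sd_v: float = 1.5e-4
    artifact_amp_v: float = 0.05
    dc_offset_v: float = 0.3
    torque_sd_frac: float = 0.01  # SD as a fraction of the torque range


@dataclass
class SyntheticSubject:
    """Ground truth and signal-path constants for one simulated volunteer."""

    subject_id: str
    ground_truth: PBMParameters
    crosstalk: np.ndarray          # (8, 8) diagonally dominant mixing
    channel_gains: np.ndarray      # volts per unit excitation
    posture_crosstalk: np.ndarray  # mixing under forearm supination
    posture_gains: np.ndarray
    coactivation: float = 0.05     # antagonist level relative to agonist
    participation_jitter: float = 0.25  # per-muscle per-segment spread
    modulation_sd: float = 0.8     # slow within-segment load-sharing swing
    secondary_scale: float = 0.35  # participation of EDC/PL/FDS (finger
    #                                muscles barely load a palm-plate rig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        X = np.asarray(self.crosstalk, dtype=float)
        if X.shape != (8, 8):
            raise InvalidInputError("crosstalk must be 8x8")
        off = X - np.diag(np.diag(X))
        if not np.all(np.diag(X) > off.max(axis=1)):
            raise InvalidParameterError(
                "crosstalk diagonal must dominate each row"
            )

    @property
    def mvc_flex(self) -> float:
        """Peak flexion torque at full flexor drive (+ antagonist level)."""
        w = self.ground_truth.torque_weights()
        flex = np.array([m.role == "flexor" for m in self.ground_truth.muscles])
        return float(w[flex].sum() + self.coactivation * w[~flex].sum())

    @property
    def mvc_ext(self) -> float:
        w = self.ground_truth.torque_weights()
        flex = np.array([m.role == "flexor" for m in self.ground_truth.muscles])
        return float(w[~flex].sum() + self.coactivation * w[flex].sum())


@dataclass
class DriftSpec:
    """Session/posture perturbations applied to the signal path.

    ``gain_drift`` are per-channel end-of-session gain factors reached by
    a smooth ramp over the first 30% of the recording; ``emg_exponent``
    warps each muscle's excitation-to-SEMG amplitude relation (e -> e^g,
    the fatigue-style nonlinear drift that per-session max-normalization
    cannot undo); ``mvc_scale`` rescales the maximal-effort segments per
    muscle (MVC efforts are not perfectly repeatable, which moves the
    per-channel normalization anchor and with it the whole envelope ->
    torque map); ``electrode_shift`` is an additive crosstalk
    perturbation; ``posture_remap``/``flip_torque_sign`` emulate forearm
    supination.
    """

    gain_drift: np.ndarray | None = None
    emg_exponent: np.ndarray | None = None
    mvc_scale: np.ndarray | None = None
    electrode_shift: np.ndarray | None = None
    posture_remap: np.ndarray | None = None
    flip_torque_sign: bool = False


# ---------------------------------------------------------------------------
# Protocol / excitation schedule
# ---------------------------------------------------------------------------

#: (direction, level) per action segment: 1 MVC each direction, then 3
#: ramps to 50% and 3 to 25% per direction.
PROTOCOL_SEGMENTS: tuple[tuple[str, float], ...] = (
    (("flexion", 1.0),) + (("extension", 1.0),)
    + tuple(("flexion", 0.5) for _ in range(3))
    + tuple(("extension", 0.5) for _ in range(3))
    + tuple(("flexion", 0.25) for _ in range(3))
    + tuple(("extension", 0.25) for _ in range(3))
)


SECONDARY_CHANNELS = ("EDC", "PL", "FDS")


def generate_excitation_schedule(
    n_samples: int = N_SAMPLES_DEFAULT,
    sample_rate_hz: float = SAMPLE_RATE_DEFAULT,
    seed: int = 0,
    coactivation: float = 0.05,
    participation_jitter: float = 0.25,
    modulation_sd: float = 0.8,
    secondary_scale: float = 0.35,
    mvc_participation: np.ndarray | None = None,
    muscles=None,
) -> tuple[np.ndarray, list[dict]]:
    """Per-muscle excitation profiles in [0, 1] following the protocol.

    Each segment is rest -> ramp up -> brief hold -> ramp down with
    seeded timing jitter. Agonist muscles carry the ramp scaled by a
    per-muscle per-segment participation factor and a slow (~1 Hz)
    independent load-sharing modulation — synergist muscles trade effort
    over time, which is what makes additional SEMG channels genuinely
    informative. Secondary (finger) muscles participate at a reduced
    level, and antagonists at a low co-activation level. Returns (N, 8)
    excitations and segment bookkeeping.
    """
    rng = np.random.default_rng(seed)
    muscles = muscles or build_muscles(CHANNEL_NAMES)
    roles = np.array([m.role for m in muscles])
    names = [m.name for m in muscles]
    secondary = np.array([n in SECONDARY_CHANNELS for n in names])
    # slow unit-SD load-sharing tracks, independent per muscle
    sos = sps.butter(2, 1.0, btype="lowpass", fs=sample_rate_hz, output="sos")
    share = sps.sosfiltfilt(
        sos, rng.standard_normal((n_samples, len(muscles))), axis=0
    )
    share /= share.std(axis=0)
    # cap the swing so submaximal segments can never exceed the MVC peak,
    # which anchors the per-channel normalization maximum
    share = np.clip(1.0 + modulation_sd * share, 0.05, 1.8)
    n_seg = len(PROTOCOL_SEGMENTS)
    base = n_samples / n_seg
    # jittered segment lengths, padded/trimmed to exactly n_samples
    lengths = np.maximum(
        (base * (1.0 + 0.08 * rng.standard_normal(n_seg))).astype(int), 50
    )
    lengths[-1] += n_samples - lengths.sum()
    exc = np.zeros((n_samples, len(muscles)))
    segments = []
    start = 0
    for (direction, level), length in zip(PROTOCOL_SEGMENTS, lengths):
        rest = int(0.15 * length)
        up = int(0.35 * length)
        hold = int(0.10 * length)
        down = length - rest - up - hold
        profile = np.concatenate([
            np.zeros(rest),
            np.linspace(0.0, 1.0, up, endpoint=False),
            np.ones(hold),
            np.linspace(1.0, 0.0, down),
        ]) * level
        agonist = roles == ("flexor" if direction == "flexion" else "extensor")
        if level == 1.0:
            # maximal effort saturates recruitment: no participation
            # jitter and no load sharing, so the per-channel maximum
            # (the normalization anchor) is reproducible across sessions
            # up to the session's MVC repeatability factor
            mvc = (np.ones(len(muscles)) if mvc_participation is None
                   else np.asarray(mvc_participation, dtype=float))
            part = np.where(agonist, mvc, coactivation)
            seg_share = 1.0
        else:
            part = np.where(
                agonist,
                1.0 - participation_jitter * rng.random(len(muscles)),
                coactivation,
            )
            seg_share = share[start:start + length]
        part = np.where(secondary, part * secondary_scale, part)
        exc[start:start + length] = (
            profile[:, None] * part[None, :] * seg_share
        )
        segments.append({
            "direction": direction, "level": level,
            "start": start, "stop": start + length,
        })
        start += length
    return np.clip(exc, 0.0, 1.0), segments


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def band_limited_carrier(
    n_samples: int,
    sample_rate_hz: float,
    band_hz: tuple[float, float],
    rng: np.random.Generator,
    n_channels: int = 1,
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the SEMG carrier band."""
    sos = sps.butter(
        4, band_hz, btype="bandpass", fs=sample_rate_hz, output="sos"
    )
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_samples, n_channels)),
                        axis=0)
    return x / x.std(axis=0)


def _gain_profile(
    n_samples: int, end_factors: np.ndarray | None,
    ramp_window: tuple[float, float] = (0.2, 0.6),
) -> np.ndarray:
    """Per-channel gain ramping smoothly from 1 to the drawn factor.

    The ramp runs between the window fractions of the recording — after
    the opening maximal-effort segments, so the normalization anchor is
    acquired at the undrifted gain and the remainder of the session
    carries the full gain error relative to it.
    """
    if end_factors is None:
        return np.ones((n_samples, 8))
    end_factors = np.asarray(end_factors, dtype=float)
    lo, hi = (int(ramp_window[0] * n_samples), int(ramp_window[1] * n_samples))
    t = np.clip((np.arange(n_samples) - lo) / max(hi - lo, 1), 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * t)  # smooth 0 -> 1
    return 1.0 + ramp[:, None] * (end_factors[None, :] - 1.0)


def synthesize_raw_semg(
    excitations: np.ndarray,
    subject: SyntheticSubject,
    rng: np.random.Generator,
    sample_rate_hz: float = SAMPLE_RATE_DEFAULT,
    drift: DriftSpec | None = None,
) -> np.ndarray:
    """Raw-like SEMG: modulated carrier + DC + motion artifact + noise."""
    n = excitations.shape[0]
    drift = drift or DriftSpec()
    mixing = (
        drift.posture_remap if drift.posture_remap is not None
        else subject.crosstalk
    )
    if drift.electrode_shift is not None:
        # displaced electrodes need not stay diagonally dominant, but the
        # result must remain a valid (nonnegative, nonzero-row) mixing
        mixing = mixing + drift.electrode_shift
        if np.any(mixing < -1e-12) or np.any(mixing.sum(axis=1) <= 0):
            raise InvalidParameterError(
                "electrode shift does not yield a valid mixing matrix"
            )
    gains = (
        subject.posture_gains if drift.posture_remap is not None
        else subject.channel_gains
    )
    exc = excitations
    if drift.emg_exponent is not None:
        exc = exc ** np.asarray(drift.emg_exponent, dtype=float)[None, :]
    modulation = exc @ mixing.T  # (N, 8) channel drive
    carrier = band_limited_carrier(
        n, sample_rate_hz, subject.noise.carrier_band_hz, rng, n_channels=8
    )
    semg = modulation * carrier * gains[None, :]
    semg *= _gain_profile(n, drift.gain_drift)
    # low-frequency motion artifact: a couple of slow seeded sinusoids
    tt = np.arange(n) / sample_rate_hz
    for _ in range(2):
        f = rng.uniform(0.2, 4.0, size=8)
        phase = rng.uniform(0, 2 * np.pi, size=8)
        amp = subject.noise.artifact_amp_v * rng.uniform(0.3, 1.0, size=8)
        semg += amp[None, :] * np.sin(
            2 * np.pi * f[None, :] * tt[:, None] + phase[None, :]
        )
    semg += subject.noise.dc_offset_v * rng.uniform(0.5, 1.5, size=8)[None, :]
    semg += subject.noise.measurement_sd_v * rng.standard_normal((n, 8))
    return semg


def synthesize_torque(
    excitations: np.ndarray,
    subject: SyntheticSubject,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
    sample_rate_hz: float = SAMPLE_RATE_DEFAULT,
) -> np.ndarray:
    """Ground-truth forward torque plus optional Gaussian sensor noise."""
    tau = forward_pbm(
        excitations, subject.ground_truth, sample_rate_hz=sample_rate_hz
    )
    if noise_sd is None:
        noise_sd = subject.noise.torque_sd_frac * (
            subject.mvc_flex + abs(subject.mvc_ext)
        )
    if noise_sd > 0:
        if rng is None:
            raise InvalidInputError("rng required when noise_sd > 0")
        tau = tau + noise_sd * rng.standard_normal(tau.shape[0])
    return tau


def clean_processed_recording(
    subject: SyntheticSubject,
    n_samples: int = N_SAMPLES_DEFAULT,
    sample_rate_hz: float = SAMPLE_RATE_DEFAULT,
    torque_noise_sd: float = 0.0,
    seed: int | None = None,
) -> ProcessedRecording:
    """Noise-free envelopes (the excitations themselves) + true torque.

    Bypasses the stochastic carrier so that calibration recovery can be
    assessed against an exactly known envelope -> torque map.
    """
    exc, _ = generate_excitation_schedule(
        n_samples, sample_rate_hz, seed=subject.seed,
        coactivation=subject.coactivation,
        participation_jitter=subject.participation_jitter,
        modulation_sd=subject.modulation_sd,
        secondary_scale=subject.secondary_scale,
        muscles=subject.ground_truth.muscles,
    )
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    tau = synthesize_torque(
        exc, subject, rng=rng, noise_sd=torque_noise_sd,
        sample_rate_hz=sample_rate_hz,
    )
    return ProcessedRecording(
        sample_rate_hz=sample_rate_hz, envelopes=exc, torque=tau,
        channel_names=tuple(m.name for m in subject.ground_truth.muscles),
        provenance=("synthetic_clean",), subject_id=subject.subject_id,
    )


# ---------------------------------------------------------------------------
# Subjects, drift, cohort
# ---------------------------------------------------------------------------

def _random_mixing(rng: np.random.Generator, off_scale=0.08) -> np.ndarray:
    X = np.eye(8)
    off = rng.uniform(0.02, off_scale, size=(8, 8))
    # crosstalk strongest between anatomically adjacent channels
    for i in range(8):
        for j in range(8):
            if i != j:
                X[i, j] = off[i, j] / (1 + abs(i - j))
    return X


def draw_subject(
    subject_id: str,
    seed: int,
    muscle_table=None,
) -> SyntheticSubject:
    """Draw ground-truth parameters uniformly inside their bounds."""
    rng = np.random.default_rng(seed)
    table = muscle_table if muscle_table is not None else load_muscle_table()
    muscles = build_muscles(CHANNEL_NAMES, table)
    gt_muscles = []
    for m in muscles:
        gt_muscles.append(replace(
            m,
            fmax_N=float(rng.uniform(*m.fmax_bounds_N)),
            ma_m=float(rng.uniform(*m.ma_bounds_m)),
        ))
    activation = ActivationParams(
        A=float(rng.uniform(-2.5, -0.5)),
        C1=float(rng.uniform(-0.5, 0.5)),
        C2=float(rng.uniform(-0.5, 0.5)),
        d_ms=float(rng.uniform(20.0, 80.0)),
    )
    crosstalk = _random_mixing(rng)
    # supination rotates the forearm under the electrode array, so
    # channels largely end up over the opposite muscle group: blend the
    # resting matrix with a half-array circular shift (flexor channels
    # pick up mostly extensor activity and vice versa)
    shifted = np.roll(crosstalk, 4, axis=1)
    posture_crosstalk = 0.35 * crosstalk + 0.65 * shifted
    posture_crosstalk += np.eye(8) * 0.45  # keep diagonal dominance
    return SyntheticSubject(
        subject_id=subject_id,
        ground_truth=PBMParameters(activation=activation, muscles=gt_muscles),
        crosstalk=crosstalk,
        channel_gains=rng.uniform(1.0e-3, 2.5e-3, size=8),
        posture_crosstalk=posture_crosstalk,
        posture_gains=rng.uniform(0.8e-3, 2.8e-3, size=8),
        seed=seed,
    )


def draw_drift(
    rng: np.random.Generator,
    gain_range: tuple[float, float] = (0.7, 1.3),
    exponent_dev: float = 0.18,
    mvc_scale_range: tuple[float, float] = (0.8, 1.0),
    electrode_shift_max: float = 0.45,
    with_shift: bool = False,
    base_crosstalk: np.ndarray | None = None,
) -> DriftSpec:
    """Session-2 style (gain ramp + EMG-force warp) or session-3 style
    (additionally a crosstalk shift from electrode replacement).

    The EMG-force exponent deviates from 1 by a fixed magnitude
    ``exponent_dev`` with a random sign per channel — fixing the
    magnitude keeps the drift severity comparable across draws. Replaced
    electrodes land slightly off the original sites, so the shift moves
    each channel's pickup toward its neighbour's: an additive
    perturbation rho * (roll(X) - X) blending the base crosstalk X with a
    one-position circular shift, rho drawn up to ``electrode_shift_max``.
    """
    shift = None
    if with_shift:
        if base_crosstalk is None:
            raise InvalidInputError(
                "electrode shift needs the subject's base crosstalk"
            )
        rho = rng.uniform(0.65 * electrode_shift_max, electrode_shift_max)
        X = np.asarray(base_crosstalk, dtype=float)
        shift = rho * (np.roll(X, 1, axis=1) - X)
    signs = rng.choice([-1.0, 1.0], size=8)
    return DriftSpec(
        gain_drift=rng.uniform(*gain_range, size=8),
        emg_exponent=1.0 + exponent_dev * signs,
        mvc_scale=rng.uniform(*mvc_scale_range, size=8),
        electrode_shift=shift,
    )


def apply_drift(
    recording: Recording, drift: DriftSpec, seed: int = 0
) -> Recording:
    """Post-hoc drift on an existing recording.

    The gain ramp is exact; electrode shift and posture remap are
    approximated by remixing the recorded channels (mixing independent
    carriers adds in quadrature rather than linearly, which is adequate
    for the qualitative transfer-degradation studies).
    """
    semg = recording.semg.copy()
    torque = recording.torque.copy()
    if drift.posture_remap is not None:
        remap = np.asarray(drift.posture_remap, dtype=float)
        semg = semg @ remap.T
        if drift.flip_torque_sign:
            torque = -torque
    if drift.electrode_shift is not None:
        mixing = np.eye(semg.shape[1]) + np.asarray(drift.electrode_shift)
        off = mixing - np.diag(np.diag(mixing))
        if not np.all(np.diag(mixing) > off.max(axis=1)):
            raise InvalidParameterError(
                "electrode shift destroys mixing diagonal dominance"
            )
        semg = semg @ mixing.T
    if drift.emg_exponent is not None:
        # warp instantaneous amplitude relative to the channel maximum
        g = np.asarray(drift.emg_exponent, dtype=float)[None, :]
        peak = np.abs(semg).max(axis=0, keepdims=True)
        peak = np.where(peak > 0, peak, 1.0)
        semg = np.sign(semg) * peak * (np.abs(semg) / peak) ** g
    if drift.gain_drift is not None:
        semg = semg * _gain_profile(semg.shape[0], drift.gain_drift)
    return replace(recording, semg=semg, torque=torque)


def generate_recording(
    subject: SyntheticSubject,
    session_id: str = "s1",
    posture: str = "pronated",
    drift: DriftSpec | None = None,
    n_samples: int = N_SAMPLES_DEFAULT,
    sample_rate_hz: float = SAMPLE_RATE_DEFAULT,
    seed: int | None = None,
) -> Recording:
    """One protocol execution: fresh excitations, SEMG and torque.

    Supinated recordings are produced through the posture crosstalk map
    and carry sensor-frame torque (sign reversed), matching how the
    hardware would record them.
    """
    rng = np.random.default_rng(
        subject.seed if seed is None else seed
    )
    drift = drift or DriftSpec()
    exc, _ = generate_excitation_schedule(
        n_samples, sample_rate_hz,
        seed=int(rng.integers(2**31)),
        coactivation=subject.coactivation,
        participation_jitter=subject.participation_jitter,
        modulation_sd=subject.modulation_sd,
        secondary_scale=subject.secondary_scale,
        mvc_participation=drift.mvc_scale,
        muscles=subject.ground_truth.muscles,
    )
    if posture == "supinated":
        drift = replace(
            drift, posture_remap=subject.posture_crosstalk,
            flip_torque_sign=True,
        )
    semg = synthesize_raw_semg(
        exc, subject, rng, sample_rate_hz=sample_rate_hz, drift=drift
    )
    torque = synthesize_torque(
        exc, subject, rng=rng, sample_rate_hz=sample_rate_hz
    )
    if drift.flip_torque_sign:
        torque = -torque
    return Recording(
        sample_rate_hz=sample_rate_hz, semg=semg, torque=torque,
        channel_names=tuple(m.name for m in subject.ground_truth.muscles),
        session_id=session_id, posture=posture,
        subject_id=subject.subject_id,
    )


@dataclass
class CohortConfig:
    n_subjects: int = 11
    n_samples: int = N_SAMPLES_DEFAULT
    sample_rate_hz: float = SAMPLE_RATE_DEFAULT
    gain_drift_range_s2: tuple[float, float] = (0.8, 1.2)
    emg_exponent_dev_s2: float = 0.15
    mvc_scale_range_s2: tuple[float, float] = (0.8, 1.0)
    # re-strapping the forearm after an hour shifts the muscles slightly
    # under the attached electrodes; replacing electrodes a day later
    # displaces the array further
    restrap_shift_rho_s2: tuple[float, float] = (0.15, 0.25)
    s3_amplification: tuple[float, float] = (1.3, 1.6)
    electrode_shift_roll: int = 2
    electrode_shift_rho: tuple[float, float] = (0.40, 0.50)


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SyntheticSubject]
    recordings: dict  # (subject_id, session_id, posture) -> Recording
    master_seed: int = 0

    def recording(self, subject_id, session_id, posture="pronated"):
        return self.recordings[(subject_id, session_id, posture)]

    def manifest(self) -> dict:
        out = {"master_seed": self.master_seed, "subjects": {}}
        for s in self.subjects:
            gt = s.ground_truth
            out["subjects"][s.subject_id] = {
                "seed": s.seed,
                "activation": {
                    "A": gt.activation.A, "C1": gt.activation.C1,
                    "C2": gt.activation.C2, "d_ms": gt.activation.d_ms,
                },
                "fmax_N": [m.fmax_N for m in gt.muscles],
                "ma_m": [m.ma_m for m in gt.muscles],
                "mvc_flex_nm": s.mvc_flex,
                "mvc_ext_nm": s.mvc_ext,
            }
        return out


def generate_cohort(
    n_subjects: int = 11,
    config: CohortConfig | None = None,
    master_seed: int = 0,
) -> Cohort:
    """Full study: per subject s1 pronated + supinated, s2, s3.

    Session 2 applies a gain-drift ramp; session 3 a stronger drift plus
    an electrode-shift crosstalk perturbation. All randomness descends
    from ``master_seed``.
    """
    if n_subjects < 1:
        raise InvalidParameterError("need at least one subject")
    config = config or CohortConfig(n_subjects=n_subjects)
    root = np.random.default_rng(master_seed)
    subjects, recordings = [], {}
    for i in range(n_subjects):
        sid = f"sub{i + 1:02d}"
        subject = draw_subject(sid, seed=int(root.integers(2**31)))
        subjects.append(subject)
        drift_rng = np.random.default_rng(int(root.integers(2**31)))
        drift_s2 = draw_drift(
            drift_rng, config.gain_drift_range_s2,
            config.emg_exponent_dev_s2,
            config.mvc_scale_range_s2, with_shift=False,
        )
        X = subject.crosstalk
        rho2 = drift_rng.uniform(*config.restrap_shift_rho_s2)
        drift_s2 = replace(
            drift_s2,
            electrode_shift=rho2 * (np.roll(X, 1, axis=1) - X),
        )
        # twenty-four hours embeds the one-hour drift: amplify its
        # deviations and add the electrode-replacement crosstalk shift
        # (re-applied electrodes landing up to two positions off), so
        # session 3 is a stochastically stronger perturbation than s2
        amp = drift_rng.uniform(*config.s3_amplification)
        rho = drift_rng.uniform(*config.electrode_shift_rho)
        drift_s3 = DriftSpec(
            gain_drift=1.0 + amp * (drift_s2.gain_drift - 1.0),
            emg_exponent=1.0 + amp * (drift_s2.emg_exponent - 1.0),
            mvc_scale=np.clip(
                1.0 + amp * (drift_s2.mvc_scale - 1.0), 0.5, 1.0
            ),
            electrode_shift=rho * (
                np.roll(X, config.electrode_shift_roll, axis=1) - X
            ),
        )
        sessions = {
            ("s1", "pronated"): None,
            ("s1", "supinated"): None,
            ("s2", "pronated"): drift_s2,
            ("s3", "pronated"): drift_s3,
        }
        for (session_id, posture), drift in sessions.items():
            recordings[(sid, session_id, posture)] = generate_recording(
                subject, session_id=session_id, posture=posture, drift=drift,
                n_samples=config.n_samples,
                sample_rate_hz=config.sample_rate_hz,
                seed=int(root.integers(2**31)),
            )
    return Cohort(
        config=config, subjects=subjects, recordings=recordings,
        master_seed=master_seed,
    )
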