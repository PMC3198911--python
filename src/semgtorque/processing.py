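"""SEMG signal conditioning: DC removal, zero-phase band filtering,
rectification, per-channel normalization and decimation.

The chain converts raw multi-channel surface-EMG voltages into
dimensionless activation envelopes in [0, 1]:

    remove DC -> 30 Hz high-pass (motion artifact) -> full-wave rectify
    -> 6 Hz low-pass (envelope smoothing) -> normalize to the
    per-channel maximum

(The smoothing low-pass must follow rectification: a 6 Hz low-pass of
the raw interference signal, whose power lives above 30 Hz, would leave
essentially nothing to rectify.) Both filters are 4th-order Butterworth
designs applied forward and backward (zero phase lag), so the effective
magnitude response is the squared design response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import yaml
from scipy import signal as sps

from .exceptions import (
    DegenerateChannelWarning,
    InvalidInputError,
    InvalidParameterError,
)

#: Channel order used throughout: four wrist extensors then four flexors.
CHANNEL_NAMES: tuple[str, ...] = (
    "ECRL", "EDC", "ECU", "ECRB", "FCR", "PL", "FDS", "FCU",
)

SESSIONS = ("s1", "s2", "s3")
POSTURES = ("pronated", "supinated")


@dataclass
class Recording:
    """Raw synchronous SEMG + wrist-torque recording.

    semg is (N, M) in volts; torque is (N,) in N·m with flexion positive
    and extension negative as acquired (supinated sessions may carry a
    reversed sensor sign until harmonized by :func:`process_recording`).
    """

    sample_rate_hz: float
    semg: np.ndarray
    torque: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    session_id: str = "s1"
    posture: str = "pronated"
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.semg = np.asarray(self.semg, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample_rate_hz must be positive")
        if self.semg.ndim != 2:
            raise InvalidInputError("semg must be 2-D (samples x channels)")
        if self.semg.shape[0] < 1:
            raise InvalidInputError("recording must contain at least one sample")
        if self.torque.shape != (self.semg.shape[0],):
            raise InvalidInputError(
                "torque length must equal the SEMG sample count"
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.semg.shape[1]:
            raise InvalidInputError("one channel name per SEMG column required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidInputError("channel names must be unique")
        if self.session_id not in SESSIONS:
            raise InvalidParameterError(f"unknown session_id {self.session_id!r}")
        if self.posture not in POSTURES:
            raise InvalidParameterError(f"unknown posture {self.posture!r}")

    @property
    def n_samples(self) -> int:
        return self.semg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.semg.shape[1]


@dataclass
class ProcessedRecording:
    """Normalized activation envelopes plus the (untouched) torque channel."""

    sample_rate_hz: float
    envelopes: np.ndarray
    torque: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    provenance: tuple[str, ...] = ()
    session_id: str = "s1"
    posture: str = "pronated"
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.envelopes = np.asarray(self.envelopes, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        if self.envelopes.shape[0] != self.torque.shape[0]:
            raise InvalidInputError("envelope/torque length mismatch")
        self.channel_names = tuple(self.channel_names)
        self.provenance = tuple(self.provenance)

    @property
    def n_samples(self) -> int:
        return self.envelopes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.envelopes.shape[1]


@dataclass
class ProcessingConfig:
    """Settings for the conditioning chain.

    ``pad_factor`` controls the reflective padding used by the zero-phase
    filter (pad length = pad_factor cutoff periods at each end).
    """

    highpass_hz: float = 30.0
    lowpass_hz: float = 6.0
    order: int = 4
    resample_k: int = 100
    pad_factor: int = 3
    flip_supinated_torque: bool = True

    @classmethod
    def from_yaml(cls, path) -> "ProcessingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def remove_dc(signal: np.ndarray) -> np.ndarray:
    """Subtract the signal mean. Output mean is zero by construction."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise InvalidInputError("cannot remove DC from an empty series")
    return x - x.mean(axis=0)


def zero_lag_butterworth(
    signal: np.ndarray,
    cutoff_hz: float,
    kind: Literal["highpass", "lowpass"],
    order: int = 4,
    sample_rate_hz: float = 1000.0,
    pad_factor: int = 3,
) -> np.ndarray:
    """Butterworth filter applied forward then backward (zero phase lag).

    ``order`` is the order of the one-way design; the bidirectional
    magnitude response is its square.
    """
    x = np.asarray(signal, dtype=float)
    nyq = sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)"
        )
    if kind not in ("highpass", "lowpass"):
        raise InvalidParameterError(f"unknown filter kind {kind!r}")
    sos = sps.butter(order, cutoff_hz, btype=kind, fs=sample_rate_hz, output="sos")
    # reflective padding at both ends; the pad must cover the filter's
    # settling time, which scales with the cutoff period, not the order
    padlen = int(round(pad_factor * sample_rate_hz / cutoff_hz))
    if x.shape[0] <= padlen:
        raise InvalidInputError(
            f"series of length {x.shape[0]} too short for padding ({padlen})"
        )
    return sps.sosfiltfilt(sos, x, axis=0, padtype="even", padlen=padlen)


def rectify_and_normalize(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectify and scale so the per-channel maximum equals 1.

    Identically-zero channels are returned unchanged with a
    :class:`DegenerateChannelWarning`.
    """
    x = np.abs(np.asarray(signal, dtype=float))
    if x.size == 0:
        raise InvalidInputError("cannot normalize an empty series")
    peak = x.max(axis=0)
    if x.ndim == 1:
        if peak == 0:
            warnings.warn("channel is identically zero", DegenerateChannelWarning)
            return x
        return x / peak
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        if peak[j] == 0:
            warnings.warn(
                f"channel {j} is identically zero", DegenerateChannelWarning
            )
            out[:, j] = 0.0
        else:
            out[:, j] = x[:, j] / peak[j]
    return out


def process_recording(
    raw: Recording, config: ProcessingConfig | None = None
) -> ProcessedRecording:
    """Run the full conditioning chain on every SEMG channel.

    The torque channel is passed through unfiltered; for supinated
    recordings its sign is flipped at this stage (the sensor reads
    flexion/extension reversed when the forearm is supinated) so that
    flexion is always positive internally.
    """
    config = config or ProcessingConfig()
    env = np.empty_like(raw.semg)
    for j, name in enumerate(raw.channel_names):
        try:
            x = remove_dc(raw.semg[:, j])
            x = zero_lag_butterworth(
                x, config.highpass_hz, "highpass", config.order,
                raw.sample_rate_hz, config.pad_factor,
            )
            x = np.abs(x)  # full-wave rectification
            x = zero_lag_butterworth(
                x, config.lowpass_hz, "lowpass", config.order,
                raw.sample_rate_hz, config.pad_factor,
            )
            # zero-phase smoothing can ring slightly below zero
            x = np.clip(x, 0.0, None)
        except (InvalidInputError, InvalidParameterError) as err:
            raise type(err)(f"channel {name}: {err}") from err
        env[:, j] = rectify_and_normalize(x)
    torque = raw.torque.copy()
    provenance = [
        "remove_dc",
        f"highpass_{config.highpass_hz:g}Hz_order{config.order}_zero_lag",
        "full_wave_rectify",
        f"lowpass_{config.lowpass_hz:g}Hz_order{config.order}_zero_lag",
        "normalize_per_channel_max",
    ]
    if raw.posture == "supinated" and config.flip_supinated_torque:
        torque = -torque
        provenance.append("flip_supinated_torque_sign")
    return ProcessedRecording(
        sample_rate_hz=raw.sample_rate_hz,
        envelopes=env,
        torque=torque,
        channel_names=raw.channel_names,
        provenance=tuple(provenance),
        session_id=raw.session_id,
        posture=raw.posture,
        subject_id=raw.subject_id,
    )


def resample_indices(n: int, k: int) -> np.ndarray:
    """Decimation indices k-1, 2k-1, ... (floor(n/k) of them)."""
    if k < 1:
        raise InvalidParameterError("k must be a positive integer")
    if k > n:
        raise InvalidParameterError(f"k={k} exceeds the series length {n}")
    return np.arange(k - 1, n, k)


def resample_every(processed: ProcessedRecording, k: int) -> ProcessedRecording:
    """Keep every k-th sample (indices k-1, 2k-1, ...) of envelopes and torque.

    A 33,520-sample recording decimated with k = 100 yields exactly 335
    samples.
    """
    idx = resample_indices(processed.n_samples, k)
    return replace(
        processed,
        envelopes=processed.envelopes[idx],
        torque=processed.torque[idx],
        sample_rate_hz=processed.sample_rate_hz / k,
        provenance=processed.provenance + (f"resample_every_{k}",),
    )
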