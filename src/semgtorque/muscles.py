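"""Forearm muscle physiology: maximum forces, moment arms, PCSA bookkeeping.

Each surface channel stands in for the deep/intermediate muscles in its
anatomical proximity (EDC for EDM/EIP/EPL, PL for FPL, FDS for FDP), and
its torque contribution is scaled by sigma PCSA / PCSA, where sigma PCSA
sums the channel muscle's own physiological cross-sectional area with
those of the muscles it represents.

The bundled table `data/muscle_parameters.csv` carries representative
literature-scale values: Fmax is approximately 35 N/cm^2 of PCSA, wrist
flexion-extension moment arms are 10-19 mm at the neutral position with
flexors signed positive and extensors negative, and the SD columns (20%
of the mean) define the +-1 SD calibration bounds. The table is plain
CSV and can be replaced by the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError
from .processing import CHANNEL_NAMES

PRIMARY_CHANNELS: tuple[str, ...] = ("ECRL", "ECU", "ECRB", "FCR", "FCU")
#: The six one-flexor/one-extensor pairs of primary wrist muscles.
PRIMARY_PAIRS: tuple[tuple[str, str], ...] = (
    ("FCR", "ECRL"), ("FCR", "ECRB"), ("FCR", "ECU"),
    ("FCU", "ECRL"), ("FCU", "ECRB"), ("FCU", "ECU"),
)


@dataclass
class MusclePhysiology:
    """Per-channel muscle constants with calibration bounds."""

    name: str
    role: str  # "flexor" | "extensor"
    fmax_N: float
    fmax_bounds_N: tuple[float, float]
    ma_m: float
    ma_bounds_m: tuple[float, float]
    pcsa_cm2: float
    sigma_pcsa_cm2: float

    def __post_init__(self) -> None:
        if self.role not in ("flexor", "extensor"):
            raise InvalidParameterError(f"unknown role {self.role!r}")
        if self.fmax_N <= 0 or self.pcsa_cm2 <= 0:
            raise InvalidParameterError("fmax and PCSA must be positive")
        if self.sigma_pcsa_cm2 < self.pcsa_cm2:
            raise InvalidParameterError("sigma PCSA cannot be below own PCSA")
        sign = 1.0 if self.role == "flexor" else -1.0
        if np.sign(self.ma_m) != sign:
            raise InvalidParameterError(
                f"{self.name}: moment-arm sign must match the {self.role} role"
            )

    @property
    def pcsa_weight(self) -> float:
        """sigma PCSA / PCSA scaling of this channel's torque."""
        return self.sigma_pcsa_cm2 / self.pcsa_cm2


def load_muscle_table(path=None) -> pd.DataFrame:
    """Load the physiology CSV (bundled default) indexed by muscle name."""
    if path is None:
        ref = resources.files("semgtorque.data") / "muscle_parameters.csv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    table = table.set_index("muscle", drop=False)
    rep = []
    for _, row in table.iterrows():
        extra = row.get("represents_pcsa_cm2")
        if isinstance(extra, str) and extra.strip():
            rep.append(sum(float(v) for v in extra.split(";")))
        else:
            rep.append(0.0)
    table["sigma_pcsa_cm2"] = table["pcsa_cm2"] + np.asarray(rep)
    return table


def _sigma_pcsa_for_subset(
    table: pd.DataFrame, channels: tuple[str, ...]
) -> dict[str, float]:
    """Redistribute total PCSA over the channels actually recorded.

    - all 8 channels: each channel keeps its own sigma PCSA;
    - the 5 primary channels: half of the non-primary flexor PCSA total is
      added to each primary flexor, a third of the non-primary extensor
      total to each primary extensor;
    - one flexor + one extensor: each carries the full PCSA total of its
      role group.
    """
    channels = tuple(channels)
    roles = table["role"]
    if set(channels) == set(CHANNEL_NAMES):
        return {c: float(table.loc[c, "sigma_pcsa_cm2"]) for c in channels}
    if set(channels) == set(PRIMARY_CHANNELS):
        out = {}
        for role, share in (("flexor", 2), ("extensor", 3)):
            members = [c for c in channels if roles[c] == role]
            missing = [
                m for m in table.index
                if roles[m] == role and m not in channels
            ]
            extra = sum(float(table.loc[m, "sigma_pcsa_cm2"]) for m in missing)
            for c in members:
                out[c] = float(table.loc[c, "sigma_pcsa_cm2"]) + extra / share
        return out
    if len(channels) == 2:
        r = {roles[c] for c in channels}
        if r != {"flexor", "extensor"}:
            raise InvalidInputError(
                "a two-channel model needs one flexor and one extensor"
            )
        totals = table.groupby("role")["sigma_pcsa_cm2"].sum()
        return {c: float(totals[roles[c]]) for c in channels}
    raise InvalidInputError(
        f"unsupported channel subset {channels!r}: expected all 8, the 5 "
        "primary channels, or one flexor + one extensor"
    )


def build_muscles(
    channels: tuple[str, ...] = CHANNEL_NAMES,
    table: pd.DataFrame | None = None,
) -> list[MusclePhysiology]:
    """Build per-channel physiology (with subset PCSA redistribution)."""
    table = table if table is not None else load_muscle_table()
    unknown = [c for c in channels if c not in table.index]
    if unknown:
        raise InvalidInputError(f"unknown channels {unknown}")
    sigma = _sigma_pcsa_for_subset(table, tuple(channels))
    muscles = []
    for c in channels:
        row = table.loc[c]
        muscles.append(
            MusclePhysiology(
                name=c,
                role=row["role"],
                fmax_N=float(row["fmax_mean_N"]),
                fmax_bounds_N=(
                    float(row["fmax_mean_N"] - row["fmax_sd_N"]),
                    float(row["fmax_mean_N"] + row["fmax_sd_N"]),
                ),
                ma_m=float(row["ma_mean_m"]),
                ma_bounds_m=tuple(sorted((
                    float(row["ma_mean_m"] - row["ma_sd_m"]),
                    float(row["ma_mean_m"] + row["ma_sd_m"]),
                ))),
                pcsa_cm2=float(row["pcsa_cm2"]),
                sigma_pcsa_cm2=sigma[c],
            )
        )
    return muscles
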