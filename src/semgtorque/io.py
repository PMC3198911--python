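"""Recording CSV + JSON-sidecar persistence.

A recording is stored as ``<stem>.csv`` with columns
``time_s, ch1..chM, torque_nm`` and a ``<stem>.json`` sidecar carrying
``sample_rate_hz``, ``subject_id``, ``session_id``, ``posture`` and the
ordered ``channel_names``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .processing import Recording


def write_recording(recording: Recording, stem) -> tuple[Path, Path]:
    """Write ``<stem>.csv`` and ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    n, m = recording.semg.shape
    frame = pd.DataFrame(
        {"time_s": np.arange(n) / recording.sample_rate_hz}
        | {f"ch{j + 1}": recording.semg[:, j] for j in range(m)}
        | {"torque_nm": recording.torque}
    )
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    frame.to_csv(csv_path, index=False, float_format="%.6g")
    sidecar = {
        "sample_rate_hz": recording.sample_rate_hz,
        "subject_id": recording.subject_id,
        "session_id": recording.session_id,
        "posture": recording.posture,
        "channel_names": list(recording.channel_names),
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


def read_recording(stem) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    if not csv_path.exists() or not json_path.exists():
        raise InvalidInputError(
            f"expected both {csv_path.name} and {json_path.name}"
        )
    sidecar = json.loads(json_path.read_text())
    frame = pd.read_csv(csv_path)
    channels = sidecar["channel_names"]
    cols = [f"ch{j + 1}" for j in range(len(channels))]
    missing = [c for c in cols + ["torque_nm"] if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"CSV is missing columns {missing}")
    return Recording(
        sample_rate_hz=float(sidecar["sample_rate_hz"]),
        semg=frame[cols].to_numpy(),
        torque=frame["torque_nm"].to_numpy(),
        channel_names=tuple(channels),
        session_id=sidecar.get("session_id", "s1"),
        posture=sidecar.get("posture", "pronated"),
        subject_id=sidecar.get("subject_id", "subject"),
    )
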