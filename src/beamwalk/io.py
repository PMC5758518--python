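"""Canonical trial file format: tidy CSV of endpoints + JSON sidecar.

One CSV per trial with columns ``time_s, segment, end, x_m, y_m, z_m``
(``end`` is ``proximal`` or ``distal``), plus a sidecar JSON holding
``participant_id, mass_kg, height_m, success, sampling_rate_hz, trial_id``.
Floats are written with 17 significant digits, so write -> read round-trips
exactly.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import SEGMENTS
from .body_model import SegmentKinematics, TrialRecord

_SIDECAR_FIELDS = ("participant_id", "mass_kg", "height_m", "success",
                   "sampling_rate_hz")
_CSV_COLUMNS = ("time_s", "segment", "end", "x_m", "y_m", "z_m")


class TrialFormatError(ValueError):
    """Raised for schema violations in trial files."""


def sidecar_path_for(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_trial(trial: TrialRecord, csv_path: str | Path,
                sidecar_path: str | Path | None = None) -> None:
    csv_path = Path(csv_path)
    sidecar_path = sidecar_path_for(csv_path) if sidecar_path is None \
        else Path(sidecar_path)
    kin = trial.kinematics
    t, n = kin.n_frames, len(kin.segment_names)
    frames = []
    for end, arr in (("proximal", kin.proximal), ("distal", kin.distal)):
        frames.append(pd.DataFrame({
            "time_s": np.repeat(kin.frame_times, n),
            "segment": np.tile(list(kin.segment_names), t),
            "end": end,
            "x_m": arr[:, :, 0].ravel(),
            "y_m": arr[:, :, 1].ravel(),
            "z_m": arr[:, :, 2].ravel(),
        }))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(csv_path, index=False, float_format="%.17g", lineterminator="\n")
    sidecar = {
        "participant_id": trial.participant_id,
        "trial_id": trial.trial_id,
        "mass_kg": kin.participant_mass,
        "height_m": kin.participant_height,
        "success": trial.success,
        "sampling_rate_hz": kin.sampling_rate,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")


def read_trial(csv_path: str | Path,
               sidecar_path: str | Path | None = None) -> TrialRecord:
    csv_path = Path(csv_path)
    sidecar_path = sidecar_path_for(csv_path) if sidecar_path is None \
        else Path(sidecar_path)
    if not sidecar_path.exists():
        raise TrialFormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    for fld in _SIDECAR_FIELDS:
        if fld not in sidecar:
            raise TrialFormatError(f"sidecar {sidecar_path} missing field {fld!r}")

    table = pd.read_csv(csv_path, skipinitialspace=True)
    table.columns = [c.strip() for c in table.columns]
    missing = set(_CSV_COLUMNS) - set(table.columns)
    if missing:
        raise TrialFormatError(f"{csv_path}: missing columns {sorted(missing)}")
    for col in ("segment", "end"):
        table[col] = table[col].astype(str).str.strip()
    bad_end = set(table["end"].unique()) - {"proximal", "distal"}
    if bad_end:
        raise TrialFormatError(f"{csv_path}: invalid 'end' values {sorted(bad_end)}")
    segs = [s for s in SEGMENTS if s in set(table["segment"])]
    if set(table["segment"].unique()) - set(SEGMENTS):
        segs = sorted(table["segment"].unique())  # non-canonical scenes
    times = np.sort(table["time_s"].unique())

    arrays = {}
    for end in ("proximal", "distal"):
        sub = table[table["end"] == end]
        pivots = [sub.pivot_table(index="time_s", columns="segment", values=col,
                                  sort=True)
                  for col in ("x_m", "y_m", "z_m")]
        for p in pivots:
            if p.isna().any().any():
                row, col = np.argwhere(p.isna().to_numpy())[0]
                raise TrialFormatError(
                    f"{csv_path}: missing {end} sample for segment "
                    f"{p.columns[col]!r} at t={p.index[row]} s")
        arrays[end] = np.stack([p[segs].to_numpy() for p in pivots], axis=2)

    kin = SegmentKinematics(
        frame_times=times, proximal=arrays["proximal"], distal=arrays["distal"],
        sampling_rate=float(sidecar["sampling_rate_hz"]),
        participant_mass=float(sidecar["mass_kg"]),
        participant_height=float(sidecar["height_m"]),
        segment_names=tuple(segs))
    return TrialRecord(kinematics=kin, success=bool(sidecar["success"]),
                       trial_id=str(sidecar.get("trial_id", csv_path.stem)),
                       participant_id=str(sidecar["participant_id"]))


def read_trial_directory(directory: str | Path) -> tuple[list[TrialRecord], list[str]]:
    """Read every ``*.csv`` trial in a directory; malformed files are skipped
    and reported in the returned error list."""
    directory = Path(directory)
    trials, errors = [], []
    for csv_path in sorted(directory.glob("*.csv")):
        try:
            trials.append(read_trial(csv_path))
        except (TrialFormatError, ValueError) as exc:
            errors.append(f"{csv_path.name}: {exc}")
    return trials, errors
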