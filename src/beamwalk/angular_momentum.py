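"""Segmental angular momentum about head, COM and beam reference axes.

Each body segment i contributes

    L_i(r_P) = (r_COM,i - r_P) x m_i v_COM,i + I_i w_i

to the whole-body angular momentum about an axis through the point P. Only
the x-component (parallel to the beam) is analysed — it is the component
that drives rotations in the medio-lateral plane — so in planar coordinates

    L_i,x = m_i [ (y_i - y_P) vz_i - (z_i - z_P) vy_i ] + I_i,x * w_i .

Three reference axes are used: a fixed point at the participant's average
head position, the (time-varying) whole-body COM, and a fixed point at the
centre of the beam.  Momenta are rendered dimensionless by dividing by
body mass * walking speed * body height before any dimensionality analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .anthropometry import SEGMENTS
from .body_model import SegmentStates

AXIS_KINDS = ("head", "com", "beam")


class AngularMomentumError(ValueError):
    """Raised for mismatched axes/frames or invalid normalization factors."""


@dataclass(frozen=True)
class AxisSpec:
    """A reference axis parallel to x, through a fixed or per-frame point.

    ``point_yz`` is shape (2,) for the fixed head/beam axes and (T, 2) for
    the per-frame whole-body-COM axis.
    """

    kind: str
    point_yz: np.ndarray

    def __post_init__(self):
        if self.kind not in AXIS_KINDS:
            raise AngularMomentumError(f"axis kind {self.kind!r} not in {AXIS_KINDS}")
        pt = np.asarray(self.point_yz, dtype=float)
        if self.kind == "com":
            if pt.ndim != 2 or pt.shape[1] != 2:
                raise AngularMomentumError("COM axis needs a (T, 2) trajectory")
        elif pt.shape != (2,):
            raise AngularMomentumError(f"{self.kind} axis needs a fixed (2,) point")
        object.__setattr__(self, "point_yz", pt)

    @classmethod
    def beam(cls, y: float = 0.0, z: float = 0.0) -> "AxisSpec":
        """Centre of the beam; default on the floor at (0, 0), configurable
        (e.g. z = 0.034 m for the beam top)."""
        return cls("beam", np.array([y, z]))

    @classmethod
    def head(cls, point_yz) -> "AxisSpec":
        """Per-participant average head position across all trials."""
        return cls("head", np.asarray(point_yz, dtype=float))

    @classmethod
    def com(cls, trajectory_yz) -> "AxisSpec":
        return cls("com", np.asarray(trajectory_yz, dtype=float))


@dataclass
class AMDecomposition:
    """time x segment matrix of x-axis angular-momentum contributions.

    ``values`` is kg m^2/s when ``normalization`` is None, dimensionless
    otherwise.
    """

    values: np.ndarray
    axis: AxisSpec
    frame_times: np.ndarray
    segment_names: tuple[str, ...] = SEGMENTS
    normalization: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.frame_times, name="time_s"),
                            columns=list(self.segment_names))


def segment_am(states: SegmentStates, axis: AxisSpec) -> AMDecomposition:
    """Per-segment x-axis angular momentum about ``axis`` (Eq. 1, x-component)."""
    pt = axis.point_yz
    if axis.kind == "com":
        if pt.shape[0] != states.n_frames:
            raise AngularMomentumError(
                f"axis trajectory has {pt.shape[0]} frames, states have {states.n_frames}")
        y_p, z_p = pt[:, 0:1], pt[:, 1:2]
    else:
        y_p, z_p = pt[0], pt[1]
    moment = states.masses * (
        (states.com_y - y_p) * states.vel_z - (states.com_z - z_p) * states.vel_y)
    spin = states.inertia_x * states.angular_velocity
    return AMDecomposition(values=moment + spin, axis=axis,
                           frame_times=states.frame_times.copy(),
                           segment_names=states.segment_names)


def total_am(dec: AMDecomposition) -> np.ndarray:
    """Whole-body angular momentum: exact row sum over segments (Eq. 2)."""
    return dec.values.sum(axis=1)


def normalize_am(dec: AMDecomposition, mass: float, speed: float,
                 height: float) -> AMDecomposition:
    """Dimensionless momenta: divide by body mass * walking speed * height."""
    for name, value in (("mass", mass), ("speed", speed), ("height", height)):
        if not value > 0:
            raise AngularMomentumError(f"normalization {name} must be > 0, got {value}")
    return replace(dec, values=dec.values / (mass * speed * height),
                   normalization={"mass_kg": mass, "speed_m_per_s": speed,
                                  "height_m": height})


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Centered Pearson R; NaN (reported as missing) for constant series."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant total-AM series: correlation undefined, "
                      "reported as missing", stacklevel=3)
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def am_summary(trials: list[dict[str, AMDecomposition]]) -> pd.DataFrame:
    """Correlations and RMS amplitudes of total AM across reference axes.

    ``trials`` holds one dict per trial mapping axis kind -> AMDecomposition
    (all axes sharing that trial's frames). Per trial, the centered Pearson R
    of each axis pair and the RMS of each total are computed; the table
    reports their mean and SD across trials (Table-1 layout).
    """
    rows = []
    for dec_by_axis in trials:
        totals = {kind: total_am(dec) for kind, dec in dec_by_axis.items()}
        n_frames = {v.shape[0] for v in totals.values()}
        if len(n_frames) != 1:
            raise AngularMomentumError("totals for the three axes must share frames")
        row = {}
        kinds = [k for k in AXIS_KINDS if k in totals]
        for i, a in enumerate(kinds):
            for b in kinds[i + 1:]:
                row[f"R_{a}-{b}"] = _pearson(totals[a], totals[b])
        for a in kinds:
            row[f"L_RMS_{a}"] = float(np.sqrt(np.mean(totals[a] ** 2)))
        rows.append(row)
    frame = pd.DataFrame(rows)
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})
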