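"""Planar rigid-body kinematics of the 14-segment chain.

Coordinates follow the beam-walking lab frame: x along the beam (walking
direction), y leftward, z up.  The balance analysis lives entirely in the
medio-lateral (y-z) plane, so endpoint trajectories are low-pass filtered,
projected onto that plane (x set to zero), and converted into per-segment
kinematic states: COM position/velocity, absolute orientation, angular
velocity about the x-axis, mass and moment of inertia.

Sign conventions
----------------
Orientation angles are measured from the +z axis, positive toward +y
(leftward) — the convention in which the trunk angle reads as lateral lean.
The angular velocity is reported about the +x axis with the right-hand rule,
which in this plane is *minus* the time derivative of that reporting angle;
this keeps the spin term I*omega consistent with the x-component of the
cross product (y*vz - z*vy) used in the angular-momentum module.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from graphlib import CycleError, TopologicalSorter

import numpy as np
from scipy.signal import butter, filtfilt

from .anthropometry import PARENTS, SEGMENTS, AnthropometricTable

_DT_TOL = 1e-9


class KinematicsError(ValueError):
    """Raised for invalid kinematic inputs (degenerate geometry, bad windows...)."""


@dataclass
class SegmentKinematics:
    """Endpoint trajectories of the segment chain.

    ``proximal`` and ``distal`` have shape (T, n_segments, 3) in metres, in
    the lab frame. Frame times must be uniformly spaced at 1/sampling_rate.
    """

    frame_times: np.ndarray
    proximal: np.ndarray
    distal: np.ndarray
    sampling_rate: float
    participant_mass: float
    participant_height: float
    segment_names: tuple[str, ...] = SEGMENTS

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        t, n = self.frame_times.shape[0], len(self.segment_names)
        if self.proximal.shape != (t, n, 3) or self.distal.shape != (t, n, 3):
            raise KinematicsError(
                f"endpoint arrays must have shape ({t}, {n}, 3); got "
                f"{self.proximal.shape} and {self.distal.shape}")
        if t >= 2:
            dt = np.diff(self.frame_times)
            if np.any(dt <= 0):
                raise KinematicsError("frame_times must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.sampling_rate) > _DT_TOL):
                raise KinematicsError(
                    "frame_times must be uniform at 1/sampling_rate "
                    f"within {_DT_TOL} s")
        lengths = np.linalg.norm(self.distal - self.proximal, axis=2)
        if np.any(lengths <= 0):
            f, s = np.argwhere(lengths <= 0)[0]
            raise KinematicsError(
                f"segment {self.segment_names[s]!r} has zero length at frame {f}")

    @property
    def n_frames(self) -> int:
        return self.frame_times.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sampling_rate

    def crop(self, start_s: float, end_s: float) -> "SegmentKinematics":
        """Restrict to frames with start_s <= t <= end_s (inclusive)."""
        mask = (self.frame_times >= start_s - _DT_TOL) & (
            self.frame_times <= end_s + _DT_TOL)
        if not mask.any():
            raise KinematicsError(f"empty window [{start_s}, {end_s}] s")
        return replace(self, frame_times=self.frame_times[mask],
                       proximal=self.proximal[mask], distal=self.distal[mask])


@dataclass
class SegmentStates:
    """Per-frame, per-segment planar kinematic state (arrays of shape (T, n))."""

    frame_times: np.ndarray
    com_y: np.ndarray
    com_z: np.ndarray
    vel_y: np.ndarray
    vel_z: np.ndarray
    orientation: np.ndarray        # rad, from +z toward +y, unwrapped
    angular_velocity: np.ndarray   # rad/s about +x (right-hand rule)
    inertia_x: np.ndarray          # kg m^2 about the segment-COM x-axis
    masses: np.ndarray             # (n,) kg
    segment_names: tuple[str, ...] = SEGMENTS

    @property
    def n_frames(self) -> int:
        return self.frame_times.shape[0]


@dataclass
class TrialRecord:
    """One trial: kinematics plus success flag and identifying labels."""

    kinematics: SegmentKinematics
    success: bool
    trial_id: str = ""
    participant_id: str = ""


@dataclass(frozen=True)
class AnalysisWindow:
    """Result of the windowing rule; ``excluded`` trials carry no interval."""

    start_s: float
    end_s: float
    excluded: bool = False
    note: str = ""


def lowpass_filter(kin: SegmentKinematics, cutoff_hz: float = 20.0) -> SegmentKinematics:
    """Zero-phase 4th-order Butterworth low-pass of every coordinate channel.

    Filtering is applied forward-backward (scipy ``filtfilt``), so there is no
    phase lag to distort the timing of the angular-momentum traces.
    """
    nyquist = kin.sampling_rate / 2.0
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise KinematicsError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    b, a = butter(4, cutoff_hz / nyquist)
    t, n = kin.n_frames, len(kin.segment_names)
    prox = filtfilt(b, a, kin.proximal.reshape(t, -1), axis=0).reshape(t, n, 3)
    dist = filtfilt(b, a, kin.distal.reshape(t, -1), axis=0).reshape(t, n, 3)
    return replace(kin, proximal=prox, distal=dist)


def project_to_ml_plane(kin: SegmentKinematics) -> SegmentKinematics:
    """Set the along-beam (x) coordinate of every endpoint to zero."""
    prox = kin.proximal.copy()
    dist = kin.distal.copy()
    prox[:, :, 0] = 0.0
    dist[:, :, 0] = 0.0
    return replace(kin, proximal=prox, distal=dist)


def _gradient(values: np.ndarray, dt: float) -> np.ndarray:
    """Central differences on interior frames, one-sided at the boundaries."""
    return np.gradient(values, dt, axis=0, edge_order=1)


def segment_states(kin: SegmentKinematics,
                   anthro: AnthropometricTable) -> SegmentStates:
    """Planar kinematic state of every segment.

    The segment COM sits at ``com_fraction`` of the way from the proximal to
    the distal endpoint; velocities come from central finite differences; the
    moment of inertia about the x-axis through the segment COM is
    m * (gyration_fraction * length)^2, evaluated per frame so that small
    violations of rigidity in measured data do not bias the spin term.
    """
    names = kin.segment_names
    dy = kin.distal[:, :, 1] - kin.proximal[:, :, 1]
    dz = kin.distal[:, :, 2] - kin.proximal[:, :, 2]
    lengths = np.hypot(dy, dz)
    if np.any(lengths <= 0):
        f, s = np.argwhere(lengths <= 0)[0]
        raise KinematicsError(
            f"segment {names[s]!r} degenerate (zero planar length) at frame {f}")

    if names == SEGMENTS:
        com_frac = anthro.com_fractions
        gyr_frac = anthro.gyration_fractions
        masses = anthro.segment_masses(kin.participant_mass)
    else:  # single-segment oracle scenes reuse the trunk row
        com_frac = np.full(len(names), 0.5)
        gyr_frac = np.full(len(names), 1.0 / np.sqrt(12.0))
        masses = np.full(len(names), kin.participant_mass / len(names))

    com_y = kin.proximal[:, :, 1] + com_frac * dy
    com_z = kin.proximal[:, :, 2] + com_frac * dz
    dt = 1.0 / kin.sampling_rate
    vel_y = _gradient(com_y, dt)
    vel_z = _gradient(com_z, dt)

    theta = np.unwrap(np.arctan2(dy, dz), axis=0)  # leftward-positive
    omega = -_gradient(theta, dt)                  # about +x, right-hand rule
    inertia = masses * (gyr_frac * lengths) ** 2

    return SegmentStates(
        frame_times=kin.frame_times.copy(), com_y=com_y, com_z=com_z,
        vel_y=vel_y, vel_z=vel_z, orientation=theta, angular_velocity=omega,
        inertia_x=inertia, masses=masses, segment_names=names)


def relative_orientations(states: SegmentStates,
                          parents: dict[str, str | None] | None = None) -> np.ndarray:
    """Signed planar angle of each segment relative to its proximal neighbour.

    Columns follow the canonical segment order. The trunk (whose parent is
    ``None``) is measured against the lab z-axis. Raises on a cyclic parent
    map.
    """
    parents = dict(PARENTS if parents is None else parents)
    names = states.segment_names
    try:
        list(TopologicalSorter(
            {s: [] if parents.get(s) is None else [parents[s]] for s in names}
        ).static_order())
    except CycleError as exc:
        raise KinematicsError(f"cyclic parent map: {exc.args}") from exc

    index = {s: i for i, s in enumerate(names)}
    rel = np.empty_like(states.orientation)
    for i, s in enumerate(names):
        parent = parents.get(s)
        if parent is None:
            rel[:, i] = states.orientation[:, i]
        else:
            rel[:, i] = states.orientation[:, i] - states.orientation[:, index[parent]]
    # canonical branch: per-channel mean wrapped into (-pi, pi], so that the
    # arbitrary 2*pi branch picked by unwrapping is consistent across trials
    # when trials are pooled for the covariance analysis
    rel -= 2 * np.pi * np.round(rel.mean(axis=0) / (2 * np.pi))
    return rel


def whole_body_com(states: SegmentStates) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted average of the segment COMs and its velocity.

    Returns ``(position, velocity)``, each of shape (T, 2) holding (y, z).
    The study computed the whole-body COM from the full marker model; here it
    is derived from the same anthropometric table as the inertial properties
    so that the pipeline is self-contained.
    """
    w = states.masses / states.masses.sum()
    pos = np.stack([states.com_y @ w, states.com_z @ w], axis=1)
    dt = float(np.mean(np.diff(states.frame_times))) if states.n_frames > 1 else 1.0
    vel = _gradient(pos, dt)
    return pos, vel


def forward_speed(kin: SegmentKinematics, anthro: AnthropometricTable,
                  window: "AnalysisWindow | None" = None) -> float:
    """Mean along-beam (x) velocity of the whole-body COM, on unprojected data.

    This is the per-trial "walking speed" used to render angular momenta
    dimensionless (normalization by mass * speed * height).
    """
    if window is not None and not window.excluded:
        kin = kin.crop(window.start_s, window.end_s)
    if kin.segment_names == SEGMENTS:
        masses = anthro.segment_masses(kin.participant_mass)
        com_frac = anthro.com_fractions
    else:
        masses = np.full(len(kin.segment_names), kin.participant_mass)
        com_frac = np.full(len(kin.segment_names), 0.5)
    com_x = kin.proximal[:, :, 0] + com_frac * (kin.distal[:, :, 0] - kin.proximal[:, :, 0])
    x = com_x @ (masses / masses.sum())
    if kin.n_frames < 2:
        raise KinematicsError("need at least 2 frames to estimate walking speed")
    return float((x[-1] - x[0]) / (kin.frame_times[-1] - kin.frame_times[0]))


def analysis_window(trial: TrialRecord,
                    lo: float = 0.15, hi: float = 0.85,
                    tail_s: float = 3.0, min_duration_s: float = 2.5) -> AnalysisWindow:
    """Study windowing rule.

    Successful trials keep the central 15-85% of their duration (transients
    at the start and end of the beam are discarded). Unsuccessful trials keep
    the last 3 s before balance loss; those shorter than 2.5 s are excluded,
    and those between 2.5 and 3 s are kept whole (the shortfall is noted).
    """
    t0 = float(trial.kinematics.frame_times[0])
    duration = float(trial.kinematics.frame_times[-1] - t0)
    if trial.success:
        return AnalysisWindow(t0 + lo * duration, t0 + hi * duration)
    if duration < min_duration_s:
        return AnalysisWindow(t0, t0 + duration, excluded=True,
                              note=f"unsuccessful trial shorter than {min_duration_s} s")
    if duration < tail_s:
        return AnalysisWindow(t0, t0 + duration,
                              note=f"shorter than the {tail_s} s tail; full trial used")
    return AnalysisWindow(t0 + duration - tail_s, t0 + duration)
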