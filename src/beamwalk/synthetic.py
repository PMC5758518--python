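"""Synthetic beam-walking kinematics with known low-dimensional structure.

The study's motion-capture data are not redistributable, so every pipeline
stage is exercised on generated planar kinematics that emulate the task: a
14-segment chain standing on a virtual beam at (y, z) = (0, 0.034) m,
oscillating in the medio-lateral plane while advancing along x at constant
walking speed.

Relative segment orientations are composed as a small number of planted
synergies — orthonormal vectors in relative-angle space, the coordinates the
dimensionality analysis operates on — weighted by sinusoids of distinct
amplitude and frequency, plus white measurement noise:

    theta_rel(t) = theta_mean + sum_k a_k * s_k * sin(2 pi f_k t + phi_k) + eps .

The default synergies mirror the balance strategies the task elicits:
mirror-symmetric flapping of the horizontally extended arms (the "T-bar"),
a whole-body lean about the mediolateral COM axis with pelvis
counter-translation (hip strategy; the trunk channel carries it), and
antisymmetric leg ab/adduction.  Trunk dominance of the beam-axis angular
momentum then *emerges* from the trunk's mass and moment arm — it is not
hard-coded.  Unsuccessful trials append an exponentially diverging ML drift
of the pelvis over the final three seconds.

Physics-oracle scenes (a rigid rod in ballistic free flight, a point-mass
discretized rod) provide closed-form angular momenta against which the
pipeline's Eq.-style computation is validated.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anthropometry import PARENTS, SEGMENTS, AnthropometricTable
from .body_model import SegmentKinematics, TrialRecord

G = 9.81  # m/s^2

#: Mean absolute orientations (rad, from +z toward +y) of the standing pose.
MEAN_ABS_ANGLES: dict[str, float] = {
    "He": 0.0, "Tr": 0.0,
    "LUA": np.pi / 2, "RUA": -np.pi / 2,       # arms extended horizontally
    "LFA": np.pi / 2, "RFA": -np.pi / 2,
    "LA": np.pi / 2, "RA": -np.pi / 2,
    "LT": np.pi + 0.05, "RT": np.pi - 0.05,    # ankles converge onto the beam
    "LS": np.pi + 0.05, "RS": np.pi - 0.05,
    "LF": 2.2, "RF": -2.2,
}

_TOPO_ORDER = ("Tr", "He", "LUA", "RUA", "LFA", "RFA", "LA", "RA",
               "LT", "RT", "LS", "RS", "LF", "RF")


class SyntheticConfigError(ValueError):
    """Raised for inconsistent generator configurations."""


def default_synergy_vectors() -> np.ndarray:
    """The three bundled synergies (14 x 3, orthonormal, relative-angle space).

    Column order matches the default amplitude order: arms (T-bar flap),
    trunk lean (+ head counter-rotation), antisymmetric leg swing.
    """
    idx = {s: i for i, s in enumerate(SEGMENTS)}
    vecs = np.zeros((14, 3))
    arms = {"LUA": -0.65, "RUA": 0.65, "LFA": -0.20, "RFA": 0.20,
            "LA": -0.08, "RA": 0.08}
    trunk = {"Tr": 0.94, "He": -0.33}
    legs = {"LT": 0.62, "RT": -0.62, "LS": 0.28, "RS": -0.28,
            "LF": 0.10, "RF": -0.10}
    for col, spec in enumerate((arms, trunk, legs)):
        for seg, val in spec.items():
            vecs[idx[seg], col] = val
    # disjoint channel support -> already orthogonal; normalize columns
    return vecs / np.linalg.norm(vecs, axis=0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of one generated trial.

    Amplitudes are radians (strictly decreasing, for identifiability of the
    planted order), frequencies Hz (distinct, well below Nyquist), noise is
    white Gaussian in relative-angle space with SD in radians.  The defaults
    reproduce the study's recording conditions: 100 Hz sampling, ~10 s
    successful walks at 0.5 m/s over a 4.75 m beam, a 70 kg / 1.76 m
    participant, successful-trial COM-velocity RMS near 0.03 m/s and
    unsuccessful-trial drift reaching ~0.12 m/s.
    """

    n_synergies: int = 3
    synergy_vectors: np.ndarray | None = None
    weight_amplitudes: tuple[float, ...] = (0.35, 0.30, 0.12)
    weight_frequencies: tuple[float, ...] = (0.9, 0.5, 1.4)
    weight_phases: tuple[float, ...] | None = None
    noise_sd: float = 0.002
    trial_duration: float = 10.0
    sampling_rate: float = 100.0
    success: bool = True
    participant_mass: float = 70.0
    participant_height: float = 1.76
    walking_speed: float = 0.5
    beam_z: float = 0.034
    com_sway_amplitude: float = 0.012   # m, uncompensated ML sway of the pelvis
    drift_scale: float = 0.006          # m, unsuccessful-trial divergence
    drift_tau: float = 0.8              # s
    random_seed: int = 0

    def __post_init__(self):
        k = self.n_synergies
        amps = np.asarray(self.weight_amplitudes, dtype=float)
        freqs = np.asarray(self.weight_frequencies, dtype=float)
        if amps.shape[0] < k or freqs.shape[0] < k:
            raise SyntheticConfigError(
                f"need >= {k} amplitudes and frequencies")
        amps, freqs = amps[:k], freqs[:k]
        if np.any(np.diff(amps) >= 0):
            raise SyntheticConfigError("amplitudes must be strictly decreasing")
        if len(set(freqs)) != k:
            raise SyntheticConfigError("frequencies must be distinct")
        if np.any(freqs >= self.sampling_rate / 8.0):
            raise SyntheticConfigError("frequencies must stay below Nyquist/4")
        if self.participant_height <= 0 or self.participant_mass <= 0:
            raise SyntheticConfigError("mass and height must be positive")

    def vectors(self) -> np.ndarray:
        vecs = default_synergy_vectors() if self.synergy_vectors is None \
            else np.asarray(self.synergy_vectors, dtype=float)
        vecs = vecs[:, :self.n_synergies]
        if vecs.shape != (14, self.n_synergies):
            raise SyntheticConfigError(
                f"synergy matrix must be 14 x {self.n_synergies}")
        gram = vecs.T @ vecs
        if not np.allclose(gram, np.eye(self.n_synergies), atol=1e-8):
            raise SyntheticConfigError("synergy vectors must be orthonormal")
        return vecs


@dataclass
class SyntheticGroundTruth:
    """Everything needed to verify recovery; regenerable from (config, seed)."""

    config: SyntheticConfig
    synergy_vectors: np.ndarray        # 14 x K, relative-angle space
    weight_series: np.ndarray          # T x K, a_k * sin(2 pi f_k t + phi_k)
    relative_angles_clean: np.ndarray  # T x 14, before noise injection
    relative_angle_means: np.ndarray   # (14,)
    noise_sd: float
    expected_trunk_dominant: bool


def _segment_lengths(anthro: AnthropometricTable, height: float) -> dict[str, float]:
    return {s: anthro[s].length_fraction * height for s in SEGMENTS}


def _chain_endpoints(abs_angles: np.ndarray, pelvis_y: np.ndarray,
                     pelvis_z: float, lengths: dict[str, float],
                     height: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward kinematics: (T, 14) absolute angles -> planar (y, z) endpoints."""
    idx = {s: i for i, s in enumerate(SEGMENTS)}
    t = abs_angles.shape[0]
    uy, uz = np.sin(abs_angles), np.cos(abs_angles)
    prox = np.zeros((t, 14, 2))
    dist = np.zeros((t, 14, 2))
    hip_half = 0.023 * height
    shoulder_half = 0.057 * height

    def place(seg: str, py: np.ndarray, pz: np.ndarray):
        i = idx[seg]
        prox[:, i, 0], prox[:, i, 1] = py, pz
        dist[:, i, 0] = py + lengths[seg] * uy[:, i]
        dist[:, i, 1] = pz + lengths[seg] * uz[:, i]

    pz0 = np.full(t, pelvis_z)
    place("Tr", pelvis_y, pz0)
    sh_y, sh_z = dist[:, idx["Tr"], 0], dist[:, idx["Tr"], 1]
    place("He", sh_y, sh_z)
    for side, sign in (("L", 1.0), ("R", -1.0)):
        place(side + "UA", sh_y + sign * shoulder_half, sh_z)
        place(side + "FA", dist[:, idx[side + "UA"], 0], dist[:, idx[side + "UA"], 1])
        place(side + "A", dist[:, idx[side + "FA"], 0], dist[:, idx[side + "FA"], 1])
        place(side + "T", pelvis_y + sign * hip_half, pz0)
        place(side + "S", dist[:, idx[side + "T"], 0], dist[:, idx[side + "T"], 1])
        place(side + "F", dist[:, idx[side + "S"], 0], dist[:, idx[side + "S"], 1])
    return prox, dist


def _mean_pose_com_z(anthro: AnthropometricTable, height: float,
                     pelvis_z: float) -> float:
    """Whole-body COM height of the static mean posture (for sway coupling)."""
    lengths = _segment_lengths(anthro, height)
    mean_abs = np.array([[MEAN_ABS_ANGLES[s] for s in SEGMENTS]])
    prox, dist = _chain_endpoints(mean_abs, np.zeros(1), pelvis_z, lengths, height)
    com_z = prox[0, :, 1] + anthro.com_fractions * (dist[0, :, 1] - prox[0, :, 1])
    w = anthro.mass_fractions
    return float(com_z @ w / w.sum())


def _relative_to_absolute(rel: np.ndarray) -> np.ndarray:
    """Invert the parent-differencing map (trunk is referenced to +z)."""
    idx = {s: i for i, s in enumerate(SEGMENTS)}
    abs_angles = np.empty_like(rel)
    for seg in _TOPO_ORDER:
        parent = PARENTS[seg]
        if parent is None:
            abs_angles[:, idx[seg]] = rel[:, idx[seg]]
        else:
            abs_angles[:, idx[seg]] = rel[:, idx[seg]] + abs_angles[:, idx[parent]]
    return abs_angles


def generate_walker_trial(cfg: SyntheticConfig,
                          anthro: AnthropometricTable | None = None,
                          trial_id: str = "synthetic",
                          participant_id: str = "P00",
                          ) -> tuple[TrialRecord, SyntheticGroundTruth]:
    """One planar beam-walking trial with planted synergies."""
    anthro = AnthropometricTable.default() if anthro is None else anthro
    rng = np.random.default_rng(cfg.random_seed)
    vecs = cfg.vectors()
    k = cfg.n_synergies
    height = cfg.participant_height
    lengths = _segment_lengths(anthro, height)
    standing = (lengths["LT"] + lengths["LS"]) * np.cos(0.05) + lengths["Tr"] \
        + lengths["He"]
    if standing > 1.05 * height:
        raise SyntheticConfigError(
            f"chain height {standing:.2f} m inconsistent with participant "
            f"height {height:.2f} m")

    n = int(round(cfg.trial_duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    amps = np.asarray(cfg.weight_amplitudes[:k])
    freqs = np.asarray(cfg.weight_frequencies[:k])
    phases = np.asarray(cfg.weight_phases[:k]) if cfg.weight_phases is not None \
        else rng.uniform(0, 2 * np.pi, size=k)
    weights = amps * np.sin(2 * np.pi * freqs * t[:, None] + phases)  # T x K

    idx = {s: i for i, s in enumerate(SEGMENTS)}
    mean_abs = np.array([MEAN_ABS_ANGLES[s] for s in SEGMENTS])
    mean_rel = np.array([
        mean_abs[i] if PARENTS[s] is None else mean_abs[i] - mean_abs[idx[PARENTS[s]]]
        for i, s in enumerate(SEGMENTS)])
    rel_clean = mean_rel + weights @ vecs.T
    noise = rng.normal(0.0, cfg.noise_sd, size=rel_clean.shape) \
        if cfg.noise_sd > 0 else np.zeros_like(rel_clean)
    rel = rel_clean + noise
    abs_angles = _relative_to_absolute(rel)

    pelvis_z = cfg.beam_z + (lengths["LT"] + lengths["LS"]) * np.cos(0.05)
    com_z0 = _mean_pose_com_z(anthro, height, pelvis_z)
    sway_gain = com_z0 - pelvis_z  # pelvis counter-shift keeps the COM put
    trunk = abs_angles[:, idx["Tr"]]
    pelvis_y = -sway_gain * (trunk - mean_abs[idx["Tr"]])
    # uncompensated residual sway at the lean frequency -> realistic VCOM_RMS
    sway_phase = rng.uniform(0, 2 * np.pi)
    lean_f = freqs[1] if k >= 2 else freqs[0]
    pelvis_y = pelvis_y + cfg.com_sway_amplitude * np.sin(
        2 * np.pi * lean_f * t + sway_phase)
    if not cfg.success:
        t0 = max(cfg.trial_duration - 3.0, 0.0)
        tail = t >= t0
        direction = 1.0 if rng.random() < 0.5 else -1.0
        pelvis_y = pelvis_y + direction * cfg.drift_scale * np.where(
            tail, np.expm1(np.where(tail, t - t0, 0.0) / cfg.drift_tau), 0.0)

    prox_yz, dist_yz = _chain_endpoints(abs_angles, pelvis_y, pelvis_z,
                                        lengths, height)
    x = (cfg.walking_speed * t)[:, None]
    prox = np.concatenate([np.broadcast_to(x[..., None], (n, 14, 1)),
                           prox_yz], axis=2)
    dist = np.concatenate([np.broadcast_to(x[..., None], (n, 14, 1)),
                           dist_yz], axis=2)

    kin = SegmentKinematics(
        frame_times=t, proximal=np.ascontiguousarray(prox),
        distal=np.ascontiguousarray(dist), sampling_rate=cfg.sampling_rate,
        participant_mass=cfg.participant_mass,
        participant_height=cfg.participant_height)
    record = TrialRecord(kinematics=kin, success=cfg.success,
                         trial_id=trial_id, participant_id=participant_id)
    truth = SyntheticGroundTruth(
        config=cfg, synergy_vectors=vecs, weight_series=weights,
        relative_angles_clean=rel_clean, relative_angle_means=mean_rel,
        noise_sd=cfg.noise_sd,
        expected_trunk_dominant=cfg.synergy_vectors is None and k >= 2)
    return record, truth


def generate_cohort(n_participants: int = 4, n_successful: int = 20,
                    n_unsuccessful: int = 9,
                    base_config: SyntheticConfig | None = None,
                    seed: int = 0, vary_participants: bool = True,
                    ) -> list[TrialRecord]:
    """A study-shaped cohort: per participant, successful and unsuccessful
    trials with per-trial phases, noise and durations.

    Participant mass/height are drawn from the study sample distribution
    (70 ± 11 kg, 1.76 ± 0.09 m) unless ``vary_participants`` is False.
    Trial seeds derive deterministically from ``seed``.
    """
    base = SyntheticConfig() if base_config is None else base_config
    master = np.random.default_rng(seed)
    trials = []
    for p in range(n_participants):
        pid = f"P{p:02d}"
        if vary_participants:
            mass = float(np.clip(master.normal(70.0, 11.0), 45.0, 110.0))
            height = float(np.clip(master.normal(1.76, 0.09), 1.5, 2.05))
        else:
            mass, height = base.participant_mass, base.participant_height
        for j in range(n_successful + n_unsuccessful):
            success = j < n_successful
            duration = float(master.uniform(8.0, 12.0)) if success \
                else float(master.uniform(2.0, 8.0))
            cfg = replace(base, success=success, trial_duration=duration,
                          participant_mass=mass, participant_height=height,
                          random_seed=int(master.integers(0, 2**31 - 1)))
            label = f"{'s' if success else 'u'}{j:03d}"
            rec, _ = generate_walker_trial(cfg, trial_id=f"{pid}_{label}",
                                           participant_id=pid)
            trials.append(rec)
    return trials


@dataclass
class FreeFlightTruth:
    """Closed-form state of a ballistic, spinning rod."""

    mass: float
    inertia: float
    omega: float
    times: np.ndarray
    com: np.ndarray       # (T, 2): y, z
    com_vel: np.ndarray   # (T, 2)

    def analytic_am(self, point_yz) -> np.ndarray:
        """Exact L_x about a fixed axis through ``point_yz``, per frame."""
        p = np.asarray(point_yz, dtype=float)
        rel = self.com - p
        moment = self.mass * (rel[:, 0] * self.com_vel[:, 1]
                              - rel[:, 1] * self.com_vel[:, 0])
        return moment + self.inertia * self.omega

    def analytic_am_about_com(self) -> float:
        return self.inertia * self.omega


def generate_free_flight(mass: float, inertia: float, omega: float,
                         v0: tuple[float, float], duration: float,
                         rate: float = 200.0, r0: tuple[float, float] = (0.0, 1.5),
                         theta0: float = 0.0,
                         ) -> tuple[SegmentKinematics, FreeFlightTruth]:
    """A single rigid rod in ballistic free flight with constant spin.

    The COM follows projectile motion under gravity; the orientation advances
    at ``omega`` rad/s about +x.  With no external torque about the moving
    COM axis, L about that axis is exactly I * omega for all time, while
    about a fixed lab axis dL/dt equals the gravity torque — both available
    in closed form from the returned :class:`FreeFlightTruth`.
    """
    if rate < 50.0:
        raise SyntheticConfigError("free-flight oracle needs rate >= 50 Hz")
    length = np.sqrt(12.0 * inertia / mass)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    y = r0[0] + v0[0] * t
    z = r0[1] + v0[1] * t - 0.5 * G * t ** 2
    vy = np.full(n, v0[0])
    vz = v0[1] - G * t
    psi = theta0 + omega * t                    # physical spin about +x
    uy, uz = -np.sin(psi), np.cos(psi)
    half = 0.5 * length
    prox = np.stack([np.zeros(n), y - half * uy, z - half * uz], axis=1)[:, None, :]
    dist = np.stack([np.zeros(n), y + half * uy, z + half * uz], axis=1)[:, None, :]
    kin = SegmentKinematics(
        frame_times=t, proximal=prox, distal=dist, sampling_rate=rate,
        participant_mass=mass, participant_height=length,
        segment_names=("rod",))
    truth = FreeFlightTruth(mass=mass, inertia=inertia, omega=omega, times=t,
                            com=np.stack([y, z], axis=1),
                            com_vel=np.stack([vy, vz], axis=1))
    return kin, truth


def point_mass_rod(n: int, mass: float, length: float,
                   com_pos: tuple[float, float], com_vel: tuple[float, float],
                   angle: float, omega: float, placement: str = "midpoint",
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discretize a rigid rod into n equal point masses with rigid-body
    velocities — the brute-force oracle for the segment angular momentum.

    ``placement="midpoint"`` puts masses at cell centres (second-order
    convergent to the continuum rod); ``"endpoint"`` spaces them
    inclusively from end to end (the classic two-point rod with
    I = m L^2 / 4 at n = 2).  ``angle`` is the physical rotation about +x
    (the rod axis points along (-sin, cos) in (y, z)).
    """
    if n < 2:
        raise SyntheticConfigError("need at least 2 point masses")
    if placement == "midpoint":
        s = -length / 2 + (np.arange(n) + 0.5) * length / n
    elif placement == "endpoint":
        s = np.linspace(-length / 2, length / 2, n)
    else:
        raise SyntheticConfigError(f"unknown placement {placement!r}")
    uy, uz = -np.sin(angle), np.cos(angle)
    pos = np.stack([com_pos[0] + s * uy, com_pos[1] + s * uz], axis=1)
    # v = v_com + omega x r_rel  (about +x): vy += -w*rz, vz += +w*ry
    vel = np.stack([com_vel[0] - omega * s * uz,
                    com_vel[1] + omega * s * uy], axis=1)
    masses = np.full(n, mass / n)
    return pos, vel, masses


def point_mass_am(pos: np.ndarray, vel: np.ndarray, masses: np.ndarray,
                  point_yz: tuple[float, float] = (0.0, 0.0)) -> float:
    """Sum_j m_j (r_j - r_P) x v_j, x-component — independent of the
    rigid-body formula."""
    ry = pos[:, 0] - point_yz[0]
    rz = pos[:, 1] - point_yz[1]
    return float(np.sum(masses * (ry * vel[:, 1] - rz * vel[:, 0])))
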