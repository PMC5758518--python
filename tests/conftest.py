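import numpy as np
import pytest

from beamwalk import (AnthropometricTable, SegmentKinematics, TrialRecord,
                      analysis_window, lowpass_filter, project_to_ml_plane,
                      relative_orientations, segment_am, segment_states,
                      whole_body_com)
from beamwalk.anthropometry import SEGMENTS


@pytest.fixture(scope="session")
def anthro():
    return AnthropometricTable.default()


def make_rod_kinematics(com_y, com_z, psi, rate, length=1.0, mass=3.0):
    """Single-segment kinematics from a prescribed COM path and physical
    rotation angle psi about +x (rod axis along (-sin psi, cos psi))."""
    t = np.arange(len(com_y)) / rate
    uy, uz = -np.sin(psi), np.cos(psi)
    half = length / 2.0
    prox = np.stack([np.zeros_like(t), com_y - half * uy, com_z - half * uz],
                    axis=1)[:, None, :]
    dist = np.stack([np.zeros_like(t), com_y + half * uy, com_z + half * uz],
                    axis=1)[:, None, :]
    return SegmentKinematics(frame_times=t, proximal=prox, distal=dist,
                             sampling_rate=rate, participant_mass=mass,
                             participant_height=length,
                             segment_names=("rod",))


def prepare_trial(record: TrialRecord, anthro, cutoff_hz=20.0):
    """Filter -> window -> project -> states -> (mask, states, rel, com)."""
    win = analysis_window(record)
    kin = lowpass_filter(record.kinematics, cutoff_hz)
    planar = project_to_ml_plane(kin)
    states = segment_states(planar, anthro)
    mask = (states.frame_times >= win.start_s - 1e-9) & \
           (states.frame_times <= win.end_s + 1e-9)
    rel = relative_orientations(states)
    com_pos, com_vel = whole_body_com(states)
    return win, states, mask, rel, com_pos, com_vel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
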