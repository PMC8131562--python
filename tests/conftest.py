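import numpy as np
import pytest

import mriemf as m


@pytest.fixture(scope="session")
def grid_spec():
    return m.default_grid_spec()


@pytest.fixture(scope="session")
def preliminary():
    """The 3.0 T machine preliminaries: m = 1.06 MA.m^2, h = 1.0 m."""
    return m.DipoleModel()


@pytest.fixture(scope="session")
def scripts():
    return m.task_scripts()


@pytest.fixture(scope="session")
def standstill_recording():
    """Zero-noise single-waypoint recording: the operator stands still."""
    script = m.TaskScript(
        "STAND", "A", ((1.0, 1.0),), v_far=1.0, v_near=0.3,
        actions=(m.Action("still", 1.5, 0),),
    )
    return m.make_task_recording(
        m.PROFILES["MRIR1"], script, seed=0, noise_sd=0.0
    )


@pytest.fixture(scope="session")
def n1_kinematics(scripts):
    """Full-pipeline kinematics of one N1 execution (tall radiographer)."""
    rec = m.make_task_recording(m.PROFILES["MRIR1"], scripts["N1"], seed=7)
    return m.extract_exposure_points(rec)


def rigid_translation_recording(speed=1.0, n=200, rate=100.0):
    """A 41-marker body shape translating rigidly along +x."""
    script = m.TaskScript(
        "STAND", "A", ((1.0, 1.0),), v_far=1.0, v_near=0.3,
        actions=(m.Action("still", 0.5, 0),),
    )
    base = m.make_task_recording(m.PROFILES["MRIR2"], script, seed=0, noise_sd=0.0)
    shape = {lab: arr[0] for lab, arr in base.markers.items()}
    t = np.arange(n) / rate
    shift = np.column_stack([speed * t, np.zeros(n), np.zeros(n)])
    return m.Recording(
        rate=rate, markers={lab: p[None, :] + shift for lab, p in shape.items()}
    )
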