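import numpy as np
import pytest

from armreach import Arm, ControlParams, Muscles, Simulator, default_config, estimate_workspace, make_target_sets


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def arm(cfg):
    return Arm(cfg)


@pytest.fixture(scope="session")
def muscles(cfg):
    return Muscles(cfg, "no_passive")


@pytest.fixture(scope="session")
def boundary(arm):
    return estimate_workspace(arm, resolution=80)


@pytest.fixture(scope="session")
def target_sets(arm, boundary, cfg):
    return make_target_sets(arm, boundary, cfg)


@pytest.fixture(scope="session")
def hand_gains():
    """Un-optimized but stable control parameters for cheap smoke reaches."""
    return ControlParams(kp=np.array([200.0, 150.0, 50.0]),
                         kd=np.array([20.0, 15.0, 5.0]), n_pred=15)


@pytest.fixture(scope="session")
def sim_no_passive(cfg):
    return Simulator(cfg, "no_passive")


@pytest.fixture(scope="session")
def feasible_q(arm):
    """100 random configurations strictly inside the joint limits."""
    rng = np.random.default_rng(42)
    lo, hi = arm.joint_limits_lower, arm.joint_limits_upper
    return lo + rng.random((100, 3)) * (hi - lo)
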