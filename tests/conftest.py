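import numpy as np
import pytest

from gaitbench.anthropometry import SubjectAnthropometry, de_leva_parameters
from gaitbench.bodymodels import build_planar_walker, build_reduced_model


@pytest.fixture(scope="session")
def female_subject():
    return SubjectAnthropometry(sex="female", total_mass=54.1, total_height=1.68,
                                leg_length=0.792)


@pytest.fixture(scope="session")
def female_segments(female_subject):
    return de_leva_parameters(female_subject)


@pytest.fixture(scope="session")
def reduced_model(female_segments):
    return build_reduced_model(female_segments, total_height=1.68)


@pytest.fixture(scope="session")
def walker_model():
    return build_planar_walker()


@pytest.fixture(scope="session")
def gait_plan(walker_model):
    from gaitbench.walker import GaitPlan

    return GaitPlan(walker_model)


@pytest.fixture(scope="session")
def stride(gait_plan):
    """One forward-simulated stride of the planar walker (ground truth).

    The tracking controller runs through a 20 ms zero-order-hold sampler and
    the contact ODE is integrated by plain RK4 at 10 ms, so the fixture's
    torques are exactly representable by the reconstruction's "hold" control
    mode with a matching RK4 defect scheme.
    """
    from gaitbench.walker import simulate_stride

    fx = simulate_stride(gait_plan, dt=0.01, control_sampling=0.02,
                         project=False)
    assert not fx.fell
    return fx


@pytest.fixture(scope="session")
def stride_schedule(stride):
    from gaitbench.reconstruction import build_phase_schedule

    return build_phase_schedule(stride.events)


@pytest.fixture(scope="session")
def stride_truth_controls(stride, stride_schedule):
    """Per-phase node grids and held ground-truth torques."""
    from gaitbench.walker import sampled_control_grid

    return sampled_control_grid(stride, stride_schedule)


@pytest.fixture(scope="session")
def ocp_config():
    from gaitbench.reconstruction import OCPConfig

    return OCPConfig(gamma_u=1e-8, defect_weight=30.0, control="hold",
                     defect_scheme="rk4", rk4_step=0.01, max_nfev=40,
                     restarts=1, x_scale_jac=True, diff_step=1e-6,
                     jac="3-point")


@pytest.fixture(scope="session")
def stride_reference(stride, walker_model):
    """Noise-free 100 Hz markers fitted back to joint space."""
    from gaitbench.markerik import VirtualMarkerSet, fit_trajectory
    from gaitbench.walker import default_walker_markers, synthesize_markers

    frames = synthesize_markers(walker_model, stride.times, stride.Q,
                                default_walker_markers(), noise_sigma=0.0, seed=0)
    mset = VirtualMarkerSet(walker_model, default_walker_markers())
    motion = fit_trajectory(walker_model, mset, frames, q_init=stride.Q[0])
    return motion, stride.Q


@pytest.fixture(scope="session")
def stride_reconstruction(walker_model, stride_reference, stride_schedule,
                          stride_truth_controls, ocp_config):
    """Optimal-control reconstruction of the stride from the IK reference."""
    from gaitbench.reconstruction import solve_reconstruction

    motion, _ = stride_reference
    node_times, _ = stride_truth_controls
    return solve_reconstruction(walker_model, motion, stride_schedule,
                                ocp_config, node_times=node_times)


@pytest.fixture(scope="session")
def lipm_gait():
    """Forward-progressing LIPM gait at the documented study conditions."""
    from gaitbench.lipm import LipmGaitSpec, simulate_lipm_gait

    spec = LipmGaitSpec(com_height=0.9, step_length=0.6, step_width=0.2,
                        step_time=0.55, n_steps=10)
    return simulate_lipm_gait(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
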