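import numpy as np
import pytest

import cowgait as cg


@pytest.fixture
def default_config():
    return cg.default_paper_config()


@pytest.fixture(scope="session")
def default_cohort():
    """The 175-cow synthetic cohort under default study conditions."""
    return cg.sample_feature_cohort(cg.default_paper_config())


@pytest.fixture(scope="session")
def level_walk():
    """A flat-backed, level-headed, symmetric synthetic walk."""
    params = cg.GaitParams(
        speed_mps=2.0,
        stride_length_cm=140.0,
        stance_fraction={h: 0.6 for h in cg.HOOVES},
        stance_asymmetry_ms=0.0,
        step_overlap_cm=(0.0, 0.0),
        back_arch_curvature=0.0,
        head_bob_amplitude_cm=0.0,
        step_time_ms=700.0,
    )
    return cg.synthesize_trajectory(params, duration_s=6.0, fps=50.0)


@pytest.fixture(scope="session")
def lame_walk():
    """An asymmetric, arched, head-bobbing synthetic walk (severe pattern)."""
    params = cg.gait_params_from_features(
        {
            "back_arch": 9.5e-4,
            "head_bob_cm": 15.8,
            "speed_mps": 1.9,
            "step_overlap_cm": 17.3,
            "supporting_phase_ms": 318.0,
            "hoof_step_time_ms": 1576.9,
        }
    )
    return cg.synthesize_trajectory(params, duration_s=8.0, fps=50.0)
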