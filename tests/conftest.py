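import numpy as np
import pandas as pd
import pytest

from ssmlab import build_design, attach_regressors, generate_behavior
from ssmlab.fitting import OptimizerConfig


@pytest.fixture(scope="session")
def design_small():
    """2 subjects x 160 trials on the default grid."""
    return build_design(n_subjects=2, n_trials=160, seed=11)


@pytest.fixture(scope="session")
def design_default():
    """The study-sized design: 22 subjects x 160 trials."""
    return build_design(n_subjects=22, n_trials=160, seed=7)


@pytest.fixture(scope="session")
def trials_ddm(design_small):
    """Behaviour from a fixed Original* parameter set on the small design."""
    rec = {"v_signVD": 7.0, "a_Intercept": -0.5, "a_absVD": 0.8,
           "z": 0.5, "p_outlier": 0.02, "t0": 0.2}
    return generate_behavior(design_small, [rec], "Original*", seed=5)


@pytest.fixture(scope="session")
def smoke_config():
    """Minimal optimizer budget for pipeline smoke tests (shape, not quality)."""
    return OptimizerConfig(popsize=2, maxiter=2, repeats=1, k_max=16,
                           n_restarts=1, polish_maxfev=0, final_repeats=2,
                           final_k_max=64)
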