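import numpy as np
import pytest

from schoolhiv.cohort import default_config, generate_cohort, recovery_config
from schoolhiv.panel import build_design, panel_from_cohort, prune_separated


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration cohort, small enough for fast unit tests."""
    return generate_cohort(default_config(n_individuals=1500, seed=11))


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    panel, log = panel_from_cohort(small_cohort)
    return panel


@pytest.fixture(scope="session")
def validation_design():
    """Correctly-specified strong-instrument design (~8k person-years)."""
    cohort = generate_cohort(recovery_config(3000, seed=42))
    panel, _ = panel_from_cohort(cohort)
    design, _ = prune_separated(build_design(panel))
    return design


def xs_matrix(design):
    """Controls plus the attendance column, with names."""
    X = np.column_stack([design.X, design.s])
    return X, design.x_names + ["attendance"]
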