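import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gliosig import roughsel, syndata

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_table() -> roughsel.DecisionTable:
    """Four objects, two binary attributes: u1=(0,0;0) u2=(0,1;1) u3=(1,0;1) u4=(1,1;1)."""
    return roughsel.DecisionTable(
        objects=["u1", "u2", "u3", "u4"],
        attributes=["a", "b"],
        values=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
        decision=np.array([0, 1, 1, 1]),
    )


@pytest.fixture(scope="session")
def planted_cohort() -> syndata.SyntheticCohort:
    """Small planted cohort shared by classifier-level tests (cheap to fit)."""
    design = syndata.SyntheticDesign(
        n_samples=160, positive_fraction=0.5, n_genes=300, n_informative=8,
        effect_size=1.5, n_modules=4, module_size=4, module_rho=0.8, seed=11,
    )
    return syndata.generate_cohort(design)


@pytest.fixture(scope="session")
def null_cohort() -> syndata.SyntheticCohort:
    design = syndata.SyntheticDesign(
        n_samples=120, positive_fraction=0.5, n_genes=150, n_informative=0,
        effect_size=0.0, n_modules=0, module_size=0, module_rho=0.0, seed=5,
    )
    return syndata.generate_cohort(design)
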