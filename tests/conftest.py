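import numpy as np
import pytest

import ontopbpk as op
from ontopbpk.nlme import PopulationModelSpec


@pytest.fixture(scope="session")
def drug():
    """Bundled low-extraction example drug (bell-shaped FMO3 ontogeny)."""
    return op.load_example_drug()


@pytest.fixture(scope="session")
def flat_drug(drug):
    """Same drug with the FMO3 ontogeny removed (flat = 1 at all ages)."""
    return drug.with_ontogeny("FMO3", None)


@pytest.fixture(scope="session")
def small_design():
    """Reduced three-arm design (180 subjects) for diagnostic tests."""
    return op.TrialDesign(arms=(
        op.TrialArm((2.0 / 12.0, 2.0), 60, dose_mg_per_kg=0.2,
                    dose_cap_mg=5.0, age_distribution="log-uniform"),
        op.TrialArm((2.0, 12.0), 60, dose_mg_per_kg=0.25, dose_cap_mg=5.0),
        op.TrialArm((18.0, 61.0), 60, dose_mg=5.0, pediatric=False),
    ))


@pytest.fixture(scope="session")
def bell_data(small_design, drug):
    """Trial simulated under the bell-shaped FMO3 truth."""
    return op.simulate_trial(small_design, drug, seed=3)


@pytest.fixture(scope="session")
def flat_data(small_design, flat_drug):
    """Trial simulated with no FMO3 maturation."""
    return op.simulate_trial(small_design, flat_drug, seed=3)


@pytest.fixture(scope="session")
def adult_design():
    return op.TrialDesign(arms=(op.TrialArm((18.0, 61.0), 20, dose_mg=5.0,
                                            pediatric=False),))


@pytest.fixture(scope="session")
def adult_data(adult_design, drug):
    """Small adults-only dataset for likelihood-level tests."""
    return op.simulate_trial(adult_design, drug, seed=1)


@pytest.fixture
def base_spec(drug):
    """Spec with every ontogeny fixed (no structural estimation)."""
    return PopulationModelSpec(drug=drug, target_pathway=None,
                               ontogeny_family=None)
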