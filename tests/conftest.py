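"""Shared fixtures: ground-truth networks and synthetic inputs.

Everything is generated programmatically at fixed seeds; heavy objects are
session-scoped so the suite builds each cohort once.
"""

import numpy as np
import pytest
from hypothesis import settings

from il23net import ode, synthetic

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def ground_truth():
    return synthetic.default_ground_truth()


@pytest.fixture(scope="session")
def conditions():
    return ode.default_condition_panel()


@pytest.fixture(scope="session")
def noiseless_panel(ground_truth, conditions):
    spec = synthetic.CohortSpec(
        n_donors=6, conditions=conditions, noise_sd=0.0, donor_effect_sd=0.0,
        seed=11,
    )
    return synthetic.simulate_cohort_panel(ground_truth, spec)


@pytest.fixture(scope="session")
def noisy_panel(ground_truth, conditions):
    spec = synthetic.CohortSpec(
        n_donors=20, conditions=conditions, noise_sd=0.1, donor_effect_sd=0.3,
        seed=23,
    )
    return synthetic.simulate_cohort_panel(ground_truth, spec)


@pytest.fixture(scope="session")
def null_network():
    """Ground truth with no regulatory edges (global null)."""
    gt = synthetic.default_ground_truth()
    return synthetic.GroundTruthNetwork(
        edges=[], basal=gt.basal, stimulated=gt.stimulated,
        degradation=gt.degradation, half_saturation=gt.half_saturation,
    )


@pytest.fixture(scope="session")
def tissue_cohort():
    spec = synthetic.TissueCohortSpec(
        signature_genes=synthetic.default_signature_genes(), noise_sd=0.3,
        seed=42,
    )
    expr, meta = synthetic.simulate_tissue_cohort(spec)
    return spec, expr, meta


@pytest.fixture(scope="session")
def single_cells():
    spec = synthetic.default_single_cell_spec(seed=7)
    return spec, synthetic.simulate_single_cells(spec)
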