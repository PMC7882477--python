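import numpy as np
import pytest

from scim import CVConfig, SphereSpec, build_index, searchlight_map
from scim.simulate import SimulationSpec, build_template_mask, simulate_trials

# light nested-CV settings used by the small end-to-end fixtures
FAST_CV = dict(outer_folds=4, inner_folds=3, c_grid=[0.01, 1.0, 100.0])


@pytest.fixture(scope="session")
def informative_sim():
    """Small dataset with a known informative blob (radius-2 template)."""
    shape = (10, 10, 6)
    template = build_template_mask(shape, [((5, 5, 3), 2.0)])
    spec = SimulationSpec(grid_shape=shape, template=template, seed=7)
    trials, brain, template = simulate_trials(spec)
    return spec, trials, brain, template


@pytest.fixture(scope="session")
def informative_map(informative_sim):
    """Searchlight AUC map of the informative dataset (radius 2, light CV)."""
    spec, trials, brain, template = informative_sim
    index = build_index(brain, SphereSpec(2.0), spec.voxel_size)
    cv = CVConfig(seed=0, **FAST_CV)
    perf = searchlight_map(trials, index, cv)
    return spec, trials, brain, template, index, perf


def template_columns(template, brain):
    """Boolean template membership in the brain-mask linearization."""
    return template.members.ravel()[brain.linear_indices()]
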