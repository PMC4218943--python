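"""Shared phantom fixtures.

Heavy objects (phantoms, atlases) are session-scoped so the suite builds
them once; every fixture is fully seeded."""

import numpy as np
import pytest

from pmbrainvol.core import LabelMap
from pmbrainvol.phantom import PhantomSpec, atlas_from_truth, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def base_spec():
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def phantom(base_spec):
    """One default phantom (64^3, 0.6 mm, bias 1.2, noise 25)."""
    return generate_phantom(base_spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free phantom."""
    return generate_phantom(PhantomSpec(seed=11, class_noise_sd=0.0, bias_amplitude=1.0))


@pytest.fixture(scope="session")
def head_mask(phantom):
    _, truth = phantom
    return LabelMap((truth.label_map.data > 0).astype(np.int16),
                    spacing=truth.label_map.spacing)


@pytest.fixture(scope="session")
def truth_atlas():
    """Prior atlas built from a 3-subject cohort disjoint from test subjects."""
    cohort = generate_cohort(PhantomSpec(seed=900, deform_sd=1.5), 3)
    return atlas_from_truth([t for _, t in cohort], smoothing_mm=1.2)


@pytest.fixture(scope="session")
def em_mask(head_mask, truth_atlas):
    """Head mask restricted to where the prior atlas has support."""
    support = truth_atlas.prior_stack().sum(axis=0) > 0
    return LabelMap(((head_mask.data > 0) & support).astype(np.int16),
                    spacing=head_mask.spacing)


@pytest.fixture(scope="session")
def warped_cohort():
    """3 warped study subjects with ground truth."""
    return generate_cohort(PhantomSpec(seed=77, deform_sd=1.5), 3)
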