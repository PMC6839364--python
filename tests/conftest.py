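import numpy as np
import pytest

import cbctrisk as cr
from cbctrisk import datasets


@pytest.fixture(scope="session")
def study_scheme():
    return cr.TissueWeightingScheme.study_subset()


@pytest.fixture(scope="session")
def full_scheme():
    return cr.TissueWeightingScheme.icrp103_full()


@pytest.fixture(scope="session")
def beir():
    return cr.BEIRParameterSet.default()


@pytest.fixture(scope="session")
def protocols():
    return cr.load_protocols()


def organ_doses(cohort, mode):
    return datasets.load_organ_doses(cohort, mode)


@pytest.fixture(scope="session")
def water_cylinder():
    """Homogeneous tissue cylinder, 8 cm radius, centred, 5 mm voxels."""
    spec = cr.PhantomSpec(8.0, 8.0, 12.0, organs=(), include_skin=False)
    phantom, _ = cr.generate_phantom(spec, voxel_size_mm=5.0)
    return phantom


@pytest.fixture(scope="session")
def symmetric_beam():
    """Wide symmetric field, bowtie and heel disabled."""
    return cr.BeamModel(
        bowtie_strength=0.0, heel_strength=0.0,
        field_x1_cm=13.25, field_x2_cm=13.25,
    )
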