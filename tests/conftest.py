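import numpy as np
import pytest

from neurofuse.atlas import dk_atlas
from neurofuse.synthetic_cohort import (
    GeneratorConfig,
    PlantedEdge,
    PlantedShift,
    generate_cohort_arrays,
)


@pytest.fixture(scope="session")
def atlas():
    return dk_atlas()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 20+20 subjects, short scans, strong planted effects."""
    return GeneratorConfig(
        n_asd=20,
        n_td=20,
        t_points=60,
        n_ados=15,
        n_missing_fmri=2,
        planted_smri=(PlantedShift(7, 1, 2.0), PlantedShift(40, 8, 2.0)),
        planted_edges=(PlantedEdge(3, 47, 0.45), PlantedEdge(10, 22, 0.45)),
        severity_weights={("smri", 0): 1.0, ("fmri", 0): 1.0},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort_arrays(small_config)


@pytest.fixture()
def manifest_csv(tmp_path):
    """A minimal valid 4-subject manifest on disk."""
    p = tmp_path / "manifest.csv"
    p.write_text(
        "subject_id,label,sex,age,ados_total,ados_sa,ados_rrb,has_smri,has_fmri\n"
        "s1,ASD,M,12.5,14,10,4,1,1\n"
        "s2,ASD,F,13.0,,,,1,1\n"
        "s3,TD,M,12.0,,,,1,1\n"
        "s4,TD,F,14.0,,,,1,0\n"
    )
    return p
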