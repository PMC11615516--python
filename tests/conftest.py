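import numpy as np
import pytest

from gcsurv.omics_io import OmicsMatrix, SurvivalTable, align_cohort
from gcsurv.synthdata import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """Default synthetic cohort: n=300, 60+20+60 features, effect size 1.0."""
    return generate_cohort(SynthConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for smoke tests: n=80, 24+8+24 features."""
    cfg = SynthConfig(
        n_samples=80, n_mrna=24, n_mirna=8, n_meth=24,
        n_pathways=4, pathway_size=6, n_signal_genes=6, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def tiny_matrix():
    return OmicsMatrix(
        "mrna",
        ["f1", "f2", "f3"],
        ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture
def simple_survival():
    return SurvivalTable(["s1", "s2", "s3", "s4"], [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
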