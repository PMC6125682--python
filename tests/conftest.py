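import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_chip():
    """A small simulated chip shared by probe-filter tests."""
    from coreis.synthetic import ChipDesign, CohortParams, simulate_chip, simulate_cohorts

    cohorts, truth = simulate_cohorts(
        CohortParams(seed=11, n_genes=200, n_cohorts=1, n_subjects=50)
    )
    abundance = 2.0 ** cohorts[0].expression
    design = ChipDesign(n_genes=200)
    intensities, annot = simulate_chip(design, abundance, seed=12)
    return {
        "design": design,
        "intensities": intensities,
        "annot": annot,
        "abundance": abundance,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def six_cohorts():
    """Default-condition baseline cohorts shared by association tests."""
    from coreis.synthetic import CohortParams, simulate_cohorts

    cohorts, truth = simulate_cohorts(CohortParams(seed=101))
    return cohorts, truth


def make_phenotypes(n, seed, is_sd=0.25):
    """Simple valid phenotype frame for direct association tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "is_log": rng.normal(1.9, is_sd, n),
            "age": rng.uniform(20, 70, n),
            "bmi": rng.uniform(20, 40, n),
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"),
    )
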