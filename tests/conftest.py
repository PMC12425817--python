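import numpy as np
import pytest

from mutscape import catalogs, synthetic_cohort as sc


@pytest.fixture(scope="session")
def sbs_catalog():
    return catalogs.synthetic_sbs_catalog()


@pytest.fixture(scope="session")
def small_bundle():
    """Small full cohort (mutations, calls, segments, survival)."""
    cfg = sc.CohortConfig(n_patients=12, seed=3)
    return sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def exposure_cohort(sbs_catalog):
    """Mid-size cohort without mutation records, for exposure/subtype tests."""
    cfg = sc.CohortConfig(
        n_patients=120,
        seed=21,
        burden_distribution=(float(np.log(8.0)), 1.0),
        min_mutations=300,
        with_mutations=False,
    )
    return sc.generate_cohort(cfg, catalog=sbs_catalog)


@pytest.fixture(scope="session")
def toy3():
    return catalogs.toy_genome(3)
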