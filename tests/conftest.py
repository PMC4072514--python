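import numpy as np
import pandas as pd
import pytest

from temqtl.synth import (
    SimCohortConfig,
    default_population_template,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with strong shared eQTLs, reused across tests."""
    cfg = SimCohortConfig(
        n_individuals=200, n_snps=1000, n_genes=40, seed=11,
        eqtl_fraction=0.4, effect_sd=1.0, state_specific_fraction=0.0,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort182():
    """Cohort at the study's effective sample size with a planted signature."""
    cfg = SimCohortConfig(n_individuals=182, n_snps=600, n_genes=215, seed=29)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def template():
    return default_population_template()


@pytest.fixture
def eqtl_covariates():
    def _get(cohort):
        return cohort.covariates[["PC1", "PC2", "PC3", "PC4", "PC5", "gender"]]
    return _get
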