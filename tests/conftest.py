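import dataclasses

import pytest

from glstrat import CohortConfig, cpm_normalize, generate_cohort, ssgsea_score
from glstrat.synthetic import GLYCOLYSIS_SET

# small-but-complete configuration used where full defaults are overkill
SMALL = CohortConfig(
    n_samples=60,
    n_coding_genes=60,
    n_lncrnas=10,
    glycolysis_set_size=10,
    n_pos_lnc=2,
    n_neg_lnc=2,
    n_assoc_coding=5,
    n_tfs=2,
    targets_per_tf=5,
    n_immune_sets=1,
    immune_set_size=5,
    checkpoint_set_size=5,
    n_decoy_sets=1,
    n_mutation_features=3,
)


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    return dataclasses.replace(SMALL, seed=seed, **overrides)


@pytest.fixture(scope="session")
def default_bundle():
    """One standard planted cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_expression(default_bundle):
    return cpm_normalize(default_bundle.counts)


@pytest.fixture(scope="session")
def default_glycolysis_score(default_bundle, default_expression):
    return ssgsea_score(default_expression, default_bundle.gene_sets[GLYCOLYSIS_SET])
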