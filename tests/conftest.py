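"""Shared fixtures: the reference synthetic cohort and networks inferred
from it. Session-scoped because network inference is the most expensive
step and several test modules interrogate the same objects."""

from __future__ import annotations

import numpy as np
import pytest

from stromamr import network as nw
from stromamr.simulate import CohortConfig, generate_cohort

COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort (550 genes x 200 samples)."""
    return generate_cohort(CohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def true_edges(cohort):
    return {(tf, t) for tf, targets in cohort.true_regulons.items()
            for t in targets}


@pytest.fixture(scope="session")
def raw_network(cohort):
    return nw.infer_regulons(cohort.expression, cohort.tf_list,
                             n_permutations=100, bh_alpha=0.05, seed=11)


@pytest.fixture(scope="session")
def bootstrapped_network(cohort, raw_network):
    return nw.bootstrap_filter(cohort.expression, raw_network,
                               n_bootstraps=50, support_threshold=0.6,
                               seed=12)


@pytest.fixture(scope="session")
def pruned_network(bootstrapped_network):
    return nw.apply_dpi(bootstrapped_network, epsilon=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
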