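"""Shared fixtures: synthetic cohorts and derived pipeline stages.

Heavy objects (the default cohort and its diff/link results) are
session-scoped so the whole suite pays their cost once. All randomness
is seeded; fixture seeds are fixed constants.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from enhancerlink.diffmeth import call_diff_probes
from enhancerlink.pairing import find_pairs
from enhancerlink.motifs import scan_windows
from enhancerlink.simulate import SimConfig, generate_cohort, generate_null_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

COHORT_SEED = 101
NULL_SEED = 202
PAIR_SEED = 7
NPERM = 1000  # scaled-down permutation count used throughout the suite


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: 100 tumors / 20 normals, subtype 0.4, delta 0.45."""
    return generate_cohort(SimConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def null_cohort():
    return generate_null_cohort(SimConfig(seed=NULL_SEED))


@pytest.fixture(scope="session")
def enhancer_beta(cohort):
    return cohort.beta.subset_features(sorted(cohort.universe.distal_enhancer))


@pytest.fixture(scope="session")
def diff_calls(cohort, enhancer_beta):
    return call_diff_probes(enhancer_beta, cohort.sheet, "hypo")


@pytest.fixture(scope="session")
def pairs(cohort, diff_calls):
    return find_pairs(
        diff_calls, cohort.universe, cohort.beta, cohort.expr,
        cohort.genes, cohort.sheet, nperm=NPERM, seed=PAIR_SEED,
    )


@pytest.fixture(scope="session")
def hits(cohort):
    probe_map = cohort.universe.probe_by_id()
    enh = [probe_map[p] for p in sorted(cohort.universe.distal_enhancer)]
    return scan_windows(enh, cohort.genome, cohort.pwms)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
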