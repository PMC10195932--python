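"""Shared fixtures: the default registry and two synthetic cohorts.

The medium cohort (8 archetypes x 100 patients, full separation, fixed
seed) feeds the clustering/elbow checks; the large cohort (x 2000,
outcomes only) feeds the outcome-rate recovery checks.  Both are
session-scoped because generation and the k scan dominate suite
runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

import phenoprint as pp

COHORT_SEED = 7


@pytest.fixture(scope="session")
def registry():
    return pp.default_registry()


@pytest.fixture(scope="session")
def cohort100():
    specs = pp.default_archetypes(n_patients=100, separation=1.0)
    return pp.generate(specs, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def stack100(cohort100, registry):
    return pp.encode_cohort(cohort100.events, registry, patients=cohort100.patients)


@pytest.fixture(scope="session")
def blurred100(stack100):
    return pp.blur_stack(stack100)


@pytest.fixture(scope="session")
def model8(blurred100):
    return pp.kmeans_fit(blurred100, k=8, seed=COHORT_SEED, n_restarts=10)


@pytest.fixture(scope="session")
def sse_curve100(blurred100):
    return pp.sse_scan(blurred100, k_min=2, k_max=20, seed=COHORT_SEED, n_restarts=10)


@pytest.fixture(scope="session")
def specs2000():
    return pp.default_archetypes(n_patients=2000, separation=1.0)


@pytest.fixture(scope="session")
def cohort2000(specs2000):
    return pp.generate(specs2000, seed=COHORT_SEED + 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
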