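"""Shared fixtures.

The expensive end-to-end artifacts (synthetic targets, the IMIS calibration
run, the four-approach PSA) are session-scoped so the whole suite pays for
them once. All seeds are fixed literals; every test is deterministic.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import crcuq as c

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SEED = 1234


@pytest.fixture(scope="session")
def life_table() -> c.LifeTable:
    return c.default_life_table()


@pytest.fixture(scope="session")
def truth() -> c.CalibratedParams:
    return c.load_truth()


@pytest.fixture(scope="session")
def fixed() -> c.FixedParams:
    return c.load_fixed()


@pytest.fixture(scope="session")
def targets(truth, fixed, life_table) -> c.TargetSet:
    """Synthetic targets at the generative truth, study-sized cohorts."""
    return c.generate_targets(truth, fixed, life_table, n_reps=100,
                              n_adenoma=500, n_cancer=100_000, seed=SEED)


@pytest.fixture(scope="session")
def calibration(targets, fixed, life_table):
    """Desk-profile IMIS calibration to the session targets."""
    sample, summary = c.run_calibration(
        targets, fixed, life_table, n0=1000, b=100, ess_target=1000,
        max_iters=100, n_resample=5000, seed=SEED)
    return sample, summary


@pytest.fixture(scope="session")
def external_dists():
    return c.fit_external_distributions()


@pytest.fixture(scope="session")
def psa_runs(calibration, external_dists, fixed, life_table):
    """One PSA per uncertainty-quantification approach.

    Uses 10,000-person cohorts per draw: the nested Monte-Carlo noise of
    small per-draw cohorts biases EVPI upward by a similar floor for every
    approach, masking the ordering between the nearly-deterministic ones
    at the decision threshold.
    """
    sample, summary = calibration
    return {
        approach: c.run_psa(approach, sample, summary, external_dists,
                            fixed, life_table, n_psa=300, n_micro=10_000,
                            seed=SEED)
        for approach in c.UQApproach
    }
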