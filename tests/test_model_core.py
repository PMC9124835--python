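"""Deterministic model core: hazards, matrices, cohort trace, outputs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import crcuq as c
from crcuq.model_core import (AgeBins, annual_transition_matrices,
                              validate_intensity_matrix,
                              validate_transition_matrix)
from crcuq.params import HealthState as S
from crcuq.params import InvalidParameterError


def series_expm(Q, t=1.0, kmax=30):
    """Independent truncated-series oracle for the matrix exponential.

    Scaling-and-squaring keeps the series convergent for the large onset
    hazards that extreme prior draws can produce: the series is applied to
    Q/2^s and the result squared s times.
    """
    A = t * np.asarray(Q, dtype=float)
    norm = np.linalg.norm(A, ord=np.inf)
    s = max(0, int(np.ceil(np.log2(norm)))) if norm > 1 else 0
    A = A / 2**s
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, kmax + 1):
        term = term @ A / k
        out = out + term
    for _ in range(s):
        out = out @ out
    return out


def random_valid_params(rng):
    return c.CalibratedParams(
        padeno=rng.uniform(0.05, 0.6), psmall=rng.uniform(0.2, 0.9),
        l=np.exp(rng.normal(-11.97, 0.59)), gamma=np.exp(rng.normal(1.04, 0.18)),
        lambda2=np.exp(rng.normal(-3.45, 0.59)),
        lambda3=np.exp(rng.normal(-3.91, 0.35)),
        lambda4=np.exp(rng.normal(-1.15, 0.23)),
        lambda5=np.exp(rng.normal(-1.41, 0.10)),
        lambda6=np.exp(rng.normal(-0.78, 0.22)))


class TestWeibullHazard:
    @pytest.mark.parametrize("a,l,gamma,expected", [
        (50.0, 2.86e-06, 2.78, 8.41e-03),   # generative values at age 50
        (0.0, 1e-5, 2.78, 0.0),             # zero at birth when shape > 1
    ])
    def test_values(self, a, l, gamma, expected):
        assert c.weibull_hazard(a, l, gamma) == pytest.approx(expected, rel=2e-3)

    def test_shape_one_is_constant(self):
        for a in (0.0, 13.0, 77.0):
            assert c.weibull_hazard(a, 0.004, 1.0) == pytest.approx(0.004)

    def test_increasing_in_age_when_shape_above_one(self):
        ages = np.arange(0, 101)
        h = c.weibull_hazard(ages, 2.86e-06, 2.78)
        assert np.all(np.diff(h) > 0)

    @pytest.mark.parametrize("a,l,gamma", [(-1, 1e-5, 2.0), (50, 0, 2.0),
                                           (50, 1e-5, -1.0)])
    def test_domain_errors(self, a, l, gamma):
        with pytest.raises(InvalidParameterError):
            c.weibull_hazard(a, l, gamma)


class TestIntensityMatrix:
    def test_structure_at_truth(self, truth, fixed):
        Q = c.build_intensity_matrix(truth, fixed, mu_a=0.0, a=50)
        assert Q[S.NORMAL, S.SMALL_ADENOMA] == pytest.approx(8.41e-03, rel=2e-3)
        assert Q[S.SMALL_ADENOMA, S.LARGE_ADENOMA] == truth.lambda2
        assert Q[S.LARGE_ADENOMA, S.PRECLIN_EARLY] == truth.lambda3
        assert Q[S.PRECLIN_EARLY, S.PRECLIN_LATE] == truth.lambda4
        assert Q[S.PRECLIN_EARLY, S.CLIN_EARLY] == truth.lambda5
        assert Q[S.PRECLIN_LATE, S.CLIN_LATE] == truth.lambda6
        assert Q[S.CLIN_EARLY, S.CRC_DEATH] == fixed.lambda7
        assert Q[S.CLIN_LATE, S.CRC_DEATH] == fixed.lambda8
        validate_intensity_matrix(Q)

    def test_zero_rates_zero_matrix(self, fixed):
        theta = c.CalibratedParams(0.25, 0.71, 1e-300, 1.0, 1e-300, 1e-300,
                                   1e-300, 1e-300, 1e-300)
        Q = c.build_intensity_matrix(theta, fixed, mu_a=0.0, a=50)
        Q[S.CLIN_EARLY, S.CRC_DEATH] = Q[S.CLIN_LATE, S.CRC_DEATH] = 0.0
        np.fill_diagonal(Q, 0.0)
        assert np.abs(Q).max() < 1e-290

    def test_rows_sum_to_zero_for_random_draws(self, fixed):
        rng = np.random.default_rng(0)
        for _ in range(100):
            theta = random_valid_params(rng)
            Q = c.build_intensity_matrix(theta, fixed, mu_a=rng.uniform(0, 0.3),
                                         a=rng.uniform(50, 100),
                                         onset_hr=rng.uniform(1, 3))
            assert np.abs(Q.sum(axis=1)).max() < 1e-12 * max(1, np.abs(Q).max())

    def test_onset_hazard_ratio_scales_onset_only(self, truth, fixed):
        Q1 = c.build_intensity_matrix(truth, fixed, 0.01, 60, onset_hr=1.0)
        Q3 = c.build_intensity_matrix(truth, fixed, 0.01, 60, onset_hr=3.0)
        assert Q3[S.NORMAL, S.SMALL_ADENOMA] == pytest.approx(
            3.0 * Q1[S.NORMAL, S.SMALL_ADENOMA])
        assert Q3[S.SMALL_ADENOMA, S.LARGE_ADENOMA] == Q1[S.SMALL_ADENOMA,
                                                          S.LARGE_ADENOMA]


class TestTransitionMatrix:
    def test_zero_generator_gives_identity(self):
        P = c.transition_probability_matrix(np.zeros((9, 9)))
        np.testing.assert_allclose(P, np.eye(9), atol=1e-14)

    def test_two_state_closed_form(self):
        # embed a single 0.0346/yr transition: P01 = 1 - exp(-0.0346)
        Q = np.zeros((9, 9))
        Q[0, 1] = 0.0346
        Q[0, 0] = -0.0346
        P = c.transition_probability_matrix(Q)
        assert P[0, 1] == pytest.approx(1 - np.exp(-0.0346), abs=1e-12)

    def test_matches_series_oracle_on_random_generators(self, fixed):
        rng = np.random.default_rng(1)
        for _ in range(100):
            theta = random_valid_params(rng)
            Q = c.build_intensity_matrix(theta, fixed, rng.uniform(0, 0.2),
                                         rng.uniform(50, 99))
            P = c.transition_probability_matrix(Q)
            np.testing.assert_allclose(P, series_expm(Q), atol=1e-9)

    def test_multi_jump_transition_positive(self, truth, fixed):
        Q = c.build_intensity_matrix(truth, fixed, 0.0, 60)
        P = c.transition_probability_matrix(Q)
        # small adenoma -> preclinical early requires two jumps in one year
        assert P[S.SMALL_ADENOMA, S.PRECLIN_EARLY] > 0
        validate_transition_matrix(P)

    def test_rows_stochastic_for_random_draws(self, fixed):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            theta = random_valid_params(rng)
            Q = c.build_intensity_matrix(theta, fixed, rng.uniform(0, 0.5),
                                         rng.uniform(50, 100))
            P = c.transition_probability_matrix(Q)
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10

    def test_rejects_non_conservative_generator(self):
        Q = np.zeros((9, 9))
        Q[0, 1] = 0.1  # row sum 0.1 != 0
        with pytest.raises(ValueError):
            c.transition_probability_matrix(Q)


class TestInitialDistribution:
    def test_generative_values(self, fixed):
        theta = c.CalibratedParams(0.25, 0.71, 2.86e-6, 2.78, .0346, .0215,
                                   .3697, .2382, .4582)
        pi = c.initial_state_distribution(theta, fixed)
        assert pi[S.SMALL_ADENOMA] == pytest.approx(0.1775)
        assert pi[S.LARGE_ADENOMA] == pytest.approx(0.0725)
        assert pi[S.NORMAL] == pytest.approx(0.748)
        assert pi[S.PRECLIN_EARLY] == pytest.approx(0.0012)
        assert pi[S.PRECLIN_LATE] == pytest.approx(0.0008)
        assert pi.sum() == pytest.approx(1.0)

    def test_no_adenomas_limit(self, fixed):
        theta = c.CalibratedParams(1e-12, 0.5, 1e-6, 2.0, .01, .01, .1, .1, .1)
        pi = c.initial_state_distribution(theta, fixed)
        assert pi[S.NORMAL] == pytest.approx(1 - 0.002)

    @given(padeno=st.floats(0.01, 0.95), psmall=st.floats(0.01, 0.99))
    def test_sums_to_one(self, padeno, psmall):
        theta = c.CalibratedParams(padeno, psmall, 1e-6, 2.0, .01, .01, .1, .1, .1)
        pi = c.initial_state_distribution(theta, c.FixedParams())
        assert pi.sum() == pytest.approx(1.0)
        assert np.all(pi >= 0)


class TestCohortTrace:
    def test_no_transitions_constant_occupancy(self, fixed):
        theta = c.CalibratedParams(0.3, 0.6, 1e-300, 1.0, 1e-300, 1e-300,
                                   1e-300, 1e-300, 1e-300)
        lt = c.LifeTable(np.arange(50, 101), np.zeros(51))
        fx = c.FixedParams(lambda7=1e-300, lambda8=1e-300)
        tr = c.cohort_trace(theta, fx, lt, 50, 80)
        np.testing.assert_allclose(
            tr.occupancy, np.tile(tr.occupancy[0], (len(tr.ages), 1)),
            atol=1e-12)

    def test_high_mortality_limit(self, truth, fixed):
        lt = c.LifeTable(np.arange(50, 101), np.full(51, 15.0))
        tr = c.cohort_trace(truth, fixed, lt, 50, 70)
        assert tr.occupancy[-1, S.OTHER_DEATH] > 0.999

    def test_onset_only_closed_form(self, fixed):
        # only normal -> small at constant rate r: occupancy decays as exp(-rk)
        r = 0.05
        theta = c.CalibratedParams(1e-12, 0.5, r, 1.0, 1e-300, 1e-300,
                                   1e-300, 1e-300, 1e-300)
        lt = c.LifeTable(np.arange(50, 101), np.zeros(51))
        fx = c.FixedParams(lambda7=1e-300, lambda8=1e-300,
                           p_preclin_early_50=0.0, p_preclin_late_50=0.0)
        tr = c.cohort_trace(theta, fx, lt, 50, 90)
        for k in (1, 10, 25, 40):
            assert tr.occupancy[k, S.NORMAL] == pytest.approx(
                np.exp(-r * k), abs=1e-9)

    def test_adenoma_prevalence_increases_with_age(self, truth, fixed, life_table):
        tr = c.cohort_trace(truth, fixed, life_table, 50, 87)
        out = c.model_outputs(tr)
        prev = out.loc[out.target_type == "adenoma_prev", "value"].to_numpy()
        assert np.all(np.diff(prev) > 0)

    def test_raising_lambda3_raises_clinical_incidence(self, truth, fixed,
                                                       life_table):
        def cum_inc(lmbda3):
            theta = c.CalibratedParams(**{**{n: getattr(truth, n) for n in
                                             c.CalibratedParams.NAMES},
                                          "lambda3": lmbda3})
            tr = c.cohort_trace(theta, fixed, life_table, 50, 87)
            return tr.inc_early.sum() + tr.inc_late.sum()

        incs = [cum_inc(x) for x in (0.01, 0.0215, 0.05)]
        assert incs[0] < incs[1] < incs[2]

    def test_life_table_gap_errors(self, truth, fixed):
        lt = c.LifeTable(np.arange(50, 70), np.full(20, 0.01))
        with pytest.raises(ValueError):
            c.cohort_trace(truth, fixed, lt, 50, 90)


class TestModelOutputs:
    def test_hand_built_single_age(self, fixed):
        tr = c.CohortTrace(
            ages=np.array([50, 51]),
            occupancy=np.array([[0.85, 0.10, 0.05, 0, 0, 0, 0, 0, 0],
                                [0.85, 0.10, 0.05, 0, 0, 0, 0, 0, 0]], float),
            inc_early=np.array([0.0]), inc_late=np.array([0.0]),
            py_at_risk=np.array([1.0]))
        out = c.model_outputs(tr, AgeBins(prevalence_ages=(50,),
                                          incidence_bins=((50, 50),)))
        prev = out.loc[out.target_type == "adenoma_prev", "value"].iloc[0]
        small = out.loc[out.target_type == "prop_small", "value"].iloc[0]
        assert prev == pytest.approx(0.15)
        assert small == pytest.approx(2 / 3)

    def test_zero_adenoma_flags_prop_small_undefined(self, fixed):
        occ = np.zeros((2, 9))
        occ[:, S.NORMAL] = 1.0
        tr = c.CohortTrace(np.array([50, 51]), occ, np.array([0.0]),
                           np.array([0.0]), np.array([1.0]))
        out = c.model_outputs(tr, AgeBins(prevalence_ages=(50,),
                                          incidence_bins=((50, 50),)))
        prev_row = out[out.target_type == "adenoma_prev"].iloc[0]
        small_row = out[out.target_type == "prop_small"].iloc[0]
        assert prev_row["value"] == 0.0 and prev_row["defined"]
        assert not small_row["defined"] and np.isnan(small_row["value"])


class TestLifeTable:
    def test_default_fixture_life_expectancy_band(self, life_table):
        assert 30.0 <= life_table.life_expectancy(50) <= 36.0

    def test_rates_monotone_above_60(self, life_table):
        sel = life_table.ages >= 60
        assert np.all(np.diff(life_table.rates[sel]) >= 0)

    def test_csv_round_trip(self, tmp_path, life_table):
        p = tmp_path / "lt.csv"
        life_table.to_csv(p)
        lt2 = c.LifeTable.from_csv(p)
        np.testing.assert_array_equal(lt2.ages, life_table.ages)
        np.testing.assert_allclose(lt2.rates, life_table.rates)

    def test_constant_rate_makeham_limit(self):
        lt = c.make_life_table(c.LifeTableFixture(makeham_c=0.02, makeham_b=0.0))
        assert np.allclose(lt.rates, 0.02)
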