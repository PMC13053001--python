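"""Cost model: arm means, incremental saving, t test, PSA, DSA, inflation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermflow.costs import (
    UncertaintySpec,
    activity_cost,
    arm_mean_cost,
    default_cost_params,
    deterministic_saving,
    incremental_saving,
    inflate_cost,
    run_dsa,
    run_psa,
    sample_patient_costs,
    total_saving,
    welch_t_test,
)
from dermflow.config import DES_DISTRIBUTION, UNIT_COSTS
from dermflow.pathways import ArmDistribution, COMPARATOR, INTERVENTION

DET_SAVING = 48.24  # comparator 261.49 minus intervention 213.25


@pytest.mark.parametrize(
    "duration,rate,add_on,expected",
    [
        (20.0, 30.0, 0.0, 10.00),          # linear proration of staff time
        (4.97, 120.0, 0.0, 9.94),          # remote review at consultant rate
        (0.0, 100.0, 55.0, 55.0),          # pure tariff add-on
    ],
)
def test_activity_cost(duration, rate, add_on, expected):
    assert activity_cost(duration, rate, add_on) == pytest.approx(expected, abs=0.005)


def test_activity_cost_rejects_negative_inputs():
    with pytest.raises(ValueError):
        activity_cost(-1.0, 30.0)


class TestArmMeans:
    def test_intervention_mean_from_published_table(self):
        params = default_cost_params("cca")
        assert arm_mean_cost(
            params.distributions[INTERVENTION], params.unit_costs
        ) == pytest.approx(213.25)

    def test_comparator_mean_from_published_table(self):
        params = default_cost_params("cca")
        assert arm_mean_cost(
            params.distributions[COMPARATOR], params.unit_costs
        ) == pytest.approx(261.49)

    def test_single_pathway_mean_is_its_unit_cost(self):
        assert arm_mean_cost(ArmDistribution({"F": 1.0}), {"F": 163.0}) == 163.0

    def test_missing_unit_cost_raises(self):
        with pytest.raises(KeyError):
            arm_mean_cost(ArmDistribution({"F": 1.0}), {"G": 364.0})

    def test_patient_level_enumeration_converges_to_dot_product(self):
        # brute-force oracle: assign floor(p*N)-rounded pathway labels to N
        # patients and average; must converge to the weighted sum
        dist = ArmDistribution(dict(DES_DISTRIBUTION[INTERVENTION]))
        exact = arm_mean_cost(dist, UNIT_COSTS)
        errors = []
        for n in (100, 1000, 100_000):
            labels = []
            for pid, p in dist.items():
                labels.extend([pid] * int(p * n))
            avg = np.mean([UNIT_COSTS[pid] for pid in labels])
            errors.append(abs(avg - exact))
        assert errors[-1] < 0.01
        assert errors[-1] <= errors[0]


class TestIncrementalSaving:
    def test_published_table_difference(self):
        assert incremental_saving(261.49, 213.25) == pytest.approx(DET_SAVING)

    def test_equal_means_give_zero(self):
        assert incremental_saving(200.0, 200.0) == 0.0

    def test_total_saving_scales_linearly(self):
        assert total_saving(0.0, 563) == 0.0
        assert total_saving(45.0, 563) == pytest.approx(25335.0)
        # published overall figure implies a per-referral value near £44.85
        assert total_saving(25251.0 / 563, 563) == pytest.approx(25251.0)

    def test_negative_cohort_rejected(self):
        with pytest.raises(ValueError):
            total_saving(45.0, -1)


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_t_test(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_welch_value(self):
        # means 2 vs 5, both variances 1, n=3: t = -3/sqrt(2/3), df = 4;
        # p from symbolic integration of the t_4 density
        t, p = welch_t_test(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert t == pytest.approx(-3.6742346141747673)
        assert p == pytest.approx(0.021311641128756727, rel=1e-9)

    def test_degenerate_samples_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            welch_t_test(np.array([5.0, 5.0]), np.array([7.0, 7.0]))

    def test_arm_cost_samples_strongly_significant(self):
        # cohort-sized mixture samples at the published arm sizes
        params = default_cost_params("cca")
        rng = np.random.default_rng(12345)
        a = sample_patient_costs(params.distributions[COMPARATOR],
                                 params.unit_costs, 4011, rng, staff_cv=0.12)
        b = sample_patient_costs(params.distributions[INTERVENTION],
                                 params.unit_costs, 563, rng, staff_cv=0.12)
        _, p = welch_t_test(a, b)
        assert p < 0.001


class TestPSA:
    def test_degenerate_specs_collapse_to_deterministic_saving(self):
        params = default_cost_params("cca")
        params.psa_specs = {pid: UncertaintySpec(se=0.0) for pid in params.unit_costs}
        res = run_psa(params, n_iter=50, seed=3)
        assert np.all(res.per_iteration_savings == pytest.approx(DET_SAVING))
        assert res.ci95[0] == pytest.approx(res.ci95[1])

    def test_seed_reproducibility_bit_identical(self):
        params = default_cost_params("cca")
        r1 = run_psa(params, n_iter=200, seed=7)
        r2 = run_psa(params, n_iter=200, seed=7)
        assert np.array_equal(r1.per_iteration_savings, r2.per_iteration_savings)

    def test_mean_tracks_deterministic_estimate(self):
        # symmetric zero-mean noise on the unit costs leaves the mean saving
        # at the deterministic value, within Monte-Carlo error
        params = default_cost_params("cca")
        res = run_psa(params, n_iter=1000, seed=11)
        mc_se = res.per_iteration_savings.std(ddof=1) / math.sqrt(res.n_iter)
        assert abs(res.mean - DET_SAVING) < 4 * mc_se

    def test_quadrupling_iterations_halves_mc_se(self):
        params = default_cost_params("cca")
        r1 = run_psa(params, n_iter=1000, seed=5)
        r2 = run_psa(params, n_iter=4000, seed=6)
        se1 = r1.per_iteration_savings.std(ddof=1) / math.sqrt(r1.n_iter)
        se2 = r2.per_iteration_savings.std(ddof=1) / math.sqrt(r2.n_iter)
        assert se1 / se2 == pytest.approx(2.0, rel=0.25)

    def test_invalid_iterations(self):
        with pytest.raises(ValueError):
            run_psa(default_cost_params(), n_iter=0, seed=0)


class TestDSA:
    def test_baseline_bounds_reproduce_baseline_saving(self):
        params = default_cost_params("cca")
        g = params.unit_costs["G"]
        assert run_dsa(params, "unit_cost.G", g, g) == (
            pytest.approx(DET_SAVING),
            pytest.approx(DET_SAVING),
        )

    def test_hand_recomputed_bound(self):
        # G at £300: comparator mean 0.51*163 + 0.49*300 = 230.13
        params = default_cost_params("cca")
        low, _ = run_dsa(params, "unit_cost.G", 300.0, params.unit_costs["G"])
        assert low == pytest.approx(230.13 - 213.25)

    def test_offsetting_biopsies_increases_saving_monotonically(self):
        # biopsy-reliant intervention pathways are the most expensive, so
        # re-routing their mass to the other pathways always helps
        params = default_cost_params("cca")
        savings = [run_dsa(params, "biopsy_offset", 0.0, f)[1]
                   for f in (0.0, 0.25, 0.5, 1.0)]
        assert savings[0] == pytest.approx(DET_SAVING)
        assert all(b > a for a, b in zip(savings, savings[1:]))

    def test_unknown_parameter(self):
        with pytest.raises(KeyError):
            run_dsa(default_cost_params(), "unit_cost.Z", 0.0, 1.0)
        with pytest.raises(ValueError):
            run_dsa(default_cost_params(), "unit_cost.G", 2.0, 1.0)


class TestInflation:
    def test_identity_and_direct_ratio(self):
        index = {2021: 1.0, 2023: 1.1}
        assert inflate_cost(100.0, 2023, 2023, index) == 100.0
        assert inflate_cost(100.0, 2021, 2023, index) == pytest.approx(110.0)

    def test_missing_year(self):
        with pytest.raises(KeyError):
            inflate_cost(100.0, 2019, 2023, {2023: 1.1})

    @settings(deadline=None, max_examples=50)
    @given(
        cost=st.floats(0.01, 1e6),
        i1=st.floats(0.5, 2.0),
        i2=st.floats(0.5, 2.0),
    )
    def test_inflate_deflate_round_trip(self, cost, i1, i2):
        index = {2021: i1, 2023: i2}
        there = inflate_cost(cost, 2021, 2023, index)
        back = inflate_cost(there, 2023, 2021, index)
        assert back == pytest.approx(cost, rel=1e-9)


def test_deterministic_saving_matches_components():
    params = default_cost_params("cca")
    assert deterministic_saving(params) == pytest.approx(DET_SAVING)
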