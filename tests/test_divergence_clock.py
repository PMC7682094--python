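"""Divergence-clock inference: branch counts, rates, curves, likelihoods."""

import numpy as np
import pytest

from tallevo.clonality import MutationRecord
from tallevo.divergence_clock import (
    AccelerationHypothesis,
    ClockConfig,
    HypothesisGrid,
    PatientClock,
    cohort_posterior,
    count_branches,
    divergence_from_shared,
    estimate_cohort,
    estimate_patient,
    evaluate_patient_grid,
    fit_rate_regression,
    hypothesis_likelihood,
    simulate_mutation_curve,
    solve_rate,
)
from tallevo.mutation_process import DAYS_PER_YEAR
from tallevo.synthetic_cohort import CohortConfig, apply_true_clonality, gen_cohort


def _clonal(sample, pos, signature="SBS5"):
    return MutationRecord(
        patient_id="P", sample=sample, chrom="1", pos=pos, ref="A", alt="T",
        alt_reads=40, depth=80, clonality="clonal", signature=signature,
    )


class TestCountBranches:
    def test_identical_clonal_sets_have_no_private_branches(self):
        recs = [_clonal("primary", i) for i in range(10)] + [
            _clonal("relapse", i) for i in range(10)
        ]
        c = count_branches(recs, 10000, 10400)
        assert (c.n_primary_private, c.n_shared, c.n_relapse_private) == (0, 10, 0)

    def test_disjoint_sets_are_fully_private(self):
        recs = [_clonal("primary", i) for i in range(5)] + [
            _clonal("relapse", 100 + i) for i in range(7)
        ]
        c = count_branches(recs, 10000, 10400)
        assert (c.n_primary_private, c.n_shared, c.n_relapse_private) == (5, 0, 7)

    def test_non_matching_signature_and_subclonal_are_excluded(self):
        recs = [_clonal("primary", 1), _clonal("relapse", 1),
                _clonal("primary", 2, signature="SBS1"),
                _clonal("relapse", 2, signature="SBS1")]
        sub = MutationRecord(
            patient_id="P", sample="primary", chrom="1", pos=3, ref="A", alt="T",
            alt_reads=5, depth=80, clonality="subclonal",
        )
        c = count_branches(recs + [sub], 10000, 10400)
        assert (c.n_primary_private, c.n_shared, c.n_relapse_private) == (0, 1, 0)

    def test_missing_sample_is_an_error(self):
        with pytest.raises(ValueError, match="relapse"):
            count_branches([_clonal("primary", 1)], 10000, 10400)

    def test_generator_records_reproduce_ground_truth_exactly(self):
        cfg = CohortConfig(n_patients=1, seed=13)
        p = gen_cohort(cfg)[0]
        recs = apply_true_clonality(p.mutations)
        c = count_branches(recs, p.counts.age_dx_days, p.counts.age_rel_days)
        assert c.n_primary_private == p.counts.n_primary_private
        assert c.n_shared == p.counts.n_shared
        assert c.n_relapse_private == p.counts.n_relapse_private


class TestRateRegression:
    def test_exact_line_is_recovered(self):
        ages = np.array([10.0, 20.0, 40.0, 60.0])
        res = fit_rate_regression(ages, 12.0 * ages)
        assert res.slope == pytest.approx(12.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.pearson_r == pytest.approx(1.0)

    def test_leukemic_regression_coefficients(self):
        # the leukemic SBS5 line: slope 20.61/yr, intercept 397.4 mutations
        ages = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
        res = fit_rate_regression(ages, 20.61 * ages + 397.4)
        assert res.slope == pytest.approx(20.61)
        assert res.intercept == pytest.approx(397.4)

    def test_confidence_interval_coverage(self):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(100):
            ages = rng.uniform(18, 70, 50)
            counts = 15.0 * ages + 100.0 + rng.normal(0, 40, 50)
            res = fit_rate_regression(ages, counts)
            if abs(res.slope - 15.0) <= 2 * res.slope_se:
                hits += 1
        assert hits >= 93

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            fit_rate_regression([40.0, 40.0, 40.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_rate_regression([1.0, 2.0], [1.0, 2.0])


def _closed_form_cfg():
    return ClockConfig(baseline_slope=12.0, baseline_intercept=0.0)


def _clock(pp, shared, rp, age_dx=14700.0, age_rel=15250.0):
    return PatientClock("P", age_dx, age_rel, pp, shared, rp)


class TestSolveRate:
    # geometry: t_n age 14610 d (baseline count 480), t* = 14975, t*-t_n = 365
    def test_constant_model_closed_form(self):
        clock = _clock(100, 700, 180)  # totals 800/880 -> N* = 840
        mu, feasible = solve_rate("constant", 90.0, clock, _closed_form_cfg())
        assert feasible
        assert mu == pytest.approx(360.0 / 365.0)

    def test_linear_model_closed_form(self):
        clock = _clock(200, 700, 320)  # totals 900/1020 -> N* = 960
        r, feasible = solve_rate("linear", 90.0, clock, _closed_form_cfg())
        assert feasible
        assert r == pytest.approx(2 ** (1 / 365.0) - 1.0)

    def test_no_excess_over_baseline_is_infeasible(self):
        clock = _clock(0, 470, 20)  # totals 470/490 -> N* = 480 = baseline
        mu, feasible = solve_rate("constant", 90.0, clock, _closed_form_cfg())
        assert mu == pytest.approx(0.0)
        assert not feasible

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            solve_rate("quadratic", 90.0, _clock(1, 1, 1), _closed_form_cfg())


class TestSimulateCurve:
    def test_zero_rate_gives_constant_trajectory(self):
        traj = simulate_mutation_curve("constant", 0.0, 100, ClockConfig(), seed=1,
                                       start_count=7)
        assert np.all(traj == 7)

    def test_constant_rate_mean_matches_analytic(self):
        rng = np.random.default_rng(3)
        finals = np.array([
            simulate_mutation_curve("constant", 0.5, 1000, ClockConfig(), rng)[-1]
            for _ in range(1000)
        ])
        se = np.sqrt(1000 * 0.5 * 0.5 / len(finals))
        assert abs(finals.mean() - 500.0) < 3 * se

    def test_trajectory_monotone_integer_through_rate_crossing_one(self):
        # linear model: daily mean log(1+r) N crosses 1/day as N grows
        traj = simulate_mutation_curve("linear", 0.01, 400, ClockConfig(), seed=4,
                                       start_count=90)
        assert np.all(np.diff(traj) >= 0)
        assert traj.dtype.kind == "i"
        assert np.log1p(0.01) * traj[-1] > 1.0  # the crossing happened


class TestLikelihoodAndDivergence:
    def test_matching_observation_outscores_distant_one(self):
        cfg = ClockConfig(n_sims=100)
        hyp = AccelerationHypothesis("constant", 730.0, 1.0)
        near = PatientClock("P", 14610, 14975, 386, 800, 751)  # at simulated means
        far = PatientClock("P", 14610, 14975, 1400, 800, 1800)  # ~10 SD away
        l_near = hypothesis_likelihood(hyp, near, cfg, seed=5)
        l_far = hypothesis_likelihood(hyp, far, cfg, seed=5)
        assert l_near > 100 * l_far
        assert l_far >= 0.0

    def test_infeasible_hypothesis_has_zero_likelihood(self):
        hyp = AccelerationHypothesis("constant", 730.0, 0.0, feasible=False)
        assert hypothesis_likelihood(hyp, _clock(1, 1, 1), ClockConfig(), 0) == 0.0

    def test_shared_equal_to_primary_total_means_divergence_zero(self):
        clock = _clock(0, 800, 100)
        assert divergence_from_shared("constant", 600.0, 1.0, clock,
                                      _closed_form_cfg()) == 0.0

    def test_constant_curve_inversion(self):
        # mu = 1/day after acceleration; 300 private mutations -> ~300 days
        cfg = _closed_form_cfg()
        clock = PatientClock("P", 14610, 14975, 300, 760, 500)
        div = divergence_from_shared("constant", 600.0, 1.0, clock, cfg)
        assert div == pytest.approx(300.0, abs=1.0)

    def test_baseline_limit_reduces_to_private_over_daily_rate(self):
        cfg = _closed_form_cfg()
        b = 12.0 / DAYS_PER_YEAR
        clock = PatientClock("P", 14610, 14975, 100, 380, 200)
        div = divergence_from_shared("constant", 0.0, b, clock, cfg)
        assert div == pytest.approx(100 / b)


def _toy_grid(likes, divs, models=None):
    n = len(likes)
    return HypothesisGrid(
        patient_id="P",
        model=np.array(models or ["constant"] * n, dtype=object),
        t_accel=np.linspace(0, 3652.5, n),
        rate=np.ones(n),
        feasible=np.ones(n, dtype=bool),
        likelihood=np.asarray(likes, dtype=float),
        divergence_days=np.asarray(divs, dtype=float),
    )


class TestCohortPooling:
    def test_single_patient_posterior_is_own_profile(self):
        g = _toy_grid([1.0, 3.0, 6.0], [100, 200, 300])
        post = cohort_posterior([g], ClockConfig())
        assert post == pytest.approx(np.array([0.1, 0.3, 0.6]))

    def test_identical_patients_do_not_shift_the_posterior(self):
        g = _toy_grid([1.0, 3.0, 6.0], [100, 200, 300])
        single = cohort_posterior([g], ClockConfig())
        double = cohort_posterior([g, g], ClockConfig())
        assert double == pytest.approx(single)

    def test_all_zero_likelihood_raises(self):
        g = _toy_grid([0.0, 0.0], [100, 200])
        with pytest.raises(ValueError):
            cohort_posterior([g], ClockConfig())

    def test_unanimous_hypotheses_give_their_divergence(self):
        g = _toy_grid([2.0, 2.0, 2.0], [250.0, 250.0, 250.0])
        est = estimate_patient(g, ClockConfig(percentile_keep=1.0))
        assert est.divergence_days == pytest.approx(250.0)

    def test_weighted_estimate_lies_within_retained_range(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            g = _toy_grid(rng.random(40), rng.uniform(0, 2000, 40))
            est = estimate_patient(g, ClockConfig())
            assert g.divergence_days.min() - 1e-9 <= est.divergence_days
            assert est.divergence_days <= g.divergence_days.max() + 1e-9


class TestCohortDeterminismAndOrder:
    def _clocks(self):
        cfg = CohortConfig(n_patients=4, seed=31)
        return [p.counts for p in gen_cohort(cfg)]

    def test_fixed_seed_reproduces_estimates_bit_for_bit(self):
        cfg = ClockConfig(n_grid=12, n_sims=20)
        clocks = self._clocks()
        a, _, _ = estimate_cohort(clocks, cfg, seed=9)
        b, _, _ = estimate_cohort(clocks, cfg, seed=9)
        assert a.equals(b)

    def test_patient_order_does_not_change_results(self):
        cfg = ClockConfig(n_grid=12, n_sims=20)
        clocks = self._clocks()
        fwd, _, _ = estimate_cohort(clocks, cfg, seed=9)
        rev, _, _ = estimate_cohort(clocks[::-1], cfg, seed=9)
        merged = fwd.merge(rev, on="patient_id", suffixes=("_f", "_r"))
        assert np.allclose(merged.divergence_days_f, merged.divergence_days_r)


def test_relapse_private_branch_exceeds_primary_private_on_average():
    patients = gen_cohort(CohortConfig(seed=23))
    pp = np.mean([p.counts.n_primary_private for p in patients])
    rp = np.mean([p.counts.n_relapse_private for p in patients])
    assert rp > pp


def test_grid_keeps_infeasible_cells_aligned():
    cfg = ClockConfig(n_grid=10, n_sims=10)
    clock = _clock(100, 700, 180)
    grid = evaluate_patient_grid(clock, cfg, seed=2)
    assert len(grid.likelihood) == 2 * cfg.n_grid
    assert np.all(grid.likelihood[~grid.feasible] == 0.0)
    assert grid.t_accel[0] == 0.0
    assert grid.t_accel[cfg.n_grid - 1] == pytest.approx(cfg.window_days)
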