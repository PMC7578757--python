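"""Four-class projection model: step operators, LTSD, growth and convergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wzpop.genetics import CLASS_ORDER, PhenotypeClass
from wzpop.popdyn import (
    ConvergenceError,
    DemographicParams,
    PopulationState,
    constant_population_step,
    estimate_alpha_from_cohort,
    generations_to_convergence,
    newborn_class_distribution,
    project_step,
    simulate_trajectory,
    stable_distribution,
    stable_distribution_fixed_point,
    time_to_threshold,
)

ZZM, IS, WZF, WWF = CLASS_ORDER


class TestNewbornDistribution:
    def test_binary_sex_population(self):
        s = PopulationState(zz=100, is_=0, wz=100, ww=0)
        d = newborn_class_distribution(s, alpha=0.0)
        assert d[ZZM] == pytest.approx(0.5) and d[WZF] == pytest.approx(0.5)

    def test_intersex_founded_population(self):
        # all sires are WZ males: the WW-creating cross
        s = PopulationState(zz=0, is_=100, wz=100, ww=0)
        d = newborn_class_distribution(s, alpha=0.0)
        assert d[ZZM] == pytest.approx(0.25)
        assert d[WZF] == pytest.approx(0.5)
        assert d[WWF] == pytest.approx(0.25)

    def test_mixed_sire_pool_is_the_cross_mixture(self):
        # half ZZ sires (0.5, 0.5, 0) + half WZ sires (0.25, 0.5, 0.25)
        s = PopulationState(zz=50, is_=50, wz=100, ww=0)
        d = newborn_class_distribution(s, alpha=0.0)
        assert d[ZZM] == pytest.approx(0.375)
        assert d[WZF] == pytest.approx(0.5)
        assert d[WWF] == pytest.approx(0.125)

    @pytest.mark.parametrize("state", [
        PopulationState(zz=10, is_=0, wz=0, ww=0),
        PopulationState(zz=0, is_=0, wz=10, ww=5),
    ])
    def test_single_sex_population_recruits_nothing(self, state):
        assert newborn_class_distribution(state, alpha=0.04) is None


class TestStepOperators:
    def test_replacement_equilibrium(self):
        # 100 females x 2 surviving recruits each, no adult survival:
        # the population replaces itself exactly, lambda = 1
        params = DemographicParams(alpha=0.0, sigma0=1.0, sigma_a=0.0, phi=2.0)
        s = PopulationState(zz=100, is_=0, wz=100, ww=0)
        nxt = project_step(s, params)
        assert nxt.zz == pytest.approx(100) and nxt.wz == pytest.approx(100)

    def test_no_females_means_geometric_decay(self):
        params = DemographicParams(alpha=0.0, sigma0=1.0, sigma_a=0.6, phi=2.0)
        s = PopulationState(zz=50, is_=50, wz=0, ww=0)
        nxt = project_step(s, params)
        assert nxt.total == pytest.approx(0.6 * s.total)

    def test_ltsd_is_a_fixed_point_of_the_fractions(self, default_params):
        sd = stable_distribution(0.04, default_params)
        s = PopulationState.from_array(sd.as_array())
        nxt = project_step(s, default_params)
        frac = nxt.as_array() / nxt.total
        assert np.max(np.abs(frac - sd.as_array())) < 1e-8

    def test_constant_step_conserves_total(self, default_params):
        s = PopulationState(zz=40, is_=7, wz=50, ww=3)
        nxt = constant_population_step(s, default_params)
        assert nxt.total == pytest.approx(s.total, rel=1e-12)

    def test_constant_step_full_turnover_still_conserves(self):
        # sigma_a = 0: every adult dies and is replaced by a recruit
        params = DemographicParams(alpha=0.04, sigma_a=0.0, sigma0=1.0, phi=1.0)
        s = PopulationState(zz=40, is_=10, wz=45, ww=5)
        nxt = constant_population_step(s, params)
        assert nxt.total == pytest.approx(100.0)

    def test_constant_step_reaches_same_structural_fixed_point(self, default_params):
        s = PopulationState(zz=50, is_=0, wz=50, ww=0)
        for _ in range(300):
            s = constant_population_step(s, default_params)
        target = stable_distribution(0.04).as_array()
        assert np.max(np.abs(s.as_array() / s.total - target)) < 1e-6

    @settings(max_examples=50, derandomize=True)
    @given(
        zz=st.floats(0, 100), is_=st.floats(0, 100),
        wz=st.floats(0, 100), ww=st.floats(0, 100),
        alpha=st.floats(0, 1), sigma_a=st.floats(0, 0.95),
        rec=st.floats(0, 5),
    )
    def test_abundances_stay_nonnegative(self, zz, is_, wz, ww, alpha, sigma_a, rec):
        params = DemographicParams(alpha=alpha, sigma0=1.0, sigma_a=sigma_a, phi=rec)
        s = PopulationState(zz=zz, is_=is_, wz=wz, ww=ww)
        nxt = project_step(s, params)
        assert min(nxt.zz, nxt.is_, nxt.wz, nxt.ww) >= 0
        if s.total > 0:
            nxt2 = constant_population_step(s, params)
            assert min(nxt2.zz, nxt2.is_, nxt2.wz, nxt2.ww) >= 0


class TestStableDistribution:
    def test_reference_fractions_at_four_percent_alpha(self):
        """The canonical LTSD: 47.96 / 2.04 / 48.96 / 1.04 percent."""
        pct = stable_distribution(0.04).percentages()
        assert pct[ZZM] == 47.96
        assert pct[IS] == 2.04
        assert pct[WZF] == 48.96
        assert pct[WWF] == 1.04

    def test_binary_sex_limit(self):
        sd = stable_distribution(0.0)
        assert sd.fractions[ZZM] == pytest.approx(0.5, abs=1e-9)
        assert sd.fractions[IS] == 0.0 and sd.fractions[WWF] == 0.0

    @pytest.mark.parametrize("sigma_a", [0.0, 0.3, 0.9])
    @pytest.mark.parametrize("rec", [0.5, 1.2, 3.0])
    def test_fractions_depend_only_on_alpha(self, sigma_a, rec):
        base = stable_distribution(0.04).as_array()
        params = DemographicParams(alpha=0.04, sigma0=1.0, sigma_a=sigma_a, phi=rec)
        sd = stable_distribution(0.04, params)
        assert np.max(np.abs(sd.as_array() - base)) < 1e-6

    @pytest.mark.parametrize("alpha", [0.0, 0.01, 0.04, 0.1, 0.2])
    def test_iterative_solver_matches_direct_fixed_point(self, alpha):
        """Projection iteration and the Newton solve of the newborn-share
        equations are independent routes to the same LTSD."""
        it = stable_distribution(alpha).fractions
        fp = stable_distribution_fixed_point(alpha)
        for c in CLASS_ORDER:
            assert it[c] == pytest.approx(fp[c], abs=1e-8)

    @pytest.mark.parametrize("alpha", [0.0, 0.01, 0.04, 0.1, 0.2])
    def test_sex_ratio_balanced_at_fixed_point(self, alpha):
        f = stable_distribution(alpha).fractions
        males = f[ZZM] + f[IS]
        assert abs(males - 0.5) < 1e-4  # within 0.01 percentage point

    @pytest.mark.parametrize("alpha", [0.01, 0.04, 0.1])
    def test_half_alpha_rule(self, alpha):
        """IS fraction at the LTSD is about alpha/2. Exactly, IS = alpha x
        (WZ-genotype total), which sits slightly above 1/2 and approaches
        1/2 as alpha -> 0 (0.51 at alpha=0.04, ~0.525 at alpha=0.1)."""
        f = stable_distribution(alpha).fractions
        ratio = f[IS] / alpha
        assert ratio == pytest.approx(f[IS] + f[WZF], abs=1e-9)
        assert 0.50 <= ratio <= 0.50 + 0.26 * alpha

    def test_growth_rate_matches_binary_sex_population(self, default_params):
        """lambda_inf is set by survival and fecundity alone: alpha does not
        change the long-run growth rate."""
        lam_binary = stable_distribution(0.0, DemographicParams(
            alpha=0.0, sigma0=1.0, sigma_a=0.6, phi=1.2)).lambda_inf
        lam_is = stable_distribution(0.04, default_params).lambda_inf
        assert abs(lam_binary - lam_is) < 1e-8


class TestConvergenceAndThresholds:
    def test_already_at_ltsd_converges_in_zero_steps(self, default_params):
        sd = stable_distribution(0.04, default_params)
        s = PopulationState.from_array(100 * sd.as_array())
        assert generations_to_convergence(s, default_params).steps == 0

    def test_convergence_within_thirty_generations(self, default_params, half_half):
        res = generations_to_convergence(half_half, default_params, tol_pp=0.1)
        assert res.steps <= 30
        assert res.years == pytest.approx(res.steps / 2.0)

    def test_smaller_tolerance_never_converges_earlier(self, default_params, half_half):
        steps = [
            generations_to_convergence(half_half, default_params, tol_pp=t).steps
            for t in (1.0, 0.5, 0.1, 0.01)
        ]
        assert steps == sorted(steps)

    def test_target_already_met(self, default_params):
        s = PopulationState(zz=600, is_=0, wz=600, ww=0)
        assert time_to_threshold(s, default_params, 1000) == 0

    def test_intersex_founders_reach_threshold_earlier(self, default_params):
        """Founding with WZ males instead of ZZ males front-loads growth:
        the female-biased progeny reaches 1,000 sooner."""
        t_is = time_to_threshold(
            PopulationState(zz=0, is_=100, wz=100, ww=0), default_params, 1000)
        t_zz = time_to_threshold(
            PopulationState(zz=100, is_=0, wz=100, ww=0), default_params, 1000)
        assert t_is < t_zz

    @pytest.mark.parametrize("sigma_a,rec", [(0.3, 1.5), (0.6, 1.2), (0.8, 0.9)])
    def test_intersex_founders_never_slower(self, sigma_a, rec):
        params = DemographicParams(alpha=0.04, sigma0=1.0, sigma_a=sigma_a, phi=rec)
        t_is = time_to_threshold(
            PopulationState(zz=0, is_=100, wz=100, ww=0), params, 1000)
        t_zz = time_to_threshold(
            PopulationState(zz=100, is_=0, wz=100, ww=0), params, 1000)
        assert t_is <= t_zz

    def test_higher_recruitment_never_slows_growth(self):
        p1 = DemographicParams(alpha=0.04, sigma0=1.0, sigma_a=0.6, phi=1.2)
        p2 = DemographicParams(alpha=0.04, sigma0=1.0, sigma_a=0.6, phi=2.4)
        s = PopulationState(zz=100, is_=0, wz=100, ww=0)
        assert time_to_threshold(s, p2, 1000) <= time_to_threshold(s, p1, 1000)

    def test_nongrowing_population_signals_failure(self):
        params = DemographicParams(alpha=0.04, sigma0=1.0, sigma_a=0.3, phi=0.5)
        s = PopulationState(zz=100, is_=0, wz=100, ww=0)
        with pytest.raises(ConvergenceError):
            time_to_threshold(s, params, 1000, step_cap=500)


class TestTrajectories:
    def test_binary_sex_growth_has_no_transient(self):
        params = DemographicParams(alpha=0.0, sigma0=1.0, sigma_a=0.6, phi=1.2)
        traj = simulate_trajectory(
            PopulationState(zz=100, is_=0, wz=100, ww=0), params, 20)
        assert np.allclose(traj.lambdas, traj.lambdas[0])

    def test_stochastic_mean_tracks_deterministic(self, default_params):
        init = PopulationState(zz=500, is_=20, wz=500, ww=10)
        det = simulate_trajectory(init, default_params, 8)
        reps = 300
        totals = np.zeros((reps, 9))
        for r in range(reps):
            traj = simulate_trajectory(init, default_params, 8,
                                       mode="stochastic", seed=1000 + r)
            totals[r] = traj.totals()
        mean, se = totals.mean(axis=0), totals.std(axis=0, ddof=1) / np.sqrt(reps)
        expected = det.totals()
        assert np.all(np.abs(mean - expected) < 4 * se + 1e-9)

    def test_stochastic_run_is_seed_reproducible(self, default_params):
        init = PopulationState(zz=50, is_=5, wz=50, ww=2)
        a = simulate_trajectory(init, default_params, 10, mode="stochastic", seed=7)
        b = simulate_trajectory(init, default_params, 10, mode="stochastic", seed=7)
        assert [s.as_array().tolist() for s in a.states] == \
               [s.as_array().tolist() for s in b.states]

    def test_stochastic_extinction_truncates_and_flags(self):
        params = DemographicParams(alpha=0.0, sigma0=1.0, sigma_a=0.05, phi=0.01)
        traj = simulate_trajectory(
            PopulationState(zz=2, is_=0, wz=2, ww=0), params, 200,
            mode="stochastic", seed=3)
        assert traj.extinct
        assert traj.final.total == 0
        assert len(traj.states) < 201

    def test_constant_step_trajectory_conserves_totals(self, default_params):
        traj = simulate_trajectory(
            PopulationState(zz=50, is_=0, wz=50, ww=0), default_params, 50,
            step="constant")
        assert np.allclose(traj.totals(), 100.0)


class TestAlphaEstimator:
    def test_point_estimates(self):
        assert estimate_alpha_from_cohort(0.0204) == pytest.approx(0.0408)
        assert estimate_alpha_from_cohort(0.0) == 0.0

    def test_out_of_model_fraction_rejected(self):
        with pytest.raises(ValueError):
            estimate_alpha_from_cohort(0.6)

    def test_recovery_from_simulated_ltsd_cohorts(self, rng):
        """Multinomial cohorts at the LTSD recover alpha without bias."""
        alpha, n, reps = 0.04, 1000, 500
        f = stable_distribution(alpha).as_array()
        counts = rng.multinomial(n, f, size=reps)
        alpha_hat = 2.0 * counts[:, 1] / n
        is_inf = stable_distribution(alpha).fractions[IS]
        se = 2.0 * np.sqrt(is_inf * (1 - is_inf) / n)
        covered = np.mean(np.abs(alpha_hat - 2 * is_inf) <= 1.96 * se)
        assert covered >= 0.93
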