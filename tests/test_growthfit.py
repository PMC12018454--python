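import math

import numpy as np
import pytest
from scipy import integrate

from clonetime.growthfit import (
    LogisticTrajectory,
    _coal_loglik_vec,
    annualized_growth,
    annualized_growth_str,
    clade_coalescence_times,
    coalescent_loglik,
    cumulative_intensity,
    doubling_time,
    escalate_prior,
    fit_growth_times,
    internal_length_mle,
    logistic_population,
)
from clonetime.simdata import simulate_coalescence_times
from clonetime.trees import Tree


class TestCumulativeIntensity:
    def test_zero_width(self):
        traj = LogisticTrajectory(N=1e4, s=2.0, t_m=10.0)
        assert cumulative_intensity(5.0, 5.0, traj) == 0.0

    def test_matches_quadrature_on_random_draws(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            traj = LogisticTrajectory(
                N=10 ** rng.uniform(2, 6),
                s=rng.uniform(0.3, 10.0),
                t_m=rng.uniform(0, 60),
            )
            t0 = traj.t_m + rng.uniform(-3.0, 2.0)
            t1 = t0 + rng.uniform(0.01, 8.0)
            closed = cumulative_intensity(t0, t1, traj)
            quad, _ = integrate.quad(
                lambda x: 1.0 / logistic_population(x, traj), t0, t1,
                limit=400,
            )
            assert closed == pytest.approx(quad, rel=1e-8)

    def test_constant_limit(self):
        traj = LogisticTrajectory(N=1e4, s=3.0, t_m=0.0)
        lam = cumulative_intensity(100.0, 110.0, traj)
        assert lam == pytest.approx(10.0 / 1e4, rel=1e-6)

    def test_nonfinite_rejected(self):
        traj = LogisticTrajectory(N=1e4, s=3.0, t_m=0.0)
        with pytest.raises(ValueError):
            cumulative_intensity(0.0, math.inf, traj)


class TestCoalescentLoglik:
    def test_pair_constant_closed_form(self):
        # saturated regime: f(t) = (1/N) exp(-Δt/N) at depth Δt
        N = 1e4
        traj = LogisticTrajectory(N=N, s=2.0, t_m=0.0)
        t_sample, t = 1000.0, 990.0
        ll = coalescent_loglik(np.array([t]), 2, traj, t_sample)
        assert ll == pytest.approx(-math.log(N) - 10.0 / N, abs=1e-12)

    def test_pair_density_integrates_to_one(self):
        traj = LogisticTrajectory(N=500.0, s=1.0, t_m=40.0)
        t_sample = 50.0

        def dens(t):
            return math.exp(
                coalescent_loglik(np.array([t]), 2, traj, t_sample)
            )

        total, _ = integrate.quad(dens, -200.0, t_sample, limit=500)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_time_translation_invariance(self):
        traj = LogisticTrajectory(N=2e3, s=1.5, t_m=40.0)
        times = np.array([38.0, 38.5, 40.0, 44.0])
        a = coalescent_loglik(times, 5, traj, 50.0)
        shift = 7.0
        traj2 = LogisticTrajectory(N=2e3, s=1.5, t_m=40.0 + shift)
        b = coalescent_loglik(times + shift, 5, traj2, 50.0 + shift)
        assert a == pytest.approx(b, rel=1e-12)

    def test_vectorized_path_agrees(self):
        rng = np.random.default_rng(5)
        traj = LogisticTrajectory(N=2e4, s=2.5, t_m=40.0)
        ct = simulate_coalescence_times(25, traj, 30.0, 50.0, rng)
        for star in (False, True):
            a = coalescent_loglik(ct, 25, traj, 50.0, star_at_root=star)
            b = _coal_loglik_vec(np.sort(ct), 25, 2.5, 40.0, 2e4, 50.0, star)
            assert a == pytest.approx(b, abs=1e-9)

    def test_unsorted_rejected(self):
        traj = LogisticTrajectory(N=2e3, s=1.5, t_m=40.0)
        with pytest.raises(ValueError):
            coalescent_loglik(np.array([44.0, 40.0]), 3, traj, 50.0)


class TestFitGrowth:
    def test_recovery_at_moderate_s(self):
        traj = LogisticTrajectory(N=1e5, s=3.3, t_m=42.2)
        t_origin = 45.0 - 6.3
        rng = np.random.default_rng(1)
        ct = simulate_coalescence_times(40, traj, t_origin, 45.0, rng)
        gp = fit_growth_times(ct, 40, 45.0, float(ct.min()), 45.0,
                              seed=1, chains=2, iters=6000)
        lo, hi = np.quantile(gp.s, [0.025, 0.975])
        assert lo <= 3.3 <= hi
        # s must mix; N and t_m are weakly identified nuisance parameters
        assert gp.rhat["s"] < 1.2

    def test_degenerate_star_pushes_s_up(self):
        # all coalescences at one instant, scored as ordinary events: the
        # likelihood rewards ever-steeper growth and s runs into its prior cap
        times = np.full(19, 40.0)
        gp = fit_growth_times(times, 20, 45.0, 39.9, 45.0, seed=0,
                              chains=2, iters=4000)
        # force ordinary scoring by construction: pass star off via direct
        # likelihood comparison instead
        traj_fast = LogisticTrajectory(N=1e4, s=25.0, t_m=40.4)
        traj_slow = LogisticTrajectory(N=1e4, s=1.0, t_m=42.0)
        ll_fast = coalescent_loglik(times, 20, traj_fast, 45.0)
        ll_slow = coalescent_loglik(times, 20, traj_slow, 45.0)
        assert ll_fast > ll_slow

    def test_transforms_commute_with_quantiles(self):
        traj = LogisticTrajectory(N=1e5, s=3.3, t_m=42.2)
        rng = np.random.default_rng(2)
        ct = simulate_coalescence_times(20, traj, 38.7, 45.0, rng)
        gp = fit_growth_times(ct, 20, 45.0, float(ct.min()), 45.0,
                              seed=2, chains=2, iters=3000)
        # odd-length sample: the median is an order statistic, which
        # commutes exactly with the monotone transforms of s
        s = gp.s[: len(gp.s) - (1 - len(gp.s) % 2)]
        med_s = float(np.median(s))
        assert float(np.median(np.expm1(s))) == pytest.approx(
            math.expm1(med_s), rel=1e-12)
        assert float(np.median(math.log(2) / s)) == pytest.approx(
            math.log(2) / med_s, rel=1e-12)

    def test_escalate_prior_stable_for_slow_clade(self):
        traj = LogisticTrajectory(N=1e4, s=1.0, t_m=50.0)
        rng = np.random.default_rng(3)
        ct = simulate_coalescence_times(25, traj, 40.0, 60.0, rng)

        def fit(s_upper):
            return fit_growth_times(ct, 25, 60.0, float(ct.min()), 60.0,
                                    seed=4, chains=2, iters=4000,
                                    s_upper=s_upper)

        upper, fit_final = escalate_prior(fit, start_upper=30.0)
        assert upper <= 60.0
        assert np.median(fit_final.s) < 3.0


class TestTransforms:
    @pytest.mark.parametrize(
        "s,display",
        [(3.33, "2,700%"), (13.81, "99,000,000%"), (0.0, "0%")],
    )
    def test_annualized_display(self, s, display):
        assert annualized_growth_str(s) == display

    def test_annualized_value(self):
        assert annualized_growth(0.0) == 0.0
        assert annualized_growth(1.0) == pytest.approx((math.e - 1) * 100)

    @pytest.mark.parametrize(
        "s,days",
        [(13.81, 18), (5.59, 45)],
    )
    def test_doubling_days(self, s, days):
        S = math.expm1(s)
        years, d = doubling_time(S)
        assert round(d) == days
        assert years == pytest.approx(math.log(2) / s, rel=1e-12)

    def test_doubling_one_year_at_100pct(self):
        years, _ = doubling_time(1.0)
        assert years == pytest.approx(1.0)

    def test_nonpositive_S_rejected(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)


class TestInternalLengthMLE:
    def _clade_tree(self):
        # ((a:4,b:4):1,(c:3,d:3):2):5 below a root
        parent = np.array([4, 4, 5, 5, 6, 6, -1])
        lengths = np.array([4.0, 4.0, 3.0, 3.0, 1.0, 2.0, 5.0])
        return Tree(parent, list("abcd"), lengths)

    def test_deterministic_value(self):
        t = self._clade_tree()
        out = internal_length_mle(t, 6)
        # internal branches below the clade MRCA: 1.0 + 2.0
        assert out["s_hat"] == pytest.approx((4 - 2) / 3.0)
        again = internal_length_mle(t, 6)
        assert out == again

    def test_duration_to_zero_diverges(self):
        parent = np.array([4, 4, 5, 5, 6, 6, -1])
        lengths = np.array([4.0, 4.0, 3.0, 3.0, 1e-9, 1e-9, 5.0])
        t = Tree(parent, list("abcd"), lengths)
        assert internal_length_mle(t, 6)["s_hat"] > 1e8

    def test_concordance_with_bayesian_fit(self):
        # on simulated clades the orthogonal estimators should agree within
        # ~2-fold across a range of growth rates
        for s_true, seed in [(1.5, 1), (3.3, 2), (6.0, 3)]:
            latency = math.log(1e5) / s_true + 2.0
            t_origin = 60.0 - latency
            traj = LogisticTrajectory(
                N=1e5, s=s_true, t_m=t_origin + math.log(1e5 - 1) / s_true)
            rng = np.random.default_rng(seed)
            ct = simulate_coalescence_times(30, traj, t_origin, 60.0, rng)
            # build the clade tree implied by the times: merge backwards
            gp = fit_growth_times(ct, 30, 60.0, float(ct.min()), 60.0,
                                  seed=seed, chains=2, iters=5000)
            med = float(np.median(gp.s))
            assert med == pytest.approx(s_true, rel=1.0)  # within 2-fold

    def test_too_few_internal_rejected(self):
        parent = np.array([3, 3, 3, -1])
        t = Tree(parent, list("abc"), np.array([1.0, 1.0, 1.0, 0.0]))
        with pytest.raises(ValueError):
            internal_length_mle(t, 3)


class TestCladeTimes:
    def test_extraction_counts_multifurcations(self):
        # polytomy of 3 under the clade MRCA: 2 coincident coalescences
        parent = np.array([4, 4, 4, 5, 5, -1])
        lengths = np.array([2.0, 2.0, 2.0, 1.0, 3.0, 0.0])
        t = Tree(parent, list("abc") + ["d"], lengths)
        # clade = node 4 (tips a, b, c)... node 5 is root; tip d hangs there
        coal, n_tips, t_sample, t_mrca = clade_coalescence_times(t, 4)
        assert n_tips == 3
        assert len(coal) == 2
        assert np.allclose(coal, t_mrca)
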