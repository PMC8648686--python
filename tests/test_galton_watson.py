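import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

from canningsim import galton_watson as gw
from canningsim.offspring_laws import make_ylaw


class TestGWLawMoments:
    def test_mixed_poisson_deterministic(self, det1):
        law = gw.mixed_poisson(det1, 1.05)
        assert law.mean == pytest.approx(1.05)
        assert law.variance == pytest.approx(1.05)  # plain Poisson

    def test_mixed_poisson_gamma(self, gamma2):
        # Var = m^2 Var(Y) + m with Var(Y) = 1/2
        law = gw.mixed_poisson(gamma2, 1.1)
        assert law.mean == pytest.approx(1.1)
        assert law.variance == pytest.approx(1.1**2 * 0.5 + 1.1, rel=1e-12)

    def test_two_point(self):
        law = gw.two_point(0.5, 0.2)
        assert law.mean == pytest.approx(1.1)
        assert law.variance == pytest.approx(0.1 * 0.9)

    def test_explicit(self):
        law = gw.explicit([0.6, 0.0, 0.4])
        assert law.mean == pytest.approx(0.8)
        assert law.variance == pytest.approx(0.4 * 4 - 0.64)

    def test_mixed_binomial_deterministic_is_binomial(self, det1):
        law = gw.mixed_binomial(100, det1, 0.011)
        b = stats.binom(100, 0.011)
        assert law.mean == pytest.approx(b.mean(), rel=1e-12)
        assert law.variance == pytest.approx(b.var(), rel=1e-12)

    def test_mixed_binomial_matches_simulation(self, gamma2):
        law = gw.mixed_binomial(50, gamma2, 0.004)
        rng = np.random.default_rng(1)
        y = gamma2.sample(200_000, rng)
        z = rng.binomial(50, np.clip(0.004 * y, 0, 1))
        assert law.mean == pytest.approx(z.mean(), abs=5 * z.std() / math.sqrt(len(z)))
        assert law.variance == pytest.approx(np.var(z, ddof=1), rel=0.05)

    def test_invalid_params(self, det1):
        with pytest.raises(ValueError):
            gw.two_point(0.5, 3.0)
        with pytest.raises(ValueError):
            gw.mixed_poisson(det1, 0.0)
        with pytest.raises(ValueError):
            gw.explicit([0.5, 0.4])


class TestSimulate:
    def test_zero_start_stays_zero(self, det1, rng):
        traj = gw.gw_simulate(gw.mixed_poisson(det1, 1.1), 0, 5, rng)
        assert np.all(traj.z == 0)

    def test_two_point_nondecreasing_never_dies(self, rng):
        traj = gw.gw_simulate(gw.two_point(0.5, 0.2), 1, 40, rng)
        assert np.all(np.diff(traj.z) >= 0)
        assert traj.z[-1] >= 1

    def test_mixed_poisson_mean_growth(self, det1):
        # E[Z_5] = m^5; SE from the closed-form generation variance
        m, reps = 1.05, 20_000
        law = gw.mixed_poisson(det1, m)
        rng = np.random.default_rng(2)
        finals = np.array([gw.gw_simulate(law, 1, 5, rng).z[-1] for _ in range(reps)])
        _, var5 = gw.gw_moments(m, law.variance, 5)
        se = math.sqrt(var5 / reps)
        assert abs(finals.mean() - m**5) <= 5 * se

    def test_explosion_flagged(self, det1, rng):
        law = gw.mixed_poisson(det1, 2.0)
        traj = gw.gw_simulate(law, 1, 100, rng, pop_cap=1000)
        assert traj.exploded or traj.z[-1] == 0


class TestSurvival:
    def test_critical_is_zero(self):
        pmf = stats.poisson(1.0).pmf(np.arange(60))
        pmf[-1] += 1.0 - pmf.sum()  # renormalize the tiny tail
        assert gw.survival_probability(gw.explicit(pmf)) == 0.0

    def test_two_point_is_one(self):
        assert gw.survival_probability(gw.two_point(0.5, 0.2)) == 1.0

    def test_poisson_fixed_point_against_brentq(self, det1):
        # independent oracle: root of 1 - phi = exp(-m*phi)
        m = 1.05
        phi = gw.survival_probability(gw.mixed_poisson(det1, m))
        oracle = optimize.brentq(lambda f: 1.0 - f - math.exp(-m * f), 1e-9, 1.0)
        assert phi == pytest.approx(oracle, abs=1e-9)

    def test_equals_pgf_iteration_limit(self, gamma2):
        # the same quantity two ways: bisection vs iterating f from 0
        law = gw.mixed_poisson(gamma2, 1.08)
        phi = gw.survival_probability(law)
        q = 0.0
        for _ in range(200_000):
            q_new = law.pgf(q)
            if abs(q_new - q) < 1e-15:
                q = q_new
                break
            q = q_new
        assert phi == pytest.approx(1.0 - q, abs=1e-9)

    def test_matches_simulation(self, det1):
        # extinction by a deep horizon approximates 1 - phi
        law = gw.mixed_poisson(det1, 1.2)
        phi = gw.survival_probability(law)
        rng = np.random.default_rng(3)
        reps = 5000
        surv = 0
        for _ in range(reps):
            traj = gw.gw_simulate(law, 1, 120, rng, pop_cap=100_000)
            surv += traj.exploded or traj.z[-1] > 0
        se = math.sqrt(phi * (1 - phi) / reps)
        assert abs(surv / reps - phi) <= 5 * se

    def test_unavailable_pgf(self):
        law = gw.mixed_poisson(make_ylaw("lognormal", (0.25,)), 1.1)
        with pytest.raises(gw.PgfUnavailableError):
            gw.survival_probability(law)


class TestHaldaneSurvival:
    def test_arithmetic(self):
        assert gw.haldane_survival(0.01, 2.0) == pytest.approx(0.01)
        assert gw.haldane_survival(0.05, 1.0) == pytest.approx(0.1)

    def test_ratio_tends_to_one(self, det1):
        # |phi sigma^2/(2s) - 1| shrinks as s drops
        devs = {}
        for s in (1e-1, 1e-3):
            law = gw.mixed_poisson(det1, 1.0 + s)
            phi = gw.survival_probability(law)
            devs[s] = abs(phi / gw.haldane_survival(s, law.variance) - 1.0)
        assert devs[1e-3] <= 0.05
        assert devs[1e-3] < devs[1e-1]

    def test_invalid(self):
        with pytest.raises(ValueError):
            gw.haldane_survival(0.0, 1.0)


class TestImmortalLineLaw:
    def test_delta2_all_immortal(self):
        law = gw.explicit([0.0, 0.0, 1.0])
        res = gw.immortal_line_law(law, 1.0, kmax=5)
        assert res.probs[2] == pytest.approx(1.0, abs=1e-12)
        assert res.probs[0] == 0.0

    def test_normalization(self, gamma2):
        law = gw.mixed_poisson(gamma2, 1.1)
        phi = gw.survival_probability(law)
        res = gw.immortal_line_law(law, phi, kmax=150)
        assert res.probs.sum() + res.overflow == pytest.approx(1.0, abs=1e-12)
        assert res.probs[0] == 0.0

    def test_mean_preserved(self, gamma2):
        # E[Z*_1] = E[Z_1]
        law = gw.mixed_poisson(gamma2, 1.1)
        phi = gw.survival_probability(law)
        res = gw.immortal_line_law(law, phi, kmax=200)
        assert res.mean() == pytest.approx(law.mean, abs=1e-8)

    def test_kmax_too_small_raises(self):
        law = gw.explicit([0.0] * 30 + [1.0])  # always 30 children
        with pytest.raises(ValueError, match="kmax too small"):
            gw.immortal_line_law(law, 0.9, kmax=3)

    def test_phi_range(self, gamma2):
        with pytest.raises(ValueError):
            gw.immortal_line_law(gw.mixed_poisson(gamma2, 1.1), 0.0, 10)


class TestTwoPointDP:
    def test_zero_generations(self):
        res = gw.two_point_dp(0.5, 0.2, 0, 16)
        assert res.probs[1] == 1.0 and res.overflow == 0.0

    def test_one_generation(self):
        res = gw.two_point_dp(0.5, 0.2, 1, 16)
        assert res.probs[1] == pytest.approx(0.9, abs=1e-14)
        assert res.probs[2] == pytest.approx(0.1, abs=1e-14)

    def test_mean_closed_form(self):
        # cap 1024 >= 2^10 is non-binding: mean is exactly (1+bs)^10
        res = gw.two_point_dp(0.5, 0.2, 10, 1024)
        assert res.overflow == 0.0
        assert res.mean() == pytest.approx(1.1**10, abs=1e-10)

    def test_variance_closed_form(self):
        res = gw.two_point_dp(0.5, 0.2, 10, 1024)
        k = np.arange(len(res.probs))
        var_dp = float(res.probs @ (k * k)) - res.mean() ** 2
        _, var_formula = gw.gw_moments(1.1, 0.09, 10)
        assert var_dp == pytest.approx(var_formula, abs=1e-10)

    def test_mass_conserved_with_overflow(self):
        res = gw.two_point_dp(0.8, 0.5, 20, 8)
        assert res.overflow > 0.5  # growth 1.4^20 >> 8
        assert res.probs.sum() + res.overflow == pytest.approx(1.0, abs=1e-12)

    def test_pz_bounds_on_grid(self):
        # with n0 chosen by the threshold rule, the proven bounds hold:
        # P(Z_{n0} <= (1/s)^(1+d)) <= 7/8 and P(Z_{n0} >= mean/2) >= 1/8
        for beta in (0.3, 0.5, 0.8):
            for s in (0.05, 0.1, 0.2):
                for delta in (0.25, 0.5):
                    n0 = gw.choose_n0(beta, s, delta)
                    half_mean = 0.5 * (1.0 + beta * s) ** n0
                    cap = max(64, int(4 * half_mean))
                    res = gw.two_point_dp(beta, s, n0, cap)
                    assert res.prob_leq((1.0 / s) ** (1.0 + delta)) <= 7.0 / 8.0
                    assert res.prob_geq(half_mean) >= 1.0 / 8.0


class TestGWMoments:
    def test_first_generation(self):
        assert gw.gw_moments(1.3, 0.7, 1) == (pytest.approx(1.3), pytest.approx(0.7))

    def test_hand_value(self):
        # law of total variance: m=2, s2=1, n=2 -> (4, 6)
        mean, var = gw.gw_moments(2.0, 1.0, 2)
        assert mean == pytest.approx(4.0) and var == pytest.approx(6.0)

    def test_critical_limit(self):
        assert gw.gw_moments(1.0, 0.5, 7) == (1.0, pytest.approx(3.5))

    def test_two_point_variance_simulation(self):
        # Var(Z_10) for the two-point process, vectorized across replicates
        beta, s, n, reps = 0.5, 0.2, 10, 100_000
        rng = np.random.default_rng(4)
        z = np.ones(reps, dtype=np.int64)
        for _ in range(n):
            z = z + rng.binomial(z, beta * s)
        _, var_formula = gw.gw_moments(1.1, 0.09, n)
        sample_var = np.var(z, ddof=1)
        dev = z - z.mean()
        var_of_var = (np.mean(dev**4) - (reps - 3) / (reps - 1) * sample_var**2) / reps
        assert abs(sample_var - var_formula) <= 5 * math.sqrt(var_of_var)


class TestChooseN0:
    def test_reference_case(self):
        # 1.1^32 < 2 * 5^1.5 <= 1.1^33
        assert gw.choose_n0(0.5, 0.2, 0.5) == 33

    def test_definition_holds(self):
        for beta, s, delta in [(0.5, 0.2, 0.5), (0.3, 0.05, 0.25), (0.9, 0.1, 1.0)]:
            n0 = gw.choose_n0(beta, s, delta)
            thr = 2.0 * (1.0 / s) ** (1.0 + delta)
            assert (1.0 + beta * s) ** n0 >= thr
            assert (1.0 + beta * s) ** (n0 - 1) < thr

    @given(b1=st.floats(0.1, 0.9), b2=st.floats(0.1, 0.9))
    def test_monotone_in_beta(self, b1, b2):
        lo, hi = sorted((b1, b2))
        assert gw.choose_n0(hi, 0.1, 0.5) <= gw.choose_n0(lo, 0.1, 0.5)

    def test_boundary_rounding_case(self):
        # threshold sits within ~2e-4 relative of a power: must not misround
        n0 = gw.choose_n0(0.5, 0.1, 0.5)
        thr = 2.0 * 10.0**1.5
        assert 1.05 ** (n0 - 1) < thr <= 1.05**n0


class TestAbsorptionTimeTail:
    def test_one_generation_is_pgf_at_zero(self):
        law = gw.explicit([0.6, 0.0, 0.4])
        assert 1.0 - gw.absorption_time_tail(law, 1, 1) == pytest.approx(0.6)

    def test_two_point_never_extinct(self):
        law = gw.two_point(0.5, 0.2)
        for horizon in (1, 10, 1000):
            assert gw.absorption_time_tail(law, 1, horizon) == 1.0

    def test_matches_monte_carlo(self):
        # offspring 0 w.p. 0.6 / 2 w.p. 0.4, i.e. Z' = 2*Bin(Z, 0.4):
        # vectorized simulation as an independent oracle
        law = gw.explicit([0.6, 0.0, 0.4])
        exact = gw.absorption_time_tail(law, 1, 20)
        reps = 100_000
        rng = np.random.default_rng(5)
        z = np.ones(reps, dtype=np.int64)
        for _ in range(20):
            z = 2 * rng.binomial(z, 0.4)
        mc = np.mean(z > 0)
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(mc - exact) <= 5 * se

    def test_mc_fallback_requires_rng(self):
        law = gw.mixed_poisson(make_ylaw("lognormal", (0.25,)), 1.1)
        with pytest.raises(gw.PgfUnavailableError):
            gw.absorption_time_tail(law, 1, 5)
        est = gw.absorption_time_tail(law, 1, 5, rng=np.random.default_rng(6), reps=500)
        assert 0.0 <= est <= 1.0


class TestGrowthFactorPresets:
    def test_both_tend_to_one_plus_s(self):
        n, s = 10**6, 1e-3
        up = gw.growth_factor_upper(n, 0.3, 0.05, 0.45, s)
        lo = gw.growth_factor_lower(n, 0.05, 0.45, s, 0.1)
        assert up == pytest.approx(1.0 + s, rel=1e-2)
        assert lo == pytest.approx(1.0 + s, rel=1e-2)
        assert up >= lo
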