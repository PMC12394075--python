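"""Sub-frame-rate kinetics: occupancy-fraction distribution, marginal frame
likelihood and the global ensemble-MCMC inference."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, quad

import smfretkit as sk
from smfretkit.subres import (PriorSpec, frame_loglik,
                              infer_rates_global, occupancy_fraction_density,
                              occupancy_point_masses)


def total_probability(k1, k2, tau):
    w0, w1 = occupancy_point_masses(k1, k2, tau)
    cont, _ = quad(occupancy_fraction_density, 0.0, 1.0, args=(k1, k2, tau),
                   limit=300)
    return w0 + w1 + cont


def model_cdf_at(points, k1, k2, tau, grid_size=8001):
    """Mixed CDF (atom at 0 + continuous part) evaluated at sorted points."""
    w0, _w1 = occupancy_point_masses(k1, k2, tau)
    xs = np.linspace(1e-9, 1 - 1e-9, grid_size)
    dens = occupancy_fraction_density(xs, k1, k2, tau)
    cum = cumulative_trapezoid(dens, xs, initial=0.0)
    return w0 + np.interp(points, xs, cum)


class TestOccupancyDistribution:
    def test_point_mass_is_stationary_survival(self):
        w0, w1 = occupancy_point_masses(1.0, 1.0, 0.1)
        assert w1 == pytest.approx(0.5 * np.exp(-0.1), rel=1e-12)
        assert w0 == pytest.approx(0.5 * np.exp(-0.1), rel=1e-12)

    def test_static_limit_mass_in_atoms(self):
        w0, w1 = occupancy_point_masses(1e-3, 1e-3, 0.1)
        assert w0 + w1 == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("k1, k2", [(1.0, 1.0), (10.0, 2.0), (100.0, 100.0)])
    def test_normalization(self, k1, k2):
        assert total_probability(k1, k2, 0.1) == pytest.approx(1.0, abs=1e-8)

    def test_asymmetric_rates_shift_mean(self):
        # mean occupancy of the k1 state is pi1 = k2/(k1+k2)
        k1, k2, tau = 8.0, 2.0, 0.1
        w0, w1 = occupancy_point_masses(k1, k2, tau)
        mean, _ = quad(lambda f: f * occupancy_fraction_density(f, k1, k2, tau),
                       0, 1, limit=300)
        mean += w1
        assert mean == pytest.approx(k2 / (k1 + k2), abs=1e-8)

    def test_matches_monte_carlo_oracle(self):
        k, tau = 10.0, 0.1
        f = sk.simulate_occupancy_windows(k, k, tau, 200_000, seed=3)
        sf = np.sort(f)
        inner = sf[(sf > 0) & (sf < 1)]
        f_model = model_cdf_at(inner, k, k, tau)
        f_emp = np.searchsorted(sf, inner, side="right") / f.size
        assert np.max(np.abs(f_emp - f_model)) < 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            occupancy_fraction_density(0.5, -1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            occupancy_fraction_density(0.5, 1.0, 1.0, 0.0)


class TestFrameLoglik:
    EPS1, EPS2, SIG = 0.44, 0.66, 0.05

    def test_static_limit_is_two_gaussian_mixture(self):
        # k*tau = 1e-5: transitions within a frame are negligible
        es = np.linspace(0.2, 0.9, 15)
        ll = frame_loglik(es, self.EPS1, self.EPS2, self.SIG, 1e-4, 1e-4, 0.1)
        norm = 1.0 / (self.SIG * np.sqrt(2 * np.pi))
        mix = 0.5 * norm * np.exp(-0.5 * ((es - self.EPS1) / self.SIG) ** 2) \
            + 0.5 * norm * np.exp(-0.5 * ((es - self.EPS2) / self.SIG) ** 2)
        assert np.allclose(ll, np.log(mix), atol=1e-4)

    def test_fast_limit_converges_to_single_gaussian_at_midpoint(self):
        """Residual switching variance decays as 1/(k tau): the marginal
        approaches a single Gaussian at the emission midpoint, reaching the
        1e-3 level once k*tau ~ 1e5 (node count raised to resolve the
        narrowing occupancy distribution)."""
        es = np.linspace(0.4, 0.7, 13)
        mid = 0.5 * (self.EPS1 + self.EPS2)
        ref = -0.5 * ((es - mid) / self.SIG) ** 2 \
            - np.log(self.SIG * np.sqrt(2 * np.pi))
        errs = []
        for k, nodes in ((1e3, 2001), (1e4, 2001), (1e5, 2001), (1e6, 4001)):
            ll = frame_loglik(es, self.EPS1, self.EPS2, self.SIG, k, k, 0.1,
                              n_nodes=nodes)
            errs.append(np.max(np.abs(ll - ref)))
        assert np.all(np.diff(errs) < 0)
        assert errs[-1] < 1e-3

    def test_intermediate_regime_matches_monte_carlo_marginal(self):
        k, tau, n = 10.0, 0.1, 400_000
        f = sk.simulate_occupancy_windows(k, k, tau, n, seed=5)
        rng = np.random.default_rng(6)
        e_draws = f * self.EPS1 + (1 - f) * self.EPS2 \
            + rng.normal(0, self.SIG, n)
        test_points = np.linspace(0.35, 0.75, 10)
        h = 0.01
        for e0 in test_points:
            inside = np.abs(e_draws - e0) < h
            p_mc = inside.mean() / (2 * h)
            se = np.sqrt(inside.mean() * (1 - inside.mean()) / n) / (2 * h)
            p_model = np.exp(frame_loglik(e0, self.EPS1, self.EPS2, self.SIG,
                                          k, k, tau))
            assert abs(p_model - p_mc) < 3 * se + 1e-4

    def test_swap_symmetry(self):
        es = np.linspace(0.0, 1.0, 21)
        a = frame_loglik(es, 0.44, 0.66, 0.05, 3.0, 12.0, 0.1)
        b = frame_loglik(es, 0.66, 0.44, 0.05, 12.0, 3.0, 0.1)
        assert np.allclose(a, b, atol=1e-10)

    def test_stable_outside_emission_range(self):
        ll = frame_loglik(np.array([-0.5, 1.5]), self.EPS1, self.EPS2,
                          self.SIG, 10.0, 10.0, 0.1)
        assert np.all(np.isfinite(ll))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            frame_loglik(0.5, 0.44, 0.66, 0.0, 1.0, 1.0, 0.1)


class TestGlobalInference:
    def test_posterior_equals_prior_without_data(self):
        res = infer_rates_global([np.array([])], 0.02, seed=0, init="prior",
                                 n_walkers=1500, min_burn=200, max_burn=200,
                                 production=100, thin=5)
        s = res.summary
        # reference medians of the (eps1 <= eps2)-truncated prior
        rng = np.random.default_rng(1)
        e1 = rng.normal(0.44, 0.2, 300_000)
        e2 = rng.normal(0.66, 0.2, 300_000)
        swap = e1 > e2
        lo = np.where(swap, e2, e1)
        hi = np.where(swap, e1, e2)
        assert s.median[0] == pytest.approx(np.median(lo), abs=0.05)
        assert s.median[1] == pytest.approx(np.median(hi), abs=0.05)
        assert s.median[2] == pytest.approx(0.1, rel=0.10)    # sqrt(0.01*1.0)
        assert abs(np.log(s.median[3])) < np.log(1.10)        # prior median 1
        assert s.ci16[3] < s.median[3] < s.ci84[3]

    def test_two_datasets_share_emissions_and_recover_rate_ratio(self):
        m_slow = sk.KineticModel.two_state(50.0, 50.0, 0.44, 0.66, 0.05)
        m_fast = sk.KineticModel.two_state(200.0, 200.0, 0.44, 0.66, 0.05)
        tr1, _ = sk.simulate_trace_set(m_slow, 60, 600, 0.02, seed=21)
        tr2, _ = sk.simulate_trace_set(m_fast, 60, 600, 0.02, seed=22)
        res = infer_rates_global([sk.pooled_fret(tr1), sk.pooled_fret(tr2)],
                                 0.02, seed=5, max_burn=600)
        s = res.summary
        lo1, med1, hi1 = s.interval("k1_0")
        lo2, med2, hi2 = s.interval("k1_1")
        assert lo1 <= 50.0 <= hi1
        assert lo2 <= 200.0 <= hi2
        assert med2 / med1 == pytest.approx(4.0, rel=0.25)
        # shared emissions recovered once, near the truth
        assert s.interval("eps1")[1] == pytest.approx(0.44, abs=0.01)
        assert s.interval("eps2")[1] == pytest.approx(0.66, abs=0.01)

    def test_posterior_width_grows_toward_static_limit(self):
        rng = np.random.default_rng(9)
        n = 4000
        # informative regime k*tau = 2 vs nearly static regime k*tau = 0.002
        widths = {}
        for label, k in (("fast", 100.0), ("static", 0.1)):
            f = sk.simulate_occupancy_windows(k, k, 0.02, n, seed=13)
            e = f * 0.44 + (1 - f) * 0.66 + rng.normal(0, 0.05, n)
            res = infer_rates_global([e], 0.02, seed=1, max_burn=500)
            lo, _med, hi = res.summary.interval("k1_0")
            widths[label] = np.log(hi) - np.log(lo)
        assert widths["static"] > 3.0 * widths["fast"]

    def test_walker_count_validation(self):
        with pytest.raises(ValueError):
            infer_rates_global([np.array([0.5, 0.6])], 0.02, n_walkers=4)
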