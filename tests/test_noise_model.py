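"""Generative model: simulation contract and closed-form RD oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svdose import (
    KidneyRecord,
    NoiseParams,
    analytic_rd_bias,
    analytic_rd_sd,
    simulate_kidney_measurement,
    simulate_measurements,
)

from oracles import exact_rd_moments, first_order_truncation_bound


class TestNoiseParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_sv": -0.1, "sigma_wkp": 0.05},
            {"sigma_sv": 0.1, "sigma_wkp": -0.05},
            {"sigma_sv": 0.1, "sigma_wkp": 0.05, "rho_sv_wkp": 1.5},
            {"sigma_sv": 0.1, "sigma_wkp": 0.05, "rho_sv_sv": -0.2},
            {"sigma_sv": 0.1, "sigma_wkp": 0.05, "bias": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NoiseParams(**kwargs)

    def test_psd_violation_rejected(self):
        # m mutually independent SVs cannot each be fully correlated with
        # the single WKP term
        p = NoiseParams(sigma_sv=0.1, sigma_wkp=0.1, rho_sv_wkp=1.0, rho_sv_sv=0.0)
        p.validate_for(1)  # fine for a single SV
        with pytest.raises(ValueError, match="positive semi-definite"):
            p.validate_for(3)
        # restoring SV-SV correlation restores feasibility
        NoiseParams(0.1, 0.1, rho_sv_wkp=1.0, rho_sv_sv=1.0).validate_for(3)

    def test_covariance_structure(self):
        p = NoiseParams(sigma_sv=0.2, sigma_wkp=0.1, rho_sv_wkp=0.4, rho_sv_sv=0.3)
        cov = p.covariance(3)
        assert cov.shape == (4, 4)
        assert cov[0, 0] == pytest.approx(0.04)
        assert cov[0, 1] == pytest.approx(0.3 * 0.04)
        assert cov[0, 3] == pytest.approx(0.4 * 0.2 * 0.1)
        assert cov[3, 3] == pytest.approx(0.01)
        np.testing.assert_allclose(cov, cov.T)


class TestKidneyRecord:
    def test_positive_doses_enforced(self):
        with pytest.raises(ValueError):
            KidneyRecord("P1", "left", 0.0, 2.0, wkp_dose_gy=0.0, sv_doses_gy=(1.0,))
        with pytest.raises(ValueError):
            KidneyRecord("P1", "left", 0.0, 2.0, wkp_dose_gy=1.0, sv_doses_gy=(1.0, -0.1))
        with pytest.raises(ValueError):
            KidneyRecord("P1", "left", 0.0, 2.0, wkp_dose_gy=1.0, sv_doses_gy=())

    def test_side_enum(self):
        with pytest.raises(ValueError):
            KidneyRecord("P1", "up", 0.0, 2.0, wkp_dose_gy=1.0, sv_doses_gy=(1.0,))


class TestSimulate:
    def test_zero_noise_identity(self, rng):
        p = NoiseParams(sigma_sv=0.0, sigma_wkp=0.0, bias=1.12)
        m = simulate_kidney_measurement(4.0, p, m_sv=5, rng=rng)
        assert m.wkp_dose_gy == pytest.approx(4.0, abs=0)
        assert all(sv == pytest.approx(4.0 * 1.12) for sv in m.sv_doses_gy)
        assert m.n_redraws == 0

    def test_full_correlation_single_sv_rd_vanishes(self, rng):
        # equal noise, rho = 1: the SV coincides with the reference and the
        # relative difference is identically zero
        p = NoiseParams(sigma_sv=0.05, sigma_wkp=0.05, rho_sv_wkp=1.0, bias=1.0)
        sv, wkp, _ = simulate_measurements(np.full(1000, 4.0), p, 1, rng)
        np.testing.assert_allclose(sv[:, 0], wkp, rtol=1e-12)

    def test_seed_determinism(self):
        p = NoiseParams(sigma_sv=0.12, sigma_wkp=0.07, rho_sv_wkp=0.3)
        a = simulate_kidney_measurement(3.5, p, 5, np.random.default_rng(7))
        b = simulate_kidney_measurement(3.5, p, 5, np.random.default_rng(7))
        assert a == b

    def test_invalid_inputs(self, rng):
        p = NoiseParams(sigma_sv=0.1, sigma_wkp=0.05)
        with pytest.raises(ValueError):
            simulate_kidney_measurement(-1.0, p, 5, rng)
        with pytest.raises(ValueError):
            simulate_kidney_measurement(1.0, p, 0, rng)
        bad = NoiseParams(sigma_sv=0.1, sigma_wkp=0.1, rho_sv_wkp=0.9)
        with pytest.raises(ValueError):
            simulate_measurements(np.ones(10), bad, 5, rng)

    def test_rejection_cap_signals_absurd_noise(self, rng):
        huge = NoiseParams(sigma_sv=1.0, sigma_wkp=0.0)
        with pytest.raises(RuntimeError, match="rejection cap"):
            simulate_measurements(np.ones(100000), huge, 1, rng, max_redraws=10)

    def test_rejection_negligible_at_realistic_noise(self, rng):
        p = NoiseParams(sigma_sv=0.15, sigma_wkp=0.15)
        _, _, n_redraws = simulate_measurements(np.ones(200000), p, 5, rng)
        # P(any factor <= 0) ~ Phi(-1/0.15) ~ 1e-11 per component
        assert n_redraws == 0

    def test_correlation_recovery(self, rng):
        p = NoiseParams(sigma_sv=0.12, sigma_wkp=0.07, rho_sv_wkp=0.4, bias=1.0)
        true = 3.0
        sv, wkp, _ = simulate_measurements(np.full(200000, true), p, 1, rng)
        eps_sv = sv[:, 0] / true - 1.0
        eps_w = wkp / true - 1.0
        r = np.corrcoef(eps_sv, eps_w)[0, 1]
        assert r == pytest.approx(0.4, abs=0.01)
        assert eps_sv.std(ddof=1) == pytest.approx(0.12, rel=0.01)
        assert eps_w.std(ddof=1) == pytest.approx(0.07, rel=0.01)

    def test_sv_sv_correlation_recovery(self, rng):
        p = NoiseParams(sigma_sv=0.12, sigma_wkp=0.0, rho_sv_sv=0.5)
        sv, _, _ = simulate_measurements(np.full(200000, 1.0), p, 2, rng)
        r = np.corrcoef(sv[:, 0], sv[:, 1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.01)


class TestAnalyticRdSd:
    def test_clt_closed_form(self):
        p = NoiseParams(sigma_sv=0.10, sigma_wkp=0.0)
        assert analytic_rd_sd(p, 4) == pytest.approx(5.0, abs=1e-12)

    def test_perfect_cancellation(self):
        p = NoiseParams(sigma_sv=0.08, sigma_wkp=0.08, rho_sv_wkp=1.0)
        assert analytic_rd_sd(p, 1) == 0.0

    @pytest.mark.parametrize("k", [1, 3, 100])
    def test_floor_is_wkp_noise(self, k):
        p = NoiseParams(sigma_sv=0.0, sigma_wkp=0.07)
        assert analytic_rd_sd(p, k) == pytest.approx(7.0, abs=1e-12)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            analytic_rd_sd(NoiseParams(0.1, 0.0), 0)

    def test_negative_radicand_raises(self):
        # sigma_sv^2/k + sigma_wkp^2 < 2 sigma_sv sigma_wkp at rho = 1:
        # no valid joint distribution averages k such SVs
        p = NoiseParams(sigma_sv=0.2, sigma_wkp=0.1, rho_sv_wkp=1.0)
        with pytest.raises(ValueError):
            analytic_rd_sd(p, 4)

    @given(
        s=st.floats(0.01, 0.15),
        w=st.floats(0.0, 0.15),
        rho_ss=st.floats(0.0, 1.0),
        k=st.integers(1, 20),
    )
    def test_nonincreasing_in_k(self, s, w, rho_ss, k):
        p = NoiseParams(sigma_sv=s, sigma_wkp=w, rho_sv_sv=rho_ss)
        assert analytic_rd_sd(p, k + 1) <= analytic_rd_sd(p, k) + 1e-12

    def test_sqrt_k_scaling_monte_carlo(self, rng):
        # uncorrelated SVs, noise-free reference: sd(RD(k)) * sqrt(k) constant
        p = NoiseParams(sigma_sv=0.12, sigma_wkp=0.0)
        vals = []
        for k in (1, 2, 5):
            sv, wkp, _ = simulate_measurements(np.full(150000, 3.0), p, k, rng)
            rd = 100 * (sv.mean(axis=1) - wkp) / wkp
            vals.append(rd.std(ddof=1) * np.sqrt(k))
        np.testing.assert_allclose(vals, 12.0, rtol=0.02)


# grid cells (sigma_sv, sigma_wkp, rho_sv_wkp, rho_sv_sv, k), all PSD-valid
MC_GRID = [
    (0.05, 0.00, 0.0, 0.0, 1),
    (0.12, 0.00, 0.0, 0.0, 3),
    (0.12, 0.07, 0.0, 0.0, 1),
    (0.15, 0.07, 0.5, 0.0, 3),
    (0.12, 0.07, 0.3, 0.2, 5),
    (0.10, 0.10, 1.0, 1.0, 2),
]


@pytest.mark.parametrize("s,w,rho_sw,rho_ss,k", MC_GRID)
def test_monte_carlo_sd_matches_oracles(s, w, rho_sw, rho_ss, k):
    """sd(RD(k)) from simulation agrees with the exact quadrature oracle
    within 3 sampling standard errors, and the first-order formula agrees
    with the exact value within its a-priori truncation envelope."""
    n = 120_000
    p = NoiseParams(sigma_sv=s, sigma_wkp=w, rho_sv_wkp=rho_sw, rho_sv_sv=rho_ss)
    rng = np.random.default_rng(42)
    sv, wkp, _ = simulate_measurements(np.full(n, 3.76), p, k, rng)
    mc_sd = float((100 * (sv.mean(axis=1) - wkp) / wkp).std(ddof=1))
    _, exact_sd = exact_rd_moments(s, w, rho_sw, rho_ss, k)
    se = exact_sd / np.sqrt(2 * (n - 1))
    # 1e-6 percent absolute floor: a degenerate (perfectly correlated)
    # covariance reproduces RD = 0 only to eigendecomposition roundoff
    assert abs(mc_sd - exact_sd) <= 3 * se + 1e-6
    first_order = analytic_rd_sd(p, k)
    assert abs(exact_sd - first_order) <= first_order_truncation_bound(w) * first_order + 1e-6


class TestAnalyticRdBias:
    def test_noise_free_denominator(self):
        assert analytic_rd_bias(NoiseParams(0.1, 0.0)) == 0.0

    def test_second_order_value(self):
        p = NoiseParams(sigma_sv=0.10, sigma_wkp=0.07)
        assert analytic_rd_bias(p) == pytest.approx(0.49, abs=1e-12)

    def test_cancellation_at_full_correlation(self):
        p = NoiseParams(sigma_sv=0.07, sigma_wkp=0.07, rho_sv_wkp=1.0)
        assert analytic_rd_bias(p) == pytest.approx(0.0, abs=1e-15)

    def test_expansion_guard(self):
        with pytest.raises(ValueError):
            analytic_rd_bias(NoiseParams(0.1, 0.35))

    def test_against_monte_carlo(self, rng):
        # ~0.49% bias from the noisy denominator, no normalization
        p = NoiseParams(sigma_sv=0.10, sigma_wkp=0.07)
        n = 2_000_000
        sv, wkp, _ = simulate_measurements(np.full(n, 1.0), p, 1, rng)
        rd = 100 * (sv[:, 0] - wkp) / wkp
        se = rd.std(ddof=1) / np.sqrt(n)
        # second-order expansion: allow 3 SE plus the next-order term
        assert rd.mean() == pytest.approx(0.49, abs=3 * se + 0.02)
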