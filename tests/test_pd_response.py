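import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from crisprqsp.engine import _pd_deviation_rhs
from crisprqsp.pd_response import (
    LDLParameters,
    PCSK9Parameters,
    TTRParameters,
    hill_inhibition,
    ldl_rhs,
    load_pd_parameters,
    pcsk9_rhs,
    ttr_rhs,
    ttr_steady_state_fraction,
)

SAT = 1e16  # saturating multiple of IC50 (sufficient even for gamma = 0.31)


class TestHill:
    def test_zero(self):
        assert hill_inhibition(0.0, 0.9, 1.0, 0.31) == 0.0

    @pytest.mark.parametrize("gamma", [0.31, 1.0, 1.1, 3.0])
    def test_half_max_at_ic50(self, gamma):
        assert hill_inhibition(4.77, 0.961, 4.77, gamma) == pytest.approx(0.961 / 2)

    def test_saturation(self):
        assert hill_inhibition(SAT * 4.77, 0.961, 4.77, 1.0) == pytest.approx(0.961, rel=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hill_inhibition(-1.0, 0.9, 1.0, 1.0)

    @given(c1=st.floats(0, 1e6), c2=st.floats(0, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_monotone_nondecreasing(self, c1, c2):
        lo, hi = sorted([c1, c2])
        assert hill_inhibition(lo, 0.961, 4.77, 0.31) <= hill_inhibition(hi, 0.961, 4.77, 0.31) + 1e-15


class TestTTR:
    def test_baseline_stationary(self, ttr_nhp):
        assert ttr_rhs(ttr_nhp.TTR0, 0.0, ttr_nhp) == pytest.approx(0.0, abs=1e-12)

    def test_nhp_saturating_steady_state(self, ttr_nhp):
        # printed Imax 0.961 -> residual fraction 0.039
        frac = ttr_steady_state_fraction(SAT * ttr_nhp.IC50, ttr_nhp)
        assert frac == pytest.approx(1 - 0.961, rel=1e-3)

    def test_human_saturating_steady_state(self, ttr_human):
        frac = ttr_steady_state_fraction(SAT * ttr_human.IC50, ttr_human)
        assert frac == pytest.approx(1 - 0.959, rel=1e-3)

    def test_ss_fraction_examples(self, ttr_nhp):
        assert ttr_steady_state_fraction(0.0, ttr_nhp) == 1.0
        assert ttr_steady_state_fraction(ttr_nhp.IC50, ttr_nhp) == pytest.approx(1 - 0.961 / 2)
        assert ttr_steady_state_fraction(ttr_nhp.IC50, ttr_nhp) == pytest.approx(0.5195)

    def test_relaxation_is_monoexponential(self, ttr_nhp):
        # oracle: linear ODE closed form at constant sub-saturating C
        C = ttr_nhp.IC50  # half-maximal inhibition
        ss = ttr_nhp.TTR0 * ttr_steady_state_fraction(C, ttr_nhp)
        k = ttr_nhp.k_out_TTR
        sol = solve_ivp(
            lambda t, y: [ttr_rhs(y[0], C, ttr_nhp)],
            (0, 20),
            [ttr_nhp.TTR0],
            t_eval=np.linspace(0, 20, 21),
            rtol=1e-10,
            atol=1e-12,
        )
        exact = ss + (ttr_nhp.TTR0 - ss) * np.exp(-k * sol.t)
        np.testing.assert_allclose(sol.y[0], exact, rtol=1e-7)

    @given(c1=st.floats(0, 1e9), c2=st.floats(0, 1e9))
    @settings(max_examples=100, deadline=None)
    def test_ss_fraction_monotone_and_bounded(self, c1, c2):
        p = TTRParameters()
        lo, hi = sorted([c1, c2])
        f_lo, f_hi = ttr_steady_state_fraction(lo, p), ttr_steady_state_fraction(hi, p)
        assert f_hi <= f_lo + 1e-15
        assert 1 - p.Imax - 1e-15 <= f_hi <= 1.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            TTRParameters(Imax=1.5)
        with pytest.raises(ValueError):
            TTRParameters(IC50=-1.0)


class TestPCSK9:
    def test_baseline_stationary(self):
        p = load_pd_parameters("nhp", "pcsk9")
        d_tr, d_obs = pcsk9_rhs(np.full(p.n_transit, p.PCSK9_0), p.PCSK9_0, 0.0, p)
        assert np.linalg.norm(np.append(d_tr, d_obs)) < 1e-12

    def test_transit_rate(self):
        p = load_pd_parameters("nhp", "pcsk9")
        assert p.MTT == 14.5
        assert p.k_tr == pytest.approx(p.n_transit / 14.5)

    def test_chain_impulse_mean_is_mtt(self):
        # oracle: quadrature of the chain impulse response (production off)
        p = PCSK9Parameters(Imax_P=1.0, IC50_P=1.0, MTT=14.5, n_transit=3)
        C_sat = 1e30  # shuts production off exactly via Imax_P = 1

        def rhs(t, y):
            d_tr, _ = pcsk9_rhs(y, p.PCSK9_0, C_sat, p)
            return d_tr

        y0 = np.zeros(p.n_transit)
        y0[0] = 1.0
        sol = solve_ivp(rhs, (0, 60 * p.MTT), y0, dense_output=True, rtol=1e-10, atol=1e-13)
        flux = lambda t: p.k_tr * sol.sol(t)[-1]
        total, _ = quad(flux, 0, 60 * p.MTT, limit=300)
        mean, _ = quad(lambda t: t * flux(t), 0, 60 * p.MTT, limit=300)
        assert total == pytest.approx(1.0, rel=1e-6)
        assert mean / total == pytest.approx(p.MTT, rel=1e-6)

    def test_feedback_off_saturating_steady_state(self):
        # linear-chain steady state: observable -> (1 - Imax) * baseline
        p = PCSK9Parameters(Imax_P=0.771, gamma_feedback=0.0, MTT=2.0)
        C_sat = SAT * p.IC50_P

        def rhs(t, y):
            d_tr, d_obs = pcsk9_rhs(y[:-1], y[-1], C_sat, p)
            return np.append(d_tr, d_obs)

        y0 = np.full(p.n_transit + 1, p.PCSK9_0)
        sol = solve_ivp(rhs, (0, 100), y0, rtol=1e-10, atol=1e-12)
        assert sol.y[-1, -1] == pytest.approx((1 - 0.771) * p.PCSK9_0, rel=1e-4)

    def test_validation(self):
        with pytest.raises(ValueError):
            PCSK9Parameters(MTT=0.0)
        with pytest.raises(ValueError):
            PCSK9Parameters(n_transit=0)


class TestLDL:
    def test_baseline_stationary(self):
        p = load_pd_parameters("nhp", "ldl")
        assert ldl_rhs(p.LDL0, 100.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_halved_pcsk9_gamma_one(self):
        p = LDLParameters(Gamma_LDL=1.0)
        ss = p.LDL0 * 0.5  # proportionality
        assert ldl_rhs(ss, 50.0, p) == pytest.approx(0.0, abs=1e-9)

    def test_halved_pcsk9_printed_gamma(self):
        # oracle: 0.5 ** 0.672 = 0.6277
        p = load_pd_parameters("nhp", "ldl")
        ss = p.LDL0 * 0.5**0.672
        assert ss == pytest.approx(62.77, rel=1e-3)
        assert ldl_rhs(ss, 50.0, p) == pytest.approx(0.0, abs=1e-9)

    def test_zero_baseline_rejected(self):
        p = load_pd_parameters("nhp", "ldl")
        with pytest.raises(ValueError):
            ldl_rhs(100.0, 50.0, p, PCSK9_0=0.0)


class TestDeviationForm:
    """The engine's deviation-coordinate PD must match the natural-form models."""

    def test_all_models_stationary_at_baseline(self):
        ttr = load_pd_parameters("nhp", "ttr")
        p9 = load_pd_parameters("nhp", "pcsk9")
        pl = load_pd_parameters("nhp", "ldl")
        assert np.linalg.norm(_pd_deviation_rhs("ttr", ttr, np.zeros(1), 0.0)) < 1e-12
        assert np.linalg.norm(_pd_deviation_rhs("pcsk9_ldl", (p9, pl), np.zeros(p9.n_transit + 2), 0.0)) < 1e-12

    def test_ttr_deviation_matches_natural_form(self, ttr_nhp):
        C = 2.0
        sol_nat = solve_ivp(
            lambda t, y: [ttr_rhs(y[0], C, ttr_nhp)],
            (0, 30),
            [ttr_nhp.TTR0],
            rtol=1e-11,
            atol=1e-13,
        )
        sol_dev = solve_ivp(
            lambda t, y: _pd_deviation_rhs("ttr", ttr_nhp, y, C),
            (0, 30),
            [0.0],
            rtol=1e-11,
            atol=1e-13,
        )
        assert ttr_nhp.TTR0 - sol_dev.y[0, -1] == pytest.approx(sol_nat.y[0, -1], rel=1e-8)

    def test_pcsk9_ldl_deviation_matches_natural_form(self):
        p9 = load_pd_parameters("nhp", "pcsk9")
        pl = load_pd_parameters("nhp", "ldl")
        C = 30.0
        n = p9.n_transit

        def nat(t, y):
            d_tr, d_obs = pcsk9_rhs(y[:n], y[n], C, p9)
            d_ldl = ldl_rhs(y[n + 1], y[n], pl, p9.PCSK9_0)
            return np.concatenate([d_tr, [d_obs, d_ldl]])

        y0 = np.concatenate([np.full(n, p9.PCSK9_0), [p9.PCSK9_0, pl.LDL0]])
        sol_nat = solve_ivp(nat, (0, 60), y0, rtol=1e-11, atol=1e-13)
        sol_dev = solve_ivp(
            lambda t, y: _pd_deviation_rhs("pcsk9_ldl", (p9, pl), y, C),
            (0, 60),
            np.zeros(n + 2),
            rtol=1e-11,
            atol=1e-13,
        )
        nat_final = sol_nat.y[:, -1]
        dev_final = sol_dev.y[:, -1]
        assert p9.PCSK9_0 - dev_final[n] == pytest.approx(nat_final[n], rel=1e-7)
        assert pl.LDL0 - dev_final[n + 1] == pytest.approx(nat_final[n + 1], rel=1e-7)
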