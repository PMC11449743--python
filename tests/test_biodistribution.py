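import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from crisprqsp.biodistribution import (
    IDX,
    N_PK_STATES,
    ModelOptions,
    ModelTopology,
    PKParameters,
    build_model,
    intracellular_rhs,
    load_parameters,
    mps_flux,
    opsonin_flux,
    receptor_flux,
    transfer_flux,
)
from crisprqsp.dosing import build_regimen
from crisprqsp.engine import simulate
from crisprqsp.physiology import load_physiology

from conftest import closed_params


class TestParameters:
    def test_k_syn_recomputed_nhp(self, params_nhp):
        # product of the bundled receptor concentration and elimination rate
        assert params_nhp.k_syn == pytest.approx(539.0 * 0.231)
        assert params_nhp.k_syn == pytest.approx(124.509)

    def test_kd_mass_conversion(self, params_nhp):
        # 0.49 nM x 160 kDa = 0.0784 ug/mL
        assert params_nhp.KD_mass == pytest.approx(0.0784, rel=1e-10)

    def test_k_on_rnp_derived(self, params_nhp):
        assert params_nhp.k_on_RNP == pytest.approx(0.00188 / 0.0784, rel=1e-10)

    def test_negative_rate_rejected(self, params_nhp):
        with pytest.raises(ValueError):
            params_nhp.replace(k_ass=-1.0)

    def test_fu_range(self, params_nhp):
        with pytest.raises(ValueError):
            params_nhp.replace(fu_LNP=0.0)

    def test_k_deg_cas_defaults_to_mrna(self, params_nhp):
        assert params_nhp.k_deg_Cas_eff == params_nhp.k_deg_mRNA
        assert params_nhp.replace(k_deg_Cas=0.5).k_deg_Cas_eff == 0.5

    def test_unknown_species_file(self):
        with pytest.raises(ValueError):
            load_parameters("rat")

    def test_status_annotations(self):
        _, status = load_parameters("nhp", with_status=True)
        assert status["k_in_endo"] == "estimated"
        assert status["k_int"] == "fixed"


class TestTopology:
    def test_kidney_for_mrna_rejected(self):
        with pytest.raises(ValueError, match="mRNA has no kidney"):
            ModelTopology(kidney_analytes=("LNP", "sgRNA", "mRNA"))

    def test_default_kidney_analytes(self):
        topo = ModelTopology()
        assert set(topo.kidney_analytes) == {"LNP", "sgRNA"}

    def test_state_vector_has_no_mrna_kidney_entry(self):
        assert "kid_mRNA" not in IDX
        assert "kid_LNP" in IDX and "kid_sgRNA" in IDX

    def test_state_dimension(self, phys_nhp, params_nhp):
        model = build_model(phys_nhp, params_nhp)
        assert model.n_states == N_PK_STATES == 23


class TestOpsoninFlux:
    def test_no_association(self):
        d_free, d_bound = opsonin_flux(2.0, 3.0, 0.0, 0.5)
        assert d_bound == pytest.approx(-1.5)
        assert d_free == pytest.approx(1.5)

    def test_zero_state(self):
        assert opsonin_flux(0.0, 0.0, 5.0, 8.0) == (0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            opsonin_flux(-1.0, 0.0, 1.0, 1.0)

    def test_equilibrium_ratio_nhp(self):
        # oracle: analytic equilibrium of the isolated linear two-state system
        k_ass, k_dis = 5.06, 8.64

        def rhs(t, y):
            d_free, d_bound = opsonin_flux(y[0], y[1], k_ass, k_dis)
            return [d_free, d_bound]

        sol = solve_ivp(rhs, (0, 50), [1.0, 0.0], rtol=1e-10, atol=1e-12)
        bound, free = sol.y[1, -1], sol.y[0, -1]
        assert bound / free == pytest.approx(k_ass / k_dis, rel=1e-6)
        assert bound / free == pytest.approx(0.5856481, rel=1e-5)

    def test_matches_matrix_exponential_closed_form(self):
        # oracle: expm of the 2x2 rate matrix on a 0-30 h grid
        k_ass, k_dis = 5.06, 8.64
        A = np.array([[-k_ass, k_dis], [k_ass, -k_dis]])
        y0 = np.array([1.0, 0.0])

        def rhs(t, y):
            d_free, d_bound = opsonin_flux(y[0], y[1], k_ass, k_dis)
            return [d_free, d_bound]

        t_grid = np.linspace(0, 30, 31)
        sol = solve_ivp(rhs, (0, 30), y0, t_eval=t_grid, rtol=1e-10, atol=1e-14)
        for i, t in enumerate(t_grid):
            exact = expm(A * t) @ y0
            assert sol.y[:, i] == pytest.approx(exact, rel=1e-6, abs=1e-12)


class TestMPSFlux:
    def test_no_internalization(self):
        uptake, deg = mps_flux(5.0, 1.0, 0.0, 1.6486)
        assert uptake == 0.0

    def test_half_life_of_closed_pool(self):
        # oracle: first-order half-life ln2 / 1.6486 = 0.4204 h
        k_deg = 1.6486

        def rhs(t, y):
            _, deg = mps_flux(0.0, y[0], 0.0, k_deg)
            return [-deg]

        t_half = np.log(2) / k_deg
        sol = solve_ivp(rhs, (0, t_half), [1.0], rtol=1e-10, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(0.5, rel=1e-7)
        assert t_half == pytest.approx(0.42043, rel=1e-4)

    def test_uptake_is_internal_transfer(self):
        uptake, deg = mps_flux(3.0, 2.0, 0.9063, 0.0)
        # total LNP change from the pair = -deg only
        assert (-uptake) + (uptake - deg) == pytest.approx(0.0)


class TestReceptorFlux:
    def test_baseline_steady_state(self, params_nhp):
        _, _, turnover = receptor_flux(0.0, params_nhp.LDL_tot, 0.0, params_nhp)
        assert turnover == pytest.approx(0.0, abs=1e-9)

    def test_binding_equilibrium_constant(self, params_nhp):
        # oracle: detailed balance of the isolated binding pair
        p = params_nhp.replace(k_deg_DR=0.0, k_el=0.0, LDL_tot=1.0)

        def rhs(t, y):
            C, R, cplx = y
            b, u, _ = receptor_flux(C, R, cplx, p)
            return [-b + u, -b + u, b - u]

        sol = solve_ivp(rhs, (0, 2000), [1.0, 1.0, 0.0], rtol=1e-11, atol=1e-14)
        C, R, cplx = sol.y[:, -1]
        keq = cplx / (C * R)
        assert keq == pytest.approx(p.k_on_LNP * p.fu_LNP / p.k_off_LNP, rel=1e-6)

    def test_nhp_k_syn_value(self, params_nhp):
        _, _, turnover = receptor_flux(0.0, 0.0, 0.0, params_nhp)
        assert turnover == pytest.approx(124.509)


class TestTransferFlux:
    def test_no_endocytosis_no_lymph(self):
        inward, _ = transfer_flux(1.0, 1.0, 2.0, 3.0, 0.0, 1.0, 0.0, 0.5)
        assert inward == 0.0

    def test_full_reflection_kills_convection(self):
        inward_reflected, _ = transfer_flux(1.0, 0.0, 2.0, 3.0, 0.0, 0.0, 10.0, 1.0)
        assert inward_reflected == 0.0

    def test_nonpositive_volume(self):
        with pytest.raises(ValueError):
            transfer_flux(1.0, 1.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.0)

    def test_isolated_equilibrium_ratio(self):
        # oracle: C_lower/C_upper = (k_in*V_up)/(k_out*V_low) at L=0
        k_in, k_out, V_up, V_low = 0.5, 2.0, 3.0, 7.0

        def rhs(t, y):
            a_up, a_low = y
            inward, outward = transfer_flux(a_up / V_up, a_low / V_low, V_up, V_low, k_in, k_out, 0.0, 0.0)
            return [-inward + outward, inward - outward]

        sol = solve_ivp(rhs, (0, 200), [1.0, 0.0], rtol=1e-11, atol=1e-14)
        c_up = sol.y[0, -1] / V_up
        c_low = sol.y[1, -1] / V_low
        assert c_low / c_up == pytest.approx(k_in * V_up / (k_out * V_low), rel=1e-6)


class TestIntracellular:
    def test_no_translation_no_cas_no_rnp(self, params_nhp):
        p = params_nhp.replace(k_trans=0.0)

        def rhs(t, y):
            return intracellular_rhs(y, p, 100.0)

        sol = solve_ivp(rhs, (0, 50), [5.0, 5.0, 0.0, 0.0], rtol=1e-9, atol=1e-12)
        assert np.all(np.abs(sol.y[3]) < 1e-12)

    def test_mrna_half_life(self, params_nhp):
        # oracle: ln2 / 0.1232 = 5.626 h first-order half-life
        t_half = np.log(2) / params_nhp.k_deg_mRNA
        assert t_half == pytest.approx(5.6262, rel=1e-4)

        def rhs(t, y):
            return intracellular_rhs(np.array([0.0, y[0], 0.0, 0.0]), params_nhp, 1.0)[1:2]

        sol = solve_ivp(rhs, (0, t_half), [1.0], rtol=1e-10, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(0.5, rel=1e-7)

    def test_rnp_monoexponential_dissociation(self, params_nhp):
        # with everything else zero the RNP pool decays at k_off_RNP = 0.00188 1/h
        p = params_nhp.replace(k_trans=0.0, k_deg_sgRNA=0.0, k_deg_mRNA=0.0, k_deg_Cas=0.0)

        def rhs(t, y):
            d = intracellular_rhs(np.array([0.0, 0.0, 0.0, y[0]]), p, 1.0)
            return [d[3]]

        T = 500.0
        sol = solve_ivp(rhs, (0, T), [1.0], rtol=1e-10, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(np.exp(-0.00188 * T), rel=1e-6)


class TestAssembledRHS:
    def test_fast_path_matches_reference(self, phys, params, rng):
        model = build_model(phys, params)
        regimen = build_regimen(2.0, phys, route="infusion")
        for _ in range(10):
            y = rng.uniform(0.0, 50.0, N_PK_STATES)
            np.testing.assert_allclose(
                model.rhs(1.0, y, regimen),
                model.rhs_reference(1.0, y, regimen),
                rtol=1e-12,
                atol=1e-12,
            )

    def test_zero_state_zero_derivative(self, phys_nhp, params_nhp):
        model = build_model(phys_nhp, params_nhp.replace(k_el=0.0, LDL_tot=0.0))
        d = model.rhs(0.0, np.zeros(N_PK_STATES))
        np.testing.assert_allclose(d, 0.0, atol=1e-14)

    def test_dimension_mismatch(self, phys_nhp, params_nhp):
        model = build_model(phys_nhp, params_nhp)
        with pytest.raises(ValueError, match="state dimension"):
            model.rhs(0.0, np.zeros(5))

    def test_nan_state_rejected(self, phys_nhp, params_nhp):
        model = build_model(phys_nhp, params_nhp)
        y = np.zeros(N_PK_STATES)
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            model.rhs(0.0, y)

    def test_receptor_baseline_without_dose(self, phys_nhp, params_nhp):
        model = build_model(phys_nhp, params_nhp)
        regimen = build_regimen(0.0, phys_nhp)
        traj = simulate(model, regimen, np.linspace(0, 48, 25), rtol=1e-8, atol=1e-10)
        R = traj.states[:, IDX["R_free"]]
        np.testing.assert_allclose(R, params_nhp.LDL_tot, rtol=1e-9)

    def test_mass_balance_closed_system(self, phys_nhp, params_nhp):
        p = closed_params(params_nhp)
        model = build_model(
            phys_nhp, p, options=ModelOptions(renal_clearance_on=False)
        )
        regimen = build_regimen(2.0, phys_nhp, route="bolus")
        y0 = model.initial_state(regimen)
        y0[IDX["lc_Cas9"]] = 100.0  # seed a Cas9 pool for the Cas9+RNP moiety

        sol = solve_ivp(
            lambda t, y: model.rhs(t, y, regimen),
            (0, 30),
            y0,
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
        )
        assert sol.success
        lnp_pools = [IDX[n] for n in ("pl_LNP_free", "pl_LNP_ops", "lv_LNP_free", "lv_LNP_ops", "mps_LNP", "li_LNP_free", "li_LNP_complex", "kid_LNP", "rem_LNP")]
        sg_pools = [IDX[n] for n in ("pl_sgRNA", "lv_sgRNA", "li_sgRNA", "lc_sgRNA", "kid_sgRNA", "rem_sgRNA")]
        m_pools = [IDX[n] for n in ("pl_mRNA", "lv_mRNA", "li_mRNA", "lc_mRNA", "rem_mRNA")]
        cas_pools = [IDX[n] for n in ("lc_Cas9", "lc_RNP")]
        for t in np.linspace(0, 30, 7):
            y = sol.sol(t)
            assert y[lnp_pools].sum() == pytest.approx(regimen.amount_LNP, rel=1e-6)
            assert y[sg_pools].sum() == pytest.approx(regimen.amount_sgRNA, rel=1e-6)
            assert y[m_pools].sum() == pytest.approx(regimen.amount_mRNA, rel=1e-6)
            assert y[cas_pools].sum() == pytest.approx(100.0, rel=1e-6)

    def test_nonnegativity_along_trajectory(self, phys_nhp, params_nhp):
        model = build_model(phys_nhp, params_nhp)
        regimen = build_regimen(3.0, phys_nhp, route="infusion")
        traj = simulate(model, regimen, np.linspace(0, 30, 61), rtol=1e-8, atol=1e-10)
        assert traj.states.min() >= -1e-10

    def test_plasma_lnp_decay_closed_form(self):
        # oracle: mono-exponential at the printed human k_deg_LNP = 0.101 1/h
        # when transport is switched off (vanishing flows)
        phys = load_physiology("human").replace(
            Q_liver=1e-12, Q_kidney=1e-12, Q_remainder=1e-12
        )
        params = closed_params(load_parameters("human"), k_deg_LNP=0.101).replace(
            k_ass=0.0, k_dis=0.0, k_int=0.0
        )
        model = build_model(phys, params, options=ModelOptions(renal_clearance_on=False))
        regimen = build_regimen(1.0, phys, route="bolus")
        t_grid = np.linspace(0, 30, 31)
        traj = simulate(model, regimen, t_grid, rtol=1e-10, atol=1e-12)
        C = traj.observables["plasma_LNP"]
        expected = C[0] * np.exp(-0.101 * t_grid)
        np.testing.assert_allclose(C, expected, rtol=1e-6)
        assert np.log(2) / 0.101 == pytest.approx(6.8627, rel=1e-4)

    def test_cell_exocytosis_option(self, phys_nhp, params_nhp):
        model_on = build_model(phys_nhp, params_nhp, options=ModelOptions(cell_exocytosis=True))
        model_off = build_model(phys_nhp, params_nhp)
        regimen = build_regimen(2.0, phys_nhp, route="infusion")
        y = np.ones(N_PK_STATES)
        d_on = model_on.rhs(3.0, y, regimen)
        d_off = model_off.rhs(3.0, y, regimen)
        # exocytosis out of the cell appears only when enabled
        assert d_on[IDX["lc_sgRNA"]] < d_off[IDX["lc_sgRNA"]]
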