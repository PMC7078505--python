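"""ODE core: mass balance, closed-form oracles, AUC and delivery metrics."""

import numpy as np
import pytest
from scipy.linalg import expm

from nanopbpk import (
    NanoparticleSpec,
    SimulationConfig,
    aggregate_outputs,
    auc,
    delivery_efficiency,
    simulate,
)
from nanopbpk.core import build_state_index, build_system_matrix, rhs
from nanopbpk.physiology import assemble_parameterization, default_body, default_tumor


class TestSystemMatrix:
    def test_zero_state_is_equilibrium(self, np_100nm):
        params = assemble_parameterization(np_100nm, tumor=default_tumor())
        idx, _ = build_system_matrix(params)
        assert np.all(rhs(np.zeros(idx.n), params) == 0.0)

    def test_mass_conserving_by_construction(self, np_100nm, rng):
        """Column sums of the generator vanish: sum of derivatives is zero
        for arbitrary states (absorbing pools included)."""
        params = assemble_parameterization(np_100nm, tumor=default_tumor())
        idx, M = build_system_matrix(params)
        assert np.abs(M.sum(axis=0)).max() < 1e-9
        # the fastest rate is ~4e5 h^-1, so float rounding in the sum sits
        # near eps * rate * state ~ 1e-9; assert well under any physical flux
        for _ in range(5):
            state = rng.uniform(0, 10, idx.n)
            assert abs(rhs(state, params).sum()) < 1e-7

    def test_rhs_matches_hand_written_organ_balance(self, np_100nm, rng):
        """The heart rows reproduce the hand-coded vascular/extravascular
        balances (perfusion in, venous out, hindered lymph flux, wall
        binding)."""
        params = assemble_parameterization(np_100nm, tumor=default_tumor())
        idx, M = build_system_matrix(params)
        state = rng.uniform(0, 5, idx.n)
        d = M @ state
        e = params.organs["heart"]
        lungs = params.organs["lungs"]
        c_art = state[idx["lungs:vascular_free"]] / lungs.v_v_ml
        c_vf = state[idx["heart:vascular_free"]] / e.v_v_ml
        c_e = state[idx["heart:extravascular"]] / e.v_e_ml
        a_vf = state[idx["heart:vascular_free"]]
        a_vb = state[idx["heart:vascular_bound"]]
        k_on = e.rates.k_on_per_s * 3600
        k_off = e.rates.k_off_per_s * 3600
        expected_vf = (
            e.q_ml_h * c_art
            - (e.q_ml_h - e.l_ml_h) * c_vf
            - e.l_ml_h * (1 - e.rates.sigma) * c_vf
            - k_on * a_vf + k_off * a_vb
        )
        expected_vb = k_on * a_vf - k_off * a_vb  # no phagocytes outside MPS
        expected_e = e.l_ml_h * (1 - e.rates.sigma) * c_vf - e.l_ml_h * c_e
        assert d[idx["heart:vascular_free"]] == pytest.approx(expected_vf, rel=1e-10)
        assert d[idx["heart:vascular_bound"]] == pytest.approx(expected_vb, rel=1e-10)
        assert d[idx["heart:extravascular"]] == pytest.approx(expected_e, rel=1e-10)

    def test_rhs_matches_hand_written_tumor_balance(self, np_100nm, rng):
        """Tumor rows: perfusion exchange with plasma, diffusive PS efflux,
        wall binding, interstitial degradation."""
        params = assemble_parameterization(np_100nm, tumor=default_tumor())
        idx, M = build_system_matrix(params)
        state = rng.uniform(0, 5, idx.n)
        d = M @ state
        t = params.tumor
        c_p = state[idx["plasma"]] / params.plasma_volume_ml
        c_tf = state[idx["tumor:vascular_free"]] / t.v_v_ml
        a_tf = state[idx["tumor:vascular_free"]]
        a_tb = state[idx["tumor:vascular_bound"]]
        n_et = state[idx["tumor:interstitium"]]
        k_on = t.rates.k_on_per_s * 3600
        k_off = t.rates.k_off_per_s * 3600
        expected_tf = (t.q_ml_h * (c_p - c_tf) - t.ps_ml_h * c_tf
                       - k_on * a_tf + k_off * a_tb)
        expected_int = t.ps_ml_h * c_tf - params.nanoparticle.k_deg_per_h * n_et
        assert d[idx["tumor:vascular_free"]] == pytest.approx(expected_tf, rel=1e-10)
        assert d[idx["tumor:vascular_bound"]] == pytest.approx(
            k_on * a_tf - k_off * a_tb, rel=1e-10)
        assert d[idx["tumor:interstitium"]] == pytest.approx(expected_int, rel=1e-10)

    def test_state_index_layout(self):
        idx = build_state_index(has_tumor=True)
        assert idx["plasma"] == 0
        assert "liver:phagocytic" in idx.index
        assert "kidneys:phagocytic" not in idx.index
        assert idx.n == 37


class TestSimulate:
    def test_initial_condition_and_conservation(self, reference_tumor_sim):
        res = reference_tumor_sim
        assert res.time_h[0] == 0.0
        assert res.trajectory("plasma")[0] == pytest.approx(100.0)
        assert res.amounts[0].sum() == pytest.approx(100.0)
        assert res.max_conservation_error <= 1e-6

    def test_conservation_for_random_parameter_draws(self, rng):
        """Total %ID stays at dose for random draws within the reference
        perturbation ranges."""
        for _ in range(20):
            np_spec = NanoparticleSpec(
                radius_nm=rng.uniform(0.5, 99.5),
                density_g_cm3=rng.uniform(1.0, 3.98),
                k_deg_per_h=rng.uniform(1e-4, 0.0199),
            )
            tumor = default_tumor({
                "viscosity_cP": rng.uniform(0.1, 14.7),
                "vascular_fraction": rng.uniform(0.001, 0.199),
                "porosity": rng.uniform(1e-5, 1.99e-3),
            })
            body = default_body({"body": {"hematocrit": rng.uniform(0.0045, 0.89)}})
            res = simulate(np_spec, body=body, tumor=tumor,
                           config=SimulationConfig(t_end_h=100.0))
            assert res.max_conservation_error <= 1e-6

    def test_dose_linearity(self, np_100nm, reference_tumor_sim):
        double = simulate(np_100nm, tumor=default_tumor(),
                          config=SimulationConfig(dose_percent_id=200.0))
        ref = reference_tumor_sim.amounts
        np.testing.assert_allclose(double.amounts, 2 * ref, rtol=1e-6,
                                   atol=1e-9)

    def test_matrix_exponential_oracle(self, np_100nm):
        """BDF trajectories agree with the exact matrix-exponential
        propagation of the same linear system."""
        params = assemble_parameterization(np_100nm, tumor=default_tumor())
        idx, M = build_system_matrix(params)
        grid = np.array([0.0, 0.01, 0.1, 1.0, 10.0, 100.0])
        res = simulate(np_100nm, tumor=default_tumor(),
                       config=SimulationConfig(time_grid_h=grid, t_end_h=100.0,
                                               rtol=1e-10, atol=1e-12))
        y0 = np.zeros(idx.n)
        y0[idx["plasma"]] = 100.0
        exact = np.stack([expm(M * t) @ y0 for t in grid])
        np.testing.assert_allclose(res.amounts, exact, rtol=1e-6, atol=1e-7)

    def test_two_compartment_closed_form(self):
        """A pure plasma-organ perfusion exchange relaxes to equal
        concentration at the closed-form exponential rate Q(1/V1 + 1/V2)."""
        q, v1, v2 = 50.0, 10.0, 2.0
        M = np.array([[-q / v1, q / v2], [q / v1, -q / v2]])
        lam = q * (1 / v1 + 1 / v2)
        t = np.linspace(0, 1.0, 50)
        a0 = 100.0
        # closed form for amounts: equilibrium split + decaying mode
        eq1 = a0 * v1 / (v1 + v2)
        a1_exact = eq1 + (a0 - eq1) * np.exp(-lam * t)
        from scipy.integrate import solve_ivp
        sol = solve_ivp(lambda _, y: M @ y, (0, 1.0), [a0, 0.0], method="BDF",
                        t_eval=t, jac=lambda *_: M, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(sol.y[0], a1_exact, rtol=1e-6)

    def test_closed_system_limit_retains_mass_in_circulation(self):
        """No degradation, a fully reflective kidney (large NP) and zero bile
        flow close the system: excreta stay empty, circulating plus tissue
        mass stays at the full dose."""
        np_spec = NanoparticleSpec.from_diameter(100.0, k_deg_per_h=0.0)
        body = default_body({"body": {"bile_flow_ml_h": 1e-12}})
        res = simulate(np_spec, body=body, config=SimulationConfig(t_end_h=10.0))
        assert res.trajectory("urine")[-1] <= 1e-9
        assert res.trajectory("degraded")[-1] <= 1e-9
        assert res.trajectory("feces")[-1] <= 1e-6
        assert res.amounts[-1].sum() == pytest.approx(100.0, abs=1e-6)

    def test_nonnegative_trajectories(self, reference_tumor_sim):
        assert reference_tumor_sim.amounts.min() >= -1e-8


class TestAUC:
    def test_rectangle(self):
        t = np.linspace(0, 10, 11)
        assert auc(t, np.full(11, 100.0), 10.0) == pytest.approx(1000.0)

    def test_exponential_against_analytic_integral(self):
        from nanopbpk.core import default_time_grid
        t = default_time_grid(1000.0)
        y = 100 * np.exp(-t)
        exact = 100 * (1 - np.exp(-1000.0))
        assert auc(t, y, 1000.0) == pytest.approx(exact, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.0]), np.array([1.0]))

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.0, 2.0, 1.0]), np.zeros(3))


class TestDeliveryMetrics:
    def test_requires_tumor(self, np_100nm):
        res = simulate(np_100nm, config=SimulationConfig(t_end_h=10.0))
        with pytest.raises(ValueError):
            delivery_efficiency(res)

    def test_no_extravasation_no_delivery(self, np_100nm):
        tumor = default_tumor({"porosity": 0.0})
        res = simulate(np_100nm, tumor=tumor)
        assert delivery_efficiency(res) == pytest.approx(0.0, abs=1e-9)

    def test_efficiency_below_peak(self, reference_tumor_sim):
        eff = delivery_efficiency(reference_tumor_sim)
        assert eff <= reference_tumor_sim.trajectory("tumor:interstitium").max()


class TestAggregates:
    def test_all_nonnegative_and_mps_composition(self, reference_tumor_sim):
        ag = aggregate_outputs(reference_tumor_sim)
        assert min(ag.auc_plasma, ag.auc_mps, ag.auc_tumor, ag.auc_excreta) >= 0
        liver = aggregate_outputs(reference_tumor_sim).per_compartment["liver"]
        spleen = ag.per_compartment["spleen"]
        assert ag.auc_mps == pytest.approx(liver + spleen, rel=1e-12)

    def test_tumor_negligible_for_systemic_balance(self, np_100nm,
                                                   reference_tumor_sim):
        """The tumor is <0.3% of body mass: removing it shifts the other
        aggregates by less than 1%."""
        free = aggregate_outputs(simulate(np_100nm))
        ag = aggregate_outputs(reference_tumor_sim)
        assert free.auc_tumor == 0.0
        assert free.auc_plasma == pytest.approx(ag.auc_plasma, rel=0.01)
        assert free.auc_mps == pytest.approx(ag.auc_mps, rel=0.01)
        assert free.auc_excreta == pytest.approx(ag.auc_excreta, rel=0.01)

    def test_degradation_rate_drives_excretion(self, np_100nm):
        """Faster degradation raises excreta and lowers MPS residence."""
        cfg = SimulationConfig(t_end_h=300.0)
        aucs = []
        for k_deg in (0.005, 0.02, 0.08):
            np_spec = NanoparticleSpec(50.0, 2.0, k_deg)
            aucs.append(aggregate_outputs(
                simulate(np_spec, tumor=default_tumor(), config=cfg),
                t_max_h=300.0))
        assert aucs[0].auc_excreta < aucs[1].auc_excreta < aucs[2].auc_excreta
        assert aucs[0].auc_mps > aucs[1].auc_mps > aucs[2].auc_mps
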