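"""Thermal network: exchange operators, losses, routing and stepping."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemotherm import load_standard_person
from hemotherm.errors import ValidationError
from hemotherm.tnw import (
    EnvironmentSpec,
    FlowRouting,
    ThermalNetwork,
    counterflow_coeff,
    counterflow_exchange,
    piston_coeff,
    piston_vessel_gain,
    respiration_and_skin_losses,
    respiration_losses,
    saturation_vapour_pressure,
)
from hemotherm.units import ML_MIN_TO_M3_S

RHO_C = 1050.0 * 3850.0


def target_flow_routing(params, sv_fraction=0.0) -> FlowRouting:
    """Compartment flows taken directly from the packaged target table."""
    comp: dict[tuple[str, str], float] = {}
    tgt = params.flow_targets.set_index("group")["target_ml_min"]
    for circ in params.peripherals.values():
        for route, spec in circ.routes.items():
            q = spec.weight * tgt[spec.group] * ML_MIN_TO_M3_S
            key = (circ.tnw_segment, spec.tnw_node)
            comp[key] = comp.get(key, 0.0) + q
    sv = {s: sv_fraction for s in
          {c.tnw_segment for c in params.peripherals.values()}}
    return FlowRouting(comp_inflow=comp, sv_fraction=sv)


@pytest.fixture(scope="module")
def env(params):
    return EnvironmentSpec.from_defaults(params.env_defaults)


@pytest.fixture(scope="module")
def network(params, env):
    return ThermalNetwork(params, env, target_flow_routing(params))


class TestPistonExchange:
    def test_zero_conductance_no_exchange(self):
        assert piston_vessel_gain(1e-6, 0.0, 38.0, 35.0, RHO_C) == 0.0

    def test_infinite_conductance_perfect_equilibration(self):
        q, dT = 1e-6, 3.0
        gain = piston_vessel_gain(q, 1e9, 37.0, 34.0, RHO_C)
        assert gain == pytest.approx(RHO_C * q * dT, rel=1e-6)

    def test_zero_flow_is_zero_by_continuity(self):
        assert piston_vessel_gain(0.0, 2.0, 37.0, 30.0, RHO_C) == 0.0

    def test_finite_case_against_plug_flow_oracle(self):
        """Exponential equilibration formula vs a 1e4-slice discretisation
        of plug flow along a tube exchanging with a constant wall."""
        rho_c, q, tc, t_wall, t_in = 3.9e6, 1e-6, 2.0, 37.0, 34.0
        n = 10_000
        t = t_in
        gain = 0.0
        for _ in range(n):
            dq = (tc / n) * (t_wall - t)
            gain += dq
            t += dq / (rho_c * q)
        expected = piston_vessel_gain(q, tc, t_wall, t_in, rho_c)
        assert expected == pytest.approx(gain, rel=1e-4)

    @settings(max_examples=50, deadline=None)
    @given(q=st.floats(min_value=1e-9, max_value=1e-3),
           tc=st.floats(min_value=0.0, max_value=100.0))
    def test_coefficient_bounded_by_advective_capacity(self, q, tc):
        k = piston_coeff(q, tc, RHO_C)
        assert 0.0 <= k <= RHO_C * q * (1.0 + 1e-12)


class TestCounterflow:
    def test_zero_conductance(self):
        assert counterflow_exchange(1e-6, 8e-7, 0.0, 34.0, 37.0, RHO_C) == 0.0

    def test_zero_driving_temperature_difference(self):
        assert counterflow_exchange(2e-6, 1e-6, 1.5, 36.0, 36.0, RHO_C) == 0.0

    @pytest.mark.parametrize("eps", [1e-8, -1e-8])
    def test_balanced_flow_limit(self, eps):
        """General formula at Q_ve/Q_ar = 1 +- 1e-8 agrees with the
        balanced-flow (L'Hopital) limit to 1e-6 relative."""
        q_ar = 1e-6
        q_ve = q_ar * (1.0 + eps)
        tc = 0.8
        ntu = tc / (RHO_C * q_ve)
        balanced = RHO_C * q_ve * ntu / (1.0 + ntu)
        # evaluate the general formula directly (bypassing the switch)
        ratio = q_ve / q_ar
        z = np.exp(-ntu * (1.0 - ratio))
        general = RHO_C * q_ve * (1.0 - z) / (1.0 - ratio * z)
        assert general == pytest.approx(balanced, rel=1e-6)
        assert counterflow_coeff(q_ar, q_ve, tc, RHO_C) == pytest.approx(balanced, rel=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(q_ar=st.floats(min_value=1e-8, max_value=1e-4),
           ratio=st.floats(min_value=0.05, max_value=20.0),
           tc=st.floats(min_value=0.0, max_value=50.0))
    def test_second_law_bound(self, q_ar, ratio, tc):
        """Exchange never exceeds rho c min(Q_ar, Q_ve) |dT|."""
        q_ve = q_ar * ratio
        k = counterflow_coeff(q_ar, q_ve, tc, RHO_C)
        assert 0.0 <= k <= RHO_C * min(q_ar, q_ve) * (1.0 + 1e-9)

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(ValidationError):
            counterflow_coeff(0.0, 1e-6, 1.0, RHO_C)


class TestLosses:
    def test_neutral_air_nearly_zero_respiration(self, env):
        neutral = EnvironmentSpec.from_defaults(
            {"ambient": {"air_temperature_C": 34.0, "relative_humidity_pct": 100.0},
             "surface_coefficients_W_m2K": env.surface_coefficients,
             "respiration": env.respiration,
             "skin_evaporation": env.skin_evaporation})
        c_res, e_res = respiration_losses(neutral, 84.0)
        assert c_res == 0.0
        assert e_res < 0.02 * 84.0

    def test_losses_linear_in_metabolism(self, env):
        c1, e1 = respiration_losses(env, 84.0)
        c2, e2 = respiration_losses(env, 168.0)
        assert c2 == pytest.approx(2 * c1) and e2 == pytest.approx(2 * e1)

    def test_baseline_respiration_hand_values(self, env):
        """28 degC / 40 % RH, basal metabolism: independent arithmetic of
        the documented formulas."""
        M = 83.738
        p_sat_28 = 0.6105 * np.exp(17.27 * 28.0 / (28.0 + 237.3))
        c_expected = 0.0014 * M * (34.0 - 28.0)
        e_expected = 0.0173 * M * (5.87 - 0.40 * p_sat_28)
        assert saturation_vapour_pressure(28.0) == pytest.approx(p_sat_28, rel=1e-12)
        c_res, e_res = respiration_losses(env, M)
        assert c_res == pytest.approx(c_expected, rel=1e-9)
        assert e_res == pytest.approx(e_expected, rel=1e-9)

    def test_skin_loss_clamped_nonnegative(self, env, network):
        hot = EnvironmentSpec.from_defaults(
            {"ambient": {"air_temperature_C": 45.0, "relative_humidity_pct": 100.0},
             "surface_coefficients_W_m2K": env.surface_coefficients,
             "respiration": env.respiration,
             "skin_evaporation": env.skin_evaporation})
        c_res, e_res, e_sk = respiration_and_skin_losses(
            {"chest": 33.0}, {"chest": network.skin_areas["chest"]}, hot, 84.0)
        assert c_res == 0.0 and e_res == 0.0
        assert e_sk["chest"] == 0.0


class TestFlowRouting:
    def test_negative_inflow_clamped(self):
        fl = FlowRouting(comp_inflow={("neck", "core"): -1e-6, ("neck", "muscle"): 1e-6})
        assert fl.comp_inflow[("neck", "core")] == 0.0

    def test_conservation_and_through_flows(self, params):
        fl = target_flow_routing(params)
        fl.check_conservation()
        # abdomen artery carries the abdominal and both leg subtrees
        legs = sum(fl._seg_comp_total(s) for s in
                   ("thigh_r", "leg_r", "foot_r", "thigh_l", "leg_l", "foot_l"))
        assert fl.artery_flow["abdomen"] == pytest.approx(
            fl._seg_comp_total("abdomen") + legs, rel=1e-12)
        assert fl.vein_flow["neck"] == pytest.approx(
            fl._seg_comp_total("neck") + fl._seg_comp_total("head"), rel=1e-12)

    def test_superficial_vein_split(self, params):
        fl = target_flow_routing(params, sv_fraction=0.25)
        fl.check_conservation()
        hand = fl._seg_comp_total("hand_r")
        assert fl.sv_flow["hand_r"] == pytest.approx(0.25 * hand, rel=1e-12)
        assert fl.vein_comp_in["hand_r"] == pytest.approx(0.75 * hand, rel=1e-12)


class TestNetwork:
    def test_isothermal_fixed_point_of_vessel_solve(self, network):
        t0 = 36.8
        comp = {n.key: t0 for n in network.nodes if n.kind == "compartment"}
        vessels = network.solve_vessel_temperatures(comp)
        for seg, (t_ar, t_ve) in vessels.items():
            assert t_ar == pytest.approx(t0, abs=1e-9), seg
            assert t_ve == pytest.approx(t0, abs=1e-9), seg

    def test_pure_advection_with_zero_film_coefficients(self):
        """With vessel-tissue and arterio-venous conductances at zero the
        artery transmits the inlet temperature unchanged."""
        p = load_standard_person(overrides={"vessel_films": {
            "film_coeff_W_m2K": 0.0, "tissue_coeff_W_m2K": 0.0,
            "av_tissue_coeff_W_m2K": 0.0, "sv_skin_conductance_W_K": 0.5}})
        env = EnvironmentSpec.from_defaults(p.env_defaults)
        net = ThermalNetwork(p, env, target_flow_routing(p))
        comp = {n.key: 36.0 for n in net.nodes if n.kind == "compartment"}
        comp[("chest", "left_heart")] = 37.5
        vessels = net.solve_vessel_temperatures(comp)
        # piston arteries carry the left-heart temperature distally untouched
        for seg in ("neck", "abdomen", "upper_arm_r", "thigh_l"):
            assert vessels[seg][0] == pytest.approx(37.5, abs=1e-9)

    def test_vessel_solve_satisfies_balance_equations(self, network):
        """Topological solve must satisfy the quasi-steady artery balance
        (brute-force residual audit of the defining equations)."""
        rng = np.random.default_rng(42)
        comp = {n.key: 36.0 + rng.uniform(-1.5, 1.5)
                for n in network.nodes if n.kind == "compartment"}
        vessels = network.solve_vessel_temperatures(comp)
        T = dict(comp)
        for seg, (t_ar, t_ve) in vessels.items():
            T[(seg, "artery")] = t_ar
            T[(seg, "vein")] = t_ve
        for seg in ("neck", "abdomen", "thigh_r", "lower_arm_l"):
            k_ar, k_ve, k_cf = network._piston_coeffs(seg)
            q_ar = network.flows.artery_flow[seg]
            parent = ("chest", "left_heart") if seg in ("neck", "abdomen") else None
            from hemotherm.tnw.network import ARTERY_PARENT
            par = ARTERY_PARENT[seg]
            t_prox = T[("chest", "left_heart")] if par == "left_heart" else T[(par, "artery")]
            weights = network._vein_inlet_weights(seg)
            t_mix = sum(w * T[k] for k, w in weights.items()) if weights else t_prox
            residual = (RHO_C * q_ar * (t_prox - T[(seg, "artery")])
                        + k_ar * (T[(seg, "core")] - t_prox)
                        + k_cf * (t_mix - t_prox))
            assert abs(residual) < 1e-8 * RHO_C * q_ar, seg

    def test_implicit_step_energy_audit(self, network):
        """Heat stored per implicit step equals (metabolism - losses) dt."""
        dt = 10.0
        state = network.initial_state(35.0)
        new = network.step(state, dt)
        caps = {n.key: (n.heat_capacity or 0.0) for n in network.nodes}
        stored = sum(caps[k] * (new[k] - state[k]) for k in network.index)
        c_res, e_res = respiration_losses(network.env, network.total_metabolism)
        sensible = sum(
            network.env.surface_coefficient(seg) * network.skin_areas[seg]
            * (new[(seg, "skin")] - network.env.air_temperature)
            for seg in network._segments())
        from hemotherm.tnw import skin_latent_loss
        latent = sum(
            skin_latent_loss(network.env, seg, network.skin_areas[seg],
                             state[(seg, "skin")])
            for seg in network._segments())
        expected = dt * (network.total_metabolism - sensible - latent - c_res - e_res)
        assert stored == pytest.approx(expected, rel=1e-8)

    def test_time_refinement(self, network):
        """One 10 s implicit step vs 100 steps of 0.1 s: < 0.01 degC per node."""
        state = network.initial_state(35.0)
        coarse = network.step(state, 10.0)
        net2 = ThermalNetwork(network.params, network.env, network.flows)
        fine = state
        for _ in range(100):
            fine = net2.step(fine, 0.1)
        assert np.max(np.abs(coarse.temps - fine.temps)) < 0.01

    def test_steady_state_energy_closure(self, network):
        """At |dT/dt| below tolerance everywhere, metabolic heat matches
        total losses within 0.5 %."""
        state, converged = network.run_to_steady()
        assert converged
        balance = network.energy_balance(state)
        assert abs(balance["closure"]) < 0.005
        # physiological placement
        assert 36.0 < state[("head", "brain")] < 38.0
        for seg in ("chest", "abdomen", "thigh_r"):
            assert state[(seg, "skin")] < state[(seg, "core")]
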