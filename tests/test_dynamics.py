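"""Flux terms and the daily update map: examples, closed forms, invariants."""

from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glymphsim as g
from glymphsim.dynamics import (ModelState, deposition_fluxes, generation_flux,
                                glymphatic_flux, initial_state, lrp_flux,
                                neuron_loss_rate, step, uptake_flux)
from glymphsim.errors import ParameterError


@pytest.fixture(scope="module")
def params():
    return g.default_params("E3")


@pytest.fixture(scope="module")
def phys():
    return g.Physiology()


class TestFluxTerms:
    def test_generation_at_full_neuron_pool(self, params):
        gen40, gen42 = generation_flux(5275.0, params)
        assert gen40 == pytest.approx(16000 * 1.5 * 5275, rel=1e-12)  # 1.266e8
        assert gen42 == pytest.approx(3000 * 1.5 * 5275, rel=1e-12)

    def test_generation_zero_neurons(self, params):
        assert generation_flux(0.0, params) == (0.0, 0.0)

    def test_generation_scales_with_k4(self, params):
        hi = replace(params, k4=2.0)
        g40_hi, _ = generation_flux(5275.0, hi)
        g40, _ = generation_flux(5275.0, params)
        assert g40_hi / g40 == pytest.approx(2.0 / 1.5, rel=1e-12)

    def test_uptake_demand_and_clamp(self, params):
        assert uptake_flux(4500.0, 1e9, 1e9, params)[0] == pytest.approx(6.3e6)
        assert uptake_flux(4500.0, 1e3, 1e9, params) == (1e3, 9e5)
        assert uptake_flux(0.0, 1e9, 1e9, params) == (0.0, 0.0)

    def test_glymphatic_transfer(self):
        assert glymphatic_flux(6.26e7, 0.29, 1.0) == pytest.approx(1.815e7, rel=1e-3)
        assert glymphatic_flux(1e9, 0.0, 1.0) == 0.0

    @given(C=st.floats(0, 1e12), v=st.floats(0, 0.5))
    def test_glymphatic_linearity(self, C, v):
        assert glymphatic_flux(2 * C, v, 1.0) == pytest.approx(
            2 * glymphatic_flux(C, v, 1.0), rel=1e-12)

    @pytest.mark.parametrize("C, ell, k6, expected", [
        (1e8, 1.0, 0.4, 4e7),
        (1e8, 0.0, 0.4, 0.0),
        (1e8, 1.0, 0.12, 1.2e7),   # ApoE4 transport rate
    ])
    def test_lrp_transport(self, C, ell, k6, expected):
        assert lrp_flux(C, ell, k6) == pytest.approx(expected, rel=1e-12)

    def test_deposition_compartment_rates(self, params):
        state = ModelState(0, 5275, 4500, 22050, 9.3e11,
                           C1=1e9, C4=0, C2=1e8, C5=0, C3=0, C6=0, C9=0, C10=0)
        db40, db42, dv40, dv42 = deposition_fluxes(state, params)
        assert db40 == pytest.approx(1e6)    # 0.001/day in parenchyma
        assert dv40 == pytest.approx(4e5)    # 0.004/day in vessel wall
        assert db42 == dv42 == 0.0

    def test_deposition_all_zero_state(self, params):
        state = ModelState(0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0)
        assert deposition_fluxes(state, params) == (0, 0, 0, 0)


class TestNeuronLossTrigger:
    def test_below_threshold_natural_rate(self, params):
        c1i = params.c1_init_molecules()
        assert neuron_loss_rate(0.5 * c1i, c1i, params) == 0.01
        assert neuron_loss_rate(0.0, c1i, params) == 0.01

    def test_above_threshold_adds_k1(self, params):
        c1i = params.c1_init_molecules()
        assert neuron_loss_rate(25 * c1i, c1i, params) == pytest.approx(0.044)


class TestStep:
    def test_first_day_ab40_rises(self, params, phys):
        # generation (1.27e8/day) dominates initial losses (~2.5e7/day)
        s0 = initial_state(params)
        s1, fx = step(s0, params, phys)
        assert s1.C1 > s0.C1
        assert fx.gen40 == pytest.approx(1.266e8, rel=1e-3)
        assert fx.gen40 - fx.upt40 - fx.glym40 - fx.dep_brain40 == pytest.approx(
            s1.C1 - s0.C1, rel=1e-9)

    def test_zero_generation_zero_ab_is_absorbing(self, phys):
        p = g.default_params("E3").with_overrides(k3=0.0, k8=0.0,
                                                  C1_0=0.0, C4_0=0.0)
        s = initial_state(p)
        for _ in range(10):
            s, fx = step(s, p, phys)
        for pool in ("C1", "C4", "C2", "C5", "C3", "C6", "C9", "C10"):
            assert getattr(s, pool) == 0.0

    def test_neuron_halving_over_69_years(self, params, phys):
        s = initial_state(params)
        # isolate the neuron pool: disable the Aβ trigger entirely
        p = params.with_overrides(theta_k1=1e12)
        for _ in range(69 * 365):
            s, _ = step(s, p, phys)
        assert s.N / p.N0 == pytest.approx(0.500, abs=0.001)

    def test_pvs_closed_form_geometric_decay(self, phys):
        # inflow, generation and uptake off: C2 decays at (k6 + k_exit + k7)
        # per day and its deposit converges to C2(0) * k7/(k6 + k_exit + k7)
        p = g.default_params("E3").with_overrides(
            k3=0.0, k8=0.0, k5=0.0, k11=0.0, k2=0.0, k10=0.0, d=0.0, k12=0.0)
        no_flow = g.Physiology(stiffness=g.StiffnessProfile(
            fold_change=2.0, compliance_law="flow_off"))
        c2_0 = 1e8
        s = ModelState(0, p.N0, p.M0, p.EC0, p.LRP0,
                       C1=0, C4=0, C2=c2_0, C5=0, C3=0, C6=0, C9=0, C10=0)
        a = p.k6 + p.k_exit + p.k7
        for n in (1, 5, 50):
            while s.t < n:
                s, _ = step(s, p, no_flow)
            assert s.C2 == pytest.approx(c2_0 * (1 - a) ** n, rel=1e-9)
        while s.t < 400:
            s, _ = step(s, p, no_flow)
        assert s.C3 == pytest.approx(c2_0 * p.k7 / a, rel=1e-9)

    def test_ab_pools_linear_in_generation_rates(self, phys):
        # with zero initial Aβ and no uptake, doubling (k3, k8) doubles
        # every Aβ pool at any horizon
        base = g.default_params("E3").with_overrides(
            C1_0=0.0, C4_0=0.0, k5=0.0, k11=0.0, theta_k1=1e12)
        doubled = base.with_overrides(k3=2 * base.k3, k8=2 * base.k8)
        t1 = g.run_simulation(params=base, years=2.0)
        t2 = g.run_simulation(params=doubled, years=2.0)
        for pool in ("C1", "C4", "C2", "C5", "C3", "C6", "C9", "C10"):
            assert t2.endpoint(pool) == pytest.approx(
                2 * t1.endpoint(pool), rel=1e-9)

    def test_uptake_clamp_never_drives_pools_negative(self, phys):
        # huge microglial demand versus a tiny Aβ pool
        p = g.default_params("E3").with_overrides(
            k5=1e9, k11=1e9, C1_0=1e-6, C4_0=1e-6, k3=10.0, k8=1.0)
        s = initial_state(p)
        for _ in range(30):
            s, fx = step(s, p, phys)
            assert s.C1 >= 0 and s.C4 >= 0
            assert fx.upt40 >= 0 and fx.upt42 >= 0

    def test_substepping_engages_for_fast_outflow(self, phys):
        # a PVS outflow fraction above 0.9/day must still yield a positive
        # explicit update
        p = g.default_params("E3").with_overrides(k6=0.8, k_exit=0.5)
        s0 = initial_state(p)
        s1, _ = step(s0, p, phys)
        assert s1.C2 > 0

    def test_rejects_invalid_dt(self, params, phys):
        with pytest.raises(ParameterError):
            step(initial_state(params), params, phys, dt=0.0)


# -- randomized invariants ---------------------------------------------------

rate_small = st.floats(0.0, 0.08)
rate_day = st.floats(0.0, 0.6)


class TestRandomizedInvariants:
    @settings(max_examples=25)
    @given(d=rate_small, k1=rate_small, k2=rate_small,
           k3=st.floats(0, 3e4), k8=st.floats(0, 6e3),
           k5=st.floats(0, 3e3), k11=st.floats(0, 500),
           k6=rate_day, k_exit=rate_day,
           k7=st.floats(0, 0.05), k9a=st.floats(0, 0.05),
           k7a=st.floats(0, 0.05), k9=st.floats(0, 0.05),
           v0=st.floats(0.144, 0.43), hr=st.floats(30, 200))
    def test_nonnegativity_and_deposit_monotonicity(
            self, d, k1, k2, k3, k8, k5, k11, k6, k_exit, k7, k9a, k7a, k9,
            v0, hr):
        """Any valid parameter set must produce non-negative pools and
        non-decreasing deposits."""
        p = g.ModelParams(d=d, k1=k1, k2=k2, k3=k3, k8=k8, k5=k5, k11=k11,
                          k6=k6, k_exit=k_exit, k7=k7, k9a=k9a, k7a=k7a,
                          k9=k9, v0=v0)
        phys = g.Physiology(heart_rate=hr)
        s = initial_state(p)
        prev_deposits = (0.0, 0.0, 0.0, 0.0)
        for _ in range(120):
            s, fx = step(s, p, phys)
            for f in ("N", "M", "EC", "LRP", "C1", "C4", "C2", "C5",
                      "C3", "C6", "C9", "C10"):
                assert getattr(s, f) >= 0.0
            deposits = (s.C3, s.C6, s.C9, s.C10)
            assert all(a >= b for a, b in zip(deposits, prev_deposits))
            prev_deposits = deposits
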