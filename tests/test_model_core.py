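"""Core model mechanics: induction term, mechanism fluxes, the assembled
right-hand side, parameter handling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiis import appired_ii_protocol, placebo_protocol
from hiis.dosing import IU_TO_BLOOD_CONC, infusion_rate_at
from hiis.model import (
    IDX,
    N_STATES,
    PARAM_TABLE,
    STATE_NAMES,
    VOLUME_RATIO,
    GaussianPulse,
    ImmuneState,
    InductionParameters,
    IntegrationFailure,
    ModelError,
    ModelParameters,
    bolus_source,
    denovo_gate,
    endothelial_permeability,
    induction_rate,
    itm_ap_neutralization,
    liver_flush_gate,
    necrosis_itm_release,
    neutrophil_fate_fluxes,
    rhs,
)


# ---------------------------------------------------------------------------
# Induction term
# ---------------------------------------------------------------------------


class TestInductionRate:
    IND = InductionParameters(r_induce_peak=4.0, r_induce=1.5, t_ap_delay=1.0)

    def test_half_peak_exactly_at_sigmoid_centre(self):
        s = 2.0e7
        assert induction_rate(self.IND.t_ap_delay, self.IND, s) == pytest.approx(
            0.5 * self.IND.r_induce_peak * s, rel=1e-14
        )

    def test_zero_supplemented_ap_gives_zero(self):
        assert induction_rate(0.5, self.IND, 0.0) == 0.0

    def test_deep_tail_is_negligible(self):
        # r*(t - delay) >= 50 puts the sigmoid below 2e-22
        t = self.IND.t_ap_delay + 50.0 / self.IND.r_induce
        s = 1.0e8
        assert induction_rate(t, self.IND, s) <= 1e-20 * self.IND.r_induce_peak * s

    def test_disabled_forces_identically_zero(self):
        off = InductionParameters(4.0, 1.5, 1.0, enabled=False)
        assert induction_rate(0.0, off, 1e9) == 0.0

    def test_negative_supplemented_ap_rejected(self):
        with pytest.raises(ModelError):
            induction_rate(1.0, self.IND, -1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        t1=st.floats(0, 30, allow_nan=False),
        dt=st.floats(0.001, 30, allow_nan=False),
        s=st.floats(0, 1e9, allow_nan=False),
    )
    def test_reverse_sigmoid_is_non_increasing_in_time(self, t1, dt, s):
        assert induction_rate(t1, self.IND, s) >= induction_rate(t1 + dt, self.IND, s)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ModelError):
            InductionParameters(-1.0, 1.0, 1.0)
        with pytest.raises(ModelError):
            InductionParameters(1.0, 0.0, 1.0)
        with pytest.raises(ModelError):
            InductionParameters(1.0, 1.0, -0.5)


# ---------------------------------------------------------------------------
# Mechanism fluxes
# ---------------------------------------------------------------------------


class TestPermeability:
    def test_resting_endothelium_is_at_baseline(self, params):
        assert endothelial_permeability(0.0, params) == pytest.approx(params.perm_base)

    def test_monotone_and_saturating(self, params):
        ch = np.linspace(0, 1e8, 200)
        vals = [endothelial_permeability(c, params) for c in ch]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        # analytic limit of the Hill form is perm_max
        assert endothelial_permeability(1e30, params) == pytest.approx(params.perm_max, rel=1e-9)
        assert vals[-1] <= params.perm_max + 1e-12

    def test_negative_cytokine_rejected(self, params):
        with pytest.raises(ModelError):
            endothelial_permeability(-1.0, params)


class TestNeutrophilFates:
    def _state(self, n_a=100.0, itm_tissue=0.0, d3=1.0):
        s = ImmuneState()
        s.n_a, s.itm_tissue, s.delay_3 = n_a, itm_tissue, d3
        return s

    def test_no_activated_neutrophils_no_fluxes(self, params):
        assert neutrophil_fate_fluxes(self._state(n_a=0.0, itm_tissue=1e9), params) == (0.0, 0.0)

    def test_cleared_inflammation_apoptosis_dominant(self, params):
        apop, necro = neutrophil_fate_fluxes(self._state(itm_tissue=0.0), params)
        assert necro == 0.0  # necrosis baseline is nil without ITM pressure
        assert apop > 0.0

    def test_necrotic_share_non_decreasing_in_tissue_itm(self, params):
        shares = []
        for itm in [0.0, 1e6, 1e7, 1e8, 1e9]:
            apop, necro = neutrophil_fate_fluxes(self._state(itm_tissue=itm), params)
            shares.append(necro / (apop + necro))
        assert all(b >= a for a, b in zip(shares, shares[1:]))

    def test_total_outflux_is_apoptosis_plus_necrosis(self, params):
        # the assembled RHS drains n_a by exactly these two fluxes
        s = self._state(n_a=50.0, itm_tissue=5e7, d3=0.5)
        apop, necro = neutrophil_fate_fluxes(s, params)
        dy = rhs(5.0, s.as_array(), params, placebo_protocol())
        assert dy[IDX["n_a"]] == pytest.approx(-(apop + necro), rel=1e-12)


class TestNecrosisRelease:
    def test_zero_without_necrotic_cells(self, params):
        assert necrosis_itm_release(ImmuneState(), params) == 0.0

    def test_linear_in_necrotic_pool(self, params):
        s1, s2 = ImmuneState(), ImmuneState()
        s1.nd_n, s2.nd_n = 40.0, 80.0
        r1, r2 = necrosis_itm_release(s1, params), necrosis_itm_release(s2, params)
        assert r1 > 0
        assert r2 == pytest.approx(2 * r1, rel=1e-12)


class TestNeutralization:
    def test_zero_reactant_zero_flux(self, params):
        s = ImmuneState()
        s.ap_endo_blood, s.ap_endo_tissue = 1e7, 1e7
        assert itm_ap_neutralization(s, params) == (0.0, 0.0)
        s2 = ImmuneState()
        s2.itm_blood, s2.itm_tissue = 1e8, 1e8
        assert itm_ap_neutralization(s2, params) == (0.0, 0.0)

    def test_supplemented_and_endogenous_ap_both_contribute(self, params):
        s = ImmuneState()
        s.itm_blood = 1e8
        s.ap_endo_blood = 2e7
        only_endo = itm_ap_neutralization(s, params)[0]
        s.ap_supp_blood = 2e7
        assert itm_ap_neutralization(s, params)[0] == pytest.approx(2 * only_endo, rel=1e-12)

    def test_blood_binding_mass_balance_is_one_to_one(self, params):
        """d(complex)/dt gain == ITM binding loss == total AP binding loss."""
        s = ImmuneState()
        s.itm_blood, s.ap_endo_blood, s.ap_supp_blood = 3e8, 5e7, 2e7
        bind, _ = itm_ap_neutralization(s, params)
        dy = rhs(0.5, s.as_array(), params, placebo_protocol())
        complex_gain = dy[IDX["itm_ap_blood"]] + params.k_kupffer * s.itm_ap_blood
        itm_loss_to_binding = params.k_bind * s.itm_blood * (s.ap_endo_blood + s.ap_supp_blood)
        assert complex_gain == pytest.approx(bind, rel=1e-12)
        assert itm_loss_to_binding == pytest.approx(bind, rel=1e-12)


# ---------------------------------------------------------------------------
# Assembled right-hand side
# ---------------------------------------------------------------------------


def _ledger_rhs(t, y, p, protocol, itm_source=None):
    """Independent bookkeeping: every mechanism flux with its stoichiometry,
    summed brute-force into a derivative vector."""
    s = ImmuneState.from_array(np.maximum(np.asarray(y, float), 0.0))
    rho = VOLUME_RATIO
    perm = endothelial_permeability(s.ch, p)
    inhib = 1.0 / (1.0 + (s.ach / p.ach_h_inhib) ** 2)
    H = liver_flush_gate(s.itm_blood, p)
    target = p.liver_store_iu * (1.0 - H)
    u = s.itm_tissue / (s.itm_tissue + p.delay_h_itm)
    kd = 3.0 / p.tau_delay
    apop, necro = neutrophil_fate_fluxes(s, p)
    bind, dephos = itm_ap_neutralization(s, p)

    ledger = [
        # (flux value, {state: stoichiometric coefficient})
        (itm_source(t) if itm_source else 0.0, {"itm_blood": +1}),
        (p.k_itm_perm * perm * s.itm_blood, {"itm_blood": -1, "itm_tissue": +rho}),
        (bind, {"itm_blood": -1, "itm_ap_blood": +1}),
        (p.k_bind * s.itm_blood * s.ap_endo_blood, {"ap_endo_blood": -1}),
        (p.k_bind * s.itm_blood * s.ap_supp_blood, {"ap_supp_blood": -1}),
        (p.k_itm_deg_b * s.itm_blood, {"itm_blood": -1}),
        (dephos, {"itm_tissue": -1}),
        (p.k_itm_phag * s.n_a * s.itm_tissue, {"itm_tissue": -1}),
        (p.k_itm_deg_t * s.itm_tissue, {"itm_tissue": -1}),
        (necrosis_itm_release(s, p), {"itm_tissue": +1}),
        (p.k_d_itm * s.d, {"itm_tissue": +1}),
        (p.k_flush * max(s.liver_store - target, 0.0),
         {"liver_store": -1, "ap_endo_blood": +IU_TO_BLOOD_CONC}),
        (p.k_refill * max(target - s.liver_store, 0.0), {"liver_store": +1}),
        (p.denovo_supply * denovo_gate(s.liver_store / p.liver_store_iu, p),
         {"ap_endo_blood": +1}),
        (induction_rate(t, p.induction, s.ap_supp_blood + s.ap_supp_tissue),
         {"ap_endo_blood": +1}),
        (p.k_ap_deg * s.ap_endo_blood, {"ap_endo_blood": -1}),
        (p.k_ap_perm * (s.ap_endo_blood - s.ap_endo_tissue),
         {"ap_endo_blood": -1, "ap_endo_tissue": +rho}),
        (p.k_apt_deg * s.ap_endo_tissue, {"ap_endo_tissue": -1}),
        (bolus_source(t, protocol), {"ap_supp_blood": +1}),
        (infusion_rate_at(t, protocol) * IU_TO_BLOOD_CONC, {"ap_supp_blood": +1}),
        (p.k_aps_deg * s.ap_supp_blood, {"ap_supp_blood": -1}),
        (p.k_ap_perm * (s.ap_supp_blood - s.ap_supp_tissue),
         {"ap_supp_blood": -1, "ap_supp_tissue": +rho}),
        (p.k_apt_deg * s.ap_supp_tissue, {"ap_supp_tissue": -1}),
        (p.k_kupffer * s.itm_ap_blood, {"itm_ap_blood": -1}),
        (p.k_mr_renew * (p.mr_pool - s.m_r), {"m_r": +1}),
        (p.k_mact * s.m_r * (s.itm_tissue + p.mact_blood_frac * s.itm_blood) * inhib,
         {"m_r": -1, "m_a": +1}),
        (p.k_ma_death * s.m_a, {"m_a": -1}),
        (p.k_nr_renew * (p.nr_pool - s.n_r), {"n_r": +1}),
        (p.k_diaped * (perm - p.perm_base) * s.n_r, {"n_r": -1, "n_a": +rho}),
        (apop, {"n_a": -1, "nd_a": +1}),
        (necro, {"n_a": -1, "nd_n": +1}),
        (p.k_nda_phag * s.m_a * s.nd_a, {"nd_a": -1}),
        (p.k_nda_deg * s.nd_a, {"nd_a": -1}),
        (p.k_ndn_phag * s.m_a * s.nd_n, {"nd_n": -1}),
        (p.k_ndn_deg * s.nd_n, {"nd_n": -1}),
        (p.k_ch_ma * s.m_a * s.delay_3 * inhib, {"ch": +1}),
        (p.k_ch_ndn * s.nd_n, {"ch": +1}),
        (p.k_ch_deg * s.ch, {"ch": -1}),
        (p.k_ach_ma * s.m_a * s.delay_3, {"ach": +1}),
        (p.k_ach_phag * s.m_a * s.nd_a, {"ach": +1}),
        (p.k_ach_deg * s.ach, {"ach": -1}),
        (p.k_d_prod * s.nd_n, {"d": +1}),
        (p.k_d_deg * s.d, {"d": -1}),
        (kd * (u - s.delay_1), {"delay_1": +1}),
        (kd * (s.delay_1 - s.delay_2), {"delay_2": +1}),
        (kd * (s.delay_2 - s.delay_3), {"delay_3": +1}),
    ]
    dy = np.zeros(N_STATES)
    for flux, stoich in ledger:
        for state, coeff in stoich.items():
            dy[IDX[state]] += coeff * flux
    return dy


def _random_states(rng, n):
    scales = np.array(
        [1e9, 1e8, 1e8, 1e7, 1e8, 1e7, 1e8, 300, 300, 5000, 500, 500, 500,
         1e6, 1e6, 1e3, 5300, 1, 1, 1], dtype=float
    )
    return rng.random((n, N_STATES)) * scales


def test_rhs_matches_independent_flux_ledger_at_random_states(params, rng):
    """Term-by-term oracle: the assembled RHS equals the brute-force
    stoichiometric sum of all mechanism fluxes at 100 random states."""
    protocol = appired_ii_protocol()
    pulse = GaussianPulse(1e8, 6.0, 1.0)
    for y in _random_states(rng, 100):
        t = float(rng.random() * 36.0)
        got = rhs(t, y, params, protocol, itm_source=pulse)
        want = _ledger_rhs(t, y, params, protocol, itm_source=pulse)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-20)


def test_homeostatic_state_is_a_fixed_point(params, placebo):
    quiet = params.with_updates(itm_insult=0.0)
    y0 = quiet.homeostatic_state().as_array()
    dy = rhs(0.0, y0, quiet, placebo)
    scale = np.maximum(np.abs(y0), 1.0)
    assert np.max(np.abs(dy) / scale) < 1e-12


def test_macrophage_activation_requires_itm(params, placebo):
    s = params.homeostatic_state()
    dy = rhs(0.0, s.as_array(), params, placebo)
    assert dy[IDX["m_r"]] == 0.0
    assert dy[IDX["m_a"]] == 0.0


def test_non_finite_state_raises_with_component_name(params, placebo):
    y = params.homeostatic_state().as_array()
    y[IDX["ch"]] = np.nan
    with pytest.raises(IntegrationFailure, match="ch"):
        rhs(0.0, y, params, placebo)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


class TestModelParameters:
    def test_bounds_contain_every_nominal_value(self):
        for name, spec in PARAM_TABLE.items():
            assert spec.lower <= spec.default <= spec.upper, name

    def test_negative_rate_rejected_at_construction(self):
        with pytest.raises(ModelError):
            ModelParameters(k_ap_deg=-0.1)

    def test_out_of_bounds_and_unknown_rejected(self):
        with pytest.raises(ModelError):
            ModelParameters(k_flush=1e9)
        with pytest.raises(ModelError):
            ModelParameters(not_a_parameter=1.0)

    def test_yaml_round_trip_is_lossless(self, params, tmp_path):
        modified = params.with_updates(k_bind=1.23456789012345e-9, induction_enabled=False)
        modified.set_free(["k_bind"])
        path = tmp_path / "params.yaml"
        modified.to_yaml(path)
        loaded = ModelParameters.from_yaml(path)
        assert loaded == modified
        assert loaded.is_free("k_bind")
        assert not loaded.induction_enabled
        assert loaded.digest() == modified.digest()

    def test_all_zero_initial_state_yields_zero_itm_trajectory(self):
        # degenerate input: nothing in the system, no insult -> ITMs stay 0
        p = ModelParameters(itm_insult=0.0)
        y = np.zeros(N_STATES)
        dy = rhs(0.0, y, p, placebo_protocol())
        assert dy[IDX["itm_blood"]] == 0.0
        assert dy[IDX["itm_tissue"]] == 0.0

    def test_tissue_baseline_balances_exchange_and_turnover(self, params):
        ap_t = params.ap_tissue_baseline_conc
        influx = VOLUME_RATIO * params.k_ap_perm * (params.ap_baseline_conc - ap_t)
        assert influx == pytest.approx(params.k_apt_deg * ap_t, rel=1e-12)


class TestGaussianPulse:
    def test_integral_closed_form_matches_quadrature(self):
        pulse = GaussianPulse(7.5e8, 6.0, 1.0)
        t = np.linspace(0, 36, 20001)
        quad = np.trapezoid([pulse(x) for x in t], t)
        assert quad == pytest.approx(pulse.integral, rel=1e-3)
        assert pulse.integral == pytest.approx(7.5e8 * math.sqrt(2 * math.pi), rel=1e-12)

    def test_zero_amplitude_is_identically_zero(self):
        pulse = GaussianPulse(0.0, 6.0, 1.0)
        assert all(pulse(t) == 0.0 for t in np.linspace(0, 36, 50))

    def test_invalid_pulse_rejected(self):
        with pytest.raises(ModelError):
            GaussianPulse(-1.0, 6.0, 1.0)
        with pytest.raises(ModelError):
            GaussianPulse(1.0, 6.0, 0.0)
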