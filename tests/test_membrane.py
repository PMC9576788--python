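"""Membrane flux laws, gating functions, and the per-end assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import osmoengine as oe
from osmoengine import membrane as M
from osmoengine.errors import InvalidInputError, ParameterError
from osmoengine.fields import end_state_from_profiles
from osmoengine.params import with_overrides
from osmoengine.solver import initial_guess


# ---------------------------------------------------------------------------
# elementary laws


@pytest.mark.parametrize("end, v0, jw, dg, p0, expected", [
    ("front", 1.0, 0.0, 0.0, 7.0, 7.0),  # zero resistance: p* = p0
    ("front", 1.0, 0.0, 2.0, 0.0, 2.0),
    ("back", 1.0, 0.0, 2.0, 0.0, -2.0),  # sign convention at the rear
])
def test_external_pressure(end, v0, jw, dg, p0, expected):
    assert M.external_pressure(end, v0, jw, dg, p0) == expected


def test_external_pressure_rejects_bad_end():
    with pytest.raises(InvalidInputError):
        M.external_pressure("middle", 0, 0, 0, 0)


def test_water_flux_values():
    assert M.water_flux(5.0, 5.0, 100.0, 100.0, 1.0, 1.0) == 0.0
    # alpha=1, (p - p*) = 2, RT (c - c0) = 5 -> J = 3
    assert M.water_flux(2.0, 0.0, 5.0, 0.0, 1.0, 1.0) == pytest.approx(3.0)
    # hypertonic outside at pressure equilibrium -> efflux
    assert M.water_flux(0.0, 0.0, 100.0, 150.0, 1.0, 2.0) < 0


def test_resolve_water_matches_implicit_pair(params):
    """Closed-form elimination solves the implicit J/p* pair exactly."""
    endp = params.front
    j, p_star = M.resolve_water("front", 30000.0, 290.5, 290.0, 1e-4, endp, params.rt)
    assert p_star == pytest.approx(M.external_pressure(
        "front", 1e-4, j, endp.hydraulic_resistance, endp.external_pressure))
    assert j == pytest.approx(M.water_flux(30000.0, p_star, 290.5, 290.0,
                                           endp.water_permeability, params.rt))


def test_membrane_tension():
    assert M.membrane_tension(1.0, 1.0, 2.0, 5.0) == 0.0
    assert M.membrane_tension(1.0, 1.0, 0.0, 2.0) == 2.0
    assert M.membrane_tension(3.0, 4.0, 1.0, 2.0) == \
        2 * M.membrane_tension(3.0, 4.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# gates


def test_gate_midpoints_and_saturation():
    assert M.gate_mechanosensitive(2.0, 1.5, 2.0) == pytest.approx(0.5)
    assert M.gate_mechanosensitive(1e6, 1.0, 0.0) == pytest.approx(1.0)
    assert M.gate_mechanosensitive(-1e6, 1.0, 0.0) == pytest.approx(0.0)
    assert M.gate_nke_voltage(-90.0, 0.1, -90.0) == pytest.approx(0.0)
    assert M.gate_nke_voltage(1e6, 0.1, 0.0) == pytest.approx(1.0)
    assert M.gate_nke_voltage(-1e6, 0.1, 0.0) == pytest.approx(-1.0)
    assert M.gate_nhe(7.2, 4.0, 7.2) == pytest.approx(0.5)
    assert M.gate_ae2(7.1, 4.0, 7.1) == pytest.approx(0.5)
    # quiescence directions: NHE shuts down and AE2 activates at high pH
    assert M.gate_nhe(9.0, 4.0, 7.2) < 1e-3
    assert M.gate_ae2(9.0, 4.0, 7.1) > 1 - 1e-3


@given(st.floats(min_value=-500, max_value=500),
       st.floats(min_value=0.001, max_value=1.0))
def test_gates_bounded_and_monotone(x, beta):
    g1 = M.gate_mechanosensitive(x, beta, 0.0)
    g2 = M.gate_mechanosensitive(x + 1.0, beta, 0.0)
    assert 0.0 <= g1 <= 1.0 and g2 >= g1
    gv1, gv2 = (M.gate_nke_voltage(v, beta, 0.0) for v in (x, x + 1.0))
    assert -1.0 <= gv1 <= 1.0 and gv2 >= gv1
    ph = 5.0 + 4.0 * M.gate_mechanosensitive(x, 0.01, 0.0)  # any pH in (5, 9)
    assert M.gate_nhe(ph + 0.1, beta, 7.2) <= M.gate_nhe(ph, beta, 7.2)
    assert M.gate_ae2(ph + 0.1, beta, 7.1) >= M.gate_ae2(ph, beta, 7.1)


# ---------------------------------------------------------------------------
# pathways


def test_passive_flux_nernst_zero():
    rt, f = 2577.0, 96.485
    v_m = -30.0
    gamma = math.exp(1 * f * v_m / rt)
    assert M.passive_ion_flux(gamma, 1, v_m, 1.0, 1.0, rt, f) == pytest.approx(
        0.0, abs=1e-12)
    assert M.passive_ion_flux(2.0, 1, 10.0, 0.0, 1.0, rt, f) == 0.0
    assert M.passive_ion_flux(math.e, 1, 0.0, 1.0, 1.0, rt, f) == pytest.approx(rt)


def test_passive_flux_single_sign_change_across_nernst():
    rt, f = 2577.0, 96.485
    gamma = 3.0
    e_n = rt / f * math.log(gamma)  # Nernst potential for z = +1
    vs = np.linspace(e_n - 50, e_n + 50, 101)
    j = np.array([M.passive_ion_flux(gamma, 1, v, 1.0, 1.0, rt, f) for v in vs])
    signs = np.sign(j[np.abs(j) > 1e-12])
    assert (np.diff(signs) != 0).sum() == 1


def test_passive_flux_rejects_bad_gamma():
    with pytest.raises(InvalidInputError):
        M.passive_ion_flux(0.0, 1, 0.0, 1.0, 1.0, 1.0, 1.0)


def test_nke_stoichiometry_and_limits():
    j_na, j_k = M.nke_flux(1.0, 1.0, -90.0, 1.0, 1.0, 1.0, 0.1, -90.0)
    assert j_na == 0.0 and j_k == 0.0  # voltage midpoint shuts the pump
    j_na, j_k = M.nke_flux(1.0, 1e-12, 0.0, 1.0, 1.0, 1.0, 0.1, -90.0)
    assert abs(j_na) < 1e-12  # no external K to import
    # both Hill factors = 1, G_V = 1: 3 Na out for 2 K in
    j_na, j_k = M.nke_flux(1e-12, 1e12, 1e9, 1.0, 1.0, 1.0, 0.1, -90.0)
    assert j_na == pytest.approx(-1.0)
    assert j_k == pytest.approx(2.0 / 3.0)
    assert j_na + j_k == pytest.approx(j_na / 3.0)  # net -1 charge per 3:2 cycle


def test_nhe_antiport():
    rt = 2577.0
    assert M.nhe_flux(2.0, 2.0, 7.0, 1.0, 4.0, 7.2, rt) == (0.0, 0.0)
    j_na, j_h = M.nhe_flux(math.e, 1.0, 7.0, 1.0, 4.0, 7.2, rt)
    assert j_na > 0 and j_h == -j_na  # one-for-one, zero net charge
    assert M.nhe_flux(2.0, 1.0, 12.0, 1.0, 50.0, 7.2, rt)[0] == pytest.approx(
        0.0, abs=1e-12)  # alkaline quiescence


def test_ae2_antiport():
    rt = 2577.0
    assert M.ae2_flux(3.0, 3.0, 7.2, 1.0, 4.0, 7.1, rt) == (0.0, 0.0)
    j_cl, j_hco3 = M.ae2_flux(math.e ** 2, math.e, 7.2, 1.0, 4.0, 7.1, rt)
    assert j_cl > 0 and j_hco3 == -j_cl
    assert M.ae2_flux(2.0, 1.0, 3.0, 1.0, 50.0, 7.1, rt)[0] == pytest.approx(
        0.0, abs=1e-12)  # acidic quiescence


def test_actin_polymerization_flux():
    assert M.actin_polymerization_flux(0.0, 1.0, 0.2) == 0.0
    assert M.actin_polymerization_flux(0.2, 1.0, 0.2) == pytest.approx(0.5)
    assert M.actin_polymerization_flux(1e9, 1.0, 0.2) == pytest.approx(1.0, rel=1e-6)
    with pytest.raises(ParameterError):
        M.actin_polymerization_flux(0.1, 1.0, 0.0)


# ---------------------------------------------------------------------------
# per-end assembly


def _end_state(params, end="front", v0=0.0):
    prof, _ = initial_guess(params, 24)
    return end_state_from_profiles(prof, v0, end, params)


def test_assembly_all_alphas_zero(params):
    shut = with_overrides(params, {
        f"{e}.{a}": 0.0 for e in ("front", "back")
        for a in ("alpha_na", "alpha_k", "alpha_cl", "alpha_nke",
                  "alpha_nhe", "alpha_ae2", "water_permeability")})
    shut = with_overrides(shut, {"front.j_actin": 0.0})
    fx = M.assemble_boundary_fluxes(_end_state(shut), shut.front, shut)
    assert fx.water == 0.0 and fx.actin == 0.0
    assert all(v == 0.0 for v in fx.totals.values())


def test_assembly_decomposition_sums(params):
    """Totals equal the sum of independently computed mechanism fluxes."""
    es = _end_state(params, "front", v0=1e-4)
    fx = M.assemble_boundary_fluxes(es, params.front, params)
    g = params.gating
    rt, f_mv = params.rt, params.f_mv
    c = es.concentrations
    gam = {n: params.external_concentration(n, "front") / c[n]
           for n in ("na", "k", "cl", "h", "hco3")}
    j_nke = M.nke_flux(gam["na"], gam["k"], es.potential_jump, params.front.alpha_nke,
                       params.nke.beta_na, params.nke.beta_k, g.beta3, g.beta4)
    j_nhe = M.nhe_flux(gam["na"], gam["h"], es.ph, params.front.alpha_nhe,
                       g.beta5, g.beta6, rt)
    j_ae2 = M.ae2_flux(gam["cl"], gam["hco3"], es.ph, params.front.alpha_ae2,
                       g.beta7, g.beta8, rt)
    pas = {n: M.passive_ion_flux(gam[n], params.valence(n), es.potential_jump,
                                 fx.gate_m, getattr(params.front, f"alpha_{n}"),
                                 rt, f_mv) for n in ("na", "k", "cl")}
    assert fx.totals["na"] == pytest.approx(pas["na"] + j_nke[0] + j_nhe[0], rel=1e-12)
    assert fx.totals["k"] == pytest.approx(pas["k"] + j_nke[1], rel=1e-12)
    assert fx.totals["cl"] == pytest.approx(pas["cl"] + j_ae2[0], rel=1e-12)
    assert fx.totals["h"] == pytest.approx(j_nhe[1], rel=1e-12)
    assert fx.totals["hco3"] == pytest.approx(j_ae2[1], rel=1e-12)
    assert fx.totals["buf"] == 0.0 and fx.totals["a"] == 0.0
    # electroneutral antiport bookkeeping
    assert fx.nhe["na"] + fx.nhe["h"] == pytest.approx(0.0, abs=1e-15)
    assert fx.ae2["cl"] + fx.ae2["hco3"] == pytest.approx(0.0, abs=1e-15)


def test_assembly_passive_cl_at_nernst_is_zero(params):
    only_cl = with_overrides(params, {
        f"{e}.{a}": 0.0 for e in ("front", "back")
        for a in ("alpha_na", "alpha_k", "alpha_nke", "alpha_nhe", "alpha_ae2")})
    es = _end_state(only_cl, "front")
    # place Cl- exactly at its Nernst equilibrium for the current V_m
    gamma = math.exp(-params.f_mv * es.potential_jump / params.rt)  # z = -1
    es.concentrations["cl"] = only_cl.external_concentration("cl", "front") / gamma
    fx = M.assemble_boundary_fluxes(es, only_cl.front, only_cl)
    assert fx.totals["cl"] == pytest.approx(0.0, abs=1e-10)
    assert fx.totals["na"] == 0.0 and fx.totals["k"] == 0.0
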