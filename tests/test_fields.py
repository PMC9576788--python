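"""Bulk residual blocks: trivial states, independent oracles, MMS order."""

import numpy as np
import pytest

import osmoengine as oe
from osmoengine import fields as F
from osmoengine import mms
from osmoengine.solver import initial_guess

from conftest import smooth_profiles


def uniform_profiles(params, n=24, **over):
    prof, _ = initial_guess(params, n)
    for k, v in over.items():
        if k == "v_c":
            prof.v_c = v
        else:
            getattr(prof, k)[:] = v
    prof.__dict__.pop("_derived", None)
    return prof


# ---------------------------------------------------------------------------
# cytosol and network momentum


def test_cytosol_residual_zero_without_network(params):
    prof = uniform_profiles(params, theta_n=0.0, p=100.0)
    assert np.allclose(F.cytosol_residuals(prof, params), 0.0)


def test_cytosol_residual_manufactured_linear_pressure(params):
    """p(x) = -eta theta (v_c - v_n) x satisfies the momentum balance."""
    prof = uniform_profiles(params, theta_n=0.3, v_n=0.0, v_c=1e-3)
    slope = -params.interfacial_friction * 0.3 * (prof.v_c - 0.0)
    prof.p[:] = slope * prof.x
    assert np.allclose(F.cytosol_residuals(prof, params), 0.0, atol=1e-14)


def test_cytosol_residual_matches_gradient_oracle(params):
    """Interval rows agree with a naive midpoint finite-difference oracle."""
    prof = smooth_profiles(params, 48)
    got = F.cytosol_residuals(prof, params)
    h = prof.h
    mid = lambda a: 0.5 * (a[1:] + a[:-1])
    oracle = -np.diff(prof.p) / h - params.interfacial_friction * \
        mid(prof.theta_n) * (prof.v_c - mid(prof.v_n))
    assert np.allclose(got, oracle, rtol=1e-12, atol=1e-14)


def test_network_residual_static_uniform(params):
    prof = uniform_profiles(params, theta_n=0.25, v_n=0.0, v_c=0.0)
    assert np.allclose(F.network_residuals(prof, params), 0.0, atol=1e-12)


def test_network_residual_matches_gradient_oracle(params):
    prof = smooth_profiles(params, 64)
    got = F.network_residuals(prof, params)[1:-1]
    sig = params.actin_stiffness * prof.theta_n
    dsig = (sig[2:] - sig[:-2]) / (2 * prof.h)
    th = prof.theta_n[1:-1] + F.THETA_REG
    oracle = (-dsig + params.interfacial_friction * th *
              (prof.v_c - prof.v_n[1:-1])
              - params.adhesion_strength * th * prof.v_n[1:-1])
    assert np.allclose(got, oracle, rtol=1e-12)


# ---------------------------------------------------------------------------
# actin conservation


def test_actin_bulk_zero_for_static_uniform_network(params):
    p0 = oe.with_overrides(params, {"depolymerization_rate": 0.0,
                                    "front.j_actin": 0.0})
    prof = uniform_profiles(p0, theta_n=0.2, theta_c=0.3, v_n=0.0, v_c=0.0)
    blocks = F.actin_mass_residuals(prof, 0.0, p0)
    assert np.allclose(blocks["factin"], 0.0, atol=1e-15)
    assert np.allclose(blocks["gactin"], 0.0, atol=1e-15)


def test_total_actin_constraint_row(params):
    prof = uniform_profiles(params, theta_n=0.5 * params.mean_actin,
                            theta_c=0.5 * params.mean_actin)
    blocks = F.actin_mass_residuals(prof, 0.0, params)
    assert blocks["actin_total"][0] == pytest.approx(0.0, abs=1e-12)
    prof2 = uniform_profiles(params, theta_n=params.mean_actin,
                             theta_c=params.mean_actin)
    blocks2 = F.actin_mass_residuals(prof2, 0.0, params)
    assert blocks2["actin_total"][0] == pytest.approx(
        params.cell_length * params.mean_actin)


def test_factin_exponential_closed_form(params):
    """With constant relative flow u, theta_n ~ exp(-gamma x / u) is exact."""
    n = 201
    prof = uniform_profiles(params, n=n)
    gam = params.depolymerization_rate
    u = 0.02
    v0 = 0.0
    prof.v_n[:] = u
    prof.theta_n[:] = 0.4 * np.exp(-gam * prof.x / u)
    rows = F.actin_mass_residuals(prof, v0, params)["factin"][1:-1] / prof.h
    # second-order truncation only
    assert np.max(np.abs(rows)) < 5e-4 * gam * 0.4


# ---------------------------------------------------------------------------
# species transport and electroneutrality


def test_species_flux_uniform_state_is_advection_only(params):
    prof = uniform_profiles(params, v_c=0.0)
    j = F.species_flux_midpoints(prof.c_na, prof.phi, 0.0,
                                 params.diffusivity["na"], 1.0, params, prof.h)
    assert np.allclose(j, 0.0, atol=1e-14)


def test_species_flux_linear_profile_constant_flux(params):
    """Pure diffusion of a linear profile gives a constant flux."""
    prof = uniform_profiles(params, n=32, v_c=0.0)
    c = 10.0 + 0.5 * prof.x
    j = F.species_flux_midpoints(c, np.zeros_like(c), 0.0, 2.0, -1.0,
                                 params, prof.h)
    assert np.allclose(j, -2.0 * 0.5, rtol=1e-13)
    assert np.allclose(np.diff(j), 0.0, atol=1e-13)


def test_species_flux_matches_independent_nernst_planck(params):
    """Midpoint fluxes agree with a separately coded NP evaluator."""
    prof = smooth_profiles(params, 48)
    h = prof.h
    d, z, u = params.diffusivity["cl"], -1.0, 3e-4
    got = F.species_flux_midpoints(prof.c_cl, prof.phi, u, d, z, params, h)
    cm = 0.5 * (prof.c_cl[1:] + prof.c_cl[:-1])
    oracle = (-d * np.diff(prof.c_cl) / h + u * cm
              - d * z * params.f_mv / params.rt * cm * np.diff(prof.phi) / h)
    assert np.allclose(got, oracle, rtol=1e-12)


def test_electroneutrality_rows(params):
    prof = uniform_profiles(params, c_na=100.0, c_k=0.0, c_cl=100.0,
                            c_a=0.0, c_buf=0.0, ph=10.0)
    q = F.electroneutrality_residuals(prof, params)
    # tiny proton/bicarbonate contribution at pH 10 aside, Na+ balances Cl-
    assert np.allclose(q, prof.c_h() - prof.c_hco3(params), atol=1e-12)
    prof.c_k[:] += 1.0
    prof.__dict__.pop("_derived", None)
    q2 = F.electroneutrality_residuals(prof, params)
    assert np.allclose(q2 - q, 1.0)


def test_impermeant_constraint_quadrature(params):
    prof = uniform_profiles(params)
    r = F.impermeant_constraints(prof, params)
    assert r[0] == pytest.approx(0.0, abs=1e-9 * params.impermeant_total)
    assert r[1] == pytest.approx(0.0, abs=1e-9 * params.buffer_total)
    prof.c_a[:] *= 2.0
    r2 = F.impermeant_constraints(prof, params)
    assert r2[0] == pytest.approx(params.impermeant_total, rel=1e-12)


def test_impermeant_constraint_nonuniform_matches_trapezoid_oracle(params):
    prof = uniform_profiles(params, n=40)
    prof.c_a[:] = 60.0 + 10.0 * np.sin(2 * np.pi * prof.x / params.cell_length)
    r = F.impermeant_constraints(prof, params)
    oracle = params.cross_section * np.trapezoid(prof.c_a, prof.x) \
        - params.impermeant_total
    assert r[0] == pytest.approx(oracle, rel=1e-14)


# ---------------------------------------------------------------------------
# manufactured-solution convergence order


def test_bulk_blocks_are_second_order(params):
    orders = mms.observed_orders(params, n=64)
    for block, order in orders.items():
        assert order >= 1.9, f"block {block} converges at order {order:.2f}"
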