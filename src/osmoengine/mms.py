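"""Manufactured-solution truncation study for the bulk discretizations.

Smooth analytic profiles (sin/cos) are injected into the discrete residual
operators; subtracting the analytically evaluated continuous operator
leaves the truncation error, whose decay under grid refinement gives the
observed order of accuracy.  All interior (bulk) blocks of the scheme are
second order; this module measures that, it does not solve anything.
"""

from __future__ import annotations

import numpy as np

from . import fields as F
from .fields import FieldProfiles
from .params import ModelParameters

__all__ = ["manufactured_profiles", "truncation_errors", "observed_orders"]

_V0 = 1.0e-4
_VC = 2.0e-4


def _trig(amp, base, k, L):
    """(f, f', f'') for f = base + amp sin(k pi x / L)."""
    w = k * np.pi / L

    def f(x):
        return base + amp * np.sin(w * x)

    def d1(x):
        return amp * w * np.cos(w * x)

    def d2(x):
        return -amp * w * w * np.sin(w * x)

    return f, d1, d2


def _cos(amp, base, k, L):
    w = k * np.pi / L

    def f(x):
        return base + amp * np.cos(w * x)

    def d1(x):
        return -amp * w * np.sin(w * x)

    def d2(x):
        return -amp * w * w * np.cos(w * x)

    return f, d1, d2


def _fields(L):
    return {
        "p": _trig(200.0, 30000.0, 1, L),
        "v_n": _cos(0.01, 0.0, 1, L),
        "theta_n": _trig(0.1, 0.3, 2, L),
        "theta_c": _trig(-0.05, 0.25, 1, L),
        "c_na": _trig(3.0, 35.0, 1, L),
        "c_k": _cos(5.0, 100.0, 1, L),
        "c_cl": _trig(-4.0, 35.0, 2, L),
        "ph": _trig(0.1, 7.2, 1, L),
        "c_a": _cos(5.0, 65.0, 1, L),
        "c_buf": _trig(2.0, 25.0, 1, L),
        "phi": _trig(5.0, -45.0, 2, L),
    }


def manufactured_profiles(params: ModelParameters, n: int) -> FieldProfiles:
    L = params.cell_length
    x = np.linspace(0.0, L, n)
    fns = _fields(L)
    return FieldProfiles(
        x=x, v_c=_VC, **{name: fn[0](x) for name, fn in fns.items()})


def truncation_errors(params: ModelParameters, n: int) -> dict:
    """Max-norm truncation error of each bulk block on an N-node grid."""
    L = params.cell_length
    prof = manufactured_profiles(params, n)
    x, h = prof.x, prof.h
    fns = _fields(L)
    uc = _VC - _V0 if params.advection == "frame" else _VC
    eta, eta_st = params.interfacial_friction, params.adhesion_strength
    gam = params.depolymerization_rate
    out = {}

    # cytosol momentum rows live on interval midpoints
    xm = 0.5 * (x[1:] + x[:-1])
    p, p1, _ = fns["p"]
    vn, vn1, _ = fns["v_n"]
    tn, tn1, _ = fns["theta_n"]
    src = -p1(xm) - eta * tn(xm) * (_VC - vn(xm))
    out["cytosol_momentum"] = np.max(np.abs(
        F.cytosol_residuals(prof, params) - src))

    # network momentum rows at nodes (interior; boundary rows are one-sided)
    k_sig = params.actin_stiffness
    src = (-k_sig * tn1(x) + eta * tn(x) * (_VC - vn(x)) - eta_st * tn(x) * vn(x))
    out["network_momentum"] = np.max(np.abs(
        F.network_residuals(prof, params)[1:-1] - src[1:-1]))

    # actin conservation, interior finite-volume rows scaled by 1/h
    actin = F.actin_mass_residuals(prof, _V0, params)
    un = (lambda xx: vn(xx) - _V0) if params.advection == "frame" else vn
    un1 = vn1
    src_f = un(x) * tn1(x) + un1(x) * tn(x) + gam * tn(x)
    out["factin"] = np.max(np.abs(actin["factin"][1:-1] / h - src_f[1:-1]))
    tc, tc1, tc2 = fns["theta_c"]
    src_g = uc * tc1(x) - params.gactin_diffusivity * tc2(x) - gam * tn(x)
    out["gactin"] = np.max(np.abs(actin["gactin"][:-1] / h - src_g[1:-1]))

    # electrodiffusive species: d/dx of the Nernst-Planck flux
    phi, phi1, phi2 = fns["phi"]
    for name in ("na", "k", "cl", "a"):
        c, c1, c2 = fns[f"c_{name}"]
        d = params.diffusivity[name]
        z = params.valence(name)
        jmid = F.species_flux_midpoints(prof.concentration(name, params),
                                        prof.phi, uc, d, z, params, h)
        djdx = (-d * c2(x) + uc * c1(x)
                - d * z / params.rt_over_f * (c1(x) * phi1(x) + c(x) * phi2(x)))
        out[name] = np.max(np.abs(np.diff(jmid) / h - djdx[1:-1]))
    return out


def observed_orders(params: ModelParameters, n: int = 64) -> dict:
    """Observed convergence order per bulk block between grids N and 2N."""
    e1, e2 = truncation_errors(params, n), truncation_errors(params, 2 * n - 1)
    return {k: float(np.log2(e1[k] / e2[k])) for k in e1}
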