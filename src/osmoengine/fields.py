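"""Bulk residual equations on the 1D moving-frame domain x in [0, L].

Orientation: back of the cell at x = 0, front at x = L; positive v0 means
migration toward the front.  All transport is discretized as a
vertex-centred finite-volume scheme on a uniform grid: fluxes are evaluated
at interval midpoints, conservation rows at nodes, and the half-cells at
the two boundaries carry the membrane fluxes directly.  The scheme
telescopes exactly, so imposing every node row forces the steady
front/back membrane flux balance per species at the solution.

Advection uses frame-relative velocities (v - v0) by default, which is what
steadiness in the cell frame requires and what makes the actin conservation
structure close exactly; ``advection: lab`` reproduces the printed
lab-velocity form of the bulk fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import acidbase
from .errors import InvalidInputError
from .membrane import EndState, MembraneFluxes, actin_polymerization_flux
from .params import ModelParameters, SPECIES_NAMES

__all__ = [
    "FieldProfiles",
    "end_state_from_profiles",
    "cytosol_residuals",
    "network_residuals",
    "actin_mass_residuals",
    "species_flux_midpoints",
    "species_transport_residuals",
    "electroneutrality_residuals",
    "impermeant_constraints",
    "global_force_balance",
]

#: regularization (mM) keeping the network momentum balance well-posed as
#: theta_n -> 0 (e.g. the latrunculin-A condition, where F-actin vanishes)
THETA_REG = 1.0e-8


@dataclass
class FieldProfiles:
    """Spatial profiles of all primary unknowns plus the scalar v_c.

    Derived fields (protons, bicarbonate, protonated buffer) are always
    recomputed from pH and c_Buf, never stored.
    """

    x: np.ndarray  # um, uniform, x[0]=0, x[-1]=L
    p: np.ndarray  # Pa
    v_n: np.ndarray  # um/s
    theta_n: np.ndarray  # mM
    theta_c: np.ndarray  # mM
    c_na: np.ndarray
    c_k: np.ndarray
    c_cl: np.ndarray
    ph: np.ndarray
    c_a: np.ndarray
    c_buf: np.ndarray
    phi: np.ndarray  # mV
    v_c: float  # um/s (spatially constant by conservation of cytosol mass)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def h(self) -> float:
        return float(self.x[1] - self.x[0])

    def _cache(self) -> dict:
        # lazy per-instance memo for derived fields; valid because profiles
        # are rebuilt (not mutated) on every solver unpack
        d = self.__dict__.get("_derived")
        if d is None:
            d = self.__dict__["_derived"] = {}
        return d

    def c_h(self) -> np.ndarray:
        cache = self._cache()
        if "h" not in cache:
            cache["h"] = acidbase.proton_from_ph(self.ph)
        return cache["h"]

    def c_hco3(self, params: ModelParameters) -> np.ndarray:
        cache = self._cache()
        if "hco3" not in cache:
            cache["hco3"] = acidbase.bicarbonate_from_ph(
                self.ph, params.pco2, params.henry_constant, params.pk_c)
        return cache["hco3"]

    def c_hbuf(self, params: ModelParameters) -> np.ndarray:
        cache = self._cache()
        if "hbuf" not in cache:
            cache["hbuf"] = acidbase.buffer_partition(self.ph, self.c_buf, params.pk_b)
        return cache["hbuf"]

    def concentration(self, name: str, params: ModelParameters) -> np.ndarray:
        if name == "h":
            return self.c_h()
        if name == "hco3":
            return self.c_hco3(params)
        if name == "hbuf":
            return self.c_hbuf(params)
        return getattr(self, f"c_{name}")

    def all_concentrations(self, params: ModelParameters) -> dict:
        return {n: self.concentration(n, params) for n in SPECIES_NAMES}

    def total_concentration(self, params: ModelParameters) -> np.ndarray:
        return sum(self.all_concentrations(params).values())

    def copy(self) -> "FieldProfiles":
        return replace(self, **{
            f: getattr(self, f).copy()
            for f in ("x", "p", "v_n", "theta_n", "theta_c", "c_na", "c_k",
                      "c_cl", "ph", "c_a", "c_buf", "phi")
        })

    def to_frame(self, params: ModelParameters) -> pd.DataFrame:
        """Columnar node table (one row per node) for inspection/serialization."""
        d = {"x": self.x, "p": self.p, "v_n": self.v_n,
             "theta_n": self.theta_n, "theta_c": self.theta_c,
             "c_na": self.c_na, "c_k": self.c_k, "c_cl": self.c_cl,
             "ph": self.ph, "c_a": self.c_a, "c_buf": self.c_buf,
             "phi": self.phi,
             "c_h": self.c_h(), "c_hco3": self.c_hco3(params),
             "c_hbuf": self.c_hbuf(params)}
        return pd.DataFrame(d)


def _advection(v, v0: float, params: ModelParameters):
    return v - v0 if params.advection == "frame" else v


def end_state_from_profiles(prof: FieldProfiles, v0: float, end: str,
                            params: ModelParameters) -> EndState:
    """Extract the membrane-facing local state at one end of the domain."""
    i = prof.n - 1 if end == "front" else 0
    conc = {n: float(prof.concentration(n, params)[i]) for n in SPECIES_NAMES}
    return EndState(
        end=end,
        cytosol_pressure=float(prof.p[i]),
        network_stress=params.actin_stiffness * float(prof.theta_n[i]),
        potential_jump=float(prof.phi[i]) - params.extracellular_potential,
        ph=float(prof.ph[i]),
        gactin=float(prof.theta_c[i]),
        concentrations=conc,
        v0=v0,
    )


# ---------------------------------------------------------------------------
# mechanics


def cytosol_residuals(prof: FieldProfiles, params: ModelParameters) -> np.ndarray:
    """Cytosol momentum rows on the N-1 intervals: -dp/dx - eta theta_n (v_c - v_n).

    v_c spatial constancy is structural (a single scalar unknown); its two
    boundary closures live with the water fluxes in the solver assembly.
    """
    h = prof.h
    tn_mid = 0.5 * (prof.theta_n[1:] + prof.theta_n[:-1])
    vn_mid = 0.5 * (prof.v_n[1:] + prof.v_n[:-1])
    dpdx = np.diff(prof.p) / h
    return -dpdx - params.interfacial_friction * tn_mid * (prof.v_c - vn_mid)


def network_residuals(prof: FieldProfiles, params: ModelParameters) -> np.ndarray:
    """Actin-network momentum rows at every node.

    -d(sigma_n)/dx + eta theta_n (v_c - v_n) - eta_st theta_n v_n = 0 with
    sigma_n = k_sigma theta_n.  The friction coefficients carry a tiny
    additive theta regularization so v_n stays determined when the network
    vanishes (latrunculin-A).
    """
    h = prof.h
    sig = params.actin_stiffness * prof.theta_n
    dsig = np.empty(prof.n)
    dsig[1:-1] = (sig[2:] - sig[:-2]) / (2 * h)
    dsig[0] = (-3 * sig[0] + 4 * sig[1] - sig[2]) / (2 * h)
    dsig[-1] = (3 * sig[-1] - 4 * sig[-2] + sig[-3]) / (2 * h)
    th = prof.theta_n + THETA_REG
    return (-dsig + params.interfacial_friction * th * (prof.v_c - prof.v_n)
            - params.adhesion_strength * th * prof.v_n)


def actin_mass_residuals(prof: FieldProfiles, v0: float,
                         params: ModelParameters) -> dict:
    """F- and G-actin conservation rows.

    Returns a dict with blocks:

    - ``factin``: N rows; half-cell rows at both boundaries carry the
      membrane conditions (zero network flux at the back; polymerization
      influx -J_actin at the front, i.e. theta_n (v0 - v_n) = J_actin).
    - ``gactin``: N-1 rows (interior half of the second-order monomer
      balance plus the front flux row, where the relative monomer flux into
      the membrane equals the polymerization sink +J_actin).
    - ``actin_total``: 1 row, the conservation integral
      int (theta_n + theta_c) dx = L theta_*, which replaces the G-actin
      back-boundary row (that condition is implied by discrete conservation
      and is reported as a diagnostic instead).
    """
    h, n = prof.h, prof.n
    gam = params.depolymerization_rate
    un = _advection(prof.v_n, v0, params)
    uc = _advection(prof.v_c, v0, params)

    j_actin = actin_polymerization_flux(float(prof.theta_c[-1]),
                                        params.front.j_actin,
                                        params.polymerization_saturation)

    # F-actin: first-order advection with distributed depolymerization sink
    un_mid = 0.5 * (un[1:] + un[:-1])
    tn_mid = 0.5 * (prof.theta_n[1:] + prof.theta_n[:-1])
    phi_n = un_mid * tn_mid
    factin = np.empty(n)
    factin[0] = (phi_n[0] - 0.0) + 0.5 * h * gam * prof.theta_n[0]
    factin[1:-1] = np.diff(phi_n) + h * gam * prof.theta_n[1:-1]
    factin[-1] = (-j_actin - phi_n[-1]) + 0.5 * h * gam * prof.theta_n[-1]

    # G-actin: advection-diffusion with the matching source
    tc_mid = 0.5 * (prof.theta_c[1:] + prof.theta_c[:-1])
    dtc = np.diff(prof.theta_c) / h
    phi_c = uc * tc_mid - params.gactin_diffusivity * dtc
    gactin = np.empty(n - 1)
    gactin[:-1] = np.diff(phi_c) - h * gam * prof.theta_n[1:-1]
    gactin[-1] = (j_actin - phi_c[-1]) - 0.5 * h * gam * prof.theta_n[-1]

    total = np.trapezoid(prof.theta_n + prof.theta_c, prof.x) \
        - params.cell_length * params.mean_actin
    return {"factin": factin, "gactin": gactin,
            "actin_total": np.array([total])}


# ---------------------------------------------------------------------------
# electrodiffusive transport


def species_flux_midpoints(c: np.ndarray, phi: np.ndarray, u: float,
                           diffusivity: float, valence: float,
                           params: ModelParameters, h: float) -> np.ndarray:
    """Nernst-Planck flux at the N-1 interval midpoints.

    J = -D dc/dx + u c - D (z F / RT) c dphi/dx, with u the (scalar)
    advection velocity.  The advective term switches to donor-cell
    upwinding when the cell Peclet number |u| h / D exceeds 2; at the
    parameter scales of this model that never triggers and the scheme stays
    second order.
    """
    dc = np.diff(c) / h
    dphi = np.diff(phi) / h
    if diffusivity <= 0:
        raise InvalidInputError("diffusivity must be positive")
    if abs(u) * h / diffusivity > 2.0:
        c_adv = c[:-1] if u > 0 else c[1:]
    else:
        c_adv = 0.5 * (c[1:] + c[:-1])
    c_mid = 0.5 * (c[1:] + c[:-1])
    drift = -(diffusivity * valence / params.rt_over_f) * c_mid * dphi
    return -diffusivity * dc + u * c_adv + drift


def _family_rows(flux_mid: np.ndarray, j_back: float, j_front: float) -> np.ndarray:
    """Finite-volume rows for one conserved family with membrane BCs.

    Inward-positive membrane fluxes translate to continuum boundary fluxes
    J(0) = +J_back and J(L) = -J_front.
    """
    n = flux_mid.size + 1
    rows = np.empty(n)
    rows[0] = flux_mid[0] - j_back
    rows[1:-1] = np.diff(flux_mid)
    rows[-1] = (-j_front) - flux_mid[-1]
    return rows


def species_transport_residuals(prof: FieldProfiles, v0: float,
                                flux_front: MembraneFluxes,
                                flux_back: MembraneFluxes,
                                params: ModelParameters) -> dict:
    """Transport rows for Na+, K+, Cl-, the combined pH family, A- and buffer.

    pH is the primary unknown of the combined H+/HCO3-/buffer balance; its
    transported flux is J_HCO3 + J_Buf - J_H with the derived concentrations
    substituted algebraically.  The buffer-total family (Buf- + HBuf) and the
    impermeant A- have zero membrane flux; their amplitude rows (conservation
    integrals) are attached by the solver assembly.
    """
    h = prof.h
    uc = float(_advection(np.asarray(prof.v_c), v0, params))
    d = params.diffusivity

    def flux(name):
        return species_flux_midpoints(prof.concentration(name, params), prof.phi,
                                      uc, d[name], params.valence(name), params, h)

    tot_f, tot_b = flux_front.totals, flux_back.totals
    out = {}
    for name in ("na", "k", "cl"):
        out[name] = _family_rows(flux(name), tot_b[name], tot_f[name])
    acid_mid = flux("hco3") + flux("buf") - flux("h")
    out["ph"] = _family_rows(acid_mid, flux_back.acid_family, flux_front.acid_family)
    out["a"] = _family_rows(flux("a"), 0.0, 0.0)
    out["buf"] = _family_rows(flux("buf") + flux("hbuf"), 0.0, 0.0)
    return out


def electroneutrality_residuals(prof: FieldProfiles,
                                params: ModelParameters) -> np.ndarray:
    """Sum z_n c_n at every node (mM of net charge); pairs with phi."""
    c = prof.all_concentrations(params)
    return sum(params.valence(n) * c[n] for n in SPECIES_NAMES)


def impermeant_constraints(prof: FieldProfiles,
                           params: ModelParameters) -> np.ndarray:
    """The two impermeant conservation rows (trapezoidal quadrature).

    S int c_A dx = N_A  and  S int (c_Buf + c_HBuf) dx = N_Buf + N_HBuf.
    """
    s = params.cross_section
    r1 = s * np.trapezoid(prof.c_a, prof.x) - params.impermeant_total
    r2 = s * np.trapezoid(prof.c_buf + prof.c_hbuf(params), prof.x) \
        - params.buffer_total
    return np.array([r1, r2])


def global_force_balance(prof: FieldProfiles, flux_front: MembraneFluxes,
                         flux_back: MembraneFluxes, params: ModelParameters,
                         v0: float) -> float:
    """Whole-cell force balance row, paired with the unknown v0.

    As printed, the hydraulic-resistance term uses the front water flux only;
    the ``symmetrized`` variant applies each end's resistance to its own
    flux.  Adhesion traction integrates lab-frame network velocity.
    """
    p0f, p0b = params.front.external_pressure, params.back.external_pressure
    dgf, dgb = params.front.hydraulic_resistance, params.back.hydraulic_resistance
    traction = params.adhesion_strength * np.trapezoid(prof.theta_n * prof.v_n, prof.x)
    if params.force_balance == "printed":
        hydraulic = (dgf + dgb) * (v0 - flux_front.water)
    else:
        hydraulic = dgf * (v0 - flux_front.water) + dgb * (v0 + flux_back.water)
    return float(-(p0f - p0b) - hydraulic - traction - params.wall_friction * v0)
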