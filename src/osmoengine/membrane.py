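"""Per-end membrane flux laws and gating functions.

All boundary fluxes are positive-inward at their own end (one convention,
asserted in tests); the bulk-equation module applies the end-specific signs
when it ties membrane fluxes to the interior transport problem.

Water flux and the external effective pressure are mutually implicit (the
hydraulic pressure just outside a moving end depends on the water flux
through it); :func:`resolve_water` eliminates that 2-variable linear system
per end in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidInputError, ParameterError
from .params import MembraneEndParameters, ModelParameters

__all__ = [
    "EndState",
    "MembraneFluxes",
    "external_pressure",
    "water_flux",
    "resolve_water",
    "membrane_tension",
    "gate_mechanosensitive",
    "gate_nke_voltage",
    "gate_nhe",
    "gate_ae2",
    "passive_ion_flux",
    "nke_flux",
    "nhe_flux",
    "ae2_flux",
    "actin_polymerization_flux",
    "assemble_boundary_fluxes",
]


@dataclass
class EndState:
    """Local state at one membrane end, as seen by the flux laws."""

    end: str  # 'front' or 'back'
    cytosol_pressure: float  # Pa
    network_stress: float  # Pa, sigma_n = k_sigma * theta_n at this end
    potential_jump: float  # mV, V_m = phi(end) - phi_0
    ph: float
    gactin: float  # mM, theta_c at this end
    concentrations: dict = field(default_factory=dict)  # mM per species name
    v0: float = 0.0  # cell velocity, needed by the hydraulic coupling


@dataclass
class MembraneFluxes:
    """Total and per-mechanism boundary fluxes at one end (positive inward)."""

    end: str
    water: float  # um/s
    external_effective_pressure: float  # Pa, p_*
    tension: float  # Pa um, tau_m
    gate_m: float
    gate_v: float
    gate_nhe: float
    gate_ae2: float
    passive: dict = field(default_factory=dict)  # na/k/cl
    nke: dict = field(default_factory=dict)  # na/k
    nhe: dict = field(default_factory=dict)  # na/h
    ae2: dict = field(default_factory=dict)  # cl/hco3
    actin: float = 0.0  # mM um/s, front only

    @property
    def totals(self) -> dict:
        """Per-species total fluxes; buffer and impermeant A- are always 0."""
        return {
            "na": self.passive["na"] + self.nke["na"] + self.nhe["na"],
            "k": self.passive["k"] + self.nke["k"],
            "cl": self.passive["cl"] + self.ae2["cl"],
            "h": self.nhe["h"],
            "hco3": self.ae2["hco3"],
            "a": 0.0,
            "buf": 0.0,
            "hbuf": 0.0,
        }

    @property
    def acid_family(self) -> float:
        """Combined boundary flux of the pH family, J_HCO3 + J_Buf - J_H."""
        return self.totals["hco3"] - self.totals["h"]


# ---------------------------------------------------------------------------
# elementary laws


def external_pressure(end: str, v0: float, j_water: float, d_g: float, p0: float) -> float:
    """Effective hydraulic pressure just outside one end.

    Front: p_* = p0 + d_g (v0 - J_water); back: p_* = p0 - d_g (v0 + J_water).
    A cell advancing into the front channel segment compresses the fluid
    column ahead of it, hence the sign asymmetry.
    """
    if d_g < 0:
        raise ParameterError("hydraulic_resistance d_g must be non-negative")
    if end == "front":
        return p0 + d_g * (v0 - j_water)
    if end == "back":
        return p0 - d_g * (v0 + j_water)
    raise InvalidInputError(f"unknown end label {end!r}")


def water_flux(p: float, p_star: float, c_total: float, c0_total: float,
               alpha: float, rt: float) -> float:
    """Osmotic water flux J = -alpha [(p - p_*) - RT (c - c0)], positive inward."""
    if alpha < 0:
        raise ParameterError("water_permeability alpha must be non-negative")
    return -alpha * ((p - p_star) - rt * (c_total - c0_total))


def resolve_water(end: str, p: float, c_total: float, c0_total: float,
                  v0: float, endp: MembraneEndParameters, rt: float):
    """Solve the implicit water-flux / external-pressure pair at one end.

    Substituting the hydraulic relation into the osmotic law gives the
    closed form J (1 + alpha d_g) = -alpha [(p - p0 -+ d_g v0) - RT dc];
    returns (j_water, p_star).  Identical to leaving both as unknowns of the
    global Newton system (the relation is linear).
    """
    a, d, p0 = endp.water_permeability, endp.hydraulic_resistance, endp.external_pressure
    sgn = 1.0 if end == "front" else -1.0
    base = (p - p0 - sgn * d * v0) - rt * (c_total - c0_total)
    j = -a * base / (1.0 + a * d)
    return j, external_pressure(end, v0, j, d, p0)


def membrane_tension(sigma_n: float, p_c: float, p_star: float, b: float) -> float:
    """Cortex/membrane tension from the normal force balance, tau = b/2 (sigma_n + p_c - p_*)."""
    if b <= 0:
        raise ParameterError("membrane_thickness_factor b must be positive")
    return 0.5 * b * (sigma_n + p_c - p_star)


def _logistic(x):
    # numerically safe logistic, exact 0/1 saturation at large |x|
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def gate_mechanosensitive(tau_m: float, beta1: float, beta2: float) -> float:
    """Boltzmann tension gate G_m in (0,1), increasing in tension for beta1 > 0."""
    return float(_logistic(beta1 * (tau_m - beta2)))


def gate_nke_voltage(v_m: float, beta3: float, beta4: float) -> float:
    """Voltage dependence of the Na/K pump, in (-1,1), zero at v_m = beta4."""
    return float(2.0 * _logistic(beta3 * (v_m - beta4)) - 1.0)


def gate_nhe(ph: float, beta5: float, beta6: float) -> float:
    """NHE pH gate in (0,1): active in acidic cytosol, quiescent at high pH."""
    return float(_logistic(-beta5 * (ph - beta6)))


def gate_ae2(ph: float, beta7: float, beta8: float) -> float:
    """AE2 pH gate in (0,1): quiescent in acidic cytosol, active at high pH."""
    return float(_logistic(beta7 * (ph - beta8)))


def passive_ion_flux(gamma_n: float, z_n: float, v_m: float, g_m: float,
                     alpha: float, rt: float, f_mv: float) -> float:
    """Tension-gated electrodiffusive leak J = alpha G_m [RT ln Gamma - z F V_m].

    Vanishes exactly at the Nernst potential V_m = (RT/zF) ln Gamma.
    """
    if gamma_n <= 0:
        raise InvalidInputError("concentration ratio Gamma must be positive")
    return alpha * g_m * (rt * math.log(gamma_n) - z_n * f_mv * v_m)


def nke_flux(gamma_na: float, gamma_k: float, v_m: float, alpha_nke: float,
             beta_na: float, beta_k: float, beta3: float, beta4: float):
    """Na/K pump fluxes (J_Na, J_K): 3 Na+ out / 2 K+ in per cycle.

    Hill saturation in both substrate ratios; the overall cycle is gated by
    membrane potential through :func:`gate_nke_voltage`.
    """
    if gamma_na <= 0 or gamma_k <= 0:
        raise InvalidInputError("concentration ratios must be positive")
    g_v = gate_nke_voltage(v_m, beta3, beta4)
    j_na = -alpha_nke * g_v * (1.0 + beta_na * gamma_na) ** -3 * (1.0 + beta_k / gamma_k) ** -2
    return j_na, -(2.0 / 3.0) * j_na


def nhe_flux(gamma_na: float, gamma_h: float, ph: float, alpha_nhe: float,
             beta5: float, beta6: float, rt: float):
    """Na+/H+ exchanger fluxes (J_Na, J_H): electroneutral 1:1 antiport."""
    if gamma_na <= 0 or gamma_h <= 0:
        raise InvalidInputError("concentration ratios must be positive")
    g = gate_nhe(ph, beta5, beta6)
    j_na = alpha_nhe * g * rt * (math.log(gamma_na) - math.log(gamma_h))
    return j_na, -j_na


def ae2_flux(gamma_cl: float, gamma_hco3: float, ph: float, alpha_ae2: float,
             beta7: float, beta8: float, rt: float):
    """Cl-/HCO3- exchanger fluxes (J_Cl, J_HCO3): electroneutral 1:1 antiport."""
    if gamma_cl <= 0 or gamma_hco3 <= 0:
        raise InvalidInputError("concentration ratios must be positive")
    g = gate_ae2(ph, beta7, beta8)
    j_cl = alpha_ae2 * g * rt * (math.log(gamma_cl) - math.log(gamma_hco3))
    return j_cl, -j_cl


def actin_polymerization_flux(theta_c_front: float, j_actin_max: float,
                              theta_cc: float) -> float:
    """Front polymerization rate J = J^f theta_c / (theta_cc + theta_c).

    Saturating in available G-actin: 0 at theta_c = 0, half-maximal at
    theta_c = theta_cc, approaching J^f at saturation.
    """
    if theta_cc <= 0:
        raise ParameterError("polymerization_saturation theta_cc must be positive")
    if theta_c_front < 0:
        # transient Newton iterates may dip below zero; treat as no monomer
        return 0.0
    return j_actin_max * theta_c_front / (theta_cc + theta_c_front)


# ---------------------------------------------------------------------------
# end assembly


def assemble_boundary_fluxes(end_state: EndState, endp: MembraneEndParameters,
                             params: ModelParameters) -> MembraneFluxes:
    """Evaluate all membrane fluxes at one end from its local state.

    Resolves the water/external-pressure pair, evaluates tension and all
    four gates, then the passive, pump and exchanger pathways.  Buffer and
    impermeant A- fluxes are identically zero.
    """
    end = end_state.end
    if end not in ("front", "back"):
        raise InvalidInputError(f"unknown end label {end!r}")
    rt, f_mv = params.rt, params.f_mv
    g = params.gating
    c = end_state.concentrations
    c_total = sum(c[n] for n in c)
    c0_total = params.external_total(end)

    j_water, p_star = resolve_water(
        end, end_state.cytosol_pressure, c_total, c0_total, end_state.v0, endp, rt)
    tau = membrane_tension(end_state.network_stress, end_state.cytosol_pressure,
                           p_star, params.membrane_thickness_factor)
    if g.clamp_gm is not None:
        g_m = float(g.clamp_gm)
    else:
        g_m = gate_mechanosensitive(tau, g.beta1, g.beta2)
    v_m = end_state.potential_jump

    def gamma(name):
        cn = c[name]
        if cn <= 0:
            raise InvalidInputError(
                f"non-positive intracellular concentration of {name!r} at {end}")
        return params.external_concentration(name, end) / cn

    passive = {
        n: passive_ion_flux(gamma(n), params.valence(n), v_m, g_m,
                            getattr(endp, f"alpha_{n}"), rt, f_mv)
        for n in ("na", "k", "cl")
    }
    j_nke_na, j_nke_k = nke_flux(gamma("na"), gamma("k"), v_m, endp.alpha_nke,
                                 params.nke.beta_na, params.nke.beta_k,
                                 g.beta3, g.beta4)
    j_nhe_na, j_nhe_h = nhe_flux(gamma("na"), gamma("h"), end_state.ph,
                                 endp.alpha_nhe, g.beta5, g.beta6, rt)
    j_ae2_cl, j_ae2_hco3 = ae2_flux(gamma("cl"), gamma("hco3"), end_state.ph,
                                    endp.alpha_ae2, g.beta7, g.beta8, rt)
    actin = 0.0
    if endp.j_actin > 0:
        actin = actin_polymerization_flux(end_state.gactin, endp.j_actin,
                                          params.polymerization_saturation)
    return MembraneFluxes(
        end=end,
        water=j_water,
        external_effective_pressure=p_star,
        tension=tau,
        gate_m=g_m,
        gate_v=gate_nke_voltage(v_m, g.beta3, g.beta4),
        gate_nhe=gate_nhe(end_state.ph, g.beta5, g.beta6),
        gate_ae2=gate_ae2(end_state.ph, g.beta7, g.beta8),
        passive=passive,
        nke={"na": j_nke_na, "k": j_nke_k},
        nhe={"na": j_nhe_na, "h": j_nhe_h},
        ae2={"cl": j_ae2_cl, "hco3": j_ae2_hco3},
        actin=actin,
    )
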