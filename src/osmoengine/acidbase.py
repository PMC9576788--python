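"""Acid-base and buffer equilibria shared by every module.

The model carries pH (not proton concentration) as the primary unknown;
proton, bicarbonate and protonated-buffer concentrations are algebraic
functions of pH evaluated on demand so derived fields can never drift out
of sync with the state they are computed from.

Unit convention (package-wide): concentrations in mM, which equals
attomol/um^3, so RT*c carries pressure units (Pa) directly.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError, ParameterError

__all__ = [
    "proton_from_ph",
    "bicarbonate_from_ph",
    "buffer_partition",
]


def proton_from_ph(ph):
    """Free proton concentration in mM from pH.

    pH is defined on the molar scale, so c_H [mM] = 10^3 * 10^(-pH).
    Strictly decreasing in pH.
    """
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise InvalidInputError("pH must be finite")
    out = 1.0e3 * np.power(10.0, -ph)
    return out if out.ndim else float(out)


def bicarbonate_from_ph(ph, pco2, k_h, pk_c):
    """Bicarbonate concentration (mM) in equilibrium with dissolved CO2.

    CO2 crosses the membrane freely, so the same dissolved-CO2 level
    P_CO2/k_H applies intra- and extracellularly and

        c_HCO3 = (P_CO2 / k_H) * 10^(pH - pK_c).
    """
    if k_h <= 0:
        raise ParameterError("henry_constant k_H must be positive")
    ph = np.asarray(ph, dtype=float)
    out = (pco2 / k_h) * np.power(10.0, ph - pk_c)
    return out if out.ndim else float(out)


def buffer_partition(ph, c_buf, pk_b):
    """Protonated-buffer concentration c_HBuf (mM) from pH and free buffer.

    HBuf <-> H+ + Buf- at equilibrium gives c_HBuf = c_Buf * 10^(pK_B - pH):
    linear in c_Buf and strictly decreasing in pH.
    """
    c_buf = np.asarray(c_buf, dtype=float)
    if np.any(c_buf < 0):
        raise InvalidInputError("c_Buf must be non-negative")
    ph = np.asarray(ph, dtype=float)
    out = c_buf * np.power(10.0, pk_b - ph)
    return out if out.ndim else float(out)
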