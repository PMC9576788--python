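"""Model parameters: loading, validation, and the ion-species registry.

A single conversion layer lives here: concentrations are mM (attomol/um^3),
lengths um, pressures Pa, time s, potentials mV.  With those choices
``RT = gas_constant * temperature`` multiplies a concentration in mM to give
Pa directly, and ``F/1000`` multiplies (mM * mV) to give Pa, so no further
unit juggling happens anywhere else in the package.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .acidbase import bicarbonate_from_ph, proton_from_ph, buffer_partition
from .errors import ParameterError

__all__ = [
    "IonSpecies",
    "ExternalBath",
    "MembraneEndParameters",
    "GatingConstants",
    "NkeScalings",
    "ModelParameters",
    "default_parameters",
    "load_parameters",
    "parameters_from_dict",
    "validate_parameters",
    "with_overrides",
    "get_override_path",
]

#: canonical species names, fixed order used by every profile array bundle
SPECIES_NAMES = ("na", "k", "cl", "h", "hco3", "a", "buf", "hbuf")

_VALENCES_FIXED = {"na": 1, "k": 1, "cl": -1, "h": 1, "hco3": -1, "hbuf": 0}


@dataclass(frozen=True)
class IonSpecies:
    """One chemical species of the transport model."""

    name: str
    valence: float
    diffusivity: float  # um^2/s
    external_concentration: float  # mM (front-end bath; may differ per end)

    def __post_init__(self):
        if self.diffusivity <= 0:
            raise ParameterError(f"diffusivity of species {self.name!r} must be positive")


@dataclass(frozen=True)
class ExternalBath:
    """Extracellular solute composition at one end of the channel."""

    na: float
    k: float
    cl: float
    a: float = 0.0
    g: float = 0.0
    ph: float = 7.4

    def proton(self) -> float:
        return proton_from_ph(self.ph)

    def bicarbonate(self, pco2: float, k_h: float, pk_c: float) -> float:
        return bicarbonate_from_ph(self.ph, pco2, k_h, pk_c)

    def total(self, pco2: float, k_h: float, pk_c: float) -> float:
        """Total external osmolyte concentration entering the water flux."""
        return (
            self.na + self.k + self.cl + self.a + self.g
            + self.proton() + self.bicarbonate(pco2, k_h, pk_c)
        )


@dataclass(frozen=True)
class MembraneEndParameters:
    """Membrane transport coefficients at one end (front or back).

    Channel polarization (SWELL1, NHE1, aquaporins) is encoded purely as
    front/back asymmetry of these coefficients.
    """

    water_permeability: float  # um/(s Pa)
    hydraulic_resistance: float  # Pa s/um
    external_pressure: float = 0.0  # Pa
    alpha_na: float = 0.0  # passive permeabilities, pre-scaled to mM um/s flux
    alpha_k: float = 0.0
    alpha_cl: float = 0.0
    alpha_nke: float = 0.0
    alpha_nhe: float = 0.0
    alpha_ae2: float = 0.0
    j_actin: float = 0.0  # mM um/s; must be 0 at the back
    external: Optional[ExternalBath] = None  # per-end bath override (shock scenarios)


@dataclass(frozen=True)
class GatingConstants:
    beta1: float  # mechanosensitive sharpness, 1/(Pa um)
    beta2: float  # mechanosensitive midpoint, Pa um
    beta3: float  # pump voltage sharpness, 1/mV
    beta4: float  # pump voltage midpoint, mV
    beta5: float  # NHE pH sharpness
    beta6: float  # NHE pH midpoint
    beta7: float  # AE2 pH sharpness
    beta8: float  # AE2 pH midpoint
    clamp_gm: Optional[float] = None  # diagnostic override of G_m


@dataclass(frozen=True)
class NkeScalings:
    beta_na: float
    beta_k: float


@dataclass(frozen=True)
class ModelParameters:
    """Every constant of the coupled mechanical/electrodynamic model."""

    cell_length: float  # um
    cross_section: float  # um^2
    interfacial_friction: float  # Pa s/(mM um^2)
    adhesion_strength: float  # Pa s/(mM um^2)
    wall_friction: float  # Pa s/um
    depolymerization_rate: float  # 1/s
    gactin_diffusivity: float  # um^2/s
    actin_stiffness: float  # Pa/mM
    mean_actin: float  # mM
    polymerization_saturation: float  # mM
    membrane_thickness_factor: float  # um
    gas_constant: float
    temperature: float
    faraday: float
    henry_constant: float
    pco2: float
    pk_c: float
    pk_b: float
    extracellular_ph: float
    extracellular_potential: float  # mV
    external: ExternalBath
    impermeant_total: float  # attomol, N_A
    buffer_total: float  # attomol, N_Buf + N_HBuf
    impermeant_valence: float
    buffer_valence: float
    diffusivity: dict = field(default_factory=dict)  # um^2/s per species name
    gating: GatingConstants = None
    nke: NkeScalings = None
    front: MembraneEndParameters = None
    back: MembraneEndParameters = None
    advection: str = "frame"  # 'frame' or 'lab'
    force_balance: str = "printed"  # 'printed' or 'symmetrized'

    # ---- derived thermodynamic quantities (one conversion layer) ----

    @property
    def rt(self) -> float:
        """RT in Pa per mM."""
        return self.gas_constant * self.temperature

    @property
    def f_mv(self) -> float:
        """F scaled so that f_mv * (c in mM) * (V in mV) is in Pa."""
        return self.faraday / 1000.0

    @property
    def rt_over_f(self) -> float:
        """Thermal voltage RT/F in mV."""
        return self.rt / self.f_mv

    @property
    def volume(self) -> float:
        """Cell volume S*L in um^3."""
        return self.cross_section * self.cell_length

    def valence(self, name: str) -> float:
        if name == "a":
            return self.impermeant_valence
        if name == "buf":
            return self.buffer_valence
        return _VALENCES_FIXED[name]

    def bath(self, end: str) -> ExternalBath:
        """Extracellular bath seen by one end ('front' or 'back')."""
        endp = self.end(end)
        bath = endp.external if endp.external is not None else self.external
        return bath

    def end(self, end: str) -> MembraneEndParameters:
        if end == "front":
            return self.front
        if end == "back":
            return self.back
        raise ParameterError(f"unknown end label {end!r}; expected 'front' or 'back'")

    def external_concentration(self, name: str, end: str) -> float:
        bath = self.bath(end)
        if name == "h":
            return bath.proton()
        if name == "hco3":
            return bath.bicarbonate(self.pco2, self.henry_constant, self.pk_c)
        if name in ("buf", "hbuf"):
            return 0.0  # buffer does not cross the membrane
        if name == "a":
            return bath.a
        return getattr(bath, name)

    def external_total(self, end: str) -> float:
        return self.bath(end).total(self.pco2, self.henry_constant, self.pk_c)

    def species_registry(self) -> list:
        """The canonical eight-species registry (front-end bath values)."""
        return [
            IonSpecies(
                name=n,
                valence=self.valence(n),
                diffusivity=self.diffusivity[n],
                external_concentration=self.external_concentration(n, "front"),
            )
            for n in SPECIES_NAMES
        ]


# ---------------------------------------------------------------------------
# loading


def _strict_keys(section: dict, allowed, where: str):
    unknown = set(section) - set(allowed)
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in {where}")


_END_KEYS = [f.name for f in dataclasses.fields(MembraneEndParameters)]
_BATH_KEYS = [f.name for f in dataclasses.fields(ExternalBath)]


def _end_from_dict(d: dict, where: str) -> MembraneEndParameters:
    d = dict(d)
    _strict_keys(d, _END_KEYS, where)
    if "external" in d and d["external"] is not None:
        _strict_keys(d["external"], _BATH_KEYS, f"{where}.external")
        d["external"] = ExternalBath(**d["external"])
    return MembraneEndParameters(**d)


_TOP_SCALARS = [
    "cell_length", "cross_section", "interfacial_friction", "adhesion_strength",
    "wall_friction", "depolymerization_rate", "gactin_diffusivity",
    "actin_stiffness", "mean_actin", "polymerization_saturation",
    "membrane_thickness_factor", "gas_constant", "temperature", "faraday",
    "henry_constant", "pco2", "pk_c", "pk_b", "extracellular_ph",
    "extracellular_potential", "impermeant_total", "buffer_total",
    "impermeant_valence", "buffer_valence", "advection", "force_balance",
]


def parameters_from_dict(raw: dict) -> ModelParameters:
    """Build a validated ModelParameters from a nested plain dict.

    Unknown keys anywhere are rejected with a message naming them.
    """
    raw = copy.deepcopy(raw)
    allowed = _TOP_SCALARS + ["external", "diffusivity", "gating", "nke", "front", "back"]
    _strict_keys(raw, allowed, "parameter file")

    ext = dict(raw.pop("external"))
    ext["ph"] = raw.get("extracellular_ph", 7.4)
    _strict_keys(ext, _BATH_KEYS, "external")
    external = ExternalBath(**ext)

    diff = dict(raw.pop("diffusivity"))
    _strict_keys(diff, SPECIES_NAMES, "diffusivity")

    gat = dict(raw.pop("gating"))
    _strict_keys(gat, [f.name for f in dataclasses.fields(GatingConstants)], "gating")
    gating = GatingConstants(**gat)

    nke = dict(raw.pop("nke"))
    _strict_keys(nke, ["beta_na", "beta_k"], "nke")

    front = _end_from_dict(raw.pop("front"), "front")
    back = _end_from_dict(raw.pop("back"), "back")

    params = ModelParameters(
        external=external,
        diffusivity=diff,
        gating=gating,
        nke=NkeScalings(**nke),
        front=front,
        back=back,
        **raw,
    )
    return validate_parameters(params)


def load_parameters(path=None) -> ModelParameters:
    """Load parameters from a YAML file, or the packaged defaults when None."""
    if path is None:
        text = resources.files("osmoengine.data").joinpath("defaults.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return parameters_from_dict(yaml.safe_load(text))


def default_parameters() -> ModelParameters:
    return load_parameters(None)


# ---------------------------------------------------------------------------
# validation


def _require(cond: bool, message: str):
    if not cond:
        raise ParameterError(message)


def validate_parameters(params: ModelParameters) -> ModelParameters:
    """Check every type invariant; return the parameter set unchanged.

    Raises ParameterError naming the offending field on the first violation.
    """
    p = params
    for name in ("cell_length", "cross_section", "temperature", "gas_constant",
                 "faraday", "henry_constant", "mean_actin", "actin_stiffness",
                 "polymerization_saturation", "membrane_thickness_factor",
                 "gactin_diffusivity"):
        _require(getattr(p, name) > 0, f"{name} must be positive")
    for name in ("depolymerization_rate", "interfacial_friction",
                 "adhesion_strength", "wall_friction", "impermeant_total",
                 "buffer_total"):
        _require(getattr(p, name) >= 0, f"{name} must be non-negative")
    for name in ("pk_c", "pk_b", "extracellular_ph"):
        _require(math.isfinite(getattr(p, name)), f"{name} must be finite")
    _require(p.advection in ("frame", "lab"), "advection must be 'frame' or 'lab'")
    _require(p.force_balance in ("printed", "symmetrized"),
             "force_balance must be 'printed' or 'symmetrized'")
    for n in SPECIES_NAMES:
        _require(n in p.diffusivity, f"diffusivity.{n} is missing")
        _require(p.diffusivity[n] > 0, f"diffusivity.{n} must be positive")
    for end in ("front", "back"):
        e = p.end(end)
        _require(e is not None, f"{end} membrane parameters are missing")
        for name in ("water_permeability", "hydraulic_resistance", "alpha_na",
                     "alpha_k", "alpha_cl", "alpha_nke", "alpha_nhe",
                     "alpha_ae2", "j_actin"):
            _require(getattr(e, name) >= 0, f"{end}.{name} must be non-negative")
    _require(p.back.j_actin == 0.0,
             "back.j_actin must be zero: actin polymerization occurs only at the "
             "front; the actin flux is zero at the back of the cell")
    _require(p.wall_friction > 0 or
             (p.front.hydraulic_resistance + p.back.hydraulic_resistance) > 0,
             "wall_friction: at least one of wall friction or hydraulic "
             "resistance must be positive for the velocity equation to be well-posed")
    return params


# ---------------------------------------------------------------------------
# dotted-path overrides (used by scenarios, sweeps, fitting, CLI --set)


def _split_root(path: str):
    parts = path.split(".")
    if not all(parts):
        raise ParameterError(f"malformed parameter path {path!r}")
    return parts


def get_override_path(params: ModelParameters, path: str):
    """Read a (possibly nested) parameter by dotted path, e.g. 'front.alpha_cl'."""
    obj = params
    for part in _split_root(path):
        if dataclasses.is_dataclass(obj) and part in {f.name for f in dataclasses.fields(obj)}:
            obj = getattr(obj, part)
        elif isinstance(obj, dict) and part in obj:
            obj = obj[part]
        else:
            raise ParameterError(f"unknown parameter path {path!r} (at {part!r})")
    return obj


def _replace_path(obj, parts, value):
    head, rest = parts[0], parts[1:]
    if dataclasses.is_dataclass(obj):
        names = {f.name for f in dataclasses.fields(obj)}
        if head not in names:
            raise ParameterError(f"unknown parameter path component {head!r}")
        current = getattr(obj, head)
        new = value if not rest else _replace_path(current, rest, value)
        return dataclasses.replace(obj, **{head: new})
    if isinstance(obj, dict):
        if head not in obj:
            raise ParameterError(f"unknown parameter path component {head!r}")
        out = dict(obj)
        out[head] = value if not rest else _replace_path(obj[head], rest, value)
        return out
    raise ParameterError(f"cannot descend into {type(obj).__name__} at {head!r}")


def with_overrides(params: ModelParameters, overrides: dict) -> ModelParameters:
    """Return a new validated parameter set with dotted-path overrides applied."""
    out = params
    for path, value in (overrides or {}).items():
        out = _replace_path(out, _split_root(path), value)
    return validate_parameters(out)


def to_plain_dict(params: ModelParameters) -> dict:
    """Round-trippable nested dict (for manifests and provenance records)."""
    d = dataclasses.asdict(params)
    d["external"].pop("ph", None)
    return d
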