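"""Assembly and damped-Newton solution of the full steady-state system.

The unknown vector stacks eleven nodal fields (pressure, network velocity,
F- and G-actin, Na+, K+, Cl-, pH, A-, free buffer, potential) plus the two
scalars v_c and v0; the residual stacks the matching finite-volume rows,
the boundary closures, the conservation integrals, electroneutrality, and
the whole-cell force balance into a square system of size 11 N + 2.

Everything is nondimensionalized by typical magnitudes before Newton (the
raw system spans many orders of magnitude between Pa-scale momentum rows
and nm/s velocities).  The Jacobian is dense finite differences — at the
grid sizes this model needs (N <= 256) that is both simple and fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import fields as F
from .errors import (InfeasibleStateError, NonConvergenceError,
                     NumericalFailureError, ParameterError)
from .fields import FieldProfiles, end_state_from_profiles
from .membrane import MembraneFluxes, assemble_boundary_fluxes
from .params import ModelParameters, validate_parameters, with_overrides

__all__ = [
    "SolverOptions",
    "CellState",
    "initial_guess",
    "solve_steady",
    "continuation_solve",
    "check_solution",
]

_NODAL_FIELDS = ("p", "v_n", "theta_n", "theta_c", "c_na", "c_k", "c_cl",
                 "ph", "c_a", "c_buf", "phi")


@dataclass(frozen=True)
class SolverOptions:
    grid_size: int = 64
    newton_tol: float = 3.0e-10  # scaled residual inf-norm, above the
    # round-off floor of the flux-difference rows at the default grid
    max_iter: int = 40
    min_step: float = 2.0 ** -22  # smallest line-search damping factor
    armijo: float = 1.0e-4
    jacobian_step: float = 3.0e-7
    restarts: int = 3  # perturbed restarts before declaring failure
    random_seed: int = 0
    continuation_steps: int = 6

    def __post_init__(self):
        if self.grid_size < 16:
            raise ParameterError("grid_size must be at least 16")
        if self.newton_tol <= 0:
            raise ParameterError("newton_tol must be positive")


@dataclass
class CellState:
    """A steady-state solution with its diagnostics.

    Diagnostics are recomputed from the profiles by :func:`check_solution`,
    never cached from the solve itself.
    """

    profiles: FieldProfiles
    v0: float
    flux_front: MembraneFluxes
    flux_back: MembraneFluxes
    converged: bool
    iterations: int
    residual_norm: float
    block_norms: dict
    params: ModelParameters
    options: SolverOptions
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Scalar summary record of the solution."""
        prof = self.profiles
        out = {
            "v0": self.v0,
            "v_c": prof.v_c,
            "converged": self.converged,
            "iterations": self.iterations,
            "residual_norm": self.residual_norm,
            "grid_size": prof.n,
        }
        for tag, fx, i in (("front", self.flux_front, -1),
                           ("back", self.flux_back, 0)):
            out[f"{tag}.j_water"] = fx.water
            out[f"{tag}.v_m"] = float(prof.phi[i]) - self.params.extracellular_potential
            out[f"{tag}.tension"] = fx.tension
            out[f"{tag}.gate_m"] = fx.gate_m
            out[f"{tag}.p"] = float(prof.p[i])
            out[f"{tag}.ph"] = float(prof.ph[i])
            for sp, j in fx.totals.items():
                if sp in ("na", "k", "cl", "h", "hco3"):
                    out[f"{tag}.j_{sp}"] = j
        return out


# ---------------------------------------------------------------------------
# initial guess


def initial_guess(params: ModelParameters, n: int):
    """Uniform Donnan-adjusted rest state.

    Satisfies electroneutrality and both impermeant integrals exactly; all
    velocities zero; pH at the extracellular value; pressure osmotically
    balanced.  Returns (profiles, v0).
    """
    params = validate_parameters(params)
    x = np.linspace(0.0, params.cell_length, n)
    vol = params.volume
    c_a = params.impermeant_total / vol
    c_buf_tot = params.buffer_total / vol
    ph0 = params.extracellular_ph
    c_buf = c_buf_tot / (1.0 + 10.0 ** (params.pk_b - ph0))
    bath = params.external
    c_h0 = bath.proton()
    c_hco30 = bath.bicarbonate(params.pco2, params.henry_constant, params.pk_c)

    cations0 = bath.na + bath.k
    fixed_charge = (c_h0 - c_hco30 + params.impermeant_valence * c_a
                    + params.buffer_valence * c_buf)
    if cations0 <= 0:
        raise InfeasibleStateError("no extracellular cations to balance the "
                                   "impermeant charge (external.na + external.k = 0)")
    disc = fixed_charge ** 2 + 4.0 * cations0 * bath.cl
    f = (-fixed_charge + math.sqrt(disc)) / (2.0 * cations0)
    if not (f > 0 and math.isfinite(f)):
        raise InfeasibleStateError(
            "impermeant totals admit no positive Donnan ion balance")

    ones = np.ones(n)
    phi = params.extracellular_potential - params.rt_over_f * math.log(f)
    prof = FieldProfiles(
        x=x,
        p=np.zeros(n),
        v_n=np.zeros(n),
        theta_n=0.5 * params.mean_actin * ones,
        theta_c=0.5 * params.mean_actin * ones,
        c_na=f * bath.na * ones,
        c_k=f * bath.k * ones,
        c_cl=bath.cl / f * ones,
        ph=ph0 * ones,
        c_a=c_a * ones,
        c_buf=c_buf * ones,
        phi=phi * ones,
        v_c=0.0,
    )
    c_tot = float(prof.total_concentration(params)[0])
    p0 = 0.5 * (params.front.external_pressure + params.back.external_pressure)
    prof.p[:] = p0 + params.rt * (c_tot - params.external_total("front"))
    return prof, 0.0


def balanced_guess(params: ModelParameters, n: int):
    """Donnan guess refined by a well-mixed (0D) membrane flux balance.

    Solves the spatially uniform fixed point of the permeant ion families
    (front+back membrane fluxes summing to zero per species, plus
    electroneutrality) and fills uniform profiles with it; pressure is set
    to the osmotic rest balance.  This lands Newton inside the physiological
    pump-on basin instead of the Donnan/pump-off one.  Falls back to the
    plain Donnan guess if the 0D solve fails (e.g. most pathways shut off).
    """
    from scipy.optimize import fsolve

    prof, v0 = initial_guess(params, n)
    perm = _permeant_families(params)
    if not all(perm.values()):
        return prof, v0
    vol = params.volume
    c_buf_tot = params.buffer_total / vol
    c_a = params.impermeant_total / vol

    def system0(u):
        cna, ck, ccl, ph, phi = u
        if min(cna, ck, ccl) <= 0 or not (2.0 < ph < 12.0):
            return np.full(5, 1e3)
        trial = prof.copy()
        trial.c_na[:], trial.c_k[:], trial.c_cl[:] = cna, ck, ccl
        trial.ph[:], trial.phi[:] = ph, phi
        c_buf = c_buf_tot / (1.0 + 10.0 ** (params.pk_b - ph))
        trial.c_buf[:] = c_buf
        trial.p[:] = 0.5 * (params.front.external_pressure
                            + params.back.external_pressure) \
            + params.rt * (float(trial.total_concentration(params)[0])
                           - params.external_total("front"))
        ff = assemble_boundary_fluxes(
            end_state_from_profiles(trial, 0.0, "front", params),
            params.front, params)
        fb = assemble_boundary_fluxes(
            end_state_from_profiles(trial, 0.0, "back", params),
            params.back, params)
        tf, tb = ff.totals, fb.totals
        charge = (cna + ck + trial.c_h()[0] - ccl - trial.c_hco3(params)[0]
                  + params.impermeant_valence * c_a + params.buffer_valence * c_buf)
        return np.array([
            tf["na"] + tb["na"], tf["k"] + tb["k"], tf["cl"] + tb["cl"],
            ff.acid_family + fb.acid_family, charge,
        ])

    u0 = np.array([float(prof.c_na[0]), max(float(prof.c_k[0]), 30.0),
                   float(prof.c_cl[0]), float(prof.ph[0]), float(prof.phi[0])])
    with np.errstate(all="ignore"):
        sol, info, ier, _ = fsolve(system0, u0, full_output=True, xtol=1e-12)
    if ier != 1 or min(sol[:3]) <= 0 or not (2.0 < sol[3] < 12.0):
        return prof, v0
    cna, ck, ccl, ph, phi = sol
    prof.c_na[:], prof.c_k[:], prof.c_cl[:] = cna, ck, ccl
    prof.ph[:], prof.phi[:] = ph, phi
    prof.c_buf[:] = c_buf_tot / (1.0 + 10.0 ** (params.pk_b - ph))
    prof.__dict__.pop("_derived", None)
    prof.p[:] = 0.5 * (params.front.external_pressure
                       + params.back.external_pressure) \
        + params.rt * (float(prof.total_concentration(params)[0])
                       - params.external_total("front"))
    return prof, v0


# ---------------------------------------------------------------------------
# system assembly


def _permeant_families(params: ModelParameters) -> dict:
    """Which transported families have any open membrane pathway."""
    f, b = params.front, params.back
    return {
        "na": any(v > 0 for v in (f.alpha_na, b.alpha_na, f.alpha_nke,
                                  b.alpha_nke, f.alpha_nhe, b.alpha_nhe)),
        "k": any(v > 0 for v in (f.alpha_k, b.alpha_k, f.alpha_nke, b.alpha_nke)),
        "cl": any(v > 0 for v in (f.alpha_cl, b.alpha_cl, f.alpha_ae2, b.alpha_ae2)),
        "ph": any(v > 0 for v in (f.alpha_nhe, b.alpha_nhe, f.alpha_ae2, b.alpha_ae2)),
    }


def _family_content(prof: FieldProfiles, name: str, params: ModelParameters) -> float:
    if name == "ph":
        dens = prof.c_hco3(params) + prof.c_buf - prof.c_h()
    else:
        dens = prof.concentration(name, params)
    return float(np.trapezoid(dens, prof.x))


class SteadySystem:
    """Packs/unpacks the unknown vector and evaluates the scaled residual."""

    def __init__(self, params: ModelParameters, options: SolverOptions):
        self.params = validate_parameters(params)
        self.options = options
        n = options.grid_size
        self.n = n
        self.nu = 11 * n + 2
        self.x = np.linspace(0.0, params.cell_length, n)

        # unknown scales (typical magnitudes)
        p = params
        conc = max(p.external_total("front"), 1.0)
        uscale = {
            "p": p.rt * 1.0, "v_n": 1e-3, "theta_n": max(p.mean_actin, 1e-3),
            "theta_c": max(p.mean_actin, 1e-3), "c_na": conc, "c_k": conc,
            "c_cl": conc, "ph": 1.0, "c_a": max(p.impermeant_total / p.volume, 1.0),
            "c_buf": max(p.buffer_total / p.volume, 1.0), "phi": p.rt_over_f,
        }
        self.u_scale = np.empty(self.nu)
        self.slices = {}
        for i, name in enumerate(_NODAL_FIELDS):
            sl = slice(i * n, (i + 1) * n)
            self.slices[name] = sl
            self.u_scale[sl] = uscale[name]
        self.i_vc, self.i_v0 = 11 * n, 11 * n + 1
        self.u_scale[self.i_vc] = self.u_scale[self.i_v0] = 1e-3

        # residual block layout and scales
        # flux-difference rows accumulate O(D c eps / h) round-off, so their
        # scale grows with resolution to keep the scaled tolerance attainable
        hfac = max(1.0, (n - 1) / 63.0)
        jscale = max(p.front.j_actin, 1e-3) * hfac
        fscale = 1.0 * hfac  # mM um/s, ion-transport rows
        v0row = (p.front.hydraulic_resistance + p.back.hydraulic_resistance
                 + p.wall_friction) * 1e-3
        blocks = [
            ("cytosol_momentum", n - 1, 4.0 * hfac),
            ("cytosol_bc", 2, 1e-3),
            ("network_momentum", n, max(p.actin_stiffness * p.mean_actin
                                        / p.cell_length, 1.0)),
            ("factin", n, jscale),
            ("gactin", n - 1, jscale),
            ("actin_total", 1, p.cell_length * p.mean_actin),
            ("na", n, fscale), ("k", n, fscale), ("cl", n, fscale),
            ("ph", n, fscale),
            ("a", n, fscale), ("buf", n, fscale),
            ("electroneutrality", n, 1.0),
            ("force_balance", 1, max(v0row, 1.0)),
        ]
        self.r_slices, self.r_scale = {}, np.empty(self.nu)
        pos = 0
        for name, size, scale in blocks:
            self.r_slices[name] = slice(pos, pos + size)
            self.r_scale[pos:pos + size] = scale
            pos += size
        assert pos == self.nu, "residual layout is not square"

        # impermeant/conserved amplitude rows (replace each family's back row)
        self.permeant = _permeant_families(params)
        guess, _ = initial_guess(params, n)
        self.content_ref = {
            name: _family_content(guess, name, params)
            for name in ("na", "k", "cl", "ph") if not self.permeant[name]
        }
        s = params.cross_section
        self.r_scale[self.r_slices["a"].start] = max(s * p.impermeant_total / p.volume
                                                     * p.cell_length, 1.0)
        self.r_scale[self.r_slices["buf"].start] = max(s * p.buffer_total / p.volume
                                                       * p.cell_length, 1.0)
        for name, ref in self.content_ref.items():
            self.r_scale[self.r_slices[name].start] = max(abs(ref), 1.0)

    # -- vector <-> state ---------------------------------------------------

    def pack(self, prof: FieldProfiles, v0: float) -> np.ndarray:
        u = np.empty(self.nu)
        for name in _NODAL_FIELDS:
            u[self.slices[name]] = getattr(prof, name)
        u[self.i_vc], u[self.i_v0] = prof.v_c, v0
        return u

    def unpack(self, u: np.ndarray):
        kw = {name: u[self.slices[name]] for name in _NODAL_FIELDS}
        prof = FieldProfiles(x=self.x, v_c=float(u[self.i_vc]), **kw)
        return prof, float(u[self.i_v0])

    def admissible(self, u: np.ndarray) -> bool:
        """Physical-domain guard used by the line search."""
        prof, _ = self.unpack(u)
        if np.any(prof.c_na <= 0) or np.any(prof.c_k <= 0) or np.any(prof.c_cl <= 0):
            return False
        if np.any(prof.c_buf < 0) or np.any(prof.c_a < -1e-30):
            return False
        if np.any(prof.ph < 2.0) or np.any(prof.ph > 12.0):
            return False
        return True

    # -- residual -----------------------------------------------------------

    def end_fluxes(self, prof: FieldProfiles, v0: float):
        params = self.params
        ff = assemble_boundary_fluxes(
            end_state_from_profiles(prof, v0, "front", params), params.front, params)
        fb = assemble_boundary_fluxes(
            end_state_from_profiles(prof, v0, "back", params), params.back, params)
        return ff, fb

    def residual(self, u: np.ndarray) -> np.ndarray:
        params = self.params
        prof, v0 = self.unpack(u)
        ff, fb = self.end_fluxes(prof, v0)
        r = np.empty(self.nu)
        rs = self.r_slices

        r[rs["cytosol_momentum"]] = F.cytosol_residuals(prof, params)
        # cytosol flux closures: v_c - v0 = J_water^b at the back,
        # v_c - v0 = -J_water^f at the front
        r[rs["cytosol_bc"]] = (prof.v_c - v0 - fb.water,
                               prof.v_c - v0 + ff.water)
        r[rs["network_momentum"]] = F.network_residuals(prof, params)
        actin = F.actin_mass_residuals(prof, v0, params)
        r[rs["factin"]] = actin["factin"]
        r[rs["gactin"]] = actin["gactin"]
        r[rs["actin_total"]] = actin["actin_total"]

        transport = F.species_transport_residuals(prof, v0, ff, fb, params)
        for name in ("na", "k", "cl", "ph"):
            rows = transport[name]
            r[rs[name]] = rows
            if name in self.content_ref:  # fully impermeant family: pin content
                r[rs[name].start] = (_family_content(prof, name, params)
                                     - self.content_ref[name])
        integ = F.impermeant_constraints(prof, params)
        r[rs["a"]] = transport["a"]
        r[rs["a"].start] = integ[0]
        r[rs["buf"]] = transport["buf"]
        r[rs["buf"].start] = integ[1]

        r[rs["electroneutrality"]] = F.electroneutrality_residuals(prof, params)
        r[rs["force_balance"]] = F.global_force_balance(prof, ff, fb, params, v0)
        return r

    def scaled_residual(self, us: np.ndarray) -> np.ndarray:
        return self.residual(us * self.u_scale) / self.r_scale

    def block_norms(self, r: np.ndarray) -> dict:
        rs = r / self.r_scale
        return {name: float(np.max(np.abs(rs[sl])))
                for name, sl in self.r_slices.items()}

    def nan_block(self, r: np.ndarray) -> Optional[str]:
        bad = ~np.isfinite(r)
        if not bad.any():
            return None
        for name, sl in self.r_slices.items():
            if bad[sl].any():
                return name
        return None


# ---------------------------------------------------------------------------
# Newton iteration


def _newton(system: SteadySystem, u0: np.ndarray, options: SolverOptions):
    """Damped Newton with Armijo backtracking on the scaled residual norm.

    Returns (u, iterations, converged, inf_norm).
    """
    us = u0 / system.u_scale
    r = system.scaled_residual(us)
    bad = system.nan_block(r * system.r_scale)
    if bad:
        raise NumericalFailureError(f"residual is not finite in block {bad!r} "
                                    "at the initial iterate")
    norm2 = float(np.linalg.norm(r))
    nu = system.nu
    step = options.jacobian_step
    lu = None  # factorized Jacobian, reused while contraction stays strong
    fresh = False
    from scipy.linalg import lu_factor, lu_solve

    def refresh():
        jac = np.empty((nu, nu))
        for j in range(nu):
            dh = step * (1.0 + abs(us[j]))
            up = us.copy()
            up[j] += dh
            jac[:, j] = (system.scaled_residual(up) - r) / dh
        return lu_factor(jac)

    for it in range(1, options.max_iter + 1):
        inf = float(np.max(np.abs(r)))
        if inf <= options.newton_tol:
            return us * system.u_scale, it - 1, True, inf
        if lu is None:
            lu, fresh = refresh(), True
        du = lu_solve(lu, -r)
        lam, accepted = 1.0, False
        while lam >= options.min_step:
            trial = us + lam * du
            if system.admissible(trial * system.u_scale):
                r_new = system.scaled_residual(trial)
                if np.all(np.isfinite(r_new)):
                    n_new = float(np.linalg.norm(r_new))
                    if n_new <= (1.0 - options.armijo * lam) * norm2:
                        ratio = n_new / norm2 if norm2 > 0 else 0.0
                        us, r, norm2, accepted = trial, r_new, n_new, True
                        # keep the factorization only after a near-full,
                        # strongly contracting step
                        if lam < 1.0 or ratio > 0.2:
                            lu = None
                        break
            lam *= 0.5
        if not accepted:
            if not fresh:
                lu = None  # stale Jacobian: retry this iterate with a fresh one
                continue
            return us * system.u_scale, it, False, float(np.max(np.abs(r)))
        fresh = False
    return us * system.u_scale, options.max_iter, False, float(np.max(np.abs(r)))


def _state_from_vector(system: SteadySystem, u, iterations, converged, inf_norm):
    prof, v0 = system.unpack(u)
    ff, fb = system.end_fluxes(prof, v0)
    raw = system.residual(u)
    state = CellState(
        profiles=prof, v0=v0, flux_front=ff, flux_back=fb,
        converged=converged, iterations=iterations, residual_norm=inf_norm,
        block_norms=system.block_norms(raw), params=system.params,
        options=system.options,
    )
    state.diagnostics = check_solution(state, system.params)
    return state


def _regrid(prof: FieldProfiles, x_new: np.ndarray) -> FieldProfiles:
    kw = {name: np.interp(x_new, prof.x, getattr(prof, name))
          for name in _NODAL_FIELDS}
    return FieldProfiles(x=x_new, v_c=prof.v_c, **kw)


def solve_steady(params: ModelParameters, options: SolverOptions = None,
                 initial: Optional[CellState] = None) -> CellState:
    """Solve the coupled steady-state system.

    Returns a converged CellState or raises NonConvergenceError carrying the
    best iterate and per-block residual norms.  Deterministic for a given
    (params, options, initial): perturbed restarts draw from the seeded
    generator in the options.
    """
    options = options or SolverOptions()
    system = SteadySystem(params, options)
    if initial is not None:
        prof0 = _regrid(initial.profiles, system.x)
        v0_0 = initial.v0
    else:
        prof0, v0_0 = balanced_guess(params, options.grid_size)
    u0 = system.pack(prof0, v0_0)

    rng = np.random.default_rng(options.random_seed)
    best = None
    for attempt in range(options.restarts + 1):
        u_try = u0 if attempt == 0 else u0 * (1.0 + 1e-3 * rng.standard_normal(u0.size))
        try:
            u, iters, ok, inf = _newton(system, u_try, options)
        except NumericalFailureError:
            if attempt == options.restarts:
                raise
            continue
        if ok:
            return _state_from_vector(system, u, iters, True, inf)
        cand = _state_from_vector(system, u, iters, False, inf)
        if best is None or cand.residual_norm < best.residual_norm:
            best = cand
    raise NonConvergenceError(
        f"Newton failed to reach tol={options.newton_tol:g} after "
        f"{options.restarts + 1} attempts (best residual {best.residual_norm:g})",
        best_state=best, block_norms=best.block_norms if best else {},
    )


def continuation_solve(params: ModelParameters, options: SolverOptions,
                       target_overrides: dict,
                       base_state: Optional[CellState] = None) -> CellState:
    """Ramp the named parameters from base to target, warm-starting each solve.

    Positive-to-positive values ramp geometrically (natural for
    permeability ratios), others linearly.  Failed steps trigger automatic
    step halving down to a floor before raising.
    """
    from .params import get_override_path

    options = options or SolverOptions()
    state = base_state or solve_steady(params, options)
    if not target_overrides:
        return state
    base_vals = {k: float(get_override_path(params, k)) for k in target_overrides}

    def at(t):
        ov = {}
        for k, target in target_overrides.items():
            b = base_vals[k]
            if b > 0 and target > 0:
                ov[k] = b * (target / b) ** t
            else:
                ov[k] = b + t * (target - b)
        return with_overrides(params, ov)

    t, dt = 0.0, 1.0 / options.continuation_steps
    dt_floor = dt / 64.0
    while t < 1.0 - 1e-12:
        t_next = min(1.0, t + dt)
        try:
            state = solve_steady(at(t_next), options, initial=state)
            t = t_next
            dt = min(2 * dt, 1.0 / options.continuation_steps)
        except NonConvergenceError:
            dt *= 0.5
            if dt < dt_floor:
                raise NonConvergenceError(
                    f"continuation stalled at t={t:.4f} (step floor reached)",
                    best_state=state)
    return state


# ---------------------------------------------------------------------------
# diagnostics


def check_solution(state: CellState, params: ModelParameters = None) -> dict:
    """Recompute conservation diagnostics from the profiles.

    Reports per-species flux spatial constancy, back-influx/front-efflux
    balance, electroneutrality error relative to ionic strength, actin and
    impermeant conservation, the whole-cell force balance, water closure,
    and the emergent zero-total-actin-flux condition at the back.
    """
    params = params or state.params
    prof, v0 = state.profiles, state.v0
    h = prof.h
    uc = (prof.v_c - v0) if params.advection == "frame" else prof.v_c
    ff, fb = state.flux_front, state.flux_back
    floor = 1e-9  # mM um/s: below this a flux is indistinguishable from zero

    out = {"flux_constancy": {}, "flux_balance": {}}
    tot_f, tot_b = ff.totals, fb.totals

    def gross(name):
        # magnitude of the membrane traffic being balanced for this species;
        # the fair scale for "relative" when the net flux nearly cancels
        vals = [tot_f[name], tot_b[name]]
        for fx in (ff, fb):
            for mech in (fx.passive, fx.nke, fx.nhe, fx.ae2):
                if name in mech:
                    vals.append(mech[name])
        return max(max(abs(v) for v in vals), floor)

    for name in ("na", "k", "cl"):
        j = F.species_flux_midpoints(prof.concentration(name, params), prof.phi,
                                     uc, params.diffusivity[name],
                                     params.valence(name), params, h)
        ref = max(abs(float(np.mean(j))), gross(name))
        out["flux_constancy"][name] = float(j.max() - j.min()) / ref
        denom = max(abs(tot_f[name]), abs(tot_b[name]), floor)
        out["flux_balance"][name] = abs(tot_f[name] + tot_b[name]) / denom
    acid_f, acid_b = ff.acid_family, fb.acid_family
    out["flux_balance"]["ph"] = abs(acid_f + acid_b) / max(abs(acid_f),
                                                           abs(acid_b), floor)

    q = F.electroneutrality_residuals(prof, params)
    strength = sum(abs(params.valence(n)) * prof.concentration(n, params)
                   for n in ("na", "k", "cl", "h", "hco3", "a", "buf"))
    out["electroneutrality"] = float(np.max(np.abs(q) / strength))

    total_actin = float(np.trapezoid(prof.theta_n + prof.theta_c, prof.x))
    out["actin_conservation"] = abs(total_actin - params.cell_length
                                    * params.mean_actin) / (params.cell_length
                                                            * params.mean_actin)
    integ = F.impermeant_constraints(prof, params)
    out["impermeant_conservation"] = {
        "a": abs(float(integ[0])) / max(params.impermeant_total, 1.0),
        "buf": abs(float(integ[1])) / max(params.buffer_total, 1.0),
    }
    fb_scale = (params.front.hydraulic_resistance + params.back.hydraulic_resistance
                + params.wall_friction) * 1e-3
    out["force_balance"] = abs(F.global_force_balance(prof, ff, fb, params, v0)) \
        / max(fb_scale, 1.0)
    out["water_closure"] = {
        "front": abs(prof.v_c - v0 + ff.water),
        "back": abs(prof.v_c - v0 - fb.water),
    }
    # emergent: total (network + monomer) relative actin flux vanishes at the back
    un0 = prof.v_n[0] - v0 if params.advection == "frame" else prof.v_n[0]
    phi_n0 = un0 * prof.theta_n[0]
    dtc0 = (prof.theta_c[1] - prof.theta_c[0]) / h
    phi_c0 = float(uc if np.isscalar(uc) else uc) * prof.theta_c[0] \
        - params.gactin_diffusivity * dtc0
    out["back_actin_flux"] = abs(phi_n0 + phi_c0) / max(params.front.j_actin, floor)
    return out
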