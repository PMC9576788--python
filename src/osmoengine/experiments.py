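"""Scenario library, polarization sweeps, sensitivity contours, and fitting.

Scenarios encode the perturbations studied experimentally: channel
polarization reversal/loss (optogenetic SWELL1 relocation), latrunculin-A
(no actin polymerization), and shRNA knockdowns (here a 0.1x multiplicative
scaling of the corresponding permeability at both ends, preserving the
front/back ratio — depletion lowers protein everywhere; polarization is a
separate axis).

Polarization sweeps vary the rear/front permeability ratio holding the
geometric mean fixed, so total pathway conductance is ratio-independent; a
``hold_front`` mode is also provided since the normalization of the swept
axis is a modeling choice.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import NonConvergenceError, ParameterError
from .params import ModelParameters, get_override_path, with_overrides
from .solver import CellState, SolverOptions, continuation_solve, solve_steady

__all__ = [
    "Scenario",
    "SCENARIOS",
    "scenario_parameters",
    "run_scenario",
    "set_polarization_ratio",
    "polarization_ratio",
    "sweep_polarization",
    "SweepResult",
    "sensitivity_contour",
    "FitResult",
    "fit_parameters",
]

_CHANNEL_PATHS = {"cl": "alpha_cl", "nhe": "alpha_nhe"}
_KNOCKDOWN_FACTOR = 0.1


@dataclass(frozen=True)
class Scenario:
    """A named perturbation of the baseline parameter set.

    ``set`` holds absolute dotted-path overrides, ``scale`` multiplicative
    ones; ``cl_ratio``/``nhe_ratio`` re-polarize a channel to the given
    back/front (Cl-) or front/back (NHE) ratio holding its geometric mean.
    """

    name: str
    description: str = ""
    set: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)
    cl_ratio: Optional[float] = None
    nhe_ratio: Optional[float] = None


SCENARIOS = {
    "baseline": Scenario(
        "baseline", "rear-polarized SWELL1, front-polarized NHE, actin on"),
    "swell1_front": Scenario(
        "swell1_front", "SWELL1 re-polarized to the front (ratio inverted)",
        cl_ratio=0.25),
    "swell1_symmetric": Scenario(
        "swell1_symmetric", "SWELL1 equally distributed at both poles",
        cl_ratio=1.0),
    "lat_a": Scenario(
        "lat_a", "latrunculin A: no actin polymerization",
        set={"front.j_actin": 0.0}),
    "nhe1_kd": Scenario(
        "nhe1_kd", "NHE1 knockdown: alpha_NHE x0.1 at both ends",
        scale={"front.alpha_nhe": _KNOCKDOWN_FACTOR,
               "back.alpha_nhe": _KNOCKDOWN_FACTOR}),
    "swell1_kd": Scenario(
        "swell1_kd", "SWELL1 knockdown: alpha_Cl x0.1 at both ends",
        scale={"front.alpha_cl": _KNOCKDOWN_FACTOR,
               "back.alpha_cl": _KNOCKDOWN_FACTOR}),
    "dual_kd": Scenario(
        "dual_kd", "dual NHE1 + SWELL1 knockdown",
        scale={"front.alpha_nhe": _KNOCKDOWN_FACTOR,
               "back.alpha_nhe": _KNOCKDOWN_FACTOR,
               "front.alpha_cl": _KNOCKDOWN_FACTOR,
               "back.alpha_cl": _KNOCKDOWN_FACTOR}),
    "lat_a_swell1_kd": Scenario(
        "lat_a_swell1_kd", "SWELL1 knockdown under latrunculin A",
        set={"front.j_actin": 0.0},
        scale={"front.alpha_cl": _KNOCKDOWN_FACTOR,
               "back.alpha_cl": _KNOCKDOWN_FACTOR}),
}


def polarization_ratio(params: ModelParameters, channel: str = "cl") -> float:
    """Back/front ratio for Cl- (SWELL1); front/back for NHE."""
    attr = _CHANNEL_PATHS[channel]
    f, b = getattr(params.front, attr), getattr(params.back, attr)
    if channel == "cl":
        return b / f
    return f / b


def set_polarization_ratio(params: ModelParameters, ratio: float,
                           channel: str = "cl",
                           mode: str = "geometric") -> ModelParameters:
    """Re-polarize one channel to the given ratio.

    ``geometric`` holds the geometric mean of the two ends fixed (total
    conductance ratio-independent); ``hold_front`` keeps the front value and
    moves only the back one.
    """
    if ratio <= 0:
        raise ParameterError("polarization ratio must be positive")
    attr = _CHANNEL_PATHS[channel]
    f, b = getattr(params.front, attr), getattr(params.back, attr)
    # enriched end: back for Cl- (SWELL1), front for NHE
    if mode == "geometric":
        g = math.sqrt(f * b)
        hi, lo = g * math.sqrt(ratio), g / math.sqrt(ratio)
    elif mode == "hold_front":
        hi, lo = f * ratio, f
    else:
        raise ParameterError(f"unknown polarization mode {mode!r}")
    if channel == "cl":
        new_f, new_b = lo, hi
    else:
        new_f, new_b = hi, lo
    return with_overrides(params, {f"front.{attr}": new_f, f"back.{attr}": new_b})


def scenario_parameters(scenario: Scenario, base: ModelParameters) -> ModelParameters:
    """Resolve a scenario into a concrete parameter set."""
    params = base
    if scenario.cl_ratio is not None:
        params = set_polarization_ratio(params, scenario.cl_ratio, "cl")
    if scenario.nhe_ratio is not None:
        params = set_polarization_ratio(params, scenario.nhe_ratio, "nhe")
    overrides = dict(scenario.set)
    for path, mult in scenario.scale.items():
        overrides[path] = get_override_path(params, path) * mult
    return with_overrides(params, overrides)


def run_scenario(scenario, base: ModelParameters,
                 options: Optional[SolverOptions] = None) -> CellState:
    """Solve one scenario, with continuation from baseline as fallback."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    options = options or SolverOptions()
    params = scenario_parameters(scenario, base)
    try:
        state = solve_steady(params, options)
    except NonConvergenceError:
        overrides = {}
        for end in ("front", "back"):
            for a in ("alpha_cl", "alpha_nhe", "j_actin"):
                path = f"{end}.{a}"
                overrides[path] = get_override_path(params, path)
        try:
            state = continuation_solve(base, options, overrides)
        except NonConvergenceError as err:
            raise NonConvergenceError(
                f"scenario {scenario.name!r} failed to converge "
                f"(direct and continuation)", best_state=err.best_state,
                block_norms=err.block_norms) from err
    state.scenario = scenario.name
    return state


# ---------------------------------------------------------------------------
# sweeps


@dataclass
class SweepResult:
    """v0 and diagnostics over a 1D or 2D parameter grid.

    Non-converged points carry NaN velocities and ``converged=False`` —
    never interpolated, never reported as 0.
    """

    axes: tuple  # axis names
    values: tuple  # tuple of 1D grids
    v0: np.ndarray  # shape (len(values[0]),) or (nx, ny)
    converged: np.ndarray
    diagnostics: list
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        if len(self.axes) == 1:
            return pd.DataFrame({self.axes[0]: self.values[0],
                                 "v0": self.v0, "converged": self.converged})
        xx, yy = np.meshgrid(self.values[0], self.values[1], indexing="ij")
        return pd.DataFrame({self.axes[0]: xx.ravel(), self.axes[1]: yy.ravel(),
                             "v0": self.v0.ravel(),
                             "converged": self.converged.ravel()})


def _provenance(base: ModelParameters, options: SolverOptions, extra: dict) -> dict:
    from .params import to_plain_dict

    blob = json.dumps(to_plain_dict(base), sort_keys=True, default=str)
    return {
        "params_sha1": hashlib.sha1(blob.encode()).hexdigest(),
        "grid_size": options.grid_size,
        "newton_tol": options.newton_tol,
        "seed": options.random_seed,
        **extra,
    }


def _apply_axis(params: ModelParameters, axis: str, value: float,
                mode: str = "geometric") -> ModelParameters:
    if axis in ("cl_ratio", "swell1_ratio"):
        return set_polarization_ratio(params, value, "cl", mode)
    if axis in ("nhe_ratio", "nhe1_ratio"):
        return set_polarization_ratio(params, value, "nhe", mode)
    return with_overrides(params, {axis: value})


def sweep_polarization(base: ModelParameters, values: Sequence[float],
                       options: Optional[SolverOptions] = None,
                       channel: str = "cl",
                       mode: str = "geometric") -> SweepResult:
    """v0 versus a channel's polarization ratio, warm-started along the sweep.

    ``values`` must be positive and sorted; per-point non-convergence is
    recorded (NaN) and the sweep continues from a cold start.
    """
    options = options or SolverOptions()
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ParameterError("sweep ratios must be positive")
    if np.any(np.diff(values) <= 0):
        raise ParameterError("sweep ratios must be strictly increasing")
    axis = "cl_ratio" if channel == "cl" else "nhe_ratio"
    v0 = np.full(values.size, np.nan)
    ok = np.zeros(values.size, dtype=bool)
    diags = [None] * values.size
    state = None
    for i, r in enumerate(values):
        params = _apply_axis(base, axis, r, mode)
        try:
            state = solve_steady(params, options, initial=state)
        except NonConvergenceError:
            try:  # cold restart before giving up on this point
                state = solve_steady(params, options)
            except NonConvergenceError:
                state = None
                continue
        v0[i], ok[i] = state.v0, True
        diags[i] = state.diagnostics
    return SweepResult(
        axes=(axis,), values=(values,), v0=v0, converged=ok, diagnostics=diags,
        provenance=_provenance(base, options, {"channel": channel, "mode": mode}),
    )


def sensitivity_contour(base: ModelParameters, axis_x: str, grid_x,
                        axis_y: str, grid_y,
                        options: Optional[SolverOptions] = None,
                        mode: str = "geometric") -> SweepResult:
    """v0 over the product grid of two parameter axes.

    Axes are either the special polarization ratios (``cl_ratio``,
    ``nhe_ratio``) or dotted parameter paths (e.g. ``front.j_actin``,
    ``adhesion_strength``).  Solves are warm-started serpentine-wise along
    rows; failures are recorded as NaN.
    """
    options = options or SolverOptions()
    gx, gy = np.asarray(grid_x, float), np.asarray(grid_y, float)
    v0 = np.full((gx.size, gy.size), np.nan)
    ok = np.zeros_like(v0, dtype=bool)
    diags = [[None] * gy.size for _ in range(gx.size)]
    state = None
    for i, vx in enumerate(gx):
        px = _apply_axis(base, axis_x, vx, mode)
        j_order = range(gy.size) if i % 2 == 0 else range(gy.size - 1, -1, -1)
        for j in j_order:
            params = _apply_axis(px, axis_y, gy[j], mode)
            try:
                state = solve_steady(params, options, initial=state)
            except NonConvergenceError:
                try:
                    state = solve_steady(params, options)
                except NonConvergenceError:
                    state = None
                    continue
            v0[i, j], ok[i, j] = state.v0, True
            diags[i][j] = state.diagnostics
    return SweepResult(
        axes=(axis_x, axis_y), values=(gx, gy), v0=v0, converged=ok,
        diagnostics=diags,
        provenance=_provenance(base, options, {"mode": mode}),
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    free: tuple  # parameter axis names
    values: dict  # fitted values
    ci95: dict  # (lo, hi) per parameter
    stderr: dict
    rss: float
    predictions: pd.DataFrame
    n_obs: int
    converged: bool
    n_starts: int
    seed: int


def _predictor(base: ModelParameters, free, conditions: dict,
               options: SolverOptions):
    """Build a cached v0 predictor over (free parameter values, condition)."""
    cache = {}
    warm = {"state": None}

    def predict(theta, condition):
        key = (tuple(np.round(theta, 12)), condition)
        if key not in cache:
            params = base
            for name, value in zip(free, theta):
                params = _apply_axis(params, name, value)
            for path, value in (conditions.get(condition) or {}).items():
                params = with_overrides(params, {path: value})
            try:
                st = solve_steady(params, options, initial=warm["state"])
            except NonConvergenceError:
                st = solve_steady(params, options)
            warm["state"] = st
            cache[key] = st.v0
        return cache[key]

    return predict


def fit_parameters(observations, base: ModelParameters, free: dict,
                   options: Optional[SolverOptions] = None,
                   n_starts: int = 3, seed: int = 0) -> FitResult:
    """Bounded least-squares fit of model parameters to velocity observations.

    ``free`` maps axis names (polarization ratios or dotted paths) to
    (lower, upper) bounds; positive-bounded axes are searched in log space.
    Multi-start (seeded, deterministic) local optimization; the reported
    confidence intervals come from the residual curvature at the optimum
    (Gauss-Newton covariance, t-quantile with n - p degrees of freedom).
    """
    options = options or SolverOptions(grid_size=32)
    table = observations.table if hasattr(observations, "table") else observations
    conditions = getattr(observations, "conditions", {}) or {}
    if len(table) == 0:
        raise ParameterError("fit requires at least one observation")
    names = tuple(free)
    bounds = np.array([free[k] for k in names], dtype=float)
    logspace = np.all(bounds > 0, axis=1)

    def to_internal(theta):
        return np.where(logspace, np.log(theta), theta)

    def to_natural(z):
        return np.where(logspace, np.exp(z), z)

    obs_v = table["v0_observed"].to_numpy(float)
    obs_c = table["condition"].tolist()
    predict = _predictor(base, names, conditions, options)

    def residuals(z):
        theta = to_natural(z)
        return np.array([predict(theta, c) for c in obs_c]) - obs_v

    rng = np.random.default_rng(seed)
    lo, hi = to_internal(bounds[:, 0]), to_internal(bounds[:, 1])
    starts = [0.5 * (lo + hi)]
    starts += [lo + (hi - lo) * rng.random(len(names))
               for _ in range(n_starts - 1)]
    best = None
    for z0 in starts:
        try:
            # diff_step well above solver round-off so the curvature (and
            # hence the confidence intervals) is estimated cleanly
            res = optimize.least_squares(residuals, z0, bounds=(lo, hi),
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                         diff_step=1e-3)
        except NonConvergenceError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise NonConvergenceError("all fit starts failed (solver non-convergence)")

    z_hat = best.x
    theta_hat = to_natural(z_hat)
    rss = float(2 * best.cost)
    n, p = len(obs_v), len(names)
    dof = max(n - p, 1)
    jac = best.jac
    try:
        cov_z = np.linalg.inv(jac.T @ jac) * (rss / dof)
    except np.linalg.LinAlgError:
        cov_z = np.full((p, p), np.nan)
    se_z = np.sqrt(np.maximum(np.diag(cov_z), 0.0))
    # delta method back to natural scale for log-searched axes
    se = np.where(logspace, se_z * np.abs(theta_hat), se_z)
    tq = stats.t.ppf(0.975, dof)
    ci = {}
    for i, k in enumerate(names):
        if logspace[i]:
            ci[k] = (float(theta_hat[i] * math.exp(-tq * se_z[i])),
                     float(theta_hat[i] * math.exp(tq * se_z[i])))
        else:
            ci[k] = (float(theta_hat[i] - tq * se[i]),
                     float(theta_hat[i] + tq * se[i]))
    pred = pd.DataFrame({
        "condition": obs_c,
        "v0_observed": obs_v,
        "v0_predicted": residuals(z_hat) + obs_v,
    })
    return FitResult(
        free=names, values={k: float(theta_hat[i]) for i, k in enumerate(names)},
        ci95=ci, stderr={k: float(se[i]) for i, k in enumerate(names)},
        rss=rss, predictions=pred, n_obs=n, converged=bool(best.success),
        n_starts=n_starts, seed=seed,
    )
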