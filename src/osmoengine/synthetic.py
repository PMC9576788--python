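"""Synthetic observations, polarized-cell intensity phantoms, trajectories.

Every generator records its full provenance (parameters + seed) on the
object it returns; regenerating from that provenance is bit-identical.
The velocity generator emulates the structure of per-cell steady-velocity
measurements (a handful of cells per condition, mean +- SD reported); the
image generator produces membrane-label phantoms with bright pole bands and
an unlabeled interior; the trajectory generator produces drift-diffusion
tracks sampled at fixed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidInputError, NonConvergenceError
from .params import ModelParameters, with_overrides
from .solver import SolverOptions, solve_steady

__all__ = [
    "ObservationSet",
    "IntensityImage",
    "Trajectory",
    "gen_velocity_observations",
    "gen_polarized_cell_image",
    "gen_trajectory",
]

#: default observation count per condition (cells per condition in the
#: polarization-velocity comparison this emulates)
N_PER_CONDITION = 11

#: default observation noise, as a fraction of the baseline speed
NOISE_FRACTION = 0.3


@dataclass
class ObservationSet:
    """Noisy per-cell velocity observations with known ground truth."""

    table: pd.DataFrame  # condition, replicate, v0_true, v0_observed
    conditions: dict  # condition name -> dotted-path overrides
    noise_sd: float  # um/s
    seed: int
    n_per: int

    @property
    def provenance(self) -> dict:
        return {"noise_sd": self.noise_sd, "seed": self.seed,
                "n_per": self.n_per, "conditions": self.conditions}


@dataclass
class IntensityImage:
    """Synthetic polarized-cell image with recorded ground truth.

    Axis 0 is the migration axis; the front pole is the high-index end.
    """

    pixels: np.ndarray  # 2D, >= 0
    front_mean: float
    rear_mean: float
    interior_mean: float
    pole_depth: int
    noise_sd: float
    seed: int

    @property
    def truth_ratio(self) -> float:
        return self.front_mean / self.rear_mean

    @property
    def interior_mask(self) -> np.ndarray:
        m = np.ones(self.pixels.shape, dtype=bool)
        m[: self.pole_depth] = False
        m[-self.pole_depth:] = False
        return m


@dataclass
class Trajectory:
    """Drift-diffusion track with uniform sampling and known (v, D)."""

    t: np.ndarray  # s, strictly increasing, uniform
    positions: np.ndarray  # (n, dims) um
    v: float  # um/s drift along axis 0
    d: float  # um^2/s per axis
    seed: Optional[int] = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def dims(self) -> int:
        return self.positions.shape[1]


def gen_velocity_observations(base: ModelParameters,
                              conditions: dict,
                              n_per: int = N_PER_CONDITION,
                              noise_sd: Optional[float] = None,
                              seed: int = 0,
                              options: Optional[SolverOptions] = None
                              ) -> ObservationSet:
    """Draw noisy velocity observations around the model's v0 per condition.

    ``conditions`` maps condition names to dotted-path parameter overrides
    (empty dict = baseline).  ``noise_sd=None`` defaults to 30% of the
    baseline speed.  Observations are v0 + N(0, noise_sd), reproducible per
    seed.
    """
    if n_per < 1:
        raise InvalidInputError("n_per must be at least 1")
    options = options or SolverOptions(grid_size=32)
    rng = np.random.default_rng(seed)
    truths = {}
    warm = None
    for name, overrides in conditions.items():
        try:
            warm = solve_steady(with_overrides(base, overrides or {}),
                                options, initial=warm)
        except NonConvergenceError as err:
            raise GenerationError(
                f"solver failed for condition {name!r}: {err}") from err
        truths[name] = warm.v0
    if noise_sd is None:
        try:
            v_base = truths.get("baseline")
            if v_base is None:
                v_base = solve_steady(base, options).v0
        except NonConvergenceError as err:
            raise GenerationError(f"solver failed for baseline: {err}") from err
        noise_sd = NOISE_FRACTION * abs(v_base)
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    rows = []
    for name in conditions:
        draws = truths[name] + noise_sd * rng.standard_normal(n_per)
        for k, v in enumerate(draws):
            rows.append({"condition": name, "replicate": k,
                         "v0_true": truths[name], "v0_observed": float(v)})
    return ObservationSet(table=pd.DataFrame(rows),
                          conditions={k: dict(v or {}) for k, v in conditions.items()},
                          noise_sd=float(noise_sd), seed=seed, n_per=n_per)


def gen_polarized_cell_image(shape_px=(120, 30), pole_depth_px: int = 12,
                             front_mean: float = 200.0, rear_mean: float = 100.0,
                             interior_mean: float = 0.0, noise_sd: float = 0.0,
                             seed: int = 0) -> IntensityImage:
    """Rectangular confined-cell phantom with bright membrane pole bands.

    The two pole bands (depth ``pole_depth_px`` along axis 0) carry the
    given mean intensities; the interior is dim or unlabeled (default 0,
    mimicking exclusion of internal vesicle signal).  Additive Gaussian
    noise is truncated at zero so pixel values stay non-negative.
    """
    length, width = shape_px
    if min(front_mean, rear_mean, interior_mean) < 0 or noise_sd < 0:
        raise InvalidInputError("intensities and noise_sd must be non-negative")
    if pole_depth_px < 1 or 2 * pole_depth_px >= length:
        raise InvalidInputError(
            "pole_depth_px must be positive with 2*pole_depth < image length")
    img = np.full((length, width), float(interior_mean))
    img[:pole_depth_px] = rear_mean  # rear pole at low indices
    img[-pole_depth_px:] = front_mean
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.maximum(img + noise_sd * rng.standard_normal(img.shape), 0.0)
    return IntensityImage(pixels=img, front_mean=front_mean, rear_mean=rear_mean,
                          interior_mean=interior_mean, pole_depth=pole_depth_px,
                          noise_sd=noise_sd, seed=seed)


def gen_trajectory(v: float, d: float, dt: float, n_steps: int,
                   dims: int = 2, seed: int = 0) -> Trajectory:
    """Drift-diffusion track: x_{k+1} = x_k + v dt e_0 + N(0, sqrt(2 D dt)).

    Drift acts along the first axis only; diffusion is isotropic.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    if n_steps < 2:
        raise InvalidInputError("n_steps must be at least 2")
    if d < 0:
        raise InvalidInputError("diffusivity must be non-negative")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_steps, dims))
    steps[1:, 0] += v * dt
    if d > 0:
        steps[1:] += np.sqrt(2.0 * d * dt) * rng.standard_normal((n_steps - 1, dims))
    pos = np.cumsum(steps, axis=0)
    t = dt * np.arange(n_steps)
    return Trajectory(t=t, positions=pos, v=v, d=d, seed=seed)
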