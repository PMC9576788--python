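"""Measurement procedures: polarity ratios, track metrics, spheroid shape.

The front/rear polarization ratio reproduces the membrane-label
quantification used for confined cells: within a rectangular window at each
pole, pixel intensities are summed and divided by the number of non-zero
(above-threshold) pixels, excluding unlabeled interior signal; the ratio is
front mean over rear mean.  Track metrics (instantaneous velocity,
time-averaged MSD) and polygon shape metrics (shoelace area, perimeter,
circularity, normalized area expansion) follow the corresponding standard
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .errors import InvalidInputError, UndefinedRatioError
from .synthetic import Trajectory

__all__ = [
    "PolarizationMeasurement",
    "ShapeMetrics",
    "front_rear_ratio",
    "instantaneous_velocity",
    "msd",
    "shape_metrics",
]


@dataclass
class PolarizationMeasurement:
    front_mean: float  # sum of included pixels / count of included pixels
    rear_mean: float
    ratio: float  # front / rear
    pole_window_px: int
    zero_threshold: float
    n_front: int  # included pixel counts
    n_rear: int


@dataclass
class ShapeMetrics:
    area: float
    perimeter: float
    circularity: float  # 4 pi A / P^2, 1 for a circle
    expansion: float  # A_t / A_0


def _window_mean(window: np.ndarray, threshold: float, which: str):
    included = window[window > threshold]
    if included.size == 0:
        raise UndefinedRatioError(
            f"{which} pole window contains no pixels above the zero threshold")
    return float(included.sum() / included.size), int(included.size)


def front_rear_ratio(image, pole_window_px: int,
                     zero_threshold: float = 0.0) -> PolarizationMeasurement:
    """Front-to-rear mean-intensity ratio over rectangular pole windows.

    Axis 0 is the migration axis with the front at the high-index end
    (matching the model's orientation).  Pixels at or below
    ``zero_threshold`` are excluded from both sum and count; a window with
    no included pixels raises UndefinedRatioError explicitly rather than
    propagating NaN.  Accepts a 2D array or an object with a ``pixels``
    attribute.
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    if pixels.ndim != 2:
        raise InvalidInputError("image must be 2D")
    if zero_threshold < 0:
        raise InvalidInputError("zero_threshold must be non-negative")
    if pole_window_px < 1 or 2 * pole_window_px > pixels.shape[0]:
        raise InvalidInputError("pole windows must fit within the image")
    rear = pixels[:pole_window_px]
    front = pixels[-pole_window_px:]
    front_mean, n_front = _window_mean(front, zero_threshold, "front")
    rear_mean, n_rear = _window_mean(rear, zero_threshold, "rear")
    return PolarizationMeasurement(
        front_mean=front_mean, rear_mean=rear_mean,
        ratio=front_mean / rear_mean, pole_window_px=pole_window_px,
        zero_threshold=zero_threshold, n_front=n_front, n_rear=n_rear)


def instantaneous_velocity(trajectory: Trajectory, window: int = 1) -> np.ndarray:
    """Signed velocity along the migration axis from a uniformly sampled track.

    v_k = (x_{k+window} - x_k) / (window dt); positive toward the front
    (increasing coordinate), so direction reversal shows as negative values.
    """
    if window < 1:
        raise InvalidInputError("window must be at least 1")
    x = np.asarray(trajectory.positions)[:, 0]
    n = x.size
    if window >= n:
        raise InvalidInputError("window must be shorter than the track")
    return (x[window:] - x[:-window]) / (window * trajectory.dt)


def msd(trajectory: Trajectory, max_lag_fraction: float = 0.5):
    """Time-averaged mean squared displacement versus lag.

    MSD(tau) averages |x(t + tau) - x(t)|^2 over all start times, for lags
    up to ``max_lag_fraction`` of the track length.  Returns (lag times,
    MSD values); drift contributes (v tau)^2, diffusion 2 dims D tau.
    """
    if not 0 < max_lag_fraction <= 1:
        raise InvalidInputError("max_lag_fraction must be in (0, 1]")
    pos = np.asarray(trajectory.positions, dtype=float)
    n = pos.shape[0]
    max_lag = max(int(np.floor(max_lag_fraction * (n - 1))), 1)
    if n < 2:
        raise InvalidInputError("track too short for MSD")
    lags = np.arange(1, max_lag + 1)
    out = np.empty(max_lag)
    for i, lag in enumerate(lags):
        disp = pos[lag:] - pos[:-lag]
        out[i] = float(np.mean(np.sum(disp ** 2, axis=1)))
    return lags * trajectory.dt, out


def _as_polygon(vertices, which: str) -> Polygon:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise InvalidInputError(f"{which} must be an (n >= 3, 2) vertex array")
    poly = Polygon(v)
    if not poly.is_valid or poly.area <= 0:
        raise InvalidInputError(f"{which} is degenerate or self-intersecting")
    return poly


def shape_metrics(polygon_t, polygon_0) -> ShapeMetrics:
    """Area, perimeter, circularity and normalized expansion of an outline.

    ``polygon_t`` is the outline at the later time, ``polygon_0`` the
    reference; expansion is A_t / A_0.  Circularity 4 pi A / P^2 is 1 for a
    circle and invariant under rigid motion and uniform scaling.
    """
    pt = _as_polygon(polygon_t, "polygon_t")
    p0 = _as_polygon(polygon_0, "polygon_0")
    area, perim = pt.area, pt.exterior.length
    return ShapeMetrics(
        area=float(area), perimeter=float(perim),
        circularity=float(4.0 * np.pi * area / perim ** 2),
        expansion=float(area / p0.area))
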