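"""The virtual-pheromone model and hourly grayscale map rendering.

A virtual pheromone source is a point on a grid with a non-negative
intensity P.  Pheromones diffuse linearly in space up to a range sigma,

    p(x) = P * (1 - x/sigma)   for x <= sigma,   0 beyond,

superpose additively over sources, and (optionally) evaporate linearly in
time with constant tau:

    p(x, t) = P * (1 - x/sigma) * (1 - (t - t_k)/tau),

both factors clipped below at zero.  Each behaviorally significant place
hosts one source; rendering the aggregated field over a 128x128 grid and
quantizing to 8-bit gives the hourly "pheromone distribution map" in which
pixel brightness encodes recent activity at and around each place.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .events import HourlyCounts

__all__ = [
    "PheromoneSource",
    "PheromoneParams",
    "PheromoneGrid",
    "point_intensity",
    "aggregate_intensity",
    "aggregate_with_evaporation",
    "render_hourly_map",
    "quantize_to_grayscale",
    "render_day_images",
    "auto_intensity_cap",
    "write_png",
    "daily_montage",
]

#: quadrant centers of the default 128-grid; the four lobes stay visually
#: separable at the default diffusion range
DEFAULT_PLACE_POSITIONS: dict[str, tuple[int, int]] = {
    "P1": (32, 32),
    "P2": (32, 96),
    "P3": (96, 32),
    "P4": (96, 96),
}


@dataclass(frozen=True)
class PheromoneSource:
    """A point source: grid position (row, col), intensity P >= 0, and an
    optional creation time in minutes (used only in evaporation mode)."""

    position: tuple[float, float]
    intensity: float
    t_created: float | None = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("pheromone intensity must be >= 0")


@dataclass(frozen=True)
class PheromoneParams:
    """Geometry and dynamics of the pheromone field.

    sigma is the diffusion range in pixels, tau the evaporation constant in
    minutes.  ``intensity_cap`` fixes the grayscale white point (intensity
    mapping to 255); ``None`` defers to the caller (the pipeline uses the
    99th percentile of all per-place hourly counts so that "white" is stable
    across days).
    """

    grid_size: int = 128
    sigma: float = 40.0
    tau: float = 60.0
    place_positions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLACE_POSITIONS)
    )
    intensity_cap: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        for p, (r, c) in self.place_positions.items():
            if not (0 <= r < self.grid_size and 0 <= c < self.grid_size):
                raise ValueError(f"place {p} position {(r, c)} outside grid")
        if self.intensity_cap is not None and self.intensity_cap <= 0:
            raise ValueError("intensity_cap must be > 0")


@dataclass(frozen=True)
class PheromoneGrid:
    """A rendered field: non-negative intensities plus their 8-bit image."""

    intensity: np.ndarray
    image: np.ndarray  # uint8, same shape

    def __post_init__(self) -> None:
        if self.intensity.shape != self.image.shape:
            raise ValueError("intensity and image shapes differ")


def point_intensity(P: float, x: float, sigma: float) -> float:
    """Sensed intensity at distance x from a single source (linear diffusion)."""
    if P < 0 or x < 0 or sigma <= 0:
        raise ValueError("require P >= 0, x >= 0, sigma > 0")
    if x > sigma:
        return 0.0
    return P * (1.0 - x / sigma)


def _distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def aggregate_intensity(
    sources: Sequence[PheromoneSource],
    point: tuple[float, float],
    params: PheromoneParams,
) -> float:
    """Superposition of all sources' diffusion at one grid point."""
    return sum(
        point_intensity(s.intensity, _distance(point, s.position), params.sigma)
        for s in sources
    )


def aggregate_with_evaporation(
    sources: Sequence[PheromoneSource],
    point: tuple[float, float],
    t: float,
    params: PheromoneParams,
) -> float:
    """Superposition with linear evaporation, evaluated at time t (minutes).

    Both the diffusion factor (1 - d/sigma) and the decay factor
    (1 - (t - t_k)/tau) are clipped below at zero: a source out of range or
    fully evaporated contributes nothing.
    """
    total = 0.0
    for s in sources:
        if s.t_created is None:
            raise ValueError("evaporation mode requires source creation times")
        if t < s.t_created:
            raise ValueError("evaluation time precedes a source creation time")
        space = max(0.0, 1.0 - _distance(point, s.position) / params.sigma)
        decay = max(0.0, 1.0 - (t - s.t_created) / params.tau)
        total += s.intensity * space * decay
    return total


@lru_cache(maxsize=32)
def _weight_grid(grid_size: int, sigma: float, position: tuple[float, float]) -> np.ndarray:
    """Diffusion kernel max(0, 1 - d/sigma) of a unit source, over the grid.

    Pixel coordinates are cell centers, row-major, origin top-left, 0-based.
    """
    rr, cc = np.mgrid[0:grid_size, 0:grid_size]
    d = np.hypot(rr - position[0], cc - position[1])
    return np.maximum(0.0, 1.0 - d / sigma)


def _place_kernels(params: PheromoneParams, places: Sequence[str]) -> np.ndarray:
    return np.stack(
        [
            _weight_grid(params.grid_size, params.sigma, tuple(params.place_positions[p]))
            for p in places
        ]
    )


def quantize_to_grayscale(intensity: np.ndarray, p_max: float) -> np.ndarray:
    """Map intensities to 8-bit gray: 0 -> black, >= p_max -> white (255).

    pixel = round(255 * min(I, p_max) / p_max) with round-half-up, so that
    I = p_max/2 gives 128.  Monotone non-decreasing in intensity.
    """
    if p_max <= 0:
        raise ValueError("p_max must be > 0")
    intensity = np.asarray(intensity, dtype=float)
    if (intensity < 0).any():
        raise ValueError("intensity must be non-negative")
    scaled = 255.0 * np.minimum(intensity, p_max) / p_max
    return np.floor(scaled + 0.5).astype(np.uint8)


def render_hourly_map(
    counts_for_hour: Mapping[str, float],
    params: PheromoneParams,
    mode: str = "count",
    event_times: Mapping[str, Sequence[float]] | None = None,
    intensity_cap: float | None = None,
) -> PheromoneGrid:
    """Render one hour's pheromone distribution map.

    In the default ``count`` mode every place gets one source whose intensity
    is the hourly (possibly fractional, e.g. averaged) event count.  In
    ``evaporation`` mode each event is a unit source created at its
    within-hour minute, and the field is evaluated at the end of the hour
    with linear decay.
    """
    unknown = set(counts_for_hour) - set(params.place_positions)
    if unknown:
        raise KeyError(f"unknown places: {sorted(unknown)}")
    places = [p for p in params.place_positions if p in counts_for_hour]
    g = params.grid_size
    if mode == "count":
        kernels = _place_kernels(params, places)
        weights = np.array([counts_for_hour[p] for p in places], dtype=float)
        if (weights < 0).any():
            raise ValueError("counts must be non-negative")
        intensity = np.tensordot(weights, kernels, axes=1) if places else np.zeros((g, g))
    elif mode == "evaporation":
        if event_times is None:
            raise ValueError("evaporation mode requires event_times")
        kernels = _place_kernels(params, places)
        intensity = np.zeros((g, g))
        for i, p in enumerate(places):
            for t_k in event_times.get(p, ()):
                decay = max(0.0, 1.0 - (60.0 - t_k) / params.tau)
                intensity += decay * kernels[i]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cap = intensity_cap if intensity_cap is not None else params.intensity_cap
    if cap is None:
        cap = max(float(intensity.max()), 1e-12)  # per-image scaling fallback
    return PheromoneGrid(intensity=intensity, image=quantize_to_grayscale(intensity, cap))


def auto_intensity_cap(counts_seq: Sequence[HourlyCounts], q: float = 99.0) -> float:
    """Grayscale white point: the q-th percentile of all per-place hourly
    counts over the processed interval (stable across days)."""
    values = np.concatenate([hc.counts.ravel() for hc in counts_seq])
    cap = float(np.percentile(values, q))
    return cap if cap > 0 else 1.0


def render_day_images(
    counts: HourlyCounts,
    params: PheromoneParams,
    intensity_cap: float | None = None,
) -> np.ndarray:
    """The 24 hourly 8-bit maps of one day, shape (24, grid, grid)."""
    return np.stack(
        [
            render_hourly_map(
                counts.place_counts(h), params, intensity_cap=intensity_cap
            ).image
            for h in range(24)
        ]
    )


def write_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def daily_montage(
    images: np.ndarray, columns: int = 6, pad: int = 2
) -> np.ndarray:
    """Tile a day's 24 hourly maps into one image (row-major, hour order)."""
    n, g, _ = images.shape
    rows = int(np.ceil(n / columns))
    out = np.zeros((rows * (g + pad) - pad, columns * (g + pad) - pad), dtype=np.uint8)
    for k in range(n):
        r, c = divmod(k, columns)
        out[r * (g + pad) : r * (g + pad) + g, c * (g + pad) : c * (g + pad) + g] = images[k]
    return out


def write_day_maps(
    day: dt.date,
    images: np.ndarray,
    outdir: str | Path,
    montage: bool = False,
) -> None:
    """Write one PNG per hour named ``YYYY-MM-DD_hHH.png`` (plus an optional
    24-tile montage)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for h in range(images.shape[0]):
        write_png(images[h], outdir / f"{day.isoformat()}_h{h:02d}.png")
    if montage:
        write_png(daily_montage(images), outdir / f"{day.isoformat()}_montage.png")
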