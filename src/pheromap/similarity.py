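"""Reference image sets and SSIM-based similarity series.

The "normal" routine is summarized as 24 reference maps, one per hour,
rendered from sensor counts averaged hour-by-hour over a reference window
(typically one low-dispersion week).  Each monitored day's 24 hourly maps
are compared to the reference with the structural similarity index

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
                 / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)),

computed globally over the whole image (the pheromone maps are smooth, so a
sliding window adds nothing), with C1 = (k1 L)^2, C2 = (k2 L)^2 and the
MATLAB defaults k1 = 0.01, k2 = 0.03, L = 255.  The daily similarity index
is the mean of the hourly SSIMs over a chosen hour subset (all 24 by
default; 7-9 isolates the breakfast routine, 0-5 the night).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import HourlyCounts
from .pheromone import PheromoneParams, render_hourly_map

__all__ = [
    "SSIMParams",
    "ReferenceSet",
    "SimilaritySeries",
    "ssim",
    "build_reference_set",
    "select_reference_window",
    "similarity_series",
    "daily_image_stacks",
    "read_annotations",
    "sleep_durations_from_annotations",
]

MORNING_HOURS = (7, 8, 9)  # the 7-10 a.m. breakfast window
NIGHT_HOURS = (0, 1, 2, 3, 4, 5)  # midnight to 6 a.m.


@dataclass(frozen=True)
class SSIMParams:
    k1: float = 0.01
    k2: float = 0.03
    L: float = 255.0

    def __post_init__(self) -> None:
        if not (0 < self.k1 < 1 and 0 < self.k2 < 1 and self.L > 0):
            raise ValueError("require 0 < k1, k2 << 1 and L > 0")

    @property
    def C1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.k2 * self.L) ** 2


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Global (single-window, whole-image) structural similarity in [-1, 1].

    Means, variances and covariance are population statistics (divisor N,
    the pixel count).  Symmetric in its arguments; ssim(x, x) == 1 exactly.
    """
    if params is None:
        params = SSIMParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cxy = ((x - mx) * (y - my)).mean()
    c1, c2 = params.C1, params.C2
    return float(
        ((2 * mx * my + c1) * (2 * cxy + c2))
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


@dataclass(frozen=True)
class ReferenceSet:
    """24 hourly reference maps averaged over a window of days."""

    hourly_images: np.ndarray  # (24, grid, grid) uint8
    window: tuple[dt.date, dt.date]
    method: str = "manual"  # manual | min_dispersion | min_sleep_std

    def __post_init__(self) -> None:
        if self.hourly_images.shape[0] != 24:
            raise ValueError("a reference set holds exactly 24 hourly images")
        if self.window[0] > self.window[1]:
            raise ValueError("reference window is empty")


def _window_slice(
    counts: Sequence[HourlyCounts], window: tuple[dt.date, dt.date]
) -> list[HourlyCounts]:
    start, end = window
    sel = [hc for hc in counts if start <= hc.day <= end]
    n_days = (end - start).days + 1
    if len(sel) != n_days:
        raise ValueError(
            f"window {start}..{end} not fully covered by counts ({len(sel)}/{n_days} days)"
        )
    return sel


def build_reference_set(
    counts: Sequence[HourlyCounts],
    window: tuple[dt.date, dt.date],
    params: PheromoneParams,
    intensity_cap: float | None = None,
    method: str = "manual",
) -> ReferenceSet:
    """Average the hourly counts over the window days (data, not pixels) and
    render the 24 mean-count maps.

    With count-mode rendering, averaging counts then rendering equals
    averaging the pre-quantization intensity fields, by linearity of the
    superposition in the source intensities; quantization is applied once,
    after averaging.
    """
    if window[0] > window[1]:
        raise ValueError("empty reference window")
    sel = _window_slice(counts, window)
    places = sel[0].places
    mean_counts = np.mean([hc.counts for hc in sel], axis=0)  # (places, 24)
    images = np.stack(
        [
            render_hourly_map(
                {p: float(mean_counts[i, h]) for i, p in enumerate(places)},
                params,
                intensity_cap=intensity_cap,
            ).image
            for h in range(24)
        ]
    )
    return ReferenceSet(hourly_images=images, window=window, method=method)


def select_reference_window(
    counts: Sequence[HourlyCounts],
    length_days: int = 7,
    criterion: str = "min_dispersion",
    sleep_durations: Mapping[dt.date, float] | None = None,
) -> tuple[dt.date, dt.date]:
    """Pick the most uniform ``length_days``-day stretch as the reference.

    min_dispersion: minimize the sum over (place, hour) cells of the
    across-days standard deviation of counts.  min_sleep_std: minimize the
    standard deviation of per-day sleep duration (requires annotations or
    simulation ground truth).  Earliest window wins ties.
    """
    days = [hc.day for hc in counts]
    if len(days) < length_days:
        raise ValueError(f"need >= {length_days} consecutive days, have {len(days)}")
    if any((days[i + 1] - days[i]).days != 1 for i in range(len(days) - 1)):
        raise ValueError("counts must cover consecutive days")
    if criterion == "min_dispersion":
        cube = np.stack([hc.counts for hc in counts])  # (days, places, 24)
        scores = [
            float(cube[i : i + length_days].std(axis=0).sum())
            for i in range(len(days) - length_days + 1)
        ]
    elif criterion == "min_sleep_std":
        if sleep_durations is None:
            raise ValueError("min_sleep_std requires per-day sleep durations")
        try:
            sleep = np.array([sleep_durations[d] for d in days], dtype=float)
        except KeyError as e:
            raise ValueError(f"missing sleep duration for day {e}") from e
        scores = [
            float(sleep[i : i + length_days].std())
            for i in range(len(days) - length_days + 1)
        ]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = int(np.argmin(scores))  # argmin takes the first minimum: earliest wins
    return (days[best], days[best + length_days - 1])


@dataclass
class SimilaritySeries:
    """Per-day similarity of the rendered maps to the reference set."""

    days: list[dt.date]
    daily_index: np.ndarray  # (n_days,), values in [-1, 1]
    hours: tuple[int, ...]  # hour subset the daily index averages over
    per_hour: np.ndarray | None = None  # (n_days, 24), NaN outside subset
    reference_window: tuple[dt.date, dt.date] | None = None

    def to_frame(self, include_hours: bool = True) -> pd.DataFrame:
        out = pd.DataFrame(
            {"date": [d.isoformat() for d in self.days], "daily_index": self.daily_index}
        )
        if include_hours and self.per_hour is not None:
            for h in self.hours:
                out[f"h{h:02d}"] = self.per_hour[:, h]
        return out

    def write_csv(self, path: str | Path, include_hours: bool = True) -> None:
        self.to_frame(include_hours).to_csv(path, index=False, float_format="%.6f")

    def value(self, day: dt.date) -> float:
        return float(self.daily_index[self.days.index(day)])

    def __len__(self) -> int:
        return len(self.days)


def daily_image_stacks(
    counts: Sequence[HourlyCounts],
    params: PheromoneParams,
    intensity_cap: float | None = None,
) -> dict[dt.date, np.ndarray]:
    """Render every day's 24 hourly maps; keyed by date."""
    from .pheromone import render_day_images

    return {
        hc.day: render_day_images(hc, params, intensity_cap=intensity_cap)
        for hc in counts
    }


def similarity_series(
    daily_images: Mapping[dt.date, np.ndarray],
    reference: ReferenceSet,
    hours: Iterable[int] | None = None,
    ssim_params: SSIMParams | None = None,
) -> SimilaritySeries:
    """SSIM of each day's hourly maps against the reference, averaged over
    the chosen hour subset into a per-day index."""
    hours = tuple(range(24)) if hours is None else tuple(sorted(hours))
    if not hours:
        raise ValueError("empty hour subset")
    if any(h < 0 or h > 23 for h in hours):
        raise ValueError("hours must lie in 0..23")
    if ssim_params is None:
        ssim_params = SSIMParams()
    days = sorted(daily_images)
    per_hour = np.full((len(days), 24), np.nan)
    for i, d in enumerate(days):
        stack = daily_images[d]
        for h in hours:
            per_hour[i, h] = ssim(stack[h], reference.hourly_images[h], ssim_params)
    daily = np.nanmean(per_hour[:, list(hours)], axis=1)
    return SimilaritySeries(
        days=list(days),
        daily_index=daily,
        hours=hours,
        per_hour=per_hour,
        reference_window=reference.window,
    )


def plot_series(
    series: SimilaritySeries,
    path: str | Path,
    title: str = "Daily similarity index",
) -> None:
    """Index-vs-date plot with the reference window shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(series.days, series.daily_index, marker="o", ms=3, lw=1)
    if series.reference_window is not None:
        ax.axvspan(*series.reference_window, alpha=0.15, label="reference window")
        ax.legend(loc="lower left")
    ax.set_xlabel("date")
    ax.set_ylabel("similarity index")
    ax.set_title(title)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# optional annotations (used only to derive sleep durations)
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Kasteren-style activity annotations: CSV ``start,end,activity``."""
    frame = pd.read_csv(path, dtype={"activity": str})
    frame["start"] = pd.to_datetime(frame["start"])
    frame["end"] = pd.to_datetime(frame["end"])
    return frame


def sleep_durations_from_annotations(
    annotations: pd.DataFrame, activity: str = "sleep"
) -> dict[dt.date, float]:
    """Hours of the named activity per day; an interval is attributed to the
    calendar day it starts on."""
    sel = annotations[annotations["activity"].str.lower().str.contains(activity.lower())]
    out: dict[dt.date, float] = {}
    for row in sel.itertuples(index=False):
        hours = (row.end - row.start).total_seconds() / 3600.0
        day = row.start.date()
        out[day] = out.get(day, 0.0) + hours
    return out
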