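"""Deviation detection on a daily similarity series.

Two kinds of routine deviation are flagged:

* **singular days** — days whose similarity index falls well below the bulk
  of the series (one-sided robust z-score: below median − k·1.4826·MAD, or
  below an optional absolute floor);
* **slow-deviating trends** — a sustained drop, found as the single change
  point of a two-segment piecewise-constant fit (exhaustive SSE scan) that
  explains enough of the variance and is *descending*.

Only low similarity is anomalous: a day more similar to the reference than
usual is not a deviation.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .similarity import SimilaritySeries

__all__ = [
    "OutlierDay",
    "TrendShift",
    "AnomalyReport",
    "detect_outlier_days",
    "detect_trend_shift",
    "analyze",
]

#: dispersion substituted when over half the values are identical (MAD = 0),
#: so genuinely deviant days remain flaggable
MAD_EPSILON = 0.01

#: consistency factor making MAD estimate the normal standard deviation
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class OutlierDay:
    date: dt.date
    daily_index: float
    robust_z: float


@dataclass(frozen=True)
class TrendShift:
    change_date: dt.date
    change_index: int  # first day of the second segment
    mean_before: float
    mean_after: float
    sse_reduction: float  # fraction of one-segment SSE removed by the split


@dataclass
class AnomalyReport:
    outlier_days: list[OutlierDay]
    trend_change: TrendShift | None
    params_used: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outlier_days": [
                {"date": o.date.isoformat(), "daily_index": o.daily_index, "robust_z": o.robust_z}
                for o in self.outlier_days
            ],
            "trend_change": None
            if self.trend_change is None
            else {
                "change_date": self.trend_change.change_date.isoformat(),
                "change_index": self.trend_change.change_index,
                "mean_before": self.trend_change.mean_before,
                "mean_after": self.trend_change.mean_after,
                "sse_reduction": self.trend_change.sse_reduction,
            },
            "params_used": self.params_used,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_text(self) -> str:
        lines = ["Anomaly report", "=============="]
        if self.outlier_days:
            lines.append("Unusual days (low similarity):")
            for o in self.outlier_days:
                lines.append(
                    f"  {o.date.isoformat()}  index={o.daily_index:.4f}  robust_z={o.robust_z:.2f}"
                )
        else:
            lines.append("No unusual days flagged.")
        if self.trend_change is not None:
            t = self.trend_change
            lines.append(
                f"Descending trend shift at {t.change_date.isoformat()}: "
                f"mean {t.mean_before:.4f} -> {t.mean_after:.4f} "
                f"(SSE reduction {100 * t.sse_reduction:.1f}%)"
            )
        else:
            lines.append("No trend shift detected.")
        return "\n".join(lines) + "\n"

    def write_text(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def _robust_flags(
    values: np.ndarray, k: float, floor: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided robust z-scores and the boolean flag mask."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    scale = MAD_SCALE * mad if mad > 0 else MAD_EPSILON
    z = (values - med) / scale
    flags = z < -k
    if floor is not None:
        flags |= values < floor
    return z, flags


def detect_outlier_days(
    series: SimilaritySeries,
    k: float = 3.0,
    floor: float | None = None,
) -> list[OutlierDay]:
    """Flag days whose similarity index is anomalously LOW.

    A day is flagged iff its index is below median − k·1.4826·MAD of the
    whole series (MAD = 0 falls back to a small fixed dispersion), or below
    the absolute ``floor`` when one is given.  Requires >= 7 days.
    """
    values = np.asarray(series.daily_index, dtype=float)
    if len(values) < 7:
        raise ValueError("outlier detection needs a series of >= 7 days")
    z, flags = _robust_flags(values, k, floor)
    return [
        OutlierDay(date=series.days[i], daily_index=float(values[i]), robust_z=float(z[i]))
        for i in np.flatnonzero(flags)
    ]


def _sse(values: np.ndarray) -> float:
    return float(((values - values.mean()) ** 2).sum())


def detect_trend_shift(
    series: SimilaritySeries,
    min_segment: int = 5,
    min_sse_reduction: float = 0.30,
) -> TrendShift | None:
    """Find a single *descending* change point by exhaustive SSE scan.

    Every split with both segments >= ``min_segment`` days is scored by the
    SSE of the two-segment piecewise-constant fit; the best split is
    reported iff it removes more than ``min_sse_reduction`` of the
    one-segment SSE and mean_after < mean_before.
    """
    values = np.asarray(series.daily_index, dtype=float)
    n = len(values)
    if n < 2 * min_segment:
        raise ValueError(f"trend detection needs >= {2 * min_segment} days, have {n}")
    sse0 = _sse(values)
    if sse0 == 0.0:
        return None
    best_c, best_sse = None, np.inf
    for c in range(min_segment, n - min_segment + 1):
        s = _sse(values[:c]) + _sse(values[c:])
        if s < best_sse:
            best_c, best_sse = c, s
    reduction = (sse0 - best_sse) / sse0
    mean_before = float(values[:best_c].mean())
    mean_after = float(values[best_c:].mean())
    if reduction <= min_sse_reduction or mean_after >= mean_before:
        return None
    return TrendShift(
        change_date=series.days[best_c],
        change_index=best_c,
        mean_before=mean_before,
        mean_after=mean_after,
        sse_reduction=float(reduction),
    )


def analyze(
    series: SimilaritySeries,
    k: float = 3.0,
    floor: float | None = None,
    min_segment: int = 5,
    min_sse_reduction: float = 0.30,
) -> AnomalyReport:
    """Full deviation analysis: singular days and a trend shift, robustly.

    The two deviation kinds interfere: a sustained level shift inflates the
    global dispersion estimate used for outliers, and extreme singular days
    dominate the SSE that scores candidate change points.  The analysis
    therefore proceeds in three passes: (1) flag extreme days with the
    global robust rule and mask them; (2) scan the masked series for a
    single descending change point; (3) if one is found, re-apply the
    outlier rule within each segment, re-centered on that segment's own
    median.  Segments shorter than 7 days fall back to the global rule.
    """
    values = np.asarray(series.daily_index, dtype=float)
    trend = None
    if len(values) >= 2 * min_segment:
        _, prelim = _robust_flags(values, k, floor)
        masked_idx = np.flatnonzero(~prelim)
        if len(masked_idx) >= 2 * min_segment:
            masked = SimilaritySeries(
                days=[series.days[i] for i in masked_idx],
                daily_index=values[masked_idx],
                hours=series.hours,
            )
            t = detect_trend_shift(masked, min_segment, min_sse_reduction)
            if t is not None:
                # map the change point back onto the full series
                full_c = series.days.index(t.change_date)
                trend = TrendShift(
                    change_date=t.change_date,
                    change_index=full_c,
                    mean_before=t.mean_before,
                    mean_after=t.mean_after,
                    sse_reduction=t.sse_reduction,
                )
    if trend is None:
        outliers = detect_outlier_days(series, k=k, floor=floor)
    else:
        c = trend.change_index
        segments = [(0, c), (c, len(values))]
        if any(b - a < 7 for a, b in segments):
            outliers = detect_outlier_days(series, k=k, floor=floor)
        else:
            outliers = []
            for a, b in segments:
                z, flags = _robust_flags(values[a:b], k, floor)
                outliers.extend(
                    OutlierDay(
                        date=series.days[a + i],
                        daily_index=float(values[a + i]),
                        robust_z=float(z[i]),
                    )
                    for i in np.flatnonzero(flags)
                )
    return AnomalyReport(
        outlier_days=sorted(outliers, key=lambda o: o.date),
        trend_change=trend,
        params_used={
            "k": k,
            "floor": floor,
            "min_segment": min_segment,
            "min_sse_reduction": min_sse_reduction,
        },
    )
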