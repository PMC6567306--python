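"""End-to-end orchestration: log -> counts -> maps -> similarity -> report.

This is the layer the command-line interface wraps; it is equally usable
from Python.  All artifacts are plain text (CSV/JSON) plus PNG images, and
every run is deterministic given its configuration and seed.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import anomaly as anomaly_mod
from .events import (
    EventLog,
    HourlyCounts,
    PlaceMapping,
    hourly_counts,
    preprocess,
    read_casas_log,
    read_generic_csv,
    write_daily_activity_csv,
)
from .pheromone import PheromoneParams, auto_intensity_cap, render_day_images, write_day_maps
from .similarity import (
    ReferenceSet,
    SimilaritySeries,
    SSIMParams,
    build_reference_set,
    daily_image_stacks,
    plot_series,
    select_reference_window,
    similarity_series,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_counts", "load_log"]


@dataclass
class PipelineConfig:
    """Everything one monitoring run needs.

    ``reference_start``/``reference_days`` pin the reference window manually;
    leaving ``reference_start`` unset selects the lowest-dispersion window of
    ``reference_days`` consecutive days automatically.
    """

    inputs: Sequence[str | Path]
    dialect: str = "casas"  # casas | generic_csv
    mapping: PlaceMapping | str | Path = "hh126"
    pheromone: PheromoneParams = field(default_factory=PheromoneParams)
    ssim: SSIMParams = field(default_factory=SSIMParams)
    hours: tuple[int, ...] | None = None
    reference_start: dt.date | None = None
    reference_days: int = 7
    reference_criterion: str = "min_dispersion"
    outlier_k: float = 3.0
    outlier_floor: float | None = None
    min_segment: int = 5
    min_sse_reduction: float = 0.30
    outdir: str | Path = "pheromap_out"
    write_maps: bool = False
    montage: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    counts: list[HourlyCounts]
    reference: ReferenceSet
    series: SimilaritySeries
    report: anomaly_mod.AnomalyReport
    ledger: dict[str, int]
    intensity_cap: float
    artifacts: dict[str, Path] = field(default_factory=dict)


def _resolve_mapping(mapping: PlaceMapping | str | Path) -> PlaceMapping:
    if isinstance(mapping, PlaceMapping):
        return mapping
    if mapping == "hh126":
        return PlaceMapping.hh126()
    if mapping == "kasteren_c":
        return PlaceMapping.kasteren_c()
    return PlaceMapping.from_yaml(mapping)


def load_log(paths: Sequence[str | Path], dialect: str) -> EventLog:
    """Read and concatenate one or more log files of the same dialect."""
    import pandas as pd

    readers = {"casas": read_casas_log, "generic_csv": read_generic_csv}
    if dialect not in readers:
        raise ValueError(f"unknown dialect {dialect!r}")
    logs = [readers[dialect](p) for p in paths]
    if not logs:
        raise ValueError("no input files")
    if len(logs) == 1:
        return logs[0]
    frame = pd.concat([l.frame for l in logs], ignore_index=True)
    return EventLog(frame, dialect=dialect)


def analyze_counts(
    counts: Sequence[HourlyCounts],
    pheromone: PheromoneParams | None = None,
    ssim_params: SSIMParams | None = None,
    hours: Sequence[int] | None = None,
    reference_window: tuple[dt.date, dt.date] | None = None,
    reference_days: int = 7,
    reference_criterion: str = "min_dispersion",
    sleep_durations=None,
    outlier_k: float = 3.0,
    outlier_floor: float | None = None,
    min_segment: int = 5,
    min_sse_reduction: float = 0.30,
) -> tuple[ReferenceSet, SimilaritySeries, anomaly_mod.AnomalyReport, float]:
    """Core analysis on already-binned counts; returns (reference, series,
    report, intensity cap).  The grayscale cap is fixed once over the whole
    interval so day and reference maps share a white point."""
    pheromone = pheromone or PheromoneParams()
    cap = pheromone.intensity_cap or auto_intensity_cap(counts)
    if reference_window is None:
        reference_window = select_reference_window(
            counts,
            length_days=reference_days,
            criterion=reference_criterion,
            sleep_durations=sleep_durations,
        )
        method = reference_criterion
    else:
        method = "manual"
    reference = build_reference_set(
        counts, reference_window, pheromone, intensity_cap=cap, method=method
    )
    stacks = daily_image_stacks(counts, pheromone, intensity_cap=cap)
    series = similarity_series(stacks, reference, hours=hours, ssim_params=ssim_params)
    report = anomaly_mod.analyze(
        series,
        k=outlier_k,
        floor=outlier_floor,
        min_segment=min_segment,
        min_sse_reduction=min_sse_reduction,
    )
    return reference, series, report, cap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole method and write its artifact set under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapping = _resolve_mapping(config.mapping)

    raw = load_log(config.inputs, config.dialect)
    placed, ledger = preprocess(raw, mapping)
    log.info("stage ledger: %s", ledger)
    counts = hourly_counts(placed, places=mapping.places)
    if not counts:
        raise ValueError("no events survive preprocessing; nothing to analyze")

    window = None
    if config.reference_start is not None:
        window = (
            config.reference_start,
            config.reference_start + dt.timedelta(days=config.reference_days - 1),
        )
    reference, series, report, cap = analyze_counts(
        counts,
        pheromone=config.pheromone,
        ssim_params=config.ssim,
        hours=config.hours,
        reference_window=window,
        reference_days=config.reference_days,
        reference_criterion=config.reference_criterion,
        outlier_k=config.outlier_k,
        outlier_floor=config.outlier_floor,
        min_segment=config.min_segment,
        min_sse_reduction=config.min_sse_reduction,
    )

    artifacts: dict[str, Path] = {}
    p = outdir / "daily_activity.csv"
    write_daily_activity_csv(counts, p)
    artifacts["daily_activity"] = p
    p = outdir / "similarity.csv"
    series.write_csv(p)
    artifacts["similarity"] = p
    p = outdir / "similarity.png"
    plot_series(series, p)
    artifacts["plot"] = p
    p = outdir / "anomaly_report.json"
    report.write_json(p)
    artifacts["report_json"] = p
    p = outdir / "anomaly_report.txt"
    report.write_text(p)
    artifacts["report_txt"] = p
    if config.write_maps:
        mapdir = outdir / "maps"
        for hc in counts:
            images = render_day_images(hc, config.pheromone, intensity_cap=cap)
            write_day_maps(hc.day, images, mapdir, montage=config.montage)
        artifacts["maps"] = mapdir

    return PipelineResult(
        counts=list(counts),
        reference=reference,
        series=series,
        report=report,
        ledger=ledger,
        intensity_cap=cap,
        artifacts=artifacts,
    )
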