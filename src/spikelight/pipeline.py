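"""End-to-end per-unit analysis: QC, classification, detection, summary record.

Thin composition of the classify, psth and cohort modules; the CLI and
batch entry points go through here.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .classify import (
    CellClass,
    InsufficientDataError,
    baseline_stats,
    classify_striatal,
    unit_qc,
)
from .cohort import UnitResult
from .io import Region, Session, SpikeTrain, StimProtocol
from .psth import (
    Alignment,
    DetectionConfig,
    ResponseCategory,
    build_psth,
    detect_response,
    latency_to_peak,
    post_train_suppression,
    response_magnitude,
)
from .psth import InsufficientDataError as _PsthInsufficientData

__all__ = ["analyze_unit", "analyze_session", "DEFAULT_N_BINS"]

#: default train-aligned PSTH geometry: 40 + 40 bins of 8.125 ms
DEFAULT_N_BINS = 40


def analyze_unit(
    train: SpikeTrain,
    protocol: StimProtocol,
    config: DetectionConfig = DetectionConfig(),
    *,
    n_bins_pre: int = DEFAULT_N_BINS,
    n_bins_post: int = DEFAULT_N_BINS,
    baseline_epoch: Optional[tuple[float, float]] = None,
    classify: bool = True,
    measure_latency: bool = True,
    suppression_bins_post: int = 96,
) -> UnitResult:
    """Run the full single-unit analysis and return its summary record.

    QC, baseline classification (striatal units only), train-aligned
    response detection and magnitude, first-pulse latency for increase
    responses, and post-train suppression on an extended window
    (``suppression_bins_post`` post bins). A unit whose firing increases
    during the train and is then significantly suppressed after train end
    is labeled COMBINATION (an increase followed by a decrease), whether
    the decrease falls inside or beyond the standard 40-bin window.
    """
    first_onset = protocol.trains[0].onset if protocol.trains else train.recording_end
    epoch = baseline_epoch or (train.recording_start, first_onset)

    try:
        qc = unit_qc(train)
        qc_passed = qc.passed
    except InsufficientDataError:
        qc_passed = False

    cell_class: Optional[CellClass] = None
    if classify and train.region is Region.PUTAMEN:
        try:
            stats = baseline_stats(train, epoch)
            cell_class = classify_striatal(stats)
        except (InsufficientDataError, ValueError):
            cell_class = CellClass.UNCLASSIFIED

    onsets = protocol.train_onsets()
    psth = build_psth(
        train, onsets, config.bin_width_train, n_bins_pre, n_bins_post,
        alignment=Alignment.TRAIN_ONSET,
    )
    result = detect_response(psth, config)

    magnitude = result.magnitude
    if magnitude is None and n_bins_pre == n_bins_post:
        magnitude = response_magnitude(psth, config)

    latency = None
    if measure_latency and result.category in (
        ResponseCategory.INCREASE,
        ResponseCategory.COMBINATION,
    ):
        # latency to maximal effect: fine bins, first pulse of each train only
        n_fine = int(round(25.0 / config.bin_width_pulse))
        fine = build_psth(
            train, onsets, config.bin_width_pulse, n_fine, n_fine,
            alignment=Alignment.PULSE_ONSET,
        )
        latency = latency_to_peak(fine)

    suppression = None
    category = result.category
    train_span_ms = protocol.trains[0].span_s * 1000.0 if protocol.trains else 0.0
    if protocol.trains and suppression_bins_post * config.bin_width_train >= train_span_ms + 400.0:
        try:
            ext = build_psth(
                train, onsets, config.bin_width_train, n_bins_pre,
                suppression_bins_post, alignment=Alignment.TRAIN_ONSET,
            )
            suppression = post_train_suppression(ext, train_span_ms, config)
        except _PsthInsufficientData:
            suppression = None
        if suppression is not None and category is ResponseCategory.INCREASE:
            category = ResponseCategory.COMBINATION

    return UnitResult(
        unit_id=train.unit_id,
        region=train.region,
        sort_quality=train.sort_quality,
        category=category,
        cell_class=cell_class,
        magnitude=magnitude,
        latency_ms=latency,
        suppression_ms=suppression,
        distance_mm=train.distance_to_injection,
        qc_passed=qc_passed,
    )


def analyze_session(
    session: Session,
    config: DetectionConfig = DetectionConfig(),
    **kwargs,
) -> list[UnitResult]:
    """Apply :func:`analyze_unit` to every unit of a session."""
    return [analyze_unit(u, session.protocol, config, **kwargs) for u in session.units]
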