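"""Pulse-width and light-intensity dose-response, and within-train decrement.

Pulse-width analysis: for single light pulses of varying duration, the
response magnitude is the number of spikes in the 20 ms after pulse onset
(regardless of pulse length — 20 ms being the longest pulse tested)
divided by the number of spikes in the 20 ms immediately preceding onset.
Both windows are half-open, ``(onset, onset + 20 ms]`` and
``(onset - 20 ms, onset]``. Significance per width reuses the run-based
2-SD detector on a pulse-aligned PSTH with 1 ms bins.

Intensity analysis: trains are grouped by block irradiance; each block is
scored with the train-aligned detector and the train-window fold-change.

Within-train decrement: evoked counts per pulse index are spikes in
``(pulse onset, next pulse onset]`` summed over trains, baseline-corrected
by subtracting rate x window, and summarized as the ratio of the first
pulse's evoked count to the mean over later pulses (1 = no decrement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import SpikeTrain, StimProtocol, TrainSpec
from .psth import (
    Alignment,
    DetectionConfig,
    ResponseCategory,
    build_psth,
    detect_response,
)

__all__ = [
    "PulseWidthResult",
    "IntensityResult",
    "TrainDecrement",
    "pulse_width_curve",
    "intensity_curve",
    "train_decrement",
    "MAGNITUDE_WINDOW_MS",
]

#: magnitude window for single-pulse analysis (the longest pulse tested), ms
MAGNITUDE_WINDOW_MS = 20.0


@dataclass(frozen=True)
class PulseWidthResult:
    width: float  # ms
    magnitude: float  # fold-change over the 20 ms pre window
    significant: bool
    n_trials: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class IntensityResult:
    intensity: float  # mW/mm^2
    magnitude: float
    significant: bool
    n_trials: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TrainDecrement:
    per_pulse_evoked: np.ndarray  # baseline-corrected counts per pulse index
    first_vs_rest_ratio: Optional[float]  # None when later pulses evoke nothing
    n_trains: int
    baseline_rate: float


def _count_left_open(ts: np.ndarray, t0: np.ndarray, t1: np.ndarray) -> np.ndarray:
    """Spikes in (t0, t1] for each window."""
    return np.searchsorted(ts, t1, side="right") - np.searchsorted(ts, t0, side="right")


def _significant_increase(
    train: SpikeTrain,
    onsets: np.ndarray,
    config: DetectionConfig,
    bin_width: float,
    n_pre: int,
    n_post: int,
    alignment: Alignment,
) -> tuple[bool, tuple[str, ...]]:
    psth = build_psth(train, onsets, bin_width, n_pre, n_post, alignment=alignment)
    res = detect_response(psth, config)
    sig = res.category in (ResponseCategory.INCREASE, ResponseCategory.COMBINATION)
    return sig, res.flags


def pulse_width_curve(
    train: SpikeTrain,
    protocol: StimProtocol,
    config: DetectionConfig = DetectionConfig(),
    *,
    widths: Optional[Sequence[float]] = None,
    sig_bin_width: float = 1.0,
) -> list[PulseWidthResult]:
    """Magnitude and significance per single-pulse width, sorted by width.

    ``widths`` restricts the analysis to the given widths; widths absent
    from the protocol are skipped with a warning. Significance uses the
    2-SD run detector on a pulse-aligned PSTH with ``sig_bin_width`` ms
    bins over 20 ms pre/post windows.
    """
    singles = [t for t in protocol.trains if t.n_pulses == 1]
    have = sorted({t.pulse_width for t in singles})
    if widths is None:
        widths = have
    results = []
    w_s = MAGNITUDE_WINDOW_MS / 1000.0
    n_bins = int(round(MAGNITUDE_WINDOW_MS / sig_bin_width))
    for w in widths:
        onsets = np.array([t.onset for t in singles if t.pulse_width == w])
        if onsets.size == 0:
            warnings.warn(f"pulse width {w:g} ms absent from protocol; skipped",
                          stacklevel=2)
            continue
        post = int(_count_left_open(train.timestamps, onsets, onsets + w_s).sum())
        pre = int(_count_left_open(train.timestamps, onsets - w_s, onsets).sum())
        magnitude = post / max(pre, config.baseline_floor_spikes)
        sig, flags = _significant_increase(
            train, onsets, config, sig_bin_width, n_bins, n_bins, Alignment.PULSE_ONSET
        )
        results.append(
            PulseWidthResult(
                width=float(w),
                magnitude=float(magnitude),
                significant=sig,
                n_trials=int(onsets.size),
                flags=flags,
            )
        )
    return sorted(results, key=lambda r: r.width)


def intensity_curve(
    train: SpikeTrain,
    protocol: StimProtocol,
    config: DetectionConfig = DetectionConfig(),
    *,
    n_bins: int = 40,
) -> list[IntensityResult]:
    """Magnitude and significance per light-intensity block, sorted by intensity.

    Blocks are maximal runs of consecutive trains sharing one irradiance
    (so an intensity revisited later forms a separate block). Each block is
    scored with the train-aligned detector (``config.bin_width_train``
    bins, ``n_bins`` pre and post) and the train-window fold-change.
    Single-trial blocks are flagged unreliable. Results are in block order.
    """
    blocks: list[tuple[float, list[TrainSpec]]] = []
    for t in protocol.trains:
        inten = protocol.train_intensity(t)
        if blocks and blocks[-1][0] == inten:
            blocks[-1][1].append(t)
        else:
            blocks.append((inten, [t]))
    results = []
    for inten, trains in blocks:
        onsets = np.array([t.onset for t in trains])
        psth = build_psth(
            train, onsets, config.bin_width_train, n_bins, n_bins,
            alignment=Alignment.TRAIN_ONSET,
        )
        res = detect_response(psth, config)
        flags = res.flags
        if onsets.size < 2:
            flags = flags + ("unreliable_single_trial",)
        pre = int(psth.baseline_counts().sum())
        post = int(psth.post_counts().sum())
        results.append(
            IntensityResult(
                intensity=float(inten),
                magnitude=post / max(pre, config.baseline_floor_spikes),
                significant=res.category
                in (ResponseCategory.INCREASE, ResponseCategory.COMBINATION),
                n_trials=int(onsets.size),
                flags=flags,
            )
        )
    return results


def train_decrement(
    train: SpikeTrain,
    protocol: StimProtocol,
    baseline_rate: Optional[float] = None,
) -> TrainDecrement:
    """Per-pulse evoked counts and the first-vs-rest decrement ratio.

    Evoked counts per pulse index are spikes in ``(onset_p, onset_{p+1}]``
    (the last pulse uses one inter-pulse period), summed over all
    multi-pulse trains, minus the expected baseline count ``rate x window``.
    ``baseline_rate`` defaults to the rate in the equal-duration windows
    preceding each train. The ratio is ``evoked[0] / mean(evoked[1:])``;
    None (undefined) when later pulses evoke no net spikes.
    """
    multi = [t for t in protocol.trains if t.n_pulses > 1]
    if not multi:
        raise ValueError("protocol contains no multi-pulse trains")
    n_pulses = {t.n_pulses for t in multi}
    period = {t.period_s for t in multi}
    if len(n_pulses) > 1 or len(period) > 1:
        raise ValueError("multi-pulse trains must share n_pulses and pulse_rate")
    npls, per = n_pulses.pop(), period.pop()
    ts = train.timestamps

    if baseline_rate is None:
        span = npls * per
        onsets = np.array([t.onset for t in multi])
        pre_counts = _count_left_open(ts, onsets - span, onsets)
        baseline_rate = float(pre_counts.sum() / (span * len(multi)))

    evoked = np.zeros(npls)
    for t in multi:
        p_on = t.pulse_onsets()
        p_off = p_on + per
        evoked += _count_left_open(ts, p_on, p_off)
    evoked -= baseline_rate * per * len(multi)

    rest = evoked[1:].mean()
    ratio = float(evoked[0] / rest) if rest > 0 else None
    if ratio is None:
        warnings.warn("later pulses evoke no net spikes; decrement ratio undefined",
                      stacklevel=2)
    return TrainDecrement(
        per_pulse_evoked=evoked,
        first_vs_rest_ratio=ratio,
        n_trains=len(multi),
        baseline_rate=float(baseline_rate),
    )
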