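"""Unit quality control and electrophysiological classification of striatal units.

Striatal cells fall into three classes separable by their spontaneous
activity: phasically active neurons (PANs, putative medium-spiny projection
neurons) fire at low rates with irregular, bursty interval statistics;
tonically active neurons (TANs, putative cholinergic interneurons) fire
regularly at intermediate rates; fast-spiking neurons (FSNs, putative
parvalbumin GABAergic interneurons) fire above 12 spikes/s. Classification
uses the firing rate and the interspike-interval coefficient of variation
(CV = SD/mean of ISIs) over a pre-stimulation baseline epoch of at least
120 s:

* PAN: rate <= 2.5 spikes/s and CV >= 1
* TAN: 2 <= rate <= 12 spikes/s and CV < 1
* FSN: rate > 12 spikes/s (any CV)
* otherwise UNCLASSIFIED

Rules are applied in the order PAN, TAN, FSN; the precedence only matters
for pathological ties. Boundary inclusion for the TAN rate range is read as
the closed interval [2, 12]. The CV uses the sample SD (n-1 denominator).

Single-unit quality control accepts a record only if fewer than 1% of its
ISIs are shorter than 2 ms; multi-unit records bypass the rule but are
flagged.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .io import SortQuality, SpikeTrain

__all__ = [
    "CellClass",
    "BaselineStats",
    "QcResult",
    "unit_qc",
    "baseline_stats",
    "classify_striatal",
    "InsufficientDataError",
    "EpochTooShortError",
    "MIN_BASELINE_EPOCH_S",
    "QC_ISI_THRESHOLD_S",
    "QC_MAX_SHORT_FRACTION",
]

MIN_BASELINE_EPOCH_S = 120.0
QC_ISI_THRESHOLD_S = 0.002
QC_MAX_SHORT_FRACTION = 0.01


class InsufficientDataError(ValueError):
    """Too few spikes to compute the requested statistic."""


class EpochTooShortError(ValueError):
    """Baseline epoch shorter than the 120 s classification floor."""


class CellClass(str, enum.Enum):
    PAN = "PAN"
    TAN = "TAN"
    FSN = "FSN"
    UNCLASSIFIED = "UNCLASSIFIED"


class QcResult(NamedTuple):
    passed: bool
    short_isi_fraction: float
    n_isis: int
    bypassed: bool  # True for MULTI records, which skip the rule


@dataclass(frozen=True)
class BaselineStats:
    """Firing rate and ISI CV over a pre-stimulation epoch.

    ``cv`` is None (undefined) when fewer than 3 spikes fall in the epoch,
    which leaves fewer than 2 ISIs.
    """

    firing_rate: float
    cv: Optional[float]
    epoch_duration: float
    n_spikes: int


def unit_qc(train: SpikeTrain) -> QcResult:
    """Check the short-ISI single-unit criterion.

    Fails iff the fraction of ISIs shorter than 2 ms is >= 1%. Multi-unit
    records bypass the rule (``bypassed=True``) but the fraction is still
    reported. The verdict is invariant to the time unit because only the
    ISI/threshold comparison enters.

    Raises
    ------
    InsufficientDataError
        If the train has fewer than 2 spikes (no ISIs).
    """
    if train.n_spikes < 2:
        raise InsufficientDataError(
            f"unit {train.unit_id}: need >= 2 spikes for ISI quality control"
        )
    isis = train.isis()
    frac = float(np.count_nonzero(isis < QC_ISI_THRESHOLD_S) / isis.size)
    if train.sort_quality is SortQuality.MULTI:
        return QcResult(passed=True, short_isi_fraction=frac, n_isis=isis.size, bypassed=True)
    return QcResult(
        passed=frac < QC_MAX_SHORT_FRACTION,
        short_isi_fraction=frac,
        n_isis=isis.size,
        bypassed=False,
    )


def baseline_stats(
    train: SpikeTrain,
    epoch: tuple[float, float],
    *,
    allow_short_epoch: bool = False,
) -> BaselineStats:
    """Compute firing rate and ISI CV over ``epoch = (t0, t1)``.

    The rate is the spike count in [t0, t1) divided by the epoch duration.
    The CV is computed on ISIs lying fully inside the epoch, with the
    sample SD (ddof=1).

    Raises
    ------
    EpochTooShortError
        If the epoch is shorter than 120 s and ``allow_short_epoch`` is not
        set (the classification rules assume at least 120 s of baseline).
    """
    t0, t1 = epoch
    duration = t1 - t0
    if duration <= 0:
        raise ValueError("epoch must have positive duration")
    if duration < MIN_BASELINE_EPOCH_S and not allow_short_epoch:
        raise EpochTooShortError(
            f"baseline epoch {duration:g} s < {MIN_BASELINE_EPOCH_S:g} s"
        )
    ts = train.timestamps
    inside = ts[(ts >= t0) & (ts < t1)]
    rate = inside.size / duration
    if inside.size < 3:
        cv: Optional[float] = None
    else:
        isis = np.diff(inside)
        mean = isis.mean()
        cv = float(isis.std(ddof=1) / mean) if mean > 0 else None
    return BaselineStats(
        firing_rate=float(rate), cv=cv, epoch_duration=float(duration), n_spikes=int(inside.size)
    )


def classify_striatal(stats: BaselineStats) -> CellClass:
    """Assign a striatal cell class from baseline rate and CV.

    Totality: every unit with a defined CV receives exactly one label; an
    undefined CV yields UNCLASSIFIED with a warning.
    """
    if stats.cv is None:
        warnings.warn(
            "CV undefined (fewer than 3 baseline spikes); unit left unclassified",
            stacklevel=2,
        )
        return CellClass.UNCLASSIFIED
    rate, cv = stats.firing_rate, stats.cv
    if rate <= 2.5 and cv >= 1.0:
        return CellClass.PAN
    if 2.0 <= rate <= 12.0 and cv < 1.0:
        return CellClass.TAN
    if rate > 12.0:
        return CellClass.FSN
    return CellClass.UNCLASSIFIED
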