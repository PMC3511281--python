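"""PSTH construction and light-evoked response detection.

The detector is a run-based exceedance rule on a trial-summed peri-stimulus
time histogram (PSTH). For train-aligned analysis the PSTH has 40 baseline
bins before train onset and 40 bins after, with 8.125 ms bins (325 ms
windows). Let mu and sigma be the mean and SD of the 40 baseline bin
counts. A response is a run of at least 2 consecutive post-onset bins with
counts strictly above mu + 2*sigma (increase) or strictly below
mu - 2*sigma (decrease). Categories:

* INCREASE — at least one increase run, no qualifying decrease ordering
* DECREASE — decrease run(s) only
* COMBINATION — an increase run ending before a decrease run begins
  (increase followed by decrease)
* NONE — no qualifying run

The response magnitude is a fold-change: total spikes in the stimulation
window divided by total spikes in the equal-duration pre-stimulation
window (with a configurable floor of 1 spike in the denominator so silent
baselines give finite ratios). Latency to the maximal effect is read off a
fine-binned (0.25 ms) PSTH aligned to the first pulse of each train, as
the center of the first maximal post-onset bin. Post-train suppression is
the same run rule applied to bins after the end of the pulse train, its
duration measured from the start of the first qualifying run to the first
bin back at or above threshold.

Baseline sigma is the sample SD (ddof=1) across baseline bins of the
trial-summed PSTH. With sigma = 0 (silent or perfectly regular baseline)
the strict inequality makes the rule permissive (any 2 consecutive bins
above mu); such results carry a ``sigma_zero`` flag.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import SpikeTrain

__all__ = [
    "Alignment",
    "Psth",
    "DetectionConfig",
    "ResponseCategory",
    "ResponseResult",
    "build_psth",
    "detect_response",
    "response_magnitude",
    "latency_to_peak",
    "normalize_population",
    "post_train_suppression",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """No usable alignment events or baseline bins."""


class Alignment(str, enum.Enum):
    TRAIN_ONSET = "TRAIN_ONSET"
    PULSE_ONSET = "PULSE_ONSET"


class ResponseCategory(str, enum.Enum):
    NONE = "NONE"
    INCREASE = "INCREASE"
    DECREASE = "DECREASE"
    COMBINATION = "COMBINATION"


@dataclass(frozen=True)
class Psth:
    """Binned, trial-aligned spike counts with an explicit baseline window.

    ``counts`` are summed over trials; bin ``i`` covers relative time
    ``[(i - n_bins_pre) * w, (i - n_bins_pre + 1) * w)`` with ``w`` the bin
    width (left-closed, right-open). ``per_trial_counts`` optionally keeps
    the trials-by-bins matrix.
    """

    alignment: Alignment
    bin_width: float  # ms
    n_bins_pre: int
    n_bins_post: int
    counts: np.ndarray
    n_trials: int
    per_trial_counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size != self.n_bins_pre + self.n_bins_post:
            raise ValueError("counts length must equal n_bins_pre + n_bins_post")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(int))
        if self.per_trial_counts is not None:
            ptc = np.asarray(self.per_trial_counts, dtype=int)
            if ptc.shape != (self.n_trials, counts.size):
                raise ValueError("per_trial_counts must be (n_trials, n_bins)")
            if not np.array_equal(ptc.sum(axis=0), counts):
                raise ValueError("per_trial_counts do not sum to counts")
            object.__setattr__(self, "per_trial_counts", ptc)

    @property
    def n_bins(self) -> int:
        return self.n_bins_pre + self.n_bins_post

    def bin_centers(self) -> np.ndarray:
        """Bin centers in ms relative to the alignment event."""
        return (np.arange(self.n_bins) - self.n_bins_pre + 0.5) * self.bin_width

    def baseline_counts(self) -> np.ndarray:
        return self.counts[: self.n_bins_pre]

    def post_counts(self) -> np.ndarray:
        return self.counts[self.n_bins_pre :]


@dataclass(frozen=True)
class DetectionConfig:
    """Detector thresholds and PSTH geometry defaults."""

    sd_multiplier: float = 2.0
    min_consecutive_bins: int = 2
    min_trials: int = 30
    bin_width_train: float = 8.125  # ms, train-aligned PSTHs
    bin_width_pulse: float = 0.25  # ms, first-pulse-aligned PSTHs
    baseline_floor_spikes: int = 1

    def __post_init__(self) -> None:
        for name in (
            "sd_multiplier",
            "min_consecutive_bins",
            "min_trials",
            "bin_width_train",
            "bin_width_pulse",
            "baseline_floor_spikes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ResponseResult:
    """Output of the response detector for one unit."""

    category: ResponseCategory
    significant_bins: tuple[tuple[int, int], ...]  # (post-onset bin index, +1/-1)
    magnitude: Optional[float]
    latency_to_peak: Optional[float] = None  # ms
    post_train_suppression: Optional[float] = None  # ms
    n_trials_used: int = 0
    flags: tuple[str, ...] = field(default=())


def build_psth(
    train: SpikeTrain,
    events: Sequence[float] | np.ndarray,
    bin_width: float,
    n_pre: int,
    n_post: int,
    *,
    alignment: Alignment = Alignment.TRAIN_ONSET,
    keep_trials: bool = False,
) -> Psth:
    """Bin spikes relative to repeated alignment events.

    A spike at time ``t`` relative to event ``e`` falls in bin
    ``floor((t - e)/w) + n_pre`` for ``t - e`` in ``[-n_pre*w, n_post*w)``.
    Events whose full window extends beyond the recording bounds are
    dropped with a warning.

    Raises
    ------
    InsufficientDataError
        If no events remain after window filtering.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if n_pre < 0 or n_post < 0 or n_pre + n_post == 0:
        raise ValueError("need a non-empty window")
    w_s = bin_width / 1000.0
    events = np.asarray(events, dtype=float)
    lo, hi = -n_pre * w_s, n_post * w_s
    ok = (events + lo >= train.recording_start) & (events + hi <= train.recording_end)
    if not np.all(ok):
        warnings.warn(
            f"dropping {int(np.count_nonzero(~ok))} event(s) whose window leaves "
            "the recording bounds",
            stacklevel=2,
        )
    events = events[ok]
    if events.size == 0:
        raise InsufficientDataError("no alignment events within the recording")

    n_bins = n_pre + n_post
    ts = train.timestamps
    per_trial = np.zeros((events.size, n_bins), dtype=int) if keep_trials else None
    counts = np.zeros(n_bins, dtype=int)
    for i, e in enumerate(events):
        seg = ts[np.searchsorted(ts, e + lo) : np.searchsorted(ts, e + hi)]
        rel = seg - e
        idx = np.floor(rel / w_s).astype(int) + n_pre
        idx = idx[(idx >= 0) & (idx < n_bins)]  # guard float edge effects
        binned = np.bincount(idx, minlength=n_bins)
        counts += binned
        if per_trial is not None:
            per_trial[i] = binned
    return Psth(
        alignment=alignment,
        bin_width=bin_width,
        n_bins_pre=n_pre,
        n_bins_post=n_post,
        counts=counts,
        n_trials=int(events.size),
        per_trial_counts=per_trial,
    )


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as (start, stop) pairs."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and mask.size - start >= min_len:
        runs.append((start, int(mask.size)))
    return runs


def baseline_mean_sd(psth: Psth) -> tuple[float, float]:
    """Mean and sample SD of the baseline bin counts."""
    base = psth.baseline_counts()
    if base.size < 2:
        raise InsufficientDataError("need >= 2 baseline bins to estimate SD")
    return float(base.mean()), float(base.std(ddof=1))


def detect_response(psth: Psth, config: DetectionConfig = DetectionConfig()) -> ResponseResult:
    """Classify a unit's light response from a trial-summed PSTH.

    See the module docstring for the rule. The result is flagged
    ``provisional`` when fewer than ``config.min_trials`` trials entered
    the PSTH and ``sigma_zero`` when the baseline SD is zero.
    """
    mu, sd = baseline_mean_sd(psth)
    flags: list[str] = []
    if sd == 0.0:
        flags.append("sigma_zero")
    if psth.n_trials < config.min_trials:
        flags.append("provisional")

    post = psth.post_counts()
    hi = mu + config.sd_multiplier * sd
    lo = mu - config.sd_multiplier * sd
    inc_runs = _runs(post > hi, config.min_consecutive_bins)
    dec_runs = _runs(post < lo, config.min_consecutive_bins)

    if inc_runs and dec_runs and any(
        ir[1] - 1 < dr[0] for ir in inc_runs for dr in dec_runs
    ):
        category = ResponseCategory.COMBINATION
    elif inc_runs:
        category = ResponseCategory.INCREASE
    elif dec_runs:
        category = ResponseCategory.DECREASE
    else:
        category = ResponseCategory.NONE

    sig: list[tuple[int, int]] = []
    for s, e in inc_runs:
        sig.extend((i, +1) for i in range(s, e))
    for s, e in dec_runs:
        sig.extend((i, -1) for i in range(s, e))
    sig.sort()

    magnitude = None
    if psth.n_bins_pre == psth.n_bins_post and category in (
        ResponseCategory.INCREASE,
        ResponseCategory.COMBINATION,
    ):
        magnitude = response_magnitude(psth, config)
        if psth.baseline_counts().sum() < config.baseline_floor_spikes:
            flags.append("zero_baseline")

    return ResponseResult(
        category=category,
        significant_bins=tuple(sig),
        magnitude=magnitude,
        n_trials_used=psth.n_trials,
        flags=tuple(flags),
    )


def response_magnitude(psth: Psth, config: DetectionConfig = DetectionConfig()) -> float:
    """Fold-change: stimulation-window spikes over pre-window spikes.

    Requires equal-duration pre and stimulation windows. A baseline with
    fewer spikes than ``config.baseline_floor_spikes`` is floored at that
    value so the ratio stays finite.
    """
    if psth.n_bins_pre != psth.n_bins_post:
        raise ValueError("magnitude needs equal-duration pre and stimulation windows")
    pre = int(psth.baseline_counts().sum())
    post = int(psth.post_counts().sum())
    return post / max(pre, config.baseline_floor_spikes)


def latency_to_peak(psth: Psth) -> Optional[float]:
    """Latency (ms) from illumination onset to the maximal-count bin.

    Uses the post-onset bins only; ties go to the earliest bin; the value
    is reported at the bin center. Returns None (with a warning) when the
    post-onset window contains no spikes.
    """
    post = psth.post_counts()
    if post.size == 0 or post.max() == 0:
        warnings.warn("no post-onset spikes; latency undefined", stacklevel=2)
        return None
    idx = int(np.argmax(post))  # argmax takes the earliest maximal bin
    return (idx + 0.5) * psth.bin_width


def normalize_population(psths: Sequence[Psth]) -> np.ndarray:
    """Per-unit max-normalized PSTHs averaged across units.

    Each unit's counts are divided by that unit's maximal bin count, then
    averaged; the output lies in [0, 1]. Units with all-zero counts are
    excluded with a warning. All inputs must share the same binning.
    """
    if not psths:
        raise ValueError("need at least one PSTH")
    ref = psths[0]
    traces = []
    for p in psths:
        if (
            p.bin_width != ref.bin_width
            or p.n_bins_pre != ref.n_bins_pre
            or p.n_bins_post != ref.n_bins_post
        ):
            raise ValueError("all PSTHs must share identical binning")
        m = p.counts.max()
        if m == 0:
            warnings.warn("excluding unit with all-zero PSTH from population average",
                          stacklevel=2)
            continue
        traces.append(p.counts / m)
    if not traces:
        raise InsufficientDataError("all units had empty PSTHs")
    return np.mean(traces, axis=0)


def post_train_suppression(
    psth: Psth,
    train_duration_ms: float,
    config: DetectionConfig = DetectionConfig(),
) -> Optional[float]:
    """Duration (ms) of significant firing suppression after train end.

    The PSTH must be train-onset aligned with a post window extending at
    least 400 ms past the end of the train. The first run of at least
    ``min_consecutive_bins`` post-train bins below mu - k*sigma starts the
    suppression; its duration runs to the first bin back at or above the
    threshold (or to the end of the window). Returns None when no
    qualifying run exists.
    """
    w = psth.bin_width
    post_window_ms = psth.n_bins_post * w
    if post_window_ms < train_duration_ms + 400.0:
        raise ValueError(
            "PSTH post window must extend >= 400 ms past the end of the train"
        )
    mu, sd = baseline_mean_sd(psth)
    lo = mu - config.sd_multiplier * sd
    post = psth.post_counts()
    first_after = int(np.ceil(train_duration_ms / w))  # first bin fully after train end
    below = post[first_after:] < lo
    runs = _runs(below, config.min_consecutive_bins)
    if not runs:
        return None
    start, stop = runs[0]  # stop is the first bin back at/above threshold
    return (stop - start) * w
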