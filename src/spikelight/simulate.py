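"""Synthetic spike trains and stimulation logs with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* Baseline spiking is a gamma-renewal process. The gamma ISI shape
  ``k = 1/CV**2`` gives independent control of rate and interspike-interval
  CV, matching the two-axis cell classification (low-rate irregular PANs,
  tonic TANs, fast FSNs, tonic GPe units, irregular/bursting VL units).
  Burstier-than-Poisson cells (CV > 1) use shape k < 1.
* Light-gated channel kinetics are first order: during light the open
  fraction obeys do/dt = (1 - o)/tau_on, after light do/dt = -o/tau_off,
  with tau_on = 1 ms and tau_off = 20 ms for the ChR2(H134R) variant.
  Activation traces are piecewise closed-form exponentials.
* The evoked response is a multiplicative rate modulation: the conditional
  intensity is ``baseline_rate * gain ** (s * o(t - latency) * d(p) * L(I))``
  with s = +1 for excitation and -1 for inhibition (so inhibition can never
  produce negative rates), ``d(p) = decrement_factor**(p-1)`` the per-pulse
  attenuation for pulse index p within a train, and ``L(I)`` a logistic
  function of log light intensity (a Hill curve centered on the half-max
  irradiance) scaling the effective drive. COMBINATION responses add a
  multiplicative suppression factor ``1 - suppression_depth`` for
  ``suppression_duration`` ms after the end of each train.
* The modulated process is sampled exactly by time rescaling: the baseline
  gamma-renewal train is generated in operational time and mapped through
  the inverse of the cumulative modulation integral. With gain = 1 the map
  is the identity, so an unresponsive unit is byte-identical in
  distribution to its baseline process.

The standard stimulation protocol is trains of ten 20 ms pulses at 30 Hz
with inter-train gaps drawn uniformly from [1, 2] s (measured from train
end to the next onset), after a 120 s pre-stimulation baseline epoch.
Output times are quantized to the 10 µs serialization grid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import (
    Region,
    Session,
    SortQuality,
    SpikeTrain,
    StimProtocol,
    TrainSpec,
    quantize_times,
)

__all__ = [
    "CellKind",
    "ResponseType",
    "CellProfile",
    "Chr2Kinetics",
    "SimConfig",
    "GroundTruth",
    "simulate_baseline_train",
    "channel_activation",
    "simulate_session",
    "simulate_cohort",
    "make_train_protocol",
    "make_single_pulse_protocol",
    "make_intensity_protocol",
    "rate_modulation_template",
    "transfection_gain",
    "BASELINE_PROFILES",
    "RESPONSE_FIXTURES",
    "InvalidProtocolError",
]

#: fine grid step for modulation templates, ms
_TEMPLATE_DT_MS = 0.05


class InvalidProtocolError(ValueError):
    """Overlapping pulses or analysis windows in a stimulation protocol."""


class CellKind(str, enum.Enum):
    PAN = "PAN"
    TAN = "TAN"
    FSN = "FSN"
    GPE = "GPE"
    VL_PROJ = "VL_PROJ"


class ResponseType(str, enum.Enum):
    NONE = "NONE"
    EXCITED = "EXCITED"
    INHIBITED = "INHIBITED"
    COMBINATION = "COMBINATION"


_REGION_OF_KIND = {
    CellKind.PAN: Region.PUTAMEN,
    CellKind.TAN: Region.PUTAMEN,
    CellKind.FSN: Region.PUTAMEN,
    CellKind.GPE: Region.GPE,
    CellKind.VL_PROJ: Region.VL,
}


@dataclass(frozen=True)
class CellProfile:
    """Generating parameters of one simulated unit.

    ``gain`` is the multiplicative rate factor at full channel activation;
    with ``response_type`` NONE (or gain = 1) light has no effect and the
    session process equals the baseline process.
    """

    cell_class: CellKind
    baseline_rate: float  # spikes/s
    target_cv: float
    gain: float = 1.0
    response_type: ResponseType = ResponseType.NONE
    response_latency: float = 0.0  # ms
    decrement_factor: float = 1.0  # per-pulse attenuation of evoked drive
    suppression_depth: float = 0.0
    suppression_duration: float = 0.0  # ms
    adaptation_tau: Optional[float] = None  # ms; None = sustained response

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.target_cv <= 0:
            raise ValueError("target_cv must be > 0")
        if not 0 < self.decrement_factor <= 1:
            raise ValueError("decrement_factor must be in (0, 1]")
        if not 0 <= self.suppression_depth <= 1:
            raise ValueError("suppression_depth must be in [0, 1]")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.suppression_duration < 0:
            raise ValueError("suppression_duration must be >= 0")
        if self.adaptation_tau is not None and self.adaptation_tau <= 0:
            raise ValueError("adaptation_tau must be positive when set")

    @property
    def region(self) -> Region:
        return _REGION_OF_KIND[self.cell_class]


#: Baseline firing phenotypes by cell class: (rate spikes/s, ISI CV).
#: PANs are near-silent and bursty, TANs tonic and regular, FSNs fast,
#: GPe units high-frequency dischargers, VL units tonic-irregular.
BASELINE_PROFILES: dict[CellKind, CellProfile] = {
    CellKind.PAN: CellProfile(CellKind.PAN, baseline_rate=1.0, target_cv=1.5),
    CellKind.TAN: CellProfile(CellKind.TAN, baseline_rate=5.0, target_cv=0.5),
    CellKind.FSN: CellProfile(CellKind.FSN, baseline_rate=20.0, target_cv=0.8),
    CellKind.GPE: CellProfile(CellKind.GPE, baseline_rate=60.0, target_cv=0.8),
    CellKind.VL_PROJ: CellProfile(CellKind.VL_PROJ, baseline_rate=15.0, target_cv=1.2),
}


#: Canonical responder fixtures used by the validation suites. Gains are
#: nominal rate factors at full sustained activation; transient profiles
#: (adaptation_tau set) reach peak instantaneous rates of a few hundred Hz
#: for a few ms — roughly one well-timed evoked spike per pulse — and never
#: sustain the nominal factor. Sustained profiles model the slower ramping
#: striatal-type response.
RESPONSE_FIXTURES: dict[str, CellProfile] = {
    # sustained striatal-type excitation (ramps through the pulse)
    "tan_excited": CellProfile(
        CellKind.TAN, baseline_rate=5.0, target_cv=0.5, gain=30.0,
        response_type=ResponseType.EXCITED, response_latency=5.0,
        decrement_factor=0.9,
    ),
    # transient thalamic-type excitation: rapid time-locked onset burst
    "vl_transient": CellProfile(
        CellKind.VL_PROJ, baseline_rate=15.0, target_cv=1.2, gain=1000.0,
        response_type=ResponseType.EXCITED, response_latency=2.0,
        decrement_factor=0.85, adaptation_tau=5.0,
    ),
    # indirect inhibition of a tonic high-rate unit
    "gpe_inhibited": CellProfile(
        CellKind.GPE, baseline_rate=60.0, target_cv=0.8, gain=8.0,
        response_type=ResponseType.INHIBITED, response_latency=5.0,
    ),
    # excitation followed by deep post-train suppression
    "vl_combination": CellProfile(
        CellKind.VL_PROJ, baseline_rate=25.0, target_cv=1.0, gain=30.0,
        response_type=ResponseType.COMBINATION, response_latency=2.0,
        decrement_factor=0.9, suppression_depth=0.95, suppression_duration=150.0,
    ),
    # light-insensitive tonic unit
    "tan_null": CellProfile(CellKind.TAN, baseline_rate=5.0, target_cv=0.5),
    # light-insensitive tonic Poisson unit (null-calibration reference)
    "poisson_null": CellProfile(CellKind.FSN, baseline_rate=20.0, target_cv=1.0),
}


@dataclass(frozen=True)
class Chr2Kinetics:
    """First-order opsin gating time constants (ms), ChR2(H134R) defaults."""

    tau_on: float = 1.0
    tau_off: float = 20.0

    def __post_init__(self) -> None:
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("kinetic time constants must be strictly positive")


@dataclass(frozen=True)
class SimConfig:
    """Session-level simulation settings.

    ``session_duration`` is a lower bound on the recording length; it is
    extended if the protocol runs longer. The 120 s default ``stim_start``
    leaves the baseline epoch the classifier requires. ``seed`` fully
    determines the output.
    """

    seed: int = 0
    n_units_per_profile: int = 1
    session_duration: float = 120.0
    protocol: Optional[StimProtocol] = None
    n_trains: int = 50
    stim_start: float = 120.0
    intensity_half_max: float = 8.0  # mW/mm^2
    intensity_slope: float = 2.0

    def __post_init__(self) -> None:
        if self.session_duration < self.stim_start:
            raise ValueError("session_duration must cover the baseline epoch")
        if self.intensity_half_max <= 0 or self.intensity_slope <= 0:
            raise ValueError("intensity parameters must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Generating labels recorded alongside a simulated unit."""

    unit_id: str
    cell_class: CellKind
    response_type: ResponseType
    profile: CellProfile
    seed: int


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_baseline_train(
    profile: CellProfile,
    duration: float,
    seed: int | np.random.Generator,
    *,
    quantize: bool = True,
) -> np.ndarray:
    """Gamma-renewal spike times (s) on [0, duration).

    ISIs are gamma with shape ``k = 1/CV**2`` and mean ``1/rate``, so the
    empirical rate approaches ``baseline_rate`` and the ISI CV approaches
    ``target_cv`` for long durations. A zero rate yields an empty train.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if profile.baseline_rate < 0:
        raise ValueError("baseline_rate must be >= 0")
    rng = _as_rng(seed)
    rate = profile.baseline_rate
    if rate == 0:
        return np.empty(0)
    k = 1.0 / profile.target_cv**2
    theta = 1.0 / (rate * k)  # mean ISI = k * theta = 1/rate
    expected = rate * duration
    times: list[np.ndarray] = []
    t = 0.0
    while t < duration:
        n = int(max(64, expected + 4 * np.sqrt(expected)))
        isis = rng.gamma(k, theta, size=n)
        chunk = t + np.cumsum(isis)
        times.append(chunk)
        t = chunk[-1]
    ts = np.concatenate(times)
    ts = ts[ts < duration]
    return quantize_times(ts) if quantize else ts


def channel_activation(
    kinetics: Chr2Kinetics,
    pulse_onsets: Sequence[float] | np.ndarray,
    pulse_width: float,
    t_grid: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Open-channel fraction o(t) in [0, 1] on ``t_grid`` (all times in ms).

    During light o relaxes toward 1 with time constant ``tau_on``; after
    light it decays toward 0 with ``tau_off``; each segment is a
    closed-form exponential. o = 0 before the first pulse; a zero-width
    pulse leaves the trace identically zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if pulse_width < 0:
        raise ValueError("pulse_width must be >= 0")
    onsets = np.asarray(pulse_onsets, dtype=float)
    if onsets.size == 0 or pulse_width == 0:
        return np.zeros_like(t_grid)
    if np.any(np.diff(onsets) <= 0):
        raise InvalidProtocolError("pulse onsets must be strictly increasing")
    if np.any(np.diff(onsets) < pulse_width):
        raise InvalidProtocolError("overlapping pulses")

    # Segment boundaries: pulse onsets (rising) interleaved with offsets
    # (decaying); the channel state at each boundary follows in closed form.
    n = onsets.size
    starts = np.empty(2 * n)
    states = np.empty(2 * n)
    rising = np.empty(2 * n, dtype=bool)
    o = 0.0
    prev_off = -np.inf
    for i, on in enumerate(onsets):
        if np.isfinite(prev_off):
            o = o * np.exp(-(on - prev_off) / kinetics.tau_off)
        starts[2 * i], states[2 * i], rising[2 * i] = on, o, True
        o = 1.0 + (o - 1.0) * np.exp(-pulse_width / kinetics.tau_on)
        off = on + pulse_width
        starts[2 * i + 1], states[2 * i + 1], rising[2 * i + 1] = off, o, False
        prev_off = off

    idx = np.searchsorted(starts, t_grid, side="right") - 1
    out = np.zeros_like(t_grid)
    inside = idx >= 0
    ii = idx[inside]
    dt = t_grid[inside] - starts[ii]
    o0 = states[ii]
    rise = rising[ii]
    vals = np.empty_like(dt)
    vals[rise] = 1.0 + (o0[rise] - 1.0) * np.exp(-dt[rise] / kinetics.tau_on)
    vals[~rise] = o0[~rise] * np.exp(-dt[~rise] / kinetics.tau_off)
    out[inside] = vals
    return np.clip(out, 0.0, 1.0)


def _intensity_drive(intensity: float, config: SimConfig) -> float:
    """Logistic-in-log-intensity scaling of the effective drive, in [0, 1)."""
    if intensity <= 0:
        return 0.0
    ratio = (config.intensity_half_max / intensity) ** config.intensity_slope
    return 1.0 / (1.0 + ratio)


def rate_modulation_template(
    profile: CellProfile,
    kinetics: Chr2Kinetics,
    train: TrainSpec,
    intensity: float,
    config: SimConfig = SimConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative rate factor m(t) for one train, on a fine grid.

    Returns ``(t_ms, m)`` with t relative to train onset, covering the
    train plus the channel-deactivation and suppression tails. The
    conditional intensity during the session is ``baseline_rate * m``.
    """
    lat = profile.response_latency
    span_ms = train.span_s * 1000.0
    tail = max(5.0 * kinetics.tau_off, profile.suppression_duration + 2.0 * kinetics.tau_off)
    total = span_ms + lat + tail
    tg = np.arange(0.0, total + _TEMPLATE_DT_MS, _TEMPLATE_DT_MS)

    onsets_ms = (train.pulse_onsets() - train.onset) * 1000.0 + lat
    o = channel_activation(kinetics, onsets_ms, train.pulse_width, tg)
    # per-pulse decrement: pulse index p(t) = latest pulse with onset <= t
    p = np.clip(np.searchsorted(onsets_ms, tg, side="right") - 1, 0, None)
    drive = o * profile.decrement_factor ** p * _intensity_drive(intensity, config)
    if profile.adaptation_tau is not None:
        # transient (adapting) responders: the evoked drive decays from each
        # pulse onset, putting the peak rate within a few ms of onset as in
        # rapidly responding thalamic cells
        t_since = tg - onsets_ms[p]
        adapt = np.where(t_since >= 0, np.exp(-np.maximum(t_since, 0) / profile.adaptation_tau), 1.0)
        drive = drive * adapt

    sign = {ResponseType.EXCITED: 1.0, ResponseType.COMBINATION: 1.0,
            ResponseType.INHIBITED: -1.0, ResponseType.NONE: 0.0}[profile.response_type]
    m = profile.gain ** (sign * drive)

    if profile.suppression_depth > 0 and profile.response_type in (
        ResponseType.EXCITED,
        ResponseType.COMBINATION,
    ):
        t_end = span_ms + lat
        mask = (tg > t_end) & (tg <= t_end + profile.suppression_duration)
        m = m.copy()
        m[mask] *= 1.0 - profile.suppression_depth
    return tg, m


def _cumulative_template(tg_ms: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Lambda_rel(x) = x + int_0^x (m - 1) dt, in seconds, on the template grid."""
    dt_s = np.diff(tg_ms) / 1000.0
    incr = 0.5 * (m[1:] + m[:-1]) * dt_s
    lam = np.concatenate([[0.0], np.cumsum(incr)])
    return lam


def make_train_protocol(
    rng: int | np.random.Generator,
    n_trains: int = 50,
    *,
    start: float = 120.0,
    n_pulses: int = 10,
    pulse_width: float = 20.0,
    pulse_rate: float = 30.0,
    gap_range: tuple[float, float] = (1.0, 2.0),
    intensity: float = 200.0,
) -> StimProtocol:
    """Standard protocol: trains of 10 x 20 ms pulses at 30 Hz, gaps U[1,2] s."""
    rng = _as_rng(rng)
    trains = []
    onset = start
    for _ in range(n_trains):
        tr = TrainSpec(onset=round(onset, 5), n_pulses=n_pulses,
                       pulse_width=pulse_width, pulse_rate=pulse_rate)
        trains.append(tr)
        onset = tr.end + rng.uniform(*gap_range)
    return StimProtocol(trains=tuple(trains), intensity=intensity)


def make_single_pulse_protocol(
    rng: int | np.random.Generator,
    widths: Sequence[float] = (20.0, 10.0, 5.0, 2.5, 1.2, 0.6, 0.3, 0.1),
    trials_per_width: int = 50,
    *,
    start: float = 120.0,
    gap_range: tuple[float, float] = (1.0, 2.0),
    intensity: float = 200.0,
) -> StimProtocol:
    """Single-pulse dose-response protocol: blocks of trials per pulse width."""
    rng = _as_rng(rng)
    trains = []
    onset = start
    for w in widths:
        for _ in range(trials_per_width):
            tr = TrainSpec(onset=round(onset, 5), n_pulses=1, pulse_width=w,
                           pulse_rate=30.0)
            trains.append(tr)
            onset = tr.end + rng.uniform(*gap_range)
    return StimProtocol(trains=tuple(trains), intensity=intensity)


def make_intensity_protocol(
    rng: int | np.random.Generator,
    intensities: Sequence[float] = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 270.0),
    trains_per_block: int = 50,
    *,
    start: float = 120.0,
    n_pulses: int = 5,
    pulse_width: float = 1.25,
    pulse_rate: float = 30.0,
    gap_range: tuple[float, float] = (1.0, 2.0),
) -> StimProtocol:
    """Intensity dose-response protocol: one irradiance per block of trains."""
    rng = _as_rng(rng)
    trains = []
    onset = start
    for inten in intensities:
        for _ in range(trains_per_block):
            tr = TrainSpec(onset=round(onset, 5), n_pulses=n_pulses,
                           pulse_width=pulse_width, pulse_rate=pulse_rate,
                           intensity=inten)
            trains.append(tr)
            onset = tr.end + rng.uniform(*gap_range)
    return StimProtocol(trains=tuple(trains), intensity=max(intensities))


def transfection_gain(base_gain: float, distance_mm: float, radius_mm: float) -> float:
    """Distance-dependent gain: log-gain decays as a Gaussian of distance.

    Models the fall-off of opsin expression away from an injection site
    with characteristic transfection radius ``radius_mm``.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    return float(base_gain ** np.exp(-((distance_mm / radius_mm) ** 2)))


def simulate_session(
    profile: CellProfile,
    kinetics: Chr2Kinetics = Chr2Kinetics(),
    config: SimConfig = SimConfig(),
    *,
    unit_id: str = "sim0",
    sort_quality: SortQuality = SortQuality.SINGLE,
    distance_mm: Optional[float] = None,
) -> tuple[SpikeTrain, StimProtocol, GroundTruth]:
    """Simulate one unit's full recording against a stimulation protocol.

    The baseline gamma-renewal process is modulated multiplicatively by the
    light-evoked drive (see module docstring) and sampled exactly by time
    rescaling. Identical ``config`` (seed included) gives byte-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    protocol = config.protocol
    if protocol is None:
        protocol = make_train_protocol(rng, config.n_trains, start=config.stim_start)
    last_end = protocol.trains[-1].end if protocol.trains else 0.0
    duration = round(max(config.session_duration, last_end + 1.0), 5)

    no_response = (
        profile.response_type is ResponseType.NONE
        or profile.gain == 1.0
        or not protocol.trains
    )
    if no_response:
        ts = simulate_baseline_train(profile, duration, rng)
    else:
        ts = _simulate_modulated(profile, kinetics, protocol, config, duration, rng)

    train = SpikeTrain(
        unit_id=unit_id,
        region=profile.region,
        sort_quality=sort_quality,
        timestamps=ts,
        recording_start=0.0,
        recording_end=duration,
        distance_to_injection=distance_mm,
    )
    truth = GroundTruth(
        unit_id=unit_id,
        cell_class=profile.cell_class,
        response_type=profile.response_type,
        profile=profile,
        seed=config.seed,
    )
    return train, protocol, truth


def _simulate_modulated(
    profile: CellProfile,
    kinetics: Chr2Kinetics,
    protocol: StimProtocol,
    config: SimConfig,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    # One modulation template per distinct train shape; trains sharing
    # (n_pulses, width, rate, intensity) reuse it.
    templates: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray, float]] = {}
    keys = []
    for tr in protocol.trains:
        key = (tr.n_pulses, tr.pulse_width, tr.pulse_rate, protocol.train_intensity(tr))
        keys.append(key)
        if key not in templates:
            tg, m = rate_modulation_template(
                profile, kinetics, tr, protocol.train_intensity(tr), config
            )
            lam = _cumulative_template(tg, m)
            templates[key] = (tg / 1000.0, m, lam, float(lam[-1] - tg[-1] / 1000.0))

    onsets = protocol.train_onsets()
    spans = np.array([templates[k][0][-1] for k in keys])
    ctots = np.array([templates[k][3] for k in keys])
    win_end = onsets + spans
    if np.any(onsets[1:] < win_end[:-1]):
        raise InvalidProtocolError(
            "modulation windows overlap; increase the inter-train gap"
        )

    shift_before = np.concatenate([[0.0], np.cumsum(ctots)])  # S_j, j=0..n
    win_start_op = onsets + shift_before[:-1]
    win_end_op = win_end + shift_before[1:]
    lam_end = duration + shift_before[-1]

    tau = simulate_baseline_train(profile, lam_end, rng, quantize=False)
    if tau.size == 0:
        return tau

    j = np.searchsorted(win_start_op, tau, side="right") - 1
    t = tau.copy()
    in_win = np.zeros(tau.size, dtype=bool)
    valid = j >= 0
    in_win[valid] = tau[valid] <= win_end_op[j[valid]]
    after = valid & ~in_win
    t[after] = tau[after] - shift_before[j[after] + 1]
    for jj in np.unique(j[in_win]):
        sel = in_win & (j == jj)
        tg_s, _, lam, _ = templates[keys[jj]]
        rel = tau[sel] - win_start_op[jj]
        t[sel] = onsets[jj] + np.interp(rel, lam, tg_s)

    t = t[(t >= 0) & (t < duration)]
    return quantize_times(np.sort(t))


def simulate_cohort(
    profiles: Sequence[tuple[CellProfile, int]],
    kinetics: Chr2Kinetics = Chr2Kinetics(),
    config: SimConfig = SimConfig(),
    *,
    distances: Optional[Sequence[Optional[float]]] = None,
) -> tuple[Session, list[GroundTruth]]:
    """Simulate ``n`` units per profile against one shared protocol.

    The protocol is realized once from ``config.seed`` (unless given);
    each unit then gets its own derived spiking seed. ``distances``
    optionally stamps a distance to the nearest injection site on each
    unit, in order of generation.
    """
    protocol = config.protocol
    if protocol is None:
        protocol = make_train_protocol(
            np.random.default_rng(config.seed), config.n_trains, start=config.stim_start
        )
    units: list[SpikeTrain] = []
    truths: list[GroundTruth] = []
    i = 0
    for profile, n in profiles:
        for _ in range(n):
            sub = replace(
                config,
                protocol=protocol,
                seed=int((config.seed * 100003 + 7919 * (i + 1)) % 2**31),
            )
            dist = None if distances is None else distances[i]
            unit, _, truth = simulate_session(
                profile, kinetics, sub, unit_id=f"u{i:04d}", distance_mm=dist
            )
            units.append(unit)
            truths.append(truth)
            i += 1
    return Session(units=units, protocol=protocol), truths
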