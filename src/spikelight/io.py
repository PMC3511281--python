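"""Session container and columnar on-disk formats.

A recording session is a set of sorted spike trains plus a light-stimulation
protocol. On disk a session is a directory of three tab-separated files with
mandatory headers:

``spikes.tsv``
    ``unit_id  t_s`` — one row per spike, times in seconds from recording
    start, written as fixed-point decimals with 5 places (10 µs resolution,
    the precision of the stimulus timing hardware).
``stim.tsv``
    ``train_id  pulse_index  onset_s  width_ms  rate_hz  intensity_mw_mm2``
    — one row per light pulse.
``units.tsv``
    ``unit_id  region  sort_quality  distance_mm  rec_start_s  rec_end_s``

All times are seconds from recording start; pulse widths are milliseconds;
light intensity is mW/mm² at the fiber tip. Reading validates every
structural invariant (strictly increasing timestamps, non-overlapping
trains) and never silently drops rows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "SortQuality",
    "SpikeTrain",
    "TrainSpec",
    "StimProtocol",
    "Session",
    "read_session",
    "write_session",
    "ParseError",
    "ValidationError",
]

#: serialization resolution for times, in seconds (10 µs)
TIME_RESOLUTION_S = 1e-5
_TIME_FMT = "%.5f"


class ParseError(ValueError):
    """A session file is structurally malformed (bad header, bad row)."""


class ValidationError(ValueError):
    """A session violates a data invariant (e.g. non-monotone timestamps)."""


class Region(str, enum.Enum):
    PUTAMEN = "PUTAMEN"
    GPE = "GPE"
    VL = "VL"
    OTHER = "OTHER"


class SortQuality(str, enum.Enum):
    SINGLE = "SINGLE"
    MULTI = "MULTI"


@dataclass(frozen=True)
class SpikeTrain:
    """Timestamps of one sorted unit plus identity/quality metadata.

    Parameters
    ----------
    unit_id : str
        Unique identifier within the session.
    region : Region
        Recording structure (putamen, external pallidum, ventrolateral
        thalamus, or other).
    sort_quality : SortQuality
        SINGLE for well-isolated single units, MULTI for multi-unit records.
    timestamps : ndarray of float
        Strictly increasing spike times in seconds from recording start.
    recording_start, recording_end : float
        Bounds of the recording epoch in seconds; all timestamps must lie
        within them.
    distance_to_injection : float, optional
        Distance from the recording site to the nearest viral injection
        site, in mm.
    """

    unit_id: str
    region: Region
    sort_quality: SortQuality
    timestamps: np.ndarray
    recording_start: float = 0.0
    recording_end: float = 0.0
    distance_to_injection: Optional[float] = None

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        self.validate()

    def validate(self) -> None:
        ts = self.timestamps
        if ts.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: timestamps must be 1-D")
        if ts.size and not np.all(np.diff(ts) > 0):
            raise ValidationError(
                f"unit {self.unit_id}: timestamps must be strictly increasing"
            )
        if self.recording_end < self.recording_start:
            raise ValidationError(
                f"unit {self.unit_id}: recording_end precedes recording_start"
            )
        if ts.size and (ts[0] < self.recording_start or ts[-1] > self.recording_end):
            raise ValidationError(
                f"unit {self.unit_id}: timestamps outside recording bounds"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return self.recording_end - self.recording_start

    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds."""
        return np.diff(self.timestamps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.unit_id == other.unit_id
            and self.region == other.region
            and self.sort_quality == other.sort_quality
            and self.recording_start == other.recording_start
            and self.recording_end == other.recording_end
            and _opt_eq(self.distance_to_injection, other.distance_to_injection)
            and self.timestamps.shape == other.timestamps.shape
            and bool(np.all(self.timestamps == other.timestamps))
        )


def _opt_eq(a: Optional[float], b: Optional[float]) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return a == b


@dataclass(frozen=True)
class TrainSpec:
    """One train of identical light pulses.

    A single-pulse experiment is a TrainSpec with ``n_pulses=1``.

    Parameters
    ----------
    onset : float
        Onset of the first pulse, seconds from recording start.
    n_pulses : int
    pulse_width : float
        Pulse duration in ms.
    pulse_rate : float
        Pulse rate within the train, Hz.
    intensity : float, optional
        Per-train light intensity (mW/mm²) overriding the protocol level.
    """

    onset: float
    n_pulses: int
    pulse_width: float
    pulse_rate: float
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValidationError("n_pulses must be >= 1")
        if self.pulse_width < 0:
            raise ValidationError("pulse_width must be >= 0")
        if self.pulse_rate <= 0:
            raise ValidationError("pulse_rate must be > 0")
        if self.n_pulses > 1 and self.pulse_width >= 1000.0 / self.pulse_rate:
            raise ValidationError(
                "pulse_width must be shorter than the inter-pulse interval"
            )

    @property
    def period_s(self) -> float:
        return 1.0 / self.pulse_rate

    def pulse_onsets(self) -> np.ndarray:
        """Pulse onset times in seconds from recording start."""
        return self.onset + np.arange(self.n_pulses) * self.period_s

    @property
    def end(self) -> float:
        """End of the last pulse, seconds."""
        return self.onset + (self.n_pulses - 1) * self.period_s + self.pulse_width / 1000.0

    @property
    def span_s(self) -> float:
        return self.end - self.onset


@dataclass(frozen=True)
class StimProtocol:
    """Full description of a light-stimulation session.

    ``intensity`` is the protocol-level irradiance at the fiber tip; a
    TrainSpec may override it for intensity dose-response blocks.
    """

    trains: tuple[TrainSpec, ...]
    intensity: float = 200.0
    fiber_diameter: float = 200.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", tuple(self.trains))
        self.validate()

    def validate(self) -> None:
        prev_end = -np.inf
        for i, tr in enumerate(self.trains):
            if tr.onset < prev_end:
                raise ValidationError(
                    f"train {i} (onset {tr.onset:g} s) overlaps the previous train"
                )
            prev_end = tr.end

    def __eq__(self, other: object) -> bool:
        # fiber_diameter is descriptive metadata and is not serialized;
        # intensities compare by effective per-train value so that the
        # protocol-level default and an explicit override are equivalent
        if not isinstance(other, StimProtocol):
            return NotImplemented
        return self._signature() == other._signature()

    def _signature(self) -> tuple:
        return tuple(
            (t.onset, t.n_pulses, t.pulse_width, t.pulse_rate, self.train_intensity(t))
            for t in self.trains
        )

    @property
    def n_trains(self) -> int:
        return len(self.trains)

    def train_intensity(self, train: TrainSpec) -> float:
        return self.intensity if train.intensity is None else train.intensity

    def train_onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trains], dtype=float)

    def first_pulse_onsets(self) -> np.ndarray:
        return self.train_onsets()

    def all_pulse_onsets(self) -> np.ndarray:
        if not self.trains:
            return np.empty(0)
        return np.concatenate([t.pulse_onsets() for t in self.trains])


@dataclass
class Session:
    """A set of spike trains recorded against one stimulation protocol."""

    units: list[SpikeTrain] = field(default_factory=list)
    protocol: StimProtocol = field(default_factory=lambda: StimProtocol(()))

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate unit ids in session")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return self.units == other.units and self.protocol == other.protocol

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


def _quantize(x: float) -> float:
    return round(round(x / TIME_RESOLUTION_S) * TIME_RESOLUTION_S, 5)


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to a directory of spikes.tsv, stim.tsv, units.tsv.

    Times are serialized as fixed-point decimals with 5 places (10 µs);
    timestamps already on that grid round-trip exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "spikes.tsv", "w") as fh:
        fh.write("unit_id\tt_s\n")
        for u in session.units:
            for t in u.timestamps:
                fh.write(f"{u.unit_id}\t{t:.5f}\n")

    with open(path / "stim.tsv", "w") as fh:
        fh.write("train_id\tpulse_index\tonset_s\twidth_ms\trate_hz\tintensity_mw_mm2\n")
        for ti, tr in enumerate(session.protocol.trains):
            inten = session.protocol.train_intensity(tr)
            for pi, onset in enumerate(tr.pulse_onsets()):
                fh.write(
                    f"{ti}\t{pi}\t{onset:.5f}\t{tr.pulse_width:g}\t"
                    f"{tr.pulse_rate:g}\t{inten:g}\n"
                )

    with open(path / "units.tsv", "w") as fh:
        fh.write("unit_id\tregion\tsort_quality\tdistance_mm\trec_start_s\trec_end_s\n")
        for u in session.units:
            dist = "" if u.distance_to_injection is None else f"{u.distance_to_injection:g}"
            fh.write(
                f"{u.unit_id}\t{u.region.value}\t{u.sort_quality.value}\t{dist}\t"
                f"{u.recording_start:.5f}\t{u.recording_end:.5f}\n"
            )
    return path


def _read_tsv(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"missing file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - wrap any reader failure
        raise ParseError(f"{path.name}: {exc}") from exc
    if list(df.columns) != list(columns):
        raise ParseError(
            f"{path.name}: expected header {list(columns)}, found {list(df.columns)}"
        )
    return df


def _to_float(df: pd.DataFrame, col: str, fname: str) -> np.ndarray:
    raw = df[col].to_numpy()
    try:
        return raw.astype(float)
    except ValueError:
        for i, v in enumerate(raw):
            try:
                float(v)
            except ValueError:
                # +2: one for the header line, one for 1-based numbering
                raise ParseError(
                    f"{fname}, line {i + 2}: cannot parse {col}={v!r}"
                ) from None
        raise


def read_session(path: str | Path) -> Session:
    """Read and fully validate a session directory.

    Raises
    ------
    ParseError
        On malformed rows, with the offending file and line number.
    ValidationError
        On invariant violations (non-monotone timestamps, overlapping
        trains, unknown unit ids), naming the unit or train.
    """
    path = Path(path)

    spikes = _read_tsv(path / "spikes.tsv", ["unit_id", "t_s"])
    stim = _read_tsv(
        path / "stim.tsv",
        ["train_id", "pulse_index", "onset_s", "width_ms", "rate_hz", "intensity_mw_mm2"],
    )
    units = _read_tsv(
        path / "units.tsv",
        ["unit_id", "region", "sort_quality", "distance_mm", "rec_start_s", "rec_end_s"],
    )

    spike_t = _to_float(spikes, "t_s", "spikes.tsv")
    spike_ids = spikes["unit_id"].to_numpy()

    trains: list[TrainSpec] = []
    intensities: list[float] = []
    if len(stim):
        for c in ("onset_s", "width_ms", "rate_hz", "intensity_mw_mm2"):
            stim[c] = _to_float(stim, c, "stim.tsv")
        for train_id, grp in stim.groupby("train_id", sort=False):
            onsets = grp["onset_s"].to_numpy()
            widths = grp["width_ms"].unique()
            rates = grp["rate_hz"].unique()
            intens = grp["intensity_mw_mm2"].unique()
            if len(widths) != 1 or len(rates) != 1 or len(intens) != 1:
                raise ValidationError(
                    f"stim.tsv: train {train_id} has inconsistent width/rate/intensity"
                )
            try:
                trains.append(
                    TrainSpec(
                        onset=float(onsets.min()),
                        n_pulses=len(grp),
                        pulse_width=float(widths[0]),
                        pulse_rate=float(rates[0]),
                        intensity=float(intens[0]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"stim.tsv: train {train_id}: {exc}") from None
            intensities.append(float(intens[0]))

    order = np.argsort([t.onset for t in trains], kind="stable")
    trains = [trains[i] for i in order]
    protocol_intensity = intensities[0] if intensities else 200.0
    protocol = StimProtocol(trains=tuple(trains), intensity=protocol_intensity)

    for c in ("rec_start_s", "rec_end_s"):
        units[c] = _to_float(units, c, "units.tsv")

    session_units: list[SpikeTrain] = []
    known_ids: set[str] = set()
    for i, row in units.iterrows():
        uid = row["unit_id"]
        if uid in known_ids:
            raise ValidationError(f"units.tsv: duplicate unit id {uid!r}")
        known_ids.add(uid)
        try:
            region = Region(row["region"])
            quality = SortQuality(row["sort_quality"])
        except ValueError as exc:
            raise ParseError(f"units.tsv, line {i + 2}: {exc}") from None
        dist_raw = row["distance_mm"]
        dist = None if dist_raw == "" else float(dist_raw)
        mask = spike_ids == uid
        ts = spike_t[mask]  # order as written; monotonicity checked by SpikeTrain
        session_units.append(
            SpikeTrain(
                unit_id=uid,
                region=region,
                sort_quality=quality,
                timestamps=ts,
                recording_start=float(row["rec_start_s"]),
                recording_end=float(row["rec_end_s"]),
                distance_to_injection=dist,
            )
        )

    orphans = set(spike_ids) - known_ids
    if orphans:
        raise ValidationError(f"spikes.tsv: unknown unit ids {sorted(orphans)}")

    n_in = len(spikes)
    n_out = sum(u.n_spikes for u in session_units)
    if n_in != n_out:  # pragma: no cover - guarded by orphan check above
        raise ValidationError(f"spike row count mismatch: {n_in} read, {n_out} assigned")

    return Session(units=session_units, protocol=protocol)


def quantize_times(timestamps: np.ndarray) -> np.ndarray:
    """Snap times to the 10 µs serialization grid, dropping collisions."""
    q = np.round(np.asarray(timestamps, dtype=float) / TIME_RESOLUTION_S)
    q = np.unique(q)
    return np.round(q * TIME_RESOLUTION_S, 5)
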