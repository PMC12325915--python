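"""Detection histories from raw camera-trap event and effort logs.

Camera-trap records arrive as timestamped species observations per station
plus a log of when each camera was actually active.  Repeated triggers of the
same animal are collapsed with an independence rule (events at one station
closer than a minimum separation are treated as the same observation), and
the surviving events are pooled into fixed-length occasions — consecutive
windows of ``period_days`` days, 5 by default — to form the site × occasion
count matrix an N-mixture model consumes.  Each camera-year is a separate
sample unit, and the number of active camera nights inside each occasion is
carried along as an observation-level effort covariate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_PERIOD_DAYS = 5
DEFAULT_MIN_SEPARATION = timedelta(minutes=15)


@dataclass(frozen=True, order=True)
class DetectionEvent:
    """One independent-or-raw camera observation of a species."""

    station_id: str
    species: str
    timestamp: datetime
    cell_id: str = ""


def read_events_csv(path) -> list[DetectionEvent]:
    """Read events from CSV with columns station_id,cell_id,species,timestamp.

    Timestamps must be ISO 8601; an unparseable timestamp raises
    :class:`InputError` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"station_id", "species", "timestamp"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"events file {path} is missing columns {sorted(missing)}")
    stamps = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = stamps.isna() & df["timestamp"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise InputError(
            f"unparseable timestamp {df['timestamp'].iloc[row]!r} in events row "
            f"{row + 2} (station {df['station_id'].iloc[row]!r})"
        )
    if stamps.isna().any():
        row = int(np.flatnonzero(stamps.isna().to_numpy())[0])
        raise InputError(f"missing timestamp in events row {row + 2}")
    cells = df["cell_id"] if "cell_id" in df.columns else pd.Series([""] * len(df))
    events = [
        DetectionEvent(
            station_id=s,
            species=sp,
            timestamp=t.to_pydatetime(),
            cell_id="" if pd.isna(c) else c,
        )
        for s, sp, t, c in zip(df["station_id"], df["species"], stamps, cells)
    ]
    _check_station_cell_consistency(events)
    return sorted(events)


def _check_station_cell_consistency(events) -> None:
    seen: dict[str, str] = {}
    for ev in events:
        if not ev.cell_id:
            continue
        prev = seen.setdefault(ev.station_id, ev.cell_id)
        if prev != ev.cell_id:
            raise InputError(
                f"station {ev.station_id!r} mapped to two cells: {prev!r} and {ev.cell_id!r}"
            )


def filter_independent_events(
    events: list[DetectionEvent],
    min_separation: timedelta = DEFAULT_MIN_SEPARATION,
) -> list[DetectionEvent]:
    """Collapse repeat triggers into independent observations.

    Within each (station, species) stream, sorted by time, an event is kept
    iff it is the first or its timestamp is at least ``min_separation`` after
    the most recently *kept* event (greedy rule).  Events at different
    stations are never compared.  The rule is idempotent, and shrinking
    ``min_separation`` can only retain more events.
    """
    if min_separation <= timedelta(0):
        raise InputError("min_separation must be positive")
    kept: list[DetectionEvent] = []
    last: dict[tuple[str, str], datetime] = {}
    for ev in sorted(events, key=lambda e: (e.station_id, e.species, e.timestamp)):
        key = (ev.station_id, ev.species)
        prev = last.get(key)
        if prev is None or ev.timestamp - prev >= min_separation:
            kept.append(ev)
            last[key] = ev.timestamp
    return kept


class EffortLog:
    """Per-station camera activity as inclusive date intervals.

    Intervals within one station are normalized: sorted, with overlapping or
    adjacent ranges merged, so total active days is well defined.
    """

    def __init__(self, intervals: dict[str, list[tuple[date, date]]]):
        self._intervals: dict[str, list[tuple[date, date]]] = {}
        self._days: dict[str, set[date]] = {}
        for station, ivals in intervals.items():
            merged = self._normalize(station, ivals)
            self._intervals[station] = merged
            days: set[date] = set()
            for a, b in merged:
                d = a
                while d <= b:
                    days.add(d)
                    d += timedelta(days=1)
            self._days[station] = days

    @staticmethod
    def _normalize(station, ivals):
        for a, b in ivals:
            if b < a:
                raise InputError(f"station {station!r}: interval end {b} before start {a}")
        out: list[tuple[date, date]] = []
        for a, b in sorted(ivals):
            if out and a <= out[-1][1] + timedelta(days=1):
                out[-1] = (out[-1][0], max(out[-1][1], b))
            else:
                out.append((a, b))
        return out

    @classmethod
    def from_csv(cls, path) -> "EffortLog":
        """Read columns station_id,start_date,end_date (inclusive dates)."""
        df = pd.read_csv(path, dtype=str)
        required = {"station_id", "start_date", "end_date"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"effort file {path} is missing columns {sorted(missing)}")
        intervals: dict[str, list[tuple[date, date]]] = {}
        for i, row in df.iterrows():
            try:
                a = date.fromisoformat(row["start_date"])
                b = date.fromisoformat(row["end_date"])
            except ValueError as exc:
                raise InputError(f"effort row {i + 2}: {exc}") from exc
            intervals.setdefault(row["station_id"], []).append((a, b))
        return cls(intervals)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"station_id": s, "start_date": a.isoformat(), "end_date": b.isoformat()}
            for s, ivals in sorted(self._intervals.items())
            for a, b in ivals
        ]
        return pd.DataFrame(rows, columns=["station_id", "start_date", "end_date"])

    @property
    def stations(self) -> list[str]:
        return sorted(self._intervals)

    def intervals(self, station: str) -> list[tuple[date, date]]:
        return list(self._intervals[station])

    def active_days(self, station: str, year: int | None = None) -> list[date]:
        days = self._days.get(station, set())
        if year is not None:
            days = {d for d in days if d.year == year}
        return sorted(days)

    def is_active(self, station: str, d: date) -> bool:
        return d in self._days.get(station, set())

    def total_active_days(self, station: str) -> int:
        return len(self._days.get(station, set()))

    def years(self) -> list[int]:
        ys = {d.year for days in self._days.values() for d in days}
        return sorted(ys)


def build_occasions(
    effort: EffortLog, year: int, period_days: int = DEFAULT_PERIOD_DAYS
) -> dict[str, list[tuple[date, date]]]:
    """Occasion calendar per station for one calendar year.

    Occasions are consecutive ``period_days`` windows anchored at the
    station's first active day within the year and running through its last
    active day; a trailing partial window (clipped to 31 December) is kept —
    the effort covariate absorbs the reduced exposure.  Stations with zero
    active days in the year are omitted with a logged notice.
    """
    if period_days < 1:
        raise InputError("period_days must be >= 1")
    out: dict[str, list[tuple[date, date]]] = {}
    year_end = date(year, 12, 31)
    for station in effort.stations:
        days = effort.active_days(station, year)
        if not days:
            logger.info("station %s: no active days in %d, unit omitted", station, year)
            continue
        start, last = days[0], days[-1]
        windows = []
        w = start
        while w <= last:
            w_end = min(w + timedelta(days=period_days - 1), year_end)
            windows.append((w, w_end))
            w = w + timedelta(days=period_days)
        out[station] = windows
    return out


@dataclass
class DetectionHistory:
    """Site-unit × occasion count matrix with effort, for one species.

    ``counts`` is float with NaN marking missing occasions (exactly where
    ``effort`` is 0); ``effort`` holds active camera nights per occasion.
    Units are camera-years labelled ``"<station>:<year>"``; unit-level
    covariates record at minimum the camera identity (station_id).
    """

    species: str
    units: list[str]
    counts: np.ndarray
    effort: np.ndarray
    unit_covariates: pd.DataFrame
    period_days: int = DEFAULT_PERIOD_DAYS
    occasion_windows: dict[str, list[tuple[date, date]]] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.effort = np.asarray(self.effort, dtype=int)
        if self.counts.shape != self.effort.shape:
            raise InputError("counts and effort shapes differ")
        if self.counts.shape[0] != len(self.units):
            raise InputError("row count does not match number of units")
        self.validate()

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_occasions(self) -> int:
        return self.counts.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) occasions."""
        return self.effort > 0

    @property
    def max_count(self) -> int:
        obs = self.counts[self.observed]
        return int(obs.max()) if obs.size else 0

    def validate(self) -> None:
        if (self.effort < 0).any() or (self.effort > self.period_days).any():
            raise InputError(f"effort must lie in [0, {self.period_days}]")
        obs = self.observed
        if np.isnan(self.counts[obs]).any():
            raise InputError("missing count at an occasion with positive effort")
        if not np.isnan(self.counts[~obs]).all():
            raise InputError("non-missing count at an occasion with zero effort")
        if (self.counts[obs] < 0).any():
            raise InputError("negative count")


def build_detection_history(
    events: list[DetectionEvent],
    effort: EffortLog,
    species: str,
    period_days: int = DEFAULT_PERIOD_DAYS,
) -> DetectionHistory:
    """Pool independence-filtered events into a per-species detection history.

    counts[i, t] is the number of events of ``species`` at unit i whose date
    falls in occasion t *and* on a day the camera was active; events on
    inactive days are discarded.  Effort is the number of active nights per
    occasion; counts are missing exactly where effort is zero.
    """
    sp_events = [e for e in events if e.species == species]
    known = set(effort.stations)
    for ev in sp_events:
        if ev.station_id not in known:
            raise InputError(
                f"event at station {ev.station_id!r} ({ev.timestamp}) "
                "has no entry in the effort log"
            )

    units: list[str] = []
    unit_windows: dict[str, list[tuple[date, date]]] = {}
    unit_station: dict[str, str] = {}
    unit_year: dict[str, int] = {}
    for year in effort.years():
        occ = build_occasions(effort, year, period_days)
        for station, windows in occ.items():
            unit = f"{station}:{year}"
            units.append(unit)
            unit_windows[unit] = windows
            unit_station[unit] = station
            unit_year[unit] = year
    units.sort()
    if not units:
        raise InputError("effort log contains no active days at all")

    n_occ = max(len(unit_windows[u]) for u in units)
    counts = np.zeros((len(units), n_occ))
    eff = np.zeros((len(units), n_occ), dtype=int)
    idx = {u: i for i, u in enumerate(units)}

    for u in units:
        station, year = unit_station[u], unit_year[u]
        active = set(effort.active_days(station, year))
        for t, (a, b) in enumerate(unit_windows[u]):
            d = a
            n_active = 0
            while d <= b:
                if d in active:
                    n_active += 1
                d += timedelta(days=1)
            eff[idx[u], t] = n_active

    for ev in sp_events:
        d = ev.timestamp.date()
        unit = f"{ev.station_id}:{d.year}"
        if unit not in idx:
            continue
        if not effort.is_active(ev.station_id, d):
            continue  # event outside camera activity is dropped
        for t, (a, b) in enumerate(unit_windows[unit]):
            if a <= d <= b:
                counts[idx[unit], t] += 1
                break

    counts[eff == 0] = np.nan
    covariates = pd.DataFrame(
        {
            "station_id": [unit_station[u] for u in units],
            "year": [unit_year[u] for u in units],
        },
        index=pd.Index(units, name="unit"),
    )
    return DetectionHistory(
        species=species,
        units=units,
        counts=counts,
        effort=eff,
        unit_covariates=covariates,
        period_days=period_days,
        occasion_windows=unit_windows,
    )


# ---------------------------------------------------------------------------
# CSV persistence: a wide counts file, a parallel effort file, unit covariates


def write_history(history: DetectionHistory, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"occ_{t + 1}" for t in range(history.n_occasions)]
    pd.DataFrame(history.counts, index=history.units, columns=cols).to_csv(
        outdir / f"{history.species}_counts.csv", index_label="unit"
    )
    pd.DataFrame(history.effort, index=history.units, columns=cols).to_csv(
        outdir / f"{history.species}_effort.csv", index_label="unit"
    )
    meta = history.unit_covariates.copy()
    meta["period_days"] = history.period_days
    meta.to_csv(outdir / f"{history.species}_units.csv")


def read_history(indir, species: str) -> DetectionHistory:
    indir = Path(indir)
    counts = pd.read_csv(indir / f"{species}_counts.csv", index_col="unit")
    eff = pd.read_csv(indir / f"{species}_effort.csv", index_col="unit")
    meta = pd.read_csv(indir / f"{species}_units.csv", index_col="unit", dtype={"station_id": str})
    period = int(meta["period_days"].iloc[0])
    return DetectionHistory(
        species=species,
        units=list(counts.index),
        counts=counts.to_numpy(dtype=float),
        effort=eff.to_numpy(dtype=int),
        unit_covariates=meta.drop(columns=["period_days"]),
        period_days=period,
    )
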