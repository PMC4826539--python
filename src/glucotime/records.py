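"""Timing-record ingestion and the ward × day study panel.

The unit of every downstream analysis is the *ward-day*: the multiset of
measurement clock times recorded in one ward on one calendar day, expressed
as decimal hours on the linear scale [0, 24).  This module parses delimited
point-of-care records, converts clock strings to decimal hours, and arranges
them on a complete ward × day grid (empty ward-days are first-class: days
without any measurements are kept with n = 0 so they can be counted).

Times come from bedside meters logged to the minute, so exact ties are
normal and preserved.  A measurement at 00:xx belongs to its calendar date;
there is no circular wrapping of late-night values past midnight.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default CSV column mapping; override via the ``config`` argument / YAML
DEFAULT_COLUMNS = {
    "patient": "patient_id",
    "ward": "ward",
    "date": "date",
    "time": "time",
}


@dataclass(frozen=True)
class TimingRecord:
    """One point-of-care measurement: who, where, when."""

    patient_id: str
    ward_id: str
    date: dt.date
    time_hours: float  # decimal hours in [0, 24)

    def __post_init__(self) -> None:
        if not (0.0 <= self.time_hours < 24.0):
            raise ValueError(f"time_hours out of [0, 24): {self.time_hours!r}")


@dataclass
class WardDay:
    """All timings for one ward on one study day (day_index is 1-based)."""

    ward_id: str
    day_index: int
    timings: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.timings = np.sort(np.asarray(self.timings, dtype=float))

    @property
    def n(self) -> int:
        return int(self.timings.size)


@dataclass
class StudyPanel:
    """Complete ward × day grid of WardDays over a study window.

    ``grid`` holds exactly ``len(wards) * n_days`` entries, including empty
    ward-days, keyed by ``(ward_id, day_index)`` with day_index in 1..n_days.
    """

    wards: list[str]
    n_days: int
    grid: dict[tuple[str, int], WardDay]
    start_date: dt.date | None = None

    def __post_init__(self) -> None:
        expected = len(self.wards) * self.n_days
        if len(self.grid) != expected:
            raise ValueError(
                f"grid has {len(self.grid)} cells, expected {expected}"
            )

    def day(self, ward_id: str, day_index: int) -> WardDay:
        return self.grid[(ward_id, day_index)]

    def ward_days(self, ward_id: str) -> list[WardDay]:
        if ward_id not in self.wards:
            raise KeyError(f"unknown ward {ward_id!r}")
        return [self.grid[(ward_id, d)] for d in range(1, self.n_days + 1)]

    @property
    def n_records(self) -> int:
        return sum(wd.n for wd in self.grid.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format interchange table (ward, day_index, time_hours).

        Empty ward-days are omitted from the long table; the panel shape is
        recovered at load time from ``wards``/``n_days`` metadata.
        """
        rows = [
            (wd.ward_id, wd.day_index, t)
            for wd in self.grid.values()
            for t in wd.timings
        ]
        return pd.DataFrame(rows, columns=["ward", "day_index", "time_hours"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        n_days: int | None = None,
        wards: Sequence[str] | None = None,
        start_date: dt.date | None = None,
    ) -> "StudyPanel":
        if wards is None:
            wards = sorted(df["ward"].astype(str).unique())
        if n_days is None:
            n_days = int(df["day_index"].max()) if len(df) else 1
        grid: dict[tuple[str, int], WardDay] = {}
        grouped = {
            (str(w), int(d)): g["time_hours"].to_numpy(dtype=float)
            for (w, d), g in df.groupby(["ward", "day_index"], sort=False)
        }
        for w in wards:
            for d in range(1, n_days + 1):
                grid[(w, d)] = WardDay(w, d, grouped.get((w, d), np.empty(0)))
        return cls(list(wards), n_days, grid, start_date)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        n_days: int | None = None,
        wards: Sequence[str] | None = None,
    ) -> "StudyPanel":
        return cls.from_frame(pd.read_csv(path), n_days=n_days, wards=wards)


def parse_clock_time(value: str) -> float:
    """Convert ``HH:MM`` or ``HH:MM:SS`` to decimal hours in [0, 24).

    Raises ValueError for malformed strings or times outside the domain
    (``24:00`` is rejected rather than wrapped).
    """
    parts = str(value).strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"unparseable time {value!r}")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    if not (0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"unparseable time {value!r}")
    hours = h + m / 60.0 + s / 3600.0
    if not (0.0 <= hours < 24.0):
        raise ValueError(f"time {value!r} outside [0, 24)")
    return hours


def parse_records(
    path: str | Path,
    config: Mapping[str, str] | None = None,
    return_rejections: bool = False,
):
    """Read a delimited record file into TimingRecords.

    Parameters
    ----------
    path : CSV file with (at least) ward, date and time columns.
    config : column-name mapping overriding :data:`DEFAULT_COLUMNS`
        (keys ``patient``, ``ward``, ``date``, ``time``).
    return_rejections : also return a DataFrame of rejected rows with reasons.

    Rows whose date or time fails to parse are collected and logged, never
    silently dropped; a missing required column is fatal.
    """
    cols = dict(DEFAULT_COLUMNS)
    if config:
        cols.update({k: v for k, v in config.items() if k in cols})
    df = pd.read_csv(path, dtype=str)
    for key in ("ward", "date", "time"):
        if cols[key] not in df.columns:
            raise ValueError(f"required column {cols[key]!r} missing from {path}")
    has_patient = cols["patient"] in df.columns

    records: list[TimingRecord] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            date = dt.date.fromisoformat(str(row[cols["date"]]).strip())
            hours = parse_clock_time(row[cols["time"]])
        except (ValueError, TypeError) as exc:
            rejected.append((int(idx), str(exc)))
            continue
        patient = str(row[cols["patient"]]) if has_patient else ""
        records.append(TimingRecord(patient, str(row[cols["ward"]]), date, hours))
    if rejected:
        logger.warning("rejected %d of %d rows from %s", len(rejected), len(df), path)
    if return_rejections:
        rej = pd.DataFrame(rejected, columns=["row", "reason"])
        return records, rej
    return records


def build_panel(
    records: Iterable[TimingRecord],
    start_date: dt.date,
    n_days: int,
    wards: Sequence[str] | None = None,
) -> StudyPanel:
    """Arrange records on the complete ward × day grid.

    day_index = 1 + (record.date − start_date) in days; records outside
    [1, n_days] are dropped with a logged count.  Empty ward-days are present
    with n = 0.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    records = list(records)
    kept: dict[tuple[str, int], list[float]] = {}
    dropped = 0
    seen_wards: set[str] = set()
    for rec in records:
        day_index = (rec.date - start_date).days + 1
        seen_wards.add(rec.ward_id)
        if not (1 <= day_index <= n_days):
            dropped += 1
            continue
        kept.setdefault((rec.ward_id, day_index), []).append(rec.time_hours)
    if dropped:
        logger.info("dropped %d records outside the %d-day window", dropped, n_days)
    if wards is None:
        wards = sorted(seen_wards)
    grid = {
        (w, d): WardDay(w, d, np.asarray(kept.get((w, d), []), dtype=float))
        for w in wards
        for d in range(1, n_days + 1)
    }
    return StudyPanel(list(wards), n_days, grid, start_date)


def count_empty_days(panel: StudyPanel, ward_subset: Sequence[str] | None = None) -> int:
    """Number of (ward, day) cells with no measurements at all."""
    if ward_subset is None:
        ward_subset = panel.wards
    unknown = set(ward_subset) - set(panel.wards)
    if unknown:
        raise KeyError(f"unknown wards: {sorted(unknown)}")
    return sum(
        1
        for w in ward_subset
        for d in range(1, panel.n_days + 1)
        if panel.grid[(w, d)].n == 0
    )
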