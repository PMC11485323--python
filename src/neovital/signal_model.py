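"""Data model and I/O for uniformly gridded neonatal vital-sign streams.

Bedside monitors display heart rate (HR, beats/min) and pulse-oximetry
oxygen saturation (SPO2, percent) every 1--2 s; all analysis here operates
on a fixed 2-second grid.  This module defines the gridded series container,
delimited-text I/O, resampling of irregular samples onto the grid,
segmentation into the 10-minute windows that are the unit of feature
extraction, and the day-validity rule (at least 12 h of non-missing data in
both signals) that gates daily aggregation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalKind",
    "VitalSeries",
    "WindowPair",
    "DayIndex",
    "GRID_STEP_S",
    "WINDOW_SAMPLES",
    "WINDOW_SECONDS",
    "SAMPLES_PER_DAY",
    "MIN_VALID_SAMPLES_PER_DAY",
    "DEFAULT_MIN_COMPLETENESS",
    "read_vitals",
    "write_vitals",
    "read_outcome_table",
    "regularize",
    "segment_windows",
    "day_validity",
]

#: Grid step of the resampled monitor streams, seconds.
GRID_STEP_S = 2.0
#: Samples per 10-minute analysis window.
WINDOW_SAMPLES = 300
#: Seconds per analysis window.
WINDOW_SECONDS = 600.0
#: 2-s samples in one calendar day.
SAMPLES_PER_DAY = 43_200
#: >= 12 h of non-missing samples per signal for a day to count.
MIN_VALID_SAMPLES_PER_DAY = 21_600
#: Default per-signal completeness a window needs to enter feature extraction.
DEFAULT_MIN_COMPLETENESS = 0.75

_HR_RANGE = (20.0, 300.0)
_SPO2_RANGE = (0.0, 100.0)


class SignalKind(str, Enum):
    HR = "HR"
    SPO2 = "SPO2"

    @property
    def physiologic_range(self) -> tuple[float, float]:
        return _HR_RANGE if self is SignalKind.HR else _SPO2_RANGE


class VitalFormatError(ValueError):
    """Raised for malformed vital-sign input files."""


class GridAlignmentError(ValueError):
    """Raised when two series expected to share a grid do not."""


@dataclass
class VitalSeries:
    """One infant's single-signal series on the uniform 2-s grid.

    ``values`` is a float array with NaN marking missing samples.  Grid time
    of sample ``i`` is ``start_time + i * step`` seconds.  ``birth_time``
    anchors the day-of-life mapping (birth day = day 1).
    """

    infant_id: str
    signal_kind: SignalKind
    start_time: _dt.datetime
    values: np.ndarray
    step: float = GRID_STEP_S
    birth_time: _dt.datetime | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.step != GRID_STEP_S:
            raise ValueError(f"grid step must be {GRID_STEP_S} s, got {self.step}")
        finite = self.values[np.isfinite(self.values)]
        lo, hi = self.signal_kind.physiologic_range
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(
                f"{self.signal_kind.value} values outside [{lo}, {hi}]"
            )

    def __len__(self) -> int:
        return self.values.size

    def time_at(self, i: int) -> _dt.datetime:
        return self.start_time + _dt.timedelta(seconds=i * self.step)

    @property
    def end_time(self) -> _dt.datetime:
        """Time just past the last sample."""
        return self.time_at(len(self))

    def day_of_life_index(self) -> np.ndarray:
        """Day of life (birth day = 1) for every sample."""
        if self.birth_time is None:
            raise ValueError("birth_time is not set")
        offs = (self.start_time.date() - self.birth_time.date()).days
        sec0 = (
            self.start_time - _dt.datetime.combine(self.start_time.date(), _dt.time())
        ).total_seconds()
        sec = sec0 + np.arange(len(self)) * self.step
        return offs + 1 + (sec // 86_400).astype(int)


@dataclass
class WindowPair:
    """Aligned 300-sample (10-minute) HR + SPO2 segment."""

    infant_id: str
    window_start: _dt.datetime
    hr: np.ndarray
    spo2: np.ndarray
    completeness_hr: float = field(init=False)
    completeness_spo2: float = field(init=False)

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=float)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        if self.hr.size != WINDOW_SAMPLES or self.spo2.size != WINDOW_SAMPLES:
            raise ValueError(f"window must hold exactly {WINDOW_SAMPLES} samples")
        self.completeness_hr = float(np.isfinite(self.hr).sum()) / WINDOW_SAMPLES
        self.completeness_spo2 = float(np.isfinite(self.spo2).sum()) / WINDOW_SAMPLES

    def is_valid(self, min_completeness: float = DEFAULT_MIN_COMPLETENESS) -> bool:
        return (
            self.completeness_hr >= min_completeness
            and self.completeness_spo2 >= min_completeness
        )


@dataclass(frozen=True)
class DayIndex:
    infant_id: str
    day_of_life: int
    valid: bool


# ---------------------------------------------------------------------------
# I/O


def _parse_timestamp(v) -> _dt.datetime:
    if isinstance(v, _dt.datetime):
        return v
    try:
        return _dt.datetime.fromtimestamp(float(v), tz=_dt.timezone.utc).replace(
            tzinfo=None
        )
    except (TypeError, ValueError):
        pass
    ts = pd.Timestamp(v)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts.to_pydatetime()


_REQUIRED_COLS = ("infant_id", "signal", "timestamp", "value")


def read_vitals(
    path,
    *,
    sep: str | None = None,
    birth_times: dict[str, _dt.datetime] | None = None,
) -> list[VitalSeries]:
    """Read a long-format delimited vitals file into per-(infant, signal) series.

    Expected header: ``infant_id,signal,timestamp,value`` (comma or tab
    separated; autodetected when ``sep`` is None).  Timestamps are ISO-8601
    or epoch seconds.  Rows whose value cell does not parse as a number
    become missing samples.  Input must already lie on a uniform 2-s grid;
    use :func:`regularize` first for irregular streams.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise VitalFormatError(f"missing required column(s): {', '.join(missing)}")
    out: list[VitalSeries] = []
    if df.empty:
        return out
    df = df.copy()
    df["timestamp"] = df["timestamp"].map(_parse_timestamp)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    for (iid, sig), grp in df.groupby(["infant_id", "signal"], sort=True):
        kind = SignalKind(str(sig))
        grp = grp.sort_values("timestamp", kind="stable")
        dup = grp["timestamp"].duplicated()
        if dup.any():
            when = grp.loc[dup, "timestamp"].iloc[0]
            raise VitalFormatError(
                f"duplicate sample for ({iid}, {kind.value}) at {when}"
            )
        t0 = grp["timestamp"].iloc[0]
        idx = np.array(
            [round((t - t0).total_seconds() / GRID_STEP_S) for t in grp["timestamp"]]
        )
        off = np.array([(t - t0).total_seconds() for t in grp["timestamp"]])
        if np.max(np.abs(off - idx * GRID_STEP_S)) > 1e-6:
            raise VitalFormatError(
                f"samples for ({iid}, {kind.value}) are not on a uniform "
                f"{GRID_STEP_S:.0f}-s grid; regularize first"
            )
        vals = np.full(int(idx[-1]) + 1, np.nan)
        vals[idx] = grp["value"].to_numpy()
        bt = (birth_times or {}).get(str(iid))
        out.append(
            VitalSeries(
                infant_id=str(iid),
                signal_kind=kind,
                start_time=t0,
                values=vals,
                birth_time=bt,
            )
        )
    return out


def write_vitals(series: Iterable[VitalSeries], path, *, sep: str = ",") -> None:
    """Write series as long-format delimited text (missing samples omitted)."""
    frames = []
    for s in series:
        mask = np.isfinite(s.values)
        idx = np.nonzero(mask)[0]
        ts = [s.time_at(int(i)).isoformat() for i in idx]
        frames.append(
            pd.DataFrame(
                {
                    "infant_id": s.infant_id,
                    "signal": s.signal_kind.value,
                    "timestamp": ts,
                    "value": s.values[idx],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(_REQUIRED_COLS))
    )
    df.to_csv(path, sep=sep, index=False)


def read_outcome_table(path, *, sep: str | None = None) -> pd.DataFrame:
    """Read the outcome table.

    Header: ``infant_id,outcome_category,birth_time,pregnancy_id`` with
    optional ``birthweight_g,ga_weeks,imv_flag,fio2`` covariates.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = ("infant_id", "outcome_category", "birth_time", "pregnancy_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VitalFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["infant_id"] = df["infant_id"].astype(str)
    df["birth_time"] = df["birth_time"].map(_parse_timestamp)
    return df


# ---------------------------------------------------------------------------
# Resampling, segmentation, day validity


def regularize(
    samples: Sequence[tuple[_dt.datetime, float]],
    t0: _dt.datetime,
    t1: _dt.datetime,
    *,
    infant_id: str = "",
    signal_kind: SignalKind = SignalKind.HR,
    birth_time: _dt.datetime | None = None,
) -> VitalSeries:
    """Resample irregular (timestamp, value) pairs onto the 2-s grid.

    Grid slot at time ``g`` takes the latest raw sample with timestamp in
    ``(g - 2 s, g]`` — i.e. sub-sampling with a one-step carry-back window
    and no interpolation.  Slots with no sample in their window are missing.
    """
    if not t0 < t1:
        raise ValueError("t0 must precede t1")
    n = int(np.ceil((t1 - t0).total_seconds() / GRID_STEP_S))
    vals = np.full(n, np.nan)
    for ts, v in sorted(samples, key=lambda p: p[0]):
        if not np.isfinite(v):
            continue
        rel = (ts - t0).total_seconds()
        slot = int(np.ceil(rel / GRID_STEP_S))
        if rel > slot * GRID_STEP_S - GRID_STEP_S and rel <= slot * GRID_STEP_S:
            if 0 <= slot < n:
                vals[slot] = v  # later samples in the same slot win
    return VitalSeries(
        infant_id=infant_id,
        signal_kind=signal_kind,
        start_time=t0,
        values=vals,
        birth_time=birth_time,
    )


def _check_aligned(hr: VitalSeries, spo2: VitalSeries) -> None:
    if hr.start_time != spo2.start_time or hr.step != spo2.step:
        raise GridAlignmentError(
            "HR and SPO2 series are not on a common grid "
            f"({hr.start_time} vs {spo2.start_time})"
        )


def segment_windows(
    hr: VitalSeries,
    spo2: VitalSeries,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
    *,
    include_invalid: bool = False,
) -> list[WindowPair]:
    """Cut aligned series into consecutive non-overlapping 10-min windows.

    Windows tile from the common grid origin.  Pairs whose completeness in
    either signal falls below ``min_completeness`` are excluded (or returned
    anyway when ``include_invalid``); a trailing partial window is dropped.
    """
    _check_aligned(hr, spo2)
    n = min(len(hr), len(spo2))
    out: list[WindowPair] = []
    for start in range(0, n - WINDOW_SAMPLES + 1, WINDOW_SAMPLES):
        w = WindowPair(
            infant_id=hr.infant_id,
            window_start=hr.time_at(start),
            hr=hr.values[start : start + WINDOW_SAMPLES],
            spo2=spo2.values[start : start + WINDOW_SAMPLES],
        )
        if include_invalid or w.is_valid(min_completeness):
            out.append(w)
    return out


def day_validity(hr: VitalSeries, spo2: VitalSeries) -> list[DayIndex]:
    """Per calendar day-of-life validity: >= 12 h non-missing in BOTH signals.

    Emits one entry per day of life intersecting the record, from day 1
    (birth day) through the last day with data.
    """
    _check_aligned(hr, spo2)
    if hr.birth_time is None:
        raise ValueError("birth_time is not set")
    if hr.birth_time > hr.start_time:
        raise ValueError("birth_time is after the first data sample")
    counts: dict[int, list[int]] = {}
    for series, j in ((hr, 0), (spo2, 1)):
        days = series.day_of_life_index()
        mask = np.isfinite(series.values)
        for d in np.unique(days):
            counts.setdefault(int(d), [0, 0])[j] += int(mask[days == d].sum())
    last = max(counts) if counts else 0
    return [
        DayIndex(
            infant_id=hr.infant_id,
            day_of_life=d,
            valid=(
                counts.get(d, [0, 0])[0] >= MIN_VALID_SAMPLES_PER_DAY
                and counts.get(d, [0, 0])[1] >= MIN_VALID_SAMPLES_PER_DAY
            ),
        )
        for d in range(1, last + 1)
    ]
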