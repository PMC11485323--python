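"""Threshold-crossing physiologic event detection and daily event statistics.

Three clinically defined event families are detected on the 2-s grid:

* ``IH80``  — intermittent hypoxemia, SPO2 < 80 % for 10–300 s
* ``IH90``  — intermittent hypoxemia, SPO2 < 90 % for 10–300 s
* ``BRADY80`` — bradycardia, HR < 80 beats/min for at least 5 s

An event is a maximal run of consecutive non-missing samples strictly below
the threshold; a monitoring gap terminates the run rather than bridging it
(no hypoxemia is invented during dropout), and runs whose duration falls
outside the inclusive [min, max] band are discarded outright.  Daily
summaries per event kind are the event count, total duration in minutes per
day (dur), and mean duration per event in seconds (dpe = 60*dur/count).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .signal_model import GRID_STEP_S, DayIndex, SignalKind, VitalSeries

__all__ = [
    "EventDefinition",
    "EventRecord",
    "DailyEventStats",
    "IH80",
    "IH90",
    "BRADY80",
    "STANDARD_EVENTS",
    "EVENT_METRIC_COLUMNS",
    "detect_events",
    "daily_event_stats",
]


@dataclass(frozen=True)
class EventDefinition:
    """A below-threshold event family.

    ``bridge_gap_s`` > 0 allows a run to continue across a missing-data gap
    of at most that many seconds (default 0: never bridge).  ``join_gap_s``
    merges events separated by at most that many seconds of recovered signal
    before the duration filter is applied (default 0: no joining).
    """

    name: str
    signal: SignalKind
    threshold: float
    min_dur_s: float
    max_dur_s: float = float("inf")
    bridge_gap_s: float = 0.0
    join_gap_s: float = 0.0


IH80 = EventDefinition("IH80", SignalKind.SPO2, 80.0, 10.0, 300.0)
IH90 = EventDefinition("IH90", SignalKind.SPO2, 90.0, 10.0, 300.0)
BRADY80 = EventDefinition("BRADY80", SignalKind.HR, 80.0, 5.0)

STANDARD_EVENTS: tuple[EventDefinition, ...] = (IH80, IH90, BRADY80)

#: 9 daily metric columns, ordered: ih80_*, ih90_*, brady80_*.
EVENT_METRIC_COLUMNS: tuple[str, ...] = tuple(
    f"{d.name.lower()}_{stat}" for d in STANDARD_EVENTS for stat in ("count", "dur", "dpe")
)


@dataclass(frozen=True)
class EventRecord:
    infant_id: str
    kind: str
    start_time: _dt.datetime
    duration_s: float


@dataclass(frozen=True)
class DailyEventStats:
    infant_id: str
    day_of_life: int
    kind: str
    count: int
    dur_min: float
    dpe_s: float  # NaN when count == 0


def _below_runs(
    values: np.ndarray, threshold: float, bridge: int
) -> list[tuple[int, int, int]]:
    """(start, end-exclusive, below-sample count) of maximal below-threshold runs.

    The count excludes bridged missing samples: no hypoxemia is credited to
    unobserved time.
    """
    below = np.isfinite(values) & (values < threshold)
    missing = ~np.isfinite(values)
    runs: list[tuple[int, int, int]] = []
    i, n = 0, values.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        start = i
        j = i
        while j < n:
            if below[j]:
                j += 1
            elif missing[j] and bridge > 0:
                # look past a short gap; resume only if the signal is still below
                g = j
                while g < n and missing[g] and (g - j) < bridge:
                    g += 1
                if g < n and below[g]:
                    j = g
                else:
                    break
            else:
                break
        runs.append((start, j, int(np.count_nonzero(below[start:j]))))
        i = j + 1
    return runs


def detect_events(series: VitalSeries, definition: EventDefinition) -> list[EventRecord]:
    """Detect events of one family on a gridded series.

    Duration is the below-threshold sample count times the 2-s grid step;
    the [min_dur, max_dur] filter is inclusive on both bounds and
    over-length runs yield no event at all.
    """
    if series.signal_kind is not definition.signal:
        raise ValueError(
            f"{definition.name} is defined on {definition.signal.value}, "
            f"got a {series.signal_kind.value} series"
        )
    bridge = int(definition.bridge_gap_s / GRID_STEP_S)
    runs = _below_runs(series.values, definition.threshold, bridge)
    if definition.join_gap_s > 0 and len(runs) > 1:
        joined = [runs[0]]
        for start, end, count in runs[1:]:
            pstart, pend, pcount = joined[-1]
            in_gap = start - pend
            if in_gap * GRID_STEP_S <= definition.join_gap_s:
                # observed recovery inside the joined episode counts toward it
                joined[-1] = (pstart, end, pcount + in_gap + count)
            else:
                joined.append((start, end, count))
        runs = joined
    out = []
    for start, _end, count in runs:
        dur = count * GRID_STEP_S
        if definition.min_dur_s <= dur <= definition.max_dur_s:
            out.append(
                EventRecord(
                    infant_id=series.infant_id,
                    kind=definition.name,
                    start_time=series.time_at(start),
                    duration_s=dur,
                )
            )
    return out


def daily_event_stats(
    events: Sequence[EventRecord],
    day: DayIndex,
    birth_time: _dt.datetime,
    *,
    kinds: Iterable[str] = tuple(d.name for d in STANDARD_EVENTS),
) -> list[DailyEventStats]:
    """Per-kind count/dur/dpe for one day of life.

    An event belongs to the day containing its start time (an event spanning
    midnight counts wholly on its start day).  ``dpe`` is NaN when no event
    of the kind occurred.
    """
    day_start = _dt.datetime.combine(birth_time.date(), _dt.time()) + _dt.timedelta(
        days=day.day_of_life - 1
    )
    day_end = day_start + _dt.timedelta(days=1)
    out = []
    for kind in kinds:
        durs = [
            ev.duration_s
            for ev in events
            if ev.kind == kind and day_start <= ev.start_time < day_end
        ]
        count = len(durs)
        dur_min = sum(durs) / 60.0
        dpe = 60.0 * dur_min / count if count else float("nan")
        out.append(
            DailyEventStats(
                infant_id=day.infant_id,
                day_of_life=day.day_of_life,
                kind=kind,
                count=count,
                dur_min=dur_min,
                dpe_s=dpe,
            )
        )
    return out
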