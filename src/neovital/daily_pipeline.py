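"""Daily aggregation: window features -> daily medians -> 42-metric table.

Window-level feature vectors are summarized as the daily median of the
every-10-minute results, merged with the daily intermittent-hypoxemia and
bradycardia event statistics, and joined to the outcome table.  The result
is one row per valid infant-day carrying exactly 42 candidate metrics
(33 daily-median window features + 3 event kinds x {count, dur, dpe}).
"""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import events_ih, features_hctsa
from .events_ih import EVENT_METRIC_COLUMNS, STANDARD_EVENTS
from .features_hctsa import FEATURE_NAMES, FeatureVector, compute_feature_vector
from .signal_model import (
    DEFAULT_MIN_COMPLETENESS,
    DayIndex,
    VitalSeries,
    day_validity,
    segment_windows,
)

__all__ = [
    "METRIC_COLUMNS",
    "daily_median",
    "assemble",
    "infant_daily_rows",
    "build_analysis_table",
]

log = logging.getLogger(__name__)

#: The 42 candidate metric columns, in stable order (manifest version 1).
METRIC_COLUMNS: tuple[str, ...] = tuple(FEATURE_NAMES) + EVENT_METRIC_COLUMNS
assert len(METRIC_COLUMNS) == 42


def daily_median(
    vectors: Sequence[FeatureVector], day: DayIndex, birth_time: _dt.datetime
) -> dict[str, float]:
    """Per-feature median over the day's windows where the feature is defined.

    A feature defined in no window of the day yields NaN.  The median of an
    even count is the midpoint of the central pair (numpy convention).
    """
    day_start = _dt.datetime.combine(birth_time.date(), _dt.time()) + _dt.timedelta(
        days=day.day_of_life - 1
    )
    day_end = day_start + _dt.timedelta(days=1)
    todays = [v for v in vectors if day_start <= v.window_start < day_end]
    out: dict[str, float] = {}
    for name in FEATURE_NAMES:
        vals = np.array([v.values[name] for v in todays], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[name] = float(np.median(vals)) if vals.size else float("nan")
    return out


def infant_daily_rows(
    hr: VitalSeries,
    spo2: VitalSeries,
    *,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
) -> pd.DataFrame:
    """Full single-infant pipeline: windows -> features -> daily 42-metric rows.

    Only days passing the >=12 h validity rule in both signals are emitted.
    """
    days = day_validity(hr, spo2)
    valid_days = [d for d in days if d.valid]
    if not valid_days:
        return pd.DataFrame(columns=["infant_id", "day_of_life", *METRIC_COLUMNS])
    windows = segment_windows(hr, spo2, min_completeness)
    vectors = [compute_feature_vector(w) for w in windows]
    events = [
        ev
        for definition in STANDARD_EVENTS
        for ev in events_ih.detect_events(
            spo2 if definition.signal.value == "SPO2" else hr, definition
        )
    ]
    rows = []
    for day in valid_days:
        row: dict[str, object] = {
            "infant_id": hr.infant_id,
            "day_of_life": day.day_of_life,
        }
        row.update(daily_median(vectors, day, hr.birth_time))
        for st in events_ih.daily_event_stats(events, day, hr.birth_time):
            key = st.kind.lower()
            row[f"{key}_count"] = st.count
            row[f"{key}_dur"] = st.dur_min
            row[f"{key}_dpe"] = st.dpe_s
        rows.append(row)
    return pd.DataFrame(rows, columns=["infant_id", "day_of_life", *METRIC_COLUMNS])


def assemble(
    daily_metrics: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> pd.DataFrame:
    """Join daily metric rows with the outcome table.

    ``daily_metrics`` holds one row per valid infant-day with the 42 metric
    columns; ``outcomes`` is the encoded outcome table (see
    :func:`neovital.outcome_eval.encode_outcome_table`) keyed by
    ``infant_id``.  Infants with vitals but no outcome record are excluded
    with a warning; row counts at each filter are logged.
    """
    missing = set(daily_metrics["infant_id"]) - set(outcomes["infant_id"])
    if missing:
        log.warning(
            "excluding %d infant(s) with vitals but no outcome record: %s",
            len(missing),
            ", ".join(sorted(missing)[:10]),
        )
    n0 = len(daily_metrics)
    merged = daily_metrics.merge(outcomes, on="infant_id", how="inner")
    log.info("assembled analysis table: %d of %d infant-day rows kept", len(merged), n0)
    extra = [c for c in merged.columns if c not in ("infant_id", "day_of_life", *METRIC_COLUMNS)]
    return merged[["infant_id", "day_of_life", *METRIC_COLUMNS, *extra]]


def build_analysis_table(
    series_pairs: Iterable[tuple[VitalSeries, VitalSeries]],
    outcomes: pd.DataFrame,
    *,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
) -> pd.DataFrame:
    """Run the daily pipeline over an iterable of (hr, spo2) pairs and assemble.

    The iterable may be lazy; each infant's series are processed and
    released before the next is materialized.
    """
    frames = [
        infant_daily_rows(hr, spo2, min_completeness=min_completeness)
        for hr, spo2 in series_pairs
    ]
    frames = [f for f in frames if len(f)]
    daily = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["infant_id", "day_of_life", *METRIC_COLUMNS])
    )
    return assemble(daily, outcomes)
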