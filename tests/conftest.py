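"""Shared fixtures: deterministic random windows spanning diverse regimes."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from neovital.signal_model import WINDOW_SAMPLES, SignalKind, VitalSeries, WindowPair

T0 = dt.datetime(2024, 1, 1)


def make_series(values, kind=SignalKind.SPO2, infant="inf0", start=T0, birth=T0):
    return VitalSeries(
        infant_id=infant,
        signal_kind=kind,
        start_time=start,
        values=np.asarray(values, dtype=float),
        birth_time=birth,
    )


def random_window(rng: np.random.Generator, regime: str) -> WindowPair:
    """One 300-sample HR/SPO2 window from a named generating regime."""
    n = WINDOW_SAMPLES
    t = np.arange(n)
    hr = np.round(150 + 8 * np.sin(2 * np.pi * t / 45) + np.cumsum(rng.normal(0, 0.8, n)) * 0.4)
    spo2 = 96 + rng.normal(0, 1.2, n)
    if regime == "desat":
        for s0 in rng.integers(0, n - 40, size=3):
            spo2[s0 : s0 + 30] -= np.interp(np.arange(30), [0, 6, 24, 29], [0, 12, 12, 0])
    elif regime == "oscillating":
        spo2 += 2.0 * np.sin(2 * np.pi * t / 12.5 + rng.uniform(0, 6.28))
    elif regime == "quiet":
        hr = np.round(160 + rng.normal(0, 0.4, n))
        spo2 = 98 + rng.normal(0, 0.3, n)
    elif regime == "constant_hr":
        hr = np.full(n, 150.0)
    spo2 = np.round(np.clip(spo2, 0, 100))
    hr = np.clip(hr, 20, 300)
    if regime != "complete":
        for sig in (hr, spo2):
            for g0 in rng.integers(0, n - 10, size=rng.integers(0, 3)):
                sig[g0 : g0 + int(rng.integers(1, 12))] = np.nan
    return WindowPair("inf0", T0, hr, spo2)


@pytest.fixture(scope="session")
def random_windows() -> list[WindowPair]:
    """100 windows cycling through the generating regimes, fixed seed."""
    rng = np.random.default_rng(20240531)
    regimes = ["complete", "desat", "oscillating", "quiet", "constant_hr"]
    return [random_window(rng, regimes[i % len(regimes)]) for i in range(100)]
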