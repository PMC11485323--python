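"""The 33-feature representative HCTSA subset for 10-minute HR/SPO2 windows.

Highly comparative time-series analysis (HCTSA) applies thousands of
time-series algorithms from many disciplines; prior unsupervised clustering
of such algorithms on NICU vital signs reduced them to 20 clusters, and the
representative subset implemented here — 31 single-signal features plus the
max/min HR-vs-SPO2 cross-correlation at lags up to 30 s — captures one or
more members of every cluster.

Conventions shared by all features
----------------------------------
* Input windows are 300-sample (10-minute) arrays on the 2-s grid with NaN
  for missing samples.
* Moment-type statistics drop missing values; sequence-type statistics
  (symbol patterns, autocorrelations, the walker) operate on contiguous
  non-missing runs only, so that no pattern, pair or transition ever spans
  a monitoring gap.
* A feature whose preconditions fail (e.g. zero variance where a
  correlation is required) evaluates to NaN — recorded, never dropped.

Several auxiliary-feature parameterizations (clipping ranges, wavelet
level, symbol codings) follow conventional choices and are provisional;
they are exposed through the feature registry so overrides need no code
change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping

import numpy as np
import pywt

from .signal_model import WindowPair

__all__ = [
    "FeatureInput",
    "FeatureSpec",
    "FeatureVector",
    "FEATURE_REGISTRY",
    "FEATURE_NAMES",
    "N_FEATURES",
    "MOTIF_WORD_LENGTH",
    "MOTIF_ALPHABET",
    "compute_feature_vector",
    "moments",
    "symbolize_diff3",
    "symbolize_tertile",
    "motif_entropy",
    "prob_increases",
    "walker_stat",
    "autocorr",
    "cross_corr_extrema",
    "contiguous_runs",
    "dump_registry",
    "load_registry",
]

MOTIF_WORD_LENGTH = 4
MOTIF_ALPHABET = 3
#: ln(3**4): upper bound of the motif entropies, nats.
MAX_MOTIF_ENTROPY = math.log(MOTIF_ALPHABET**MOTIF_WORD_LENGTH)

_CLIP_RANGE = {"HR": (50.0, 250.0), "SPO2": (50.0, 100.0)}


class FeatureInput(str, Enum):
    HR = "HR"
    SPO2 = "SPO2"
    BOTH = "BOTH"


@dataclass(frozen=True)
class FeatureSpec:
    """Registry entry: name, input signal, algorithm cluster, parameters."""

    name: str
    input: FeatureInput
    cluster: int | None
    func: Callable[..., float]
    params: Mapping[str, float] = field(default_factory=dict)


@dataclass
class FeatureVector:
    infant_id: str
    window_start: object
    values: dict[str, float]


# ---------------------------------------------------------------------------
# Run helpers


def contiguous_runs(x: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of consecutive non-missing samples, in order."""
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(x)
    if not mask.any():
        return []
    idx = np.nonzero(mask)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    return [x[seg[0] : seg[-1] + 1] for seg in np.split(idx, breaks + 1)]


def _finite(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def _std(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")


# ---------------------------------------------------------------------------
# Moment-type statistics


def moments(x: np.ndarray, trim_fraction: float = 0.1) -> dict[str, float]:
    """Distributional moments of the non-missing window values.

    ``std`` is the n-1 sample standard deviation; ``skew``/``kurt`` are the
    standardized third/fourth central moments (kurtosis of a normal is 3,
    not 0); ``mean_trim`` discards the top and bottom ``trim_fraction`` of
    the sorted values; ``cv`` = std/mean, undefined for zero mean.
    """
    v = _finite(x)
    nan = float("nan")
    out = dict.fromkeys(
        ("mean", "std", "cv", "min", "max", "skew", "kurt", "mean_trim"), nan
    )
    if v.size < 2:
        return out
    mean = float(np.mean(v))
    std = _std(v)
    out["mean"] = mean
    out["std"] = std
    out["cv"] = std / mean if mean != 0.0 else nan
    out["min"] = float(np.min(v))
    out["max"] = float(np.max(v))
    m2 = float(np.mean((v - mean) ** 2))
    if m2 > 0.0:
        out["skew"] = float(np.mean((v - mean) ** 3)) / m2**1.5
        out["kurt"] = float(np.mean((v - mean) ** 4)) / m2**2
    s = np.sort(v)
    k = int(math.floor(trim_fraction * v.size))
    trimmed = s[k : v.size - k]
    out["mean_trim"] = float(np.mean(trimmed)) if trimmed.size else nan
    return out


# ---------------------------------------------------------------------------
# Symbolization


def symbolize_diff3(x: np.ndarray) -> list[np.ndarray]:
    """3-symbol coding of successive differences, per contiguous run.

    Symbols: +1 (increasing), 0 (same), -1 (decreasing).  The "same" band is
    exact equality — monitor HR is integer-valued, so ties are meaningful.
    Returns one symbol array per run with >= 2 samples.
    """
    out = []
    for run in contiguous_runs(x):
        if run.size >= 2:
            out.append(np.sign(np.diff(run)).astype(int))
    return out


def symbolize_tertile(x: np.ndarray) -> list[np.ndarray]:
    """Per-window empirical tertile coding (0 low / 1 mid / 2 high).

    Bin edges are the window's 33.3rd and 66.7th percentiles (linear
    interpolation); values tied with an edge go to the lower bin, so a
    constant window is all-low.
    """
    v = _finite(x)
    if v.size == 0:
        return []
    q1, q2 = np.percentile(v, [100.0 / 3.0, 200.0 / 3.0])
    out = []
    for run in contiguous_runs(x):
        sym = np.where(run > q2, 2, np.where(run > q1, 1, 0))
        out.append(sym.astype(int))
    return out


# ---------------------------------------------------------------------------
# Sequence statistics


def motif_entropy(
    symbol_runs: list[np.ndarray],
    word_length: int = MOTIF_WORD_LENGTH,
    *,
    base: str = "nats",
) -> float:
    """Shannon entropy of overlapping length-4 words of a 3-symbol sequence.

    With word length 4 there are 3^4 = 81 possible patterns, so the result
    lies in [0, ln 81] nats (set ``base="bits"`` for log2).  Words are
    counted within contiguous runs only and pooled across runs.  Accepts
    either digit-coded (0..2) or sign-coded (-1..1) symbol runs.
    """
    runs = [(s + 1 if s.size and s.min() < 0 else s) for s in symbol_runs]
    h = _entropy_from_counts(_count_words_digits(runs, word_length))
    return h / math.log(2.0) if base == "bits" else h


def _count_words_digits(runs: list[np.ndarray], word_length: int) -> np.ndarray:
    counts = np.zeros(MOTIF_ALPHABET**word_length, dtype=np.int64)
    for sym in runs:
        if sym.size < word_length:
            continue
        n_words = sym.size - word_length + 1
        code = np.zeros(n_words, dtype=np.int64)
        for j in range(word_length):
            code = code * MOTIF_ALPHABET + sym[j : j + n_words]
        counts += np.bincount(code, minlength=counts.size)
    return counts


def _diff3_digits(x: np.ndarray) -> list[np.ndarray]:
    """diff3 symbols mapped to digits 0..2 (dec=0, same=1, inc=2)."""
    return [s + 1 for s in symbolize_diff3(x)]


def prob_increases(x: np.ndarray) -> float:
    """Probability of the "uu" pattern of the binary up/down HR coding.

    Each successive difference is coded u (increase) or d (non-increase;
    staying the same counts as down).  Returns count(uu) over all adjacent
    symbol pairs within contiguous runs; low values flag low variability.
    """
    uu = 0
    pairs = 0
    for sym in symbolize_diff3(x):
        if sym.size < 2:
            continue
        u = sym > 0
        pairs += u.size - 1
        uu += int(np.count_nonzero(u[:-1] & u[1:]))
    if pairs == 0:
        return float("nan")
    return uu / pairs


def walker_stat(x: np.ndarray, m: float = 5.0, *, runs: list[np.ndarray] | None = None) -> float:
    """Ratio std(walker)/std(signal) for an inertial walker of mass ``m``.

    The walker starts on the signal (w1 = x1, w2 = x2) and thereafter
    extrapolates its previous step, with the signal acting as a restoring
    force attenuated by the mass: w_i = w_inert + (x_i - w_inert)/m where
    w_inert = 2 w_{i-1} - w_{i-2}.  Signals the walker can follow — slow,
    persistent patterns such as long desaturations — give ratios near 1
    (high risk); mid-frequency variability excites the walker's resonance
    and pushes the ratio well above 1.  Restarted per contiguous run; NaN
    for zero-variance input.  With m = 1 the walker is the signal and the
    ratio is exactly 1.
    """
    runs = contiguous_runs(x) if runs is None else runs
    vals = np.concatenate(runs) if runs else np.array([])
    sx = _std(vals)
    if not np.isfinite(sx) or sx == 0.0 or vals.size < 3:
        return float("nan")
    if m == 1.0:  # unit mass: the walker is the signal, exactly
        return 1.0
    ws = []
    for run in runs:
        w = np.empty(run.size)
        w[: min(2, run.size)] = run[: min(2, run.size)]
        for i in range(2, run.size):
            w_inert = 2.0 * w[i - 1] - w[i - 2]
            w[i] = w_inert + (run[i] - w_inert) / m
        ws.append(w)
    return _std(np.concatenate(ws)) / sx


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Numerically stable Pearson r; NaN for degenerate input."""
    if a.size < 2:
        return float("nan")
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        return float("nan")
    return float(a @ b) / denom


def autocorr(x: np.ndarray, lag: int = 4) -> float:
    """Pearson correlation of (x_t, x_{t+lag}) over within-run pairs.

    At the 2-s grid, lag 4 is 8 s.  High values mean variability over the
    window without local high-frequency variation.
    """
    a_parts, b_parts = [], []
    for run in contiguous_runs(x):
        if run.size >= lag + 1:
            a_parts.append(run[:-lag])
            b_parts.append(run[lag:])
    if not a_parts:
        return float("nan")
    return _pearson(np.concatenate(a_parts), np.concatenate(b_parts))


def cross_corr_extrema(
    hr: np.ndarray, spo2: np.ndarray, max_lag: int = 15
) -> dict[str, float]:
    """Max and min Pearson cross-correlation of HR vs SPO2 over lags.

    Lags run over every integer in [-max_lag, +max_lag] samples (±30 s at
    the 2-s grid); positive lag correlates HR at t with SPO2 at t+lag.
    Pairs with either sample missing are dropped.
    """
    hr = np.asarray(hr, dtype=float)
    spo2 = np.asarray(spo2, dtype=float)
    n = hr.size
    ma = np.isfinite(hr).astype(float)
    mb = np.isfinite(spo2).astype(float)
    # zero-fill and center so the per-lag moment sums below are exact
    # correlations of short arrays (missing samples contribute nothing)
    a = np.where(ma > 0, hr - np.nanmean(hr) if ma.any() else 0.0, 0.0)
    b = np.where(mb > 0, spo2 - np.nanmean(spo2) if mb.any() else 0.0, 0.0)
    sl = slice(n - 1 - max_lag, n + max_lag)  # lags -max_lag..+max_lag
    cnt = np.correlate(mb, ma, "full")[sl]
    sab = np.correlate(b, a, "full")[sl]
    sa = np.correlate(mb, a, "full")[sl]
    sb = np.correlate(b, ma, "full")[sl]
    saa = np.correlate(mb, a * a, "full")[sl]
    sbb = np.correlate(b * b, ma, "full")[sl]
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sab - sa * sb / cnt
        var = (saa - sa * sa / cnt) * (sbb - sb * sb / cnt)
        r = cov / np.sqrt(var)
    r = r[(cnt >= 2) & np.isfinite(r)]
    if r.size == 0:
        return {"xc_max": float("nan"), "xc_min": float("nan")}
    return {"xc_max": float(r.max()), "xc_min": float(r.min())}


# ---------------------------------------------------------------------------
# Auxiliary single-signal statistics


def _avgthresh(x: np.ndarray, lo: float, hi: float) -> float:
    v = _finite(x)
    if v.size == 0:
        return float("nan")
    return float(np.mean(np.clip(v, lo, hi)))


def _corrmean(x: np.ndarray) -> float:
    """Mean of the 3-point moving average (within-run triples)."""
    parts = []
    for run in contiguous_runs(x):
        if run.size >= 3:
            parts.append((run[:-2] + run[1:-1] + run[2:]) / 3.0)
    if not parts:
        return float("nan")
    return float(np.mean(np.concatenate(parts)))


def _transition_counts(runs: list[np.ndarray]) -> np.ndarray:
    c = np.zeros((MOTIF_ALPHABET, MOTIF_ALPHABET), dtype=np.int64)
    for sym in runs:
        if sym.size >= 2:
            np.add.at(c, (sym[:-1], sym[1:]), 1)
    return c


def _surprise_from_counts(c: np.ndarray) -> float:
    total = c.sum()
    if total == 0:
        return float("nan")
    row = c.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = c / row
    obs = c > 0
    return float((c[obs] * -np.log(p[obs])).sum() / total)


def _surprise(x: np.ndarray) -> float:
    """Mean negative log-probability of first-order tertile-symbol transitions."""
    return _surprise_from_counts(_transition_counts(symbolize_tertile(x)))


def _wavelet_fraction(x: np.ndarray, level: int = 3, *, runs: list[np.ndarray] | None = None) -> float:
    """Fraction of detail energy at the coarsest level of a db2 decomposition.

    Computed on the longest contiguous run truncated to a multiple of
    2**level samples, with periodized boundary handling, so the transform
    is critically sampled and exactly defined.  Level 3 of the 4-tap
    Daubechies filter at the 2-s grid captures fluctuation on the ~16-32 s
    scale.
    """
    runs = contiguous_runs(x) if runs is None else runs
    if not runs:
        return float("nan")
    run = max(runs, key=lambda r: r.size)
    block = 2**level
    n = (run.size // block) * block
    if n < 2 * block:
        return float("nan")
    coeffs = pywt.wavedec(run[:n], "db2", mode="periodization", level=level)
    detail_energy = [float(np.sum(c**2)) for c in coeffs[1:]]  # cD3, cD2, cD1
    total = sum(detail_energy)
    if total == 0.0:
        return float("nan")
    return detail_energy[0] / total


def _derivative(x: np.ndarray) -> float:
    """Sample std of the within-run second difference."""
    parts = [np.diff(run, n=2) for run in contiguous_runs(x) if run.size >= 3]
    if not parts:
        return float("nan")
    d = np.concatenate(parts)
    return _std(d)


def _symautocorr(x: np.ndarray) -> float:
    """Lag-1 autocorrelation of the numeric-coded diff3 symbol sequence."""
    runs = symbolize_diff3(x)
    a_parts, b_parts = [], []
    for sym in runs:
        if sym.size >= 2:
            a_parts.append(sym[:-1].astype(float))
            b_parts.append(sym[1:].astype(float))
    if not a_parts:
        return float("nan")
    return _pearson(np.concatenate(a_parts), np.concatenate(b_parts))


def _symeigen(x: np.ndarray) -> float:
    """Std of eigenvalue moduli of the tertile-symbol transition matrix.

    Rows with no observed outgoing transitions are set uniform so the
    matrix stays stochastic; the spread of its spectrum (population std of
    the three moduli) reflects the mixing structure of the symbol dynamics.
    """
    return _symeigen_from_counts(_transition_counts(symbolize_tertile(x)))


def _symeigen_from_counts(c: np.ndarray) -> float:
    if c.sum() == 0:
        return float("nan")
    row = c.sum(axis=1, keepdims=True).astype(float)
    p = np.where(row > 0, c / np.where(row == 0, 1.0, row), 1.0 / MOTIF_ALPHABET)
    mod = np.abs(np.linalg.eigvals(p))
    return float(np.std(mod))


def _symbin(x: np.ndarray, *, runs: list[np.ndarray] | None = None) -> float:
    """Longest within-run streak at or below the window mean, as a fraction.

    The binary coding splits samples into above-mean vs not-above-mean; a
    constant window is therefore entirely "not above" and scores 1.
    Normalized by the number of non-missing samples.
    """
    v = _finite(x)
    if v.size == 0:
        return float("nan")
    mean = float(np.mean(v))
    longest = 0
    for run in contiguous_runs(x) if runs is None else runs:
        below = run <= mean
        streak = 0
        for b in below:
            streak = streak + 1 if b else 0
            longest = max(longest, streak)
    return longest / v.size


def _symiqr(x: np.ndarray, *, runs: list[np.ndarray] | None = None) -> float:
    """Switch rate of the inside/outside-interquartile-range binary sequence.

    A sample is "inside" when q25 <= x <= q75 of the window; the statistic
    is the fraction of adjacent within-run pairs whose coding differs.
    """
    v = _finite(x)
    if v.size < 2:
        return float("nan")
    q25, q75 = np.percentile(v, [25.0, 75.0])
    switches = 0
    pairs = 0
    for run in contiguous_runs(x) if runs is None else runs:
        inside = (run >= q25) & (run <= q75)
        if inside.size >= 2:
            pairs += inside.size - 1
            switches += int(np.count_nonzero(inside[:-1] != inside[1:]))
    if pairs == 0:
        return float("nan")
    return switches / pairs


# ---------------------------------------------------------------------------
# Registry


def _motif_entropy_diff(x: np.ndarray, word_length: int = MOTIF_WORD_LENGTH) -> float:
    counts = _count_words_digits(_diff3_digits(x), word_length)
    return _entropy_from_counts(counts)


def _motif_entropy_tertile(x: np.ndarray, word_length: int = MOTIF_WORD_LENGTH) -> float:
    counts = _count_words_digits(symbolize_tertile(x), word_length)
    return _entropy_from_counts(counts)


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def _moment(stat: str) -> Callable[[np.ndarray], float]:
    def f(x: np.ndarray) -> float:
        return moments(x)[stat]

    f.__name__ = f"moment_{stat}"
    return f


def _build_registry() -> dict[str, FeatureSpec]:
    S = FeatureSpec
    HR, SP, BOTH = FeatureInput.HR, FeatureInput.SPO2, FeatureInput.BOTH
    hr_lo, hr_hi = _CLIP_RANGE["HR"]
    sp_lo, sp_hi = _CLIP_RANGE["SPO2"]
    specs = [
        # HR
        S("hr_mean", HR, 1, _moment("mean")),
        S("hr_avgthresh", HR, 1, _avgthresh, {"lo": hr_lo, "hi": hr_hi}),
        S("hr_corrmean", HR, 1, _corrmean),
        S("hr_std", HR, 2, _moment("std")),
        S("hr_cv", HR, 2, _moment("cv")),
        S("hr_max", HR, 3, _moment("max")),
        S("hr_min", HR, 4, _moment("min")),
        S("hr_kurt", HR, 5, _moment("kurt")),
        S("hr_skew", HR, 5, _moment("skew")),
        S("hr_symautocorr", HR, 6, _symautocorr),
        S("hr_surprise", HR, 7, _surprise),
        S("hr_entropy", HR, 7, _motif_entropy_tertile,
          {"word_length": MOTIF_WORD_LENGTH}),
        S("hr_wavelet", HR, 8, _wavelet_fraction, {"level": 3}),
        S("hr_probincreases", HR, 9, prob_increases),
        S("hr_entropy_diff", HR, 9, _motif_entropy_diff,
          {"word_length": MOTIF_WORD_LENGTH}),
        S("hr_derivative", HR, 12, _derivative),
        # SPO2
        S("sp_std", SP, 10, _moment("std")),
        S("sp_mean", SP, 11, _moment("mean")),
        S("sp_avgthres", SP, 11, _avgthresh, {"lo": sp_lo, "hi": sp_hi}),
        S("sp_corrmean", SP, 11, _corrmean),
        S("sp_min", SP, 13, _moment("min")),
        S("sp_skew", SP, 14, _moment("skew")),
        S("sp_kurt", SP, 14, _moment("kurt")),
        S("sp_mean_trim", SP, 14, _moment("mean_trim")),
        S("sp_wavelet", SP, 15, _wavelet_fraction, {"level": 3}),
        S("sp_symeigen", SP, 16, _symeigen),
        S("sp_walk", SP, 17, walker_stat, {"m": 5.0}),
        S("sp_autocorr", SP, 17, autocorr, {"lag": 4}),
        S("sp_symentropy", SP, 18, _motif_entropy_tertile,
          {"word_length": MOTIF_WORD_LENGTH}),
        S("sp_symbin", SP, 19, _symbin),
        S("sp_symiqr", SP, 20, _symiqr),
        # cross-correlation
        S("xc_max", BOTH, None, cross_corr_extrema, {"max_lag": 15}),
        S("xc_min", BOTH, None, cross_corr_extrema, {"max_lag": 15}),
    ]
    reg = {s.name: s for s in specs}
    assert len(reg) == 33
    return reg


FEATURE_REGISTRY: dict[str, FeatureSpec] = _build_registry()
FEATURE_NAMES: tuple[str, ...] = tuple(FEATURE_REGISTRY)
N_FEATURES = len(FEATURE_NAMES)


class _SignalContext:
    """Shared intermediates for one window signal, computed once.

    Lets :func:`compute_feature_vector` evaluate the many features that
    reuse the same runs / moments / symbol sequences without recomputing
    them per feature; single-feature calls through the registry functions
    produce identical values by construction (verified against independent
    oracles in the test suite).
    """

    def __init__(self, x: np.ndarray):
        self.x = np.asarray(x, dtype=float)
        self.runs = contiguous_runs(self.x)
        self.moments = moments(self.x)
        self.diff3 = [np.sign(np.diff(r)).astype(int) for r in self.runs if r.size >= 2]
        v = _finite(self.x)
        self.n_finite = v.size
        if v.size:
            q1, q2 = np.percentile(v, [100.0 / 3.0, 200.0 / 3.0])
            self.tertile = [
                np.where(r > q2, 2, np.where(r > q1, 1, 0)).astype(int)
                for r in self.runs
            ]
        else:
            self.tertile = []
        self.transitions = _transition_counts(self.tertile)


def _lagged_pearson(runs: list[np.ndarray], lag: int) -> float:
    a_parts = [r[:-lag] for r in runs if r.size >= lag + 1]
    b_parts = [r[lag:] for r in runs if r.size >= lag + 1]
    if not a_parts:
        return float("nan")
    return _pearson(np.concatenate(a_parts), np.concatenate(b_parts))


def _eval_fast(name: str, spec: FeatureSpec, ctx: _SignalContext) -> float:
    """Evaluate one single-signal feature from shared intermediates."""
    stat = name.split("_", 1)[1]
    if stat in ("mean", "std", "cv", "min", "max", "skew", "kurt", "mean_trim"):
        return ctx.moments[stat]
    if stat in ("avgthresh", "avgthres"):
        return _avgthresh(ctx.x, **spec.params)
    if stat == "corrmean":
        parts = [(r[:-2] + r[1:-1] + r[2:]) / 3.0 for r in ctx.runs if r.size >= 3]
        return float(np.mean(np.concatenate(parts))) if parts else float("nan")
    if stat == "symautocorr":
        return _lagged_pearson([s.astype(float) for s in ctx.diff3], 1)
    if stat == "surprise":
        return _surprise_from_counts(ctx.transitions)
    if stat in ("entropy", "symentropy"):
        return _entropy_from_counts(
            _count_words_digits(ctx.tertile, int(spec.params.get("word_length", MOTIF_WORD_LENGTH)))
        )
    if stat == "entropy_diff":
        return _entropy_from_counts(
            _count_words_digits([s + 1 for s in ctx.diff3],
                                int(spec.params.get("word_length", MOTIF_WORD_LENGTH)))
        )
    if stat == "wavelet":
        return _wavelet_fraction(ctx.x, runs=ctx.runs, **spec.params)
    if stat == "probincreases":
        uu = pairs = 0
        for sym in ctx.diff3:
            if sym.size >= 2:
                u = sym > 0
                pairs += u.size - 1
                uu += int(np.count_nonzero(u[:-1] & u[1:]))
        return uu / pairs if pairs else float("nan")
    if stat == "derivative":
        parts = [np.diff(r, n=2) for r in ctx.runs if r.size >= 3]
        return _std(np.concatenate(parts)) if parts else float("nan")
    if stat == "walk":
        return walker_stat(ctx.x, runs=ctx.runs, **spec.params)
    if stat == "autocorr":
        return _lagged_pearson(ctx.runs, int(spec.params.get("lag", 4)))
    if stat == "symeigen":
        return _symeigen_from_counts(ctx.transitions)
    if stat == "symbin":
        return _symbin(ctx.x, runs=ctx.runs)
    if stat == "symiqr":
        return _symiqr(ctx.x, runs=ctx.runs)
    return float(spec.func(ctx.x, **spec.params))


def compute_feature_vector(w: WindowPair) -> FeatureVector:
    """Evaluate all 33 registered features on one valid window pair.

    Undefined features are recorded as NaN, never dropped; the result
    always carries exactly 33 named values.
    """
    vals: dict[str, float] = {}
    ctx = {FeatureInput.HR: _SignalContext(w.hr), FeatureInput.SPO2: _SignalContext(w.spo2)}
    xc: dict[str, float] | None = None
    for name, spec in FEATURE_REGISTRY.items():
        if spec.input is FeatureInput.BOTH:
            if xc is None:
                xc = cross_corr_extrema(w.hr, w.spo2, **_only(spec.params, "max_lag"))
            vals[name] = xc[name]
            continue
        vals[name] = float(_eval_fast(name, spec, ctx[spec.input]))
    return FeatureVector(infant_id=w.infant_id, window_start=w.window_start, values=vals)


def _only(params: Mapping[str, float], *keys: str) -> dict[str, float]:
    return {k: params[k] for k in keys if k in params}


# ---------------------------------------------------------------------------
# Registry (de)serialization — parameter overrides without code changes


def dump_registry(path) -> None:
    """Serialize the registry (name, input, cluster, params) as JSON."""
    payload = [
        {
            "name": s.name,
            "input": s.input.value,
            "cluster": s.cluster,
            "params": dict(s.params),
        }
        for s in FEATURE_REGISTRY.values()
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_registry(path) -> dict[str, FeatureSpec]:
    """Load a registry file, applying parameter overrides to built-in specs."""
    with open(path) as fh:
        payload = json.load(fh)
    reg = {}
    for entry in payload:
        base = FEATURE_REGISTRY[entry["name"]]
        reg[base.name] = FeatureSpec(
            name=base.name,
            input=FeatureInput(entry.get("input", base.input.value)),
            cluster=entry.get("cluster", base.cluster),
            func=base.func,
            params=entry.get("params", dict(base.params)),
        )
    return reg
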