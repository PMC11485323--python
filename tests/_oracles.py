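"""Independent brute-force transcriptions of every window feature.

Each oracle re-derives its statistic from the written definition with plain
Python loops and shares no code with the package (numpy is used only for
array plumbing and the 3x3 eigenvalue primitive).  The equivalence harness
compares these against the package's feature vector on random windows.
"""

from __future__ import annotations

import math

import numpy as np

NAN = float("nan")


def runs_of(x) -> list[list[float]]:
    """Contiguous non-NaN runs, as plain lists."""
    out, cur = [], []
    for v in x:
        if v is not None and not math.isnan(v):
            cur.append(float(v))
        elif cur:
            out.append(cur)
            cur = []
    if cur:
        out.append(cur)
    return out


def finite_of(x) -> list[float]:
    return [float(v) for v in x if not math.isnan(v)]


def o_mean(v):
    return sum(v) / len(v) if len(v) >= 2 else NAN


def o_std(v):
    if len(v) < 2:
        return NAN
    m = sum(v) / len(v)
    return math.sqrt(sum((u - m) ** 2 for u in v) / (len(v) - 1))


def o_cv(v):
    m = o_mean(v)
    s = o_std(v)
    if math.isnan(m) or m == 0.0:
        return NAN
    return s / m


def o_minmax(v, which):
    if len(v) < 2:
        return NAN
    return min(v) if which == "min" else max(v)


def o_skew(v):
    if len(v) < 2:
        return NAN
    m = sum(v) / len(v)
    m2 = sum((u - m) ** 2 for u in v) / len(v)
    if m2 == 0.0:
        return NAN
    m3 = sum((u - m) ** 3 for u in v) / len(v)
    return m3 / m2**1.5


def o_kurt(v):
    if len(v) < 2:
        return NAN
    m = sum(v) / len(v)
    m2 = sum((u - m) ** 2 for u in v) / len(v)
    if m2 == 0.0:
        return NAN
    m4 = sum((u - m) ** 4 for u in v) / len(v)
    return m4 / m2**2


def o_mean_trim(v, frac=0.1):
    if len(v) < 2:
        return NAN
    s = sorted(v)
    k = math.floor(frac * len(v))
    t = s[k : len(v) - k]
    return sum(t) / len(t) if t else NAN


def o_avgthresh(v, lo, hi):
    if not v:
        return NAN
    return sum(min(max(u, lo), hi) for u in v) / len(v)


def o_corrmean(runs):
    acc = []
    for r in runs:
        for i in range(len(r) - 2):
            acc.append((r[i] + r[i + 1] + r[i + 2]) / 3.0)
    return sum(acc) / len(acc) if acc else NAN


def o_pearson(a, b):
    n = len(a)
    if n < 2:
        return NAN
    ma = sum(a) / n
    mb = sum(b) / n
    sa = [u - ma for u in a]
    sb = [u - mb for u in b]
    den = math.sqrt(sum(u * u for u in sa) * sum(u * u for u in sb))
    if den == 0.0:
        return NAN
    return sum(u * w for u, w in zip(sa, sb)) / den


def o_percentile(v, q):
    """Linear-interpolation percentile (standard primitive, bit-exact)."""
    return float(np.percentile(np.array(v, dtype=float), q))


def diff3_runs(runs):
    """Per-run difference symbols: +1 up, 0 same, -1 down."""
    out = []
    for r in runs:
        if len(r) >= 2:
            sym = []
            for i in range(len(r) - 1):
                d = r[i + 1] - r[i]
                sym.append(1 if d > 0 else (-1 if d < 0 else 0))
            out.append(sym)
    return out


def tertile_runs(x):
    v = finite_of(x)
    if not v:
        return []
    q1 = o_percentile(v, 100.0 / 3.0)
    q2 = o_percentile(v, 200.0 / 3.0)
    out = []
    for r in runs_of(x):
        out.append([2 if u > q2 else (1 if u > q1 else 0) for u in r])
    return out


def o_word_entropy(sym_runs, word_length=4):
    counts: dict[tuple, int] = {}
    for sym in sym_runs:
        for i in range(len(sym) - word_length + 1):
            w = tuple(sym[i : i + word_length])
            counts[w] = counts.get(w, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return NAN
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def o_probincreases(runs):
    uu = pairs = 0
    for sym in diff3_runs(runs):
        ups = [s == 1 for s in sym]
        for i in range(len(ups) - 1):
            pairs += 1
            if ups[i] and ups[i + 1]:
                uu += 1
    return uu / pairs if pairs else NAN


def o_symautocorr(runs):
    a, b = [], []
    for sym in diff3_runs(runs):
        for i in range(len(sym) - 1):
            a.append(float(sym[i]))
            b.append(float(sym[i + 1]))
    return o_pearson(a, b)


def o_surprise(x):
    counts: dict[tuple, int] = {}
    row: dict[int, int] = {}
    for sym in tertile_runs(x):
        for i in range(len(sym) - 1):
            counts[(sym[i], sym[i + 1])] = counts.get((sym[i], sym[i + 1]), 0) + 1
            row[sym[i]] = row.get(sym[i], 0) + 1
    total = sum(counts.values())
    if total == 0:
        return NAN
    acc = 0.0
    for (a, _b), c in counts.items():
        acc += c * -math.log(c / row[a])
    return acc / total


def o_symeigen(x):
    counts = [[0, 0, 0] for _ in range(3)]
    for sym in tertile_runs(x):
        for i in range(len(sym) - 1):
            counts[sym[i]][sym[i + 1]] += 1
    total = sum(sum(r) for r in counts)
    if total == 0:
        return NAN
    p = []
    for r in counts:
        s = sum(r)
        p.append([c / s for c in r] if s else [1 / 3, 1 / 3, 1 / 3])
    mod = [abs(ev) for ev in np.linalg.eigvals(np.array(p))]
    m = sum(mod) / 3.0
    return math.sqrt(sum((u - m) ** 2 for u in mod) / 3.0)


def o_symbin(x):
    v = finite_of(x)
    if not v:
        return NAN
    mean = sum(v) / len(v)
    longest = 0
    for r in runs_of(x):
        streak = 0
        for u in r:
            streak = streak + 1 if u <= mean else 0
            longest = max(longest, streak)
    return longest / len(v)


def o_symiqr(x):
    v = finite_of(x)
    if len(v) < 2:
        return NAN
    q25 = o_percentile(v, 25.0)
    q75 = o_percentile(v, 75.0)
    switches = pairs = 0
    for r in runs_of(x):
        inside = [q25 <= u <= q75 for u in r]
        for i in range(len(inside) - 1):
            pairs += 1
            if inside[i] != inside[i + 1]:
                switches += 1
    return switches / pairs if pairs else NAN


def o_derivative(runs):
    dd = []
    for r in runs:
        for i in range(len(r) - 2):
            dd.append(r[i + 2] - 2.0 * r[i + 1] + r[i])
    return o_std(dd)


def o_walker(x, m=5.0):
    rr = runs_of(x)
    pooled = [u for r in rr for u in r]
    sx = o_std(pooled)
    if math.isnan(sx) or sx == 0.0 or len(pooled) < 3:
        return NAN
    ws = []
    for r in rr:
        w = list(r[:2])
        for i in range(2, len(r)):
            inert = w[i - 1] + (w[i - 1] - w[i - 2])
            w.append(inert + (r[i] - inert) / m)
        ws.extend(w)
    return o_std(ws) / sx


def o_autocorr(runs, lag=4):
    a, b = [], []
    for r in runs:
        if len(r) >= lag + 1:
            a.extend(r[: len(r) - lag])
            b.extend(r[lag:])
    return o_pearson(a, b)


# 4-tap Daubechies low-pass in natural order; high-pass by the QMF relation.
_DB2_H = [
    (1 + math.sqrt(3)) / (4 * math.sqrt(2)),
    (3 + math.sqrt(3)) / (4 * math.sqrt(2)),
    (3 - math.sqrt(3)) / (4 * math.sqrt(2)),
    (1 - math.sqrt(3)) / (4 * math.sqrt(2)),
]
_DB2_G = [(-1) ** j * _DB2_H[3 - j] for j in range(4)]


def _dwt_step(v, f):
    n = len(v)
    return [
        sum(f[j] * v[(2 * k + j - 1) % n] for j in range(4)) for k in range(n // 2)
    ]


def o_wavelet(x, level=3):
    rr = runs_of(x)
    if not rr:
        return NAN
    run = max(rr, key=len)
    block = 2**level
    n = (len(run) // block) * block
    if n < 2 * block:
        return NAN
    a = list(run[:n])
    detail_energy = []
    for _ in range(level):
        d = _dwt_step(a, _DB2_G)
        a = _dwt_step(a, _DB2_H)
        detail_energy.append(sum(u * u for u in d))
    total = sum(detail_energy)
    if total == 0.0:
        return NAN
    return detail_energy[-1] / total


def o_cross_corr(hr, spo2, max_lag=15):
    n = len(hr)
    rs = []
    for lag in range(-max_lag, max_lag + 1):
        a, b = [], []
        for t in range(n):
            u = t + lag
            if 0 <= u < n:
                va, vb = hr[t], spo2[u]
                if not (math.isnan(va) or math.isnan(vb)):
                    a.append(va)
                    b.append(vb)
        r = o_pearson(a, b)
        if not math.isnan(r):
            rs.append(r)
    if not rs:
        return NAN, NAN
    return max(rs), min(rs)


def oracle_vector(hr, spo2) -> dict[str, float]:
    """All 33 features from the independent transcriptions above."""
    hr = [float(v) for v in hr]
    spo2 = [float(v) for v in spo2]
    out = {}
    for prefix, x in (("hr", hr), ("sp", spo2)):
        v = finite_of(x)
        rr = runs_of(x)
        lo, hi = (50.0, 250.0) if prefix == "hr" else (50.0, 100.0)
        out[f"{prefix}_mean"] = o_mean(v)
        out[f"{prefix}_std"] = o_std(v)
        out[f"{prefix}_min"] = o_minmax(v, "min")
        out[f"{prefix}_skew"] = o_skew(v)
        out[f"{prefix}_kurt"] = o_kurt(v)
        if prefix == "hr":
            out["hr_cv"] = o_cv(v)
            out["hr_max"] = o_minmax(v, "max")
            out["hr_avgthresh"] = o_avgthresh(v, lo, hi)
            out["hr_corrmean"] = o_corrmean(rr)
            out["hr_symautocorr"] = o_symautocorr(rr)
            out["hr_surprise"] = o_surprise(x)
            out["hr_entropy"] = o_word_entropy(tertile_runs(x))
            out["hr_wavelet"] = o_wavelet(x)
            out["hr_probincreases"] = o_probincreases(rr)
            out["hr_entropy_diff"] = o_word_entropy(diff3_runs(rr))
            out["hr_derivative"] = o_derivative(rr)
        else:
            out["sp_mean_trim"] = o_mean_trim(v)
            out["sp_avgthres"] = o_avgthresh(v, lo, hi)
            out["sp_corrmean"] = o_corrmean(rr)
            out["sp_wavelet"] = o_wavelet(x)
            out["sp_symeigen"] = o_symeigen(x)
            out["sp_walk"] = o_walker(x)
            out["sp_autocorr"] = o_autocorr(rr, 4)
            out["sp_symentropy"] = o_word_entropy(tertile_runs(x))
            out["sp_symbin"] = o_symbin(x)
            out["sp_symiqr"] = o_symiqr(x)
    out["xc_max"], out["xc_min"] = o_cross_corr(hr, spo2)
    return out
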