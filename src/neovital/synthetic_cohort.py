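"""Synthetic NICU cohort generator: 2-s HR/SPO2 streams, outcomes, twins.

A latent severity ``s`` (standard normal across infants, correlated 0.7
within a twin pregnancy) drives every risk-linked property:

* desaturation events appear at a rate increasing in ``s``, with durations
  and depths increasing in ``s`` (trapezoidal dips: linear fall, dwell,
  linear recovery);
* healthy-infant SPO2 carries a quasi-periodic oscillatory component with a
  ~25 s cycle, emulating periodic-breathing-like variability, on top of
  white noise — so in high-severity infants the record is dominated by
  persistent low-frequency desaturation patterns instead;
* HR is an AR(1) process whose innovation scale *shrinks* with ``s``
  (suppressed heart-rate variability in high-risk infants), with occasional
  bradycardia dips at a severity-linked rate;
* the 5-level respiratory outcome is an ordered logit on ``s``;
* monitoring gaps (missing data) arrive independently of severity.

Signals are integer-rounded as bedside monitors display them.  The master
seed fully determines every stream; each infant's signals are regenerated
lazily from a per-infant child seed so a large cohort never needs to be
held in memory at once.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .outcome_eval import CATEGORIES, encode_outcome_table
from .signal_model import SAMPLES_PER_DAY, SignalKind, VitalSeries, write_vitals

__all__ = ["CohortParams", "SyntheticCohort", "generate_cohort", "designed_auc_cohort"]

_BIRTH_EPOCH = _dt.datetime(2024, 1, 1)


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration; defaults are the package's study conditions."""

    n_infants: int = 200
    seed: int = 0
    days: int = 5
    twin_fraction: float = 0.12  # fraction of pregnancies carrying twins
    twin_rho: float = 0.7  # within-pregnancy severity correlation

    # SPO2 model (percent)
    spo2_baseline: float = 96.5
    spo2_baseline_drop: float = 0.3  # baseline shift times expit(severity)
    spo2_noise_sd: float = 0.5
    osc_amplitude: float = 1.1  # periodic-breathing-like component
    osc_suppression: float = 0.6  # oscillation shrink times expit(severity)
    osc_period_s: float = 25.0
    osc_pole: float = 0.95
    wander_sd: float = 0.3  # slow oxygenation-instability drift, percent
    wander_gain: float = 0.9  # extra drift sd times expit(severity)
    wander_pole: float = 0.995

    # desaturation events
    desat_rate_per_h: float = 2.5  # rate at severity 0
    desat_rate_slope: float = 0.4  # log-rate per unit severity
    desat_rate_heterogeneity: float = 0.4  # per-infant lognormal frailty, log-sd
    desat_rate_cap_per_h: float = 20.0
    desat_dur_median_s: float = 20.0
    desat_dur_slope: float = 1.0  # log-duration per unit severity
    desat_dur_sigma: float = 0.35
    desat_depth_base: float = 8.0
    desat_depth_gain: float = 5.0  # extra depth times expit(severity)
    desat_depth_sigma: float = 0.3

    # HR model (beats/min)
    hr_baseline: float = 155.0
    hr_baseline_sd: float = 5.0
    hr_phi: float = 0.97
    hr_innov_sd: float = 1.2
    hr_suppression: float = 0.35  # innovation shrink times expit(severity)
    hr_innov_heterogeneity: float = 0.3  # per-infant lognormal spread, log-sd
    brady_rate_per_h: float = 0.2
    brady_rate_slope: float = 0.9
    brady_dur_median_s: float = 8.0
    brady_dur_sigma: float = 0.4
    brady_depth: float = 85.0  # HR drop at dip bottom

    # missingness
    missing_fraction: float = 0.08
    gap_mean_samples: int = 60  # geometric mean gap length (2 min)

    # ordered-logit thresholds on severity + 0.5*logistic noise, tuned to the
    # nested prevalence profile 45.4 / 20.7 / 13.7 / 6.8 %
    outcome_thresholds: tuple[float, float, float, float] = (0.156, 1.103, 1.476, 2.013)
    outcome_noise_scale: float = 0.5

    def validate(self) -> None:
        bad = []
        if self.n_infants < 1:
            bad.append("n_infants")
        if self.days < 1:
            bad.append("days")
        if not 0.0 <= self.twin_fraction <= 1.0:
            bad.append("twin_fraction")
        if not -1.0 <= self.twin_rho <= 1.0:
            bad.append("twin_rho")
        for name in (
            "desat_rate_per_h",
            "desat_dur_median_s",
            "brady_rate_per_h",
            "spo2_noise_sd",
            "osc_amplitude",
        ):
            if getattr(self, name) < 0:
                bad.append(name)
        if not 0.0 <= self.missing_fraction < 1.0:
            bad.append("missing_fraction")
        if list(self.outcome_thresholds) != sorted(self.outcome_thresholds) or len(
            set(self.outcome_thresholds)
        ) != 4:
            bad.append("outcome_thresholds")
        if bad:
            raise ValueError(f"invalid CohortParams field(s): {', '.join(bad)}")


def _infant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _trapezoid(dur_samples: int) -> np.ndarray:
    """Unit-depth trapezoidal dip: 20% fall, 60% dwell, 20% recovery."""
    n = max(dur_samples, 3)
    t = np.arange(n, dtype=float)
    return -np.interp(t, [0, 0.2 * (n - 1), 0.8 * (n - 1), n - 1], [0, 1, 1, 0])


def _insert_dips(
    base: np.ndarray,
    starts: np.ndarray,
    durs: np.ndarray,
    depths: np.ndarray,
) -> None:
    """Overlay dips in place, taking the deepest value where events overlap."""
    n = base.size
    dip = np.zeros(n)
    for s0, d, depth in zip(starts, durs, depths):
        prof = _trapezoid(int(d)) * depth
        end = min(s0 + prof.size, n)
        if end > s0:
            seg = dip[s0:end]
            np.minimum(seg, prof[: end - s0], out=seg)
    base += dip


class SyntheticCohort:
    """Lazy handle on a generated cohort.

    ``outcomes`` holds one row per infant (id, pregnancy, category, the 4
    nested flags, covariates and the ground-truth latent severity).
    Signals are regenerated deterministically per infant on demand.
    """

    def __init__(self, params: CohortParams, outcomes: pd.DataFrame):
        self.params = params
        self.outcomes = outcomes

    def infant_series(self, infant_id: str) -> tuple[VitalSeries, VitalSeries]:
        row = self.outcomes[self.outcomes["infant_id"] == infant_id]
        if not len(row):
            raise KeyError(infant_id)
        row = row.iloc[0]
        return _simulate_signals(
            self.params, int(row["_index"]), infant_id, float(row["severity"]),
            row["birth_time"],
        )

    def series_pairs(self) -> Iterator[tuple[VitalSeries, VitalSeries]]:
        for iid in self.outcomes["infant_id"]:
            yield self.infant_series(iid)

    def write(self, outdir) -> dict[str, Path]:
        """Write vitals, outcome table and ground-truth severity sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vitals": outdir / "vitals.csv",
            "outcomes": outdir / "outcomes.csv",
            "severity": outdir / "severity.csv",
        }
        import io

        with open(paths["vitals"], "w") as fh:
            header = True
            for hr, spo2 in self.series_pairs():
                buf = io.StringIO()
                write_vitals([hr, spo2], buf)
                text = buf.getvalue()
                fh.write(text if header else text.split("\n", 1)[1])
                header = False
        cols = [c for c in self.outcomes.columns if c not in ("severity", "_index")]
        self.outcomes[cols].to_csv(paths["outcomes"], index=False)
        self.outcomes[["infant_id", "severity"]].to_csv(paths["severity"], index=False)
        return paths


def generate_cohort(params: CohortParams | None = None, **overrides) -> SyntheticCohort:
    """Draw pregnancies, severities and outcomes for a cohort.

    Keyword overrides are applied to the default :class:`CohortParams`.
    Deterministic: the same params (including seed) give byte-identical
    output, file writes included.
    """
    params = replace(params or CohortParams(), **overrides)
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(2**20,)))
    rows = []
    preg = 0
    while len(rows) < params.n_infants:
        preg += 1
        twins = rng.random() < params.twin_fraction
        s1 = rng.standard_normal()
        sev = [s1]
        if twins:
            sev.append(
                params.twin_rho * s1
                + np.sqrt(1 - params.twin_rho**2) * rng.standard_normal()
            )
        for s in sev:
            if len(rows) >= params.n_infants:
                break
            u = s + params.outcome_noise_scale * rng.logistic()
            t = params.outcome_thresholds
            if u <= t[0]:
                cat = "Favorable"
            elif u <= t[1]:
                cat = "Mild"
            elif u <= t[2]:
                cat = "Moderate"
            elif u <= t[3]:
                cat = "Severe"
            else:
                cat = "Death"
            assert cat in CATEGORIES
            i = len(rows)
            rows.append(
                {
                    "infant_id": f"inf{i:04d}",
                    "_index": i,
                    "pregnancy_id": f"preg{preg:04d}",
                    "outcome_category": cat,
                    "birth_time": _BIRTH_EPOCH,
                    "severity": float(s),
                    "birthweight_g": float(
                        np.clip(870.0 - 180.0 * s + rng.normal(0, 120.0), 350.0, 1800.0)
                    ),
                    "ga_weeks": float(np.clip(26.4 - 0.8 * s + rng.normal(0, 1.0), 22.0, 28.9)),
                    "imv_flag": int(rng.random() < expit(s)),
                    "fio2": float(np.clip(0.21 + 0.25 * expit(s) + rng.normal(0, 0.05), 0.21, 1.0)),
                }
            )
    outcomes = encode_outcome_table(pd.DataFrame(rows))
    return SyntheticCohort(params, outcomes)


def _simulate_signals(
    params: CohortParams,
    index: int,
    infant_id: str,
    severity: float,
    birth_time: _dt.datetime,
) -> tuple[VitalSeries, VitalSeries]:
    rng = _infant_rng(params.seed, index)
    n = params.days * SAMPLES_PER_DAY
    sev_u = float(expit(severity))

    # --- SPO2 ---
    spo2 = np.full(n, params.spo2_baseline - params.spo2_baseline_drop * sev_u)
    # quasi-periodic component: resonant AR(2) at the target period
    omega = 2 * np.pi * 2.0 / params.osc_period_s  # radians per 2-s sample
    phi1 = 2 * params.osc_pole * np.cos(omega)
    phi2 = -params.osc_pole**2
    osc = lfilter([1.0], [1.0, -phi1, -phi2], rng.standard_normal(n))
    sd = float(np.std(osc))
    amp = params.osc_amplitude * (1.0 - params.osc_suppression * sev_u)
    if sd > 0:
        spo2 += amp * osc / sd
    # slow wander: unstable oxygenation control drifts over minutes
    wander = lfilter([1.0], [1.0, -params.wander_pole], rng.standard_normal(n))
    wsd = float(np.std(wander))
    if wsd > 0:
        spo2 += (params.wander_sd + params.wander_gain * sev_u) * wander / wsd
    spo2 += params.spo2_noise_sd * rng.standard_normal(n)

    lam = min(
        params.desat_rate_per_h
        * np.exp(params.desat_rate_slope * severity)
        * np.exp(params.desat_rate_heterogeneity * rng.standard_normal()),
        params.desat_rate_cap_per_h,
    )
    n_ev = rng.poisson(lam * 24.0 * params.days)
    if n_ev:
        starts = rng.integers(0, n, size=n_ev)
        durs = np.clip(
            np.exp(
                np.log(params.desat_dur_median_s)
                + params.desat_dur_slope * severity
                + params.desat_dur_sigma * rng.standard_normal(n_ev)
            ),
            4.0,
            400.0,
        ) / 2.0  # seconds -> samples
        depths = (params.desat_depth_base + params.desat_depth_gain * sev_u) * np.exp(
            params.desat_depth_sigma * rng.standard_normal(n_ev)
        )
        _insert_dips(spo2, starts, durs.astype(int), np.clip(depths, 2.0, 50.0))
    np.clip(np.round(spo2), 0.0, 100.0, out=spo2)

    # --- HR ---
    hr = np.full(n, params.hr_baseline + params.hr_baseline_sd * rng.standard_normal())
    innov = (
        params.hr_innov_sd
        * (1.0 - params.hr_suppression * sev_u)
        * np.exp(params.hr_innov_heterogeneity * rng.standard_normal())
    )
    hr += lfilter([1.0], [1.0, -params.hr_phi], innov * rng.standard_normal(n))
    lam_b = params.brady_rate_per_h * np.exp(params.brady_rate_slope * severity)
    n_b = rng.poisson(lam_b * 24.0 * params.days)
    if n_b:
        starts = rng.integers(0, n, size=n_b)
        durs = np.clip(
            np.exp(
                np.log(params.brady_dur_median_s)
                + params.brady_dur_sigma * rng.standard_normal(n_b)
            ),
            4.0,
            120.0,
        ) / 2.0
        depths = params.brady_depth * np.exp(0.15 * rng.standard_normal(n_b))
        _insert_dips(hr, starts, durs.astype(int), depths)
    np.clip(np.round(hr), 20.0, 300.0, out=hr)

    # --- monitoring gaps ---
    for sig in (hr, spo2):
        if params.missing_fraction > 0:
            p_start = params.missing_fraction / params.gap_mean_samples
            starts = np.nonzero(rng.random(n) < p_start)[0]
            lengths = rng.geometric(1.0 / params.gap_mean_samples, size=starts.size)
            for s0, ln in zip(starts, lengths):
                sig[s0 : s0 + ln] = np.nan

    mk = lambda kind, vals: VitalSeries(
        infant_id=infant_id,
        signal_kind=kind,
        start_time=birth_time,
        values=vals,
        birth_time=birth_time,
    )
    return mk(SignalKind.HR, hr), mk(SignalKind.SPO2, spo2)


def designed_auc_cohort(
    target_auc: float,
    n: int,
    seed: int,
    *,
    prevalence: float = 0.454,
    metric_name: str = "marker",
) -> pd.DataFrame:
    """Binormal single-metric cohort with a known population AUC.

    Controls draw the metric from N(0, 1) and cases from N(delta, 1) with
    delta = sqrt(2) * Phi^-1(target_auc), so the population AUC is exactly
    the target.  Each infant is its own pregnancy; rows carry day_of_life 7
    and the ``unfavorable`` flag, ready for the evaluation machinery.
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must lie strictly between 0.5 and 1")
    from scipy.stats import norm

    delta = np.sqrt(2.0) * norm.ppf(target_auc)
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < prevalence).astype(int)
    x = rng.standard_normal(n) + delta * y
    return pd.DataFrame(
        {
            "infant_id": [f"inf{i:05d}" for i in range(n)],
            "pregnancy_id": [f"preg{i:05d}" for i in range(n)],
            "day_of_life": 7,
            metric_name: x,
            "unfavorable": y,
        }
    )
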