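"""Outcome encoding and evaluation: AUC ranking, pregnancy-clustered CV,
spline signature-of-risk curves, the fixed 3-feature model, variable
importance, and day-of-life performance trajectories.

Respiratory outcome at 40 weeks post-menstrual age is a 5-level ordered
category (Death > Severe > Moderate > Mild > Favorable) analyzed through 4
nested binary flags: ``unfavorable`` (anything but Favorable),
``mod_sev_death``, ``sev_death`` and ``death``.  Because siblings share a
pregnancy (and much else), every cross-validated quantity here partitions
*pregnancy clusters* across folds, so an infant's twin is never used to
predict its outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

__all__ = [
    "CATEGORIES",
    "OUTCOME_FLAGS",
    "FIXED_MODEL_FEATURES",
    "AucResult",
    "RiskCurve",
    "Trajectory",
    "encode_outcomes",
    "encode_outcome_table",
    "prevalence",
    "auc",
    "cluster_folds",
    "clustered_cv",
    "spline_risk_curve",
    "fixed_model",
    "variable_importance",
    "select_features",
    "trajectory",
]

log = logging.getLogger(__name__)

#: Outcome categories in order of decreasing severity.
CATEGORIES = ("Death", "Severe", "Moderate", "Mild", "Favorable")
#: Nested binary flags in order of decreasing prevalence / increasing severity.
OUTCOME_FLAGS = ("unfavorable", "mod_sev_death", "sev_death", "death")
#: The fixed 3-feature model: walker + SPO2 mean + HR difference-symbol entropy.
FIXED_MODEL_FEATURES = ("sp_walk", "sp_mean", "hr_entropy_diff")

DEFAULT_FOLDS = 10
DEFAULT_SEED = 20240603
SELECTION_DELTA = 0.005


@dataclass(frozen=True)
class AucResult:
    metric: str
    outcome: str
    auc: float  # oriented, >= 0.5
    orientation: int  # +1: larger value = higher risk; -1: inverted
    n: int
    day_of_life: int | None = None
    rank: int | None = None


@dataclass
class RiskCurve:
    metric: str
    outcome: str
    grid: np.ndarray
    probability: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    event_rate: float
    significant: np.ndarray  # CI excludes the event rate
    central95: tuple[float, float]


@dataclass
class Trajectory:
    name: str
    outcome: str
    days: np.ndarray
    auc: np.ndarray  # per-day, NaN where undefined
    smoothed: np.ndarray  # ±2-day mean over defined days


# ---------------------------------------------------------------------------
# Outcome encoding and prevalence


def encode_outcomes(category: str) -> dict[str, int]:
    """Nested binary flags for one outcome category.

    death => sev_death => mod_sev_death => unfavorable; Favorable is all 0.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown outcome category: {category!r}")
    sev = CATEGORIES.index(category)  # 0 = Death ... 4 = Favorable
    return {
        "unfavorable": int(sev <= 3),
        "mod_sev_death": int(sev <= 2),
        "sev_death": int(sev <= 1),
        "death": int(sev == 0),
    }


def encode_outcome_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Add the 4 nested flag columns to an outcome table."""
    flags = pd.DataFrame(
        [encode_outcomes(c) for c in outcomes["outcome_category"]],
        index=outcomes.index,
    )
    return pd.concat([outcomes, flags], axis=1)


def prevalence(cohort: pd.DataFrame) -> pd.DataFrame:
    """Count and percent per nested flag over a (restricted) cohort.

    ``cohort`` must carry one row per infant with the flag columns; restrict
    to infants with a valid day-of-interest before calling.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    n = len(cohort)
    for flag in OUTCOME_FLAGS:
        k = int(cohort[flag].sum())
        rows.append({"outcome": flag, "count": k, "n": n, "percent": 100.0 * k / n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AUC


def auc(
    values: np.ndarray,
    labels: np.ndarray,
    *,
    metric: str = "",
    outcome: str = "",
    day_of_life: int | None = None,
    oriented: bool = True,
) -> AucResult:
    """Rank-based AUC (probability a random case outranks a random control).

    Mid-rank tie handling; missing values excluded pairwise.  When
    ``oriented``, the result is folded to >= 0.5 and the orientation sign
    (+1 if larger values indicate risk) recorded.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask = np.isfinite(values) & pd.notna(labels)
    values, labels = values[mask], labels[mask].astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        return AucResult(metric, outcome, float("nan"), 1, n1 + n0, day_of_life)
    r = rankdata(values)
    a = (r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    orientation = 1
    if oriented and a < 0.5:
        a, orientation = 1.0 - a, -1
    return AucResult(metric, outcome, float(a), orientation, n1 + n0, day_of_life)


def rank_metrics(
    table: pd.DataFrame,
    metrics: Sequence[str],
    outcome: str,
    *,
    day_of_life: int | None = None,
) -> list[AucResult]:
    """Oriented AUC for each metric, sorted and ranked (1 = best)."""
    sub = table if day_of_life is None else table[table["day_of_life"] == day_of_life]
    results = [
        auc(
            sub[m].to_numpy(),
            sub[outcome].to_numpy(),
            metric=m,
            outcome=outcome,
            day_of_life=day_of_life,
        )
        for m in metrics
    ]
    results.sort(key=lambda r: (-(r.auc if np.isfinite(r.auc) else -1.0), r.metric))
    return [
        AucResult(r.metric, r.outcome, r.auc, r.orientation, r.n, r.day_of_life, i + 1)
        for i, r in enumerate(results)
    ]


# ---------------------------------------------------------------------------
# Pregnancy-clustered cross-validation


def cluster_folds(
    pregnancy_ids: Sequence, n_folds: int, seed: int
) -> dict[object, int]:
    """Partition pregnancy clusters into folds balanced by infant count.

    Clusters are shuffled deterministically, then greedily assigned (largest
    first) to the currently smallest fold, so twins always land together and
    fold sizes stay within one cluster of each other.
    """
    ids = pd.Series(list(pregnancy_ids))
    sizes = ids.value_counts()
    if n_folds > len(sizes):
        raise ValueError(f"{n_folds} folds requested but only {len(sizes)} clusters")
    rng = np.random.default_rng(seed)
    clusters = list(sizes.index)
    rng.shuffle(clusters)
    clusters.sort(key=lambda c: -sizes[c])  # stable: keeps shuffle order within ties
    load = np.zeros(n_folds)
    assignment: dict[object, int] = {}
    for c in clusters:
        f = int(np.argmin(load))
        assignment[c] = f
        load[f] += sizes[c]
    return assignment


def _model_matrix(
    frame: pd.DataFrame, metrics: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix with missing-dpe imputation; mask of complete rows.

    dpe is undefined on days with no events; those cells are imputed at the
    minimum observed dpe (an event-free day behaves like very short events,
    i.e. low risk).  Rows still incomplete after imputation are dropped.
    """
    X = frame[list(metrics)].to_numpy(dtype=float).copy()
    for j, m in enumerate(metrics):
        if m.endswith("_dpe"):
            col = X[:, j]
            if np.isnan(col).any() and np.isfinite(col).any():
                col[np.isnan(col)] = np.nanmin(col)
    mask = np.isfinite(X).all(axis=1)
    return X, mask


def clustered_cv(
    table: pd.DataFrame,
    metrics: Sequence[str],
    outcome: str,
    *,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = DEFAULT_SEED,
    return_predictions: bool = False,
):
    """Cross-validated AUC of a logistic model, folds clustered by pregnancy.

    Out-of-fold predicted probabilities are pooled into a single AUC.
    ``table`` needs one row per infant(-day) with the metric columns, the
    binary ``outcome`` column and ``pregnancy_id``.  Deterministic given
    ``seed``.
    """
    X_all, mask = _model_matrix(table, metrics)
    y_all = table[outcome].to_numpy(dtype=float)
    preg = table["pregnancy_id"].to_numpy()
    mask &= np.isfinite(y_all)
    X_all, y_all, preg = X_all[mask], y_all[mask].astype(int), preg[mask]
    if len(np.unique(y_all)) < 2:
        raise ValueError("both outcome classes must be present")
    assignment = cluster_folds(preg, n_folds, seed)
    fold = np.array([assignment[c] for c in preg])
    # invariant, asserted every run: a pregnancy never straddles folds
    assert (pd.Series(fold).groupby(pd.Series(preg)).nunique() == 1).all()
    score = np.full(y_all.size, np.nan)
    for f in np.unique(fold):
        tr, te = fold != f, fold == f
        if len(np.unique(y_all[tr])) < 2:
            continue
        mu = X_all[tr].mean(axis=0)
        sd = X_all[tr].std(axis=0)
        sd[sd == 0] = 1.0
        model = LogisticRegression(C=np.inf, max_iter=2000)
        model.fit((X_all[tr] - mu) / sd, y_all[tr])
        eta = model.decision_function((X_all[te] - mu) / sd)
        # center per fold before pooling: fold intercepts track training-split
        # prevalence and would otherwise bias the pooled ranking
        score[te] = eta - eta.mean()
    ok = np.isfinite(score)
    result = auc(score[ok], y_all[ok], metric="+".join(metrics), outcome=outcome,
                 oriented=False)
    if return_predictions:
        return result, expit(score), y_all, fold
    return result


def fixed_model(
    table: pd.DataFrame,
    outcome: str = "unfavorable",
    *,
    day_of_life: int | None = None,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = DEFAULT_SEED,
) -> AucResult:
    """Clustered-CV AUC of the fixed 3-feature logistic model (linear terms)."""
    sub = table if day_of_life is None else table[table["day_of_life"] == day_of_life]
    r = clustered_cv(sub, FIXED_MODEL_FEATURES, outcome, n_folds=n_folds, seed=seed)
    return AucResult(r.metric, r.outcome, r.auc, r.orientation, r.n, day_of_life)


def variable_importance(
    table: pd.DataFrame,
    metrics: Sequence[str],
    metric: str,
    outcome: str,
    *,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = DEFAULT_SEED,
) -> float:
    """Drop in cross-validated AUC when ``metric`` is removed from the model.

    Both models use the same seed, hence the same pregnancy partition.
    """
    if metric not in metrics:
        raise ValueError(f"{metric!r} is not in the model")
    full = clustered_cv(table, metrics, outcome, n_folds=n_folds, seed=seed)
    reduced_metrics = [m for m in metrics if m != metric]
    if not reduced_metrics:
        return full.auc - 0.5
    reduced = clustered_cv(table, reduced_metrics, outcome, n_folds=n_folds, seed=seed)
    return full.auc - reduced.auc


def select_features(
    table: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str,
    *,
    delta: float = SELECTION_DELTA,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = DEFAULT_SEED,
    max_features: int | None = None,
) -> list[str]:
    """Greedy forward-backward search on cross-validated AUC.

    Forward: add the candidate with the largest CV-AUC gain while some gain
    is >= ``delta``.  Backward: drop any selected feature whose removal
    costs <= ``delta``.  The stopping state mirrors a model where removing
    any feature loses more than delta and adding any candidate gains less
    than delta.  Ties break alphabetically; deterministic given seed.
    """
    if not len(candidates):
        raise ValueError("no candidate metrics")
    candidates = sorted(candidates)
    selected: list[str] = []
    current = 0.5

    def score(feats: Sequence[str]) -> float:
        try:
            return clustered_cv(table, feats, outcome, n_folds=n_folds, seed=seed).auc
        except ValueError:
            return float("nan")

    for _ in range(len(candidates)):
        gains = []
        for c in candidates:
            if c in selected:
                continue
            s = score(selected + [c])
            if np.isfinite(s):
                gains.append((s - current, c))
        if not gains:
            break
        gains.sort(key=lambda g: (-g[0], g[1]))
        best_gain, best = gains[0]
        if best_gain < delta:
            break
        selected.append(best)
        current = score(selected)
        # backward pass
        changed = True
        while changed and len(selected) > 1:
            changed = False
            drops = []
            for m in sorted(selected):
                s = score([x for x in selected if x != m])
                if np.isfinite(s):
                    drops.append((current - s, m))
            drops.sort(key=lambda d: (d[0], d[1]))
            if drops and drops[0][0] <= delta:
                selected.remove(drops[0][1])
                current = score(selected)
                changed = True
        if max_features and len(selected) >= max_features:
            break
    return selected


# ---------------------------------------------------------------------------
# Signature-of-risk curves


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear in the tails).

    With k knots the basis has k-1 columns: x itself plus k-2 nonlinear
    terms, each normalized by the squared outer-knot span.
    """
    t = np.asarray(knots, dtype=float)
    k = t.size
    norm = (t[-1] - t[0]) ** 2

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def spline_risk_curve(
    table: pd.DataFrame,
    metric: str,
    outcome: str,
    *,
    grid_size: int = 100,
    alpha: float = 0.05,
) -> RiskCurve:
    """Signature of risk: P(outcome) vs daily metric value.

    Logistic regression on a restricted cubic spline of the metric with 3
    knots at the 10th/50th/90th percentiles; pointwise Wald CIs on the
    linear predictor mapped through the inverse logit; grid spans the
    central 99% of the metric.  Spans where the CI excludes the cohort
    event rate are flagged.
    """
    x = table[metric].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask].astype(int)
    if x.size < 50:
        raise ValueError("need at least 50 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    knots = np.percentile(x, [10.0, 50.0, 90.0])
    if np.unique(knots).size < 3:
        raise ValueError(f"{metric} is degenerate (tied knots)")
    X = sm.add_constant(_rcs_basis(x, knots))
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    grid = np.linspace(*np.percentile(x, [0.5, 99.5]), grid_size)
    Xg = sm.add_constant(_rcs_basis(grid, knots), has_constant="add")
    eta = Xg @ fit.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, fit.cov_params(), Xg))
    from scipy.stats import norm as _norm

    z = _norm.ppf(1 - alpha / 2)
    lo, hi = expit(eta - z * se), expit(eta + z * se)
    rate = float(np.mean(y))
    return RiskCurve(
        metric=metric,
        outcome=outcome,
        grid=grid,
        probability=expit(eta),
        ci_low=lo,
        ci_high=hi,
        event_rate=rate,
        significant=(lo > rate) | (hi < rate),
        central95=tuple(np.percentile(x, [2.5, 97.5])),
    )


# ---------------------------------------------------------------------------
# Trajectories


def trajectory(
    table: pd.DataFrame,
    metric_or_model: str | Sequence[str],
    outcome: str,
    *,
    days: Sequence[int] = range(1, 57),
    smooth_halfwidth: int = 2,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = DEFAULT_SEED,
) -> Trajectory:
    """Per-day AUC over the first 8 weeks, smoothed by a ±2-day mean.

    A single metric name gives the oriented rank AUC per day; a sequence of
    names gives the clustered-CV AUC of the logistic model per day.  Days
    where a class is absent (or the fit fails) are gaps; smoothing averages
    only the defined days in the window.
    """
    days = np.asarray(list(days), dtype=int)
    per_day = np.full(days.size, np.nan)
    is_model = not isinstance(metric_or_model, str)
    for i, d in enumerate(days):
        sub = table[table["day_of_life"] == d]
        if len(sub) == 0:
            continue
        if is_model:
            try:
                per_day[i] = clustered_cv(
                    sub, list(metric_or_model), outcome, n_folds=n_folds, seed=seed
                ).auc
            except ValueError:
                continue
        else:
            per_day[i] = auc(sub[metric_or_model].to_numpy(), sub[outcome].to_numpy()).auc
    smoothed = np.full(days.size, np.nan)
    for i, d in enumerate(days):
        win = per_day[(days >= d - smooth_halfwidth) & (days <= d + smooth_halfwidth)]
        win = win[np.isfinite(win)]
        if win.size:
            smoothed[i] = float(np.mean(win))
    name = "+".join(metric_or_model) if is_model else metric_or_model
    return Trajectory(name=name, outcome=outcome, days=days, auc=per_day, smoothed=smoothed)
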