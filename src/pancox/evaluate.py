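"""Model evaluation on left-truncated, right-censored survival data.

Implements the three headline metrics — concordance index, integrated
Brier score (IPCW-weighted), and the median-split low-vs-high hazard
ratio — plus bias-corrected bootstrap percentile confidence intervals.

All risk sets respect delayed entry: a subject is at risk at time t only
when entry < t <= exit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._exceptions import DataError, FitError


def _validate_response(entry, exit_, status):
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    status = np.asarray(status, dtype=int)
    if not (len(entry) == len(exit_) == len(status)):
        raise DataError("entry/exit/status lengths differ")
    if np.any(entry >= exit_):
        raise DataError("entry must be strictly less than exit for every subject")
    if not np.all(np.isin(status, (0, 1))):
        raise DataError("status must be 0 or 1")
    return entry, exit_, status


# ----------------------------------------------------------------------
# concordance


def concordance_index(entry, exit_, status, scores) -> tuple[float, int]:
    """Truncation-aware Harrell concordance.

    A pair (i, j) is comparable iff subject i has an event and subject j
    is at risk when i dies: entry_j < exit_i < exit_j.  Concordant when
    score_i > score_j (higher score, earlier death); score ties count
    half.  Returns (c, number of comparable pairs).
    """
    entry, exit_, status = _validate_response(entry, exit_, status)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise DataError("scores must be finite")

    conc = 0.0
    ncomp = 0
    event_idx = np.flatnonzero(status == 1)
    for i in event_idx:
        t = exit_[i]
        at_risk = (entry < t) & (t < exit_)
        at_risk[i] = False
        n_i = int(at_risk.sum())
        if n_i == 0:
            continue
        ncomp += n_i
        sj = scores[at_risk]
        conc += float(np.sum(scores[i] > sj)) + 0.5 * float(np.sum(scores[i] == sj))
    if ncomp == 0:
        raise FitError("concordance_index: no comparable pairs")
    return conc / ncomp, ncomp


# ----------------------------------------------------------------------
# Kaplan-Meier with delayed entry


def kaplan_meier(entry, exit_, status) -> pd.DataFrame:
    """Left-truncation-adjusted Kaplan-Meier estimate.

    Returns a step function as a DataFrame with columns
    ``time``, ``n_risk``, ``n_event``, ``survival``; survival is the
    value for t >= time (right-continuous), with S = 1 before the first
    event.
    """
    entry, exit_, status = _validate_response(entry, exit_, status)
    times = np.unique(exit_[status == 1])
    if times.size == 0:
        return pd.DataFrame({"time": [], "n_risk": [], "n_event": [], "survival": []})
    # at risk at t: entry < t <= exit
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    n = len(exit_)
    n_ge_exit = n - np.searchsorted(exit_sorted, times, side="left")
    n_ge_entry = n - np.searchsorted(entry_sorted, times, side="left")
    n_risk = n_ge_exit - n_ge_entry
    d = np.zeros_like(times)
    ev_times = exit_[status == 1]
    for k, t in enumerate(times):
        d[k] = np.sum(ev_times == t)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_risk > 0, 1.0 - d / n_risk, 1.0)
    surv = np.cumprod(frac)
    return pd.DataFrame({"time": times, "n_risk": n_risk.astype(int),
                         "n_event": d.astype(int), "survival": surv})


def km_eval(km: pd.DataFrame, t, left_limit: bool = False) -> np.ndarray:
    """Evaluate a KM step function at times t (S(t), or S(t-) if left_limit)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if len(km) == 0:
        return np.ones_like(t)
    side = "left" if left_limit else "right"
    idx = np.searchsorted(km["time"].to_numpy(), t, side=side) - 1
    out = np.ones_like(t)
    pos = idx >= 0
    out[pos] = km["survival"].to_numpy()[idx[pos]]
    return out


# ----------------------------------------------------------------------
# integrated Brier score


def integrated_brier_score(y_train: pd.DataFrame, y_test: pd.DataFrame,
                           predicted_survival: np.ndarray,
                           time_grid: np.ndarray,
                           max_weight: float = 20.0) -> float:
    """IPCW integrated Brier score.

    ``predicted_survival`` is (n_test, len(time_grid)).  The censoring
    distribution is a left-truncation-adjusted KM of 1-status fitted on
    the training response.  BS(t) is averaged by the trapezoid rule over
    the part of the grid within [first test event time, 95th percentile
    of test exit times].  Weights are capped at ``max_weight``.
    """
    tr_entry, tr_exit, tr_status = _validate_response(
        y_train["entry"], y_train["exit"], y_train["status"])
    te_entry, te_exit, te_status = _validate_response(
        y_test["entry"], y_test["exit"], y_test["status"])
    S = np.asarray(predicted_survival, dtype=float)
    grid = np.asarray(time_grid, dtype=float)
    if S.shape != (len(te_exit), len(grid)):
        raise DataError("predicted_survival must be (n_test, len(time_grid))")
    if np.any(np.diff(grid) <= 0):
        raise DataError("time_grid must be strictly increasing")

    if te_status.sum() == 0:
        raise FitError("integrated_brier_score: no events in the test set")
    t_lo = float(te_exit[te_status == 1].min())
    t_hi = float(np.quantile(te_exit, 0.95))
    keep = (grid >= t_lo) & (grid <= t_hi)
    if keep.sum() < 2:
        raise DataError("time_grid has fewer than 2 points inside the IBS horizon")
    grid_u = grid[keep]
    S_u = S[:, keep]

    cens_km = kaplan_meier(tr_entry, tr_exit, 1 - tr_status)
    g_exit = np.clip(km_eval(cens_km, te_exit, left_limit=True),
                     1.0 / max_weight, None)
    g_grid = np.clip(km_eval(cens_km, grid_u), 1.0 / max_weight, None)

    n = len(te_exit)
    bs = np.empty(len(grid_u))
    for k, t in enumerate(grid_u):
        died = (te_exit <= t) & (te_status == 1)
        alive = te_exit > t
        term_died = (S_u[died, k] ** 2) / g_exit[died]
        term_alive = ((1.0 - S_u[alive, k]) ** 2) / g_grid[k]
        bs[k] = (term_died.sum() + term_alive.sum()) / n
    return float(np.trapezoid(bs, grid_u) / (grid_u[-1] - grid_u[0]))


def km_null_survival(y_train: pd.DataFrame, time_grid: np.ndarray,
                     n_test: int) -> np.ndarray:
    """Kaplan-Meier 'null model' predictions: same curve for every subject."""
    km = kaplan_meier(np.asarray(y_train["entry"], dtype=float),
                      np.asarray(y_train["exit"], dtype=float),
                      np.asarray(y_train["status"], dtype=int))
    s = km_eval(km, np.asarray(time_grid, dtype=float))
    return np.tile(s, (n_test, 1))


# ----------------------------------------------------------------------
# median-split risk stratification


@dataclass
class RiskStratification:
    groups: pd.Series                 # 'low' / 'high' per test subject
    hr_low_vs_high: float             # hazard(low)/hazard(high); nan if undefined
    ci: tuple[float, float]
    defined: bool
    km_curves: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)


def risk_stratify_and_hr(train_scores, test_scores, y_test: pd.DataFrame,
                         train_cohorts=None, test_cohorts=None) -> RiskStratification:
    """Median-split test subjects using per-cohort training medians.

    The HR is from a one-covariate unpenalized Cox fit (delayed entry) of
    the low-risk indicator, so values < 1 mean the low-risk group does
    better — matching the low-vs-high reporting convention.
    """
    from statsmodels.duration.hazard_regression import PHReg

    train_scores = np.asarray(train_scores, dtype=float)
    test_scores = np.asarray(test_scores, dtype=float)
    n_test = len(test_scores)
    if train_cohorts is None:
        train_cohorts = np.array(["all"] * len(train_scores))
    if test_cohorts is None:
        test_cohorts = np.array(["all"] * n_test)
    train_cohorts = np.asarray(train_cohorts)
    test_cohorts = np.asarray(test_cohorts)

    thresholds = {}
    for c in np.unique(test_cohorts):
        mask = train_cohorts == c
        if not mask.any():
            raise DataError(f"no training scores for cohort {c!r}")
        thresholds[c] = float(np.median(train_scores[mask]))
    thr = np.array([thresholds[c] for c in test_cohorts])
    low = test_scores <= thr
    groups = pd.Series(np.where(low, "low", "high"), index=np.arange(n_test))

    entry, exit_, status = _validate_response(
        y_test["entry"], y_test["exit"], y_test["status"])

    km_curves = {}
    for g in ("low", "high"):
        mask = groups.to_numpy() == g
        if mask.any():
            km_curves[g] = kaplan_meier(entry[mask], exit_[mask], status[mask])

    defined = bool(low.any() and (~low).any()
                   and status[low].sum() > 0 and status[~low].sum() > 0)
    if not defined:
        return RiskStratification(groups, float("nan"), (float("nan"), float("nan")),
                                  False, km_curves, thresholds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg(exit_, low.astype(float)[:, None], status=status, entry=entry,
                      ties="breslow")
        res = model.fit(disp=False)
    beta = float(res.params[0])
    se = float(res.bse[0])
    z = norm.ppf(0.975)
    # clip Wald bounds before exponentiating: a near-degenerate fit can have a
    # huge SE and the CI endpoint is then effectively 0 or +inf
    lo, hi = np.clip([beta - z * se, beta + z * se], -700.0, 700.0)
    return RiskStratification(groups, float(np.exp(beta)),
                              (float(np.exp(lo)), float(np.exp(hi))),
                              True, km_curves, thresholds)


# ----------------------------------------------------------------------
# bias-corrected bootstrap


def _take(data, idx):
    if data is None:
        return None
    if isinstance(data, (pd.DataFrame, pd.Series)):
        return data.iloc[idx]
    return np.asarray(data)[idx]


def _strat_resample(n: int, strata, rng: np.random.Generator) -> np.ndarray:
    if strata is None:
        return rng.integers(0, n, size=n)
    strata = np.asarray(strata)
    out = np.empty(n, dtype=int)
    pos = 0
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        take = idx[rng.integers(0, len(idx), size=len(idx))]
        out[pos:pos + len(idx)] = take
        pos += len(idx)
    return out


def bc_bootstrap_ci(statistic_fn, train_data, test_data, B: int, seed: int,
                    alpha: float = 0.05, train_strata=None, test_strata=None
                    ) -> tuple[float, float, float]:
    """Bias-corrected (BC, acceleration = 0) bootstrap percentile interval.

    Each replicate resamples train rows and test rows with replacement
    (stratified when strata labels are given) and recomputes
    ``statistic_fn(train, test)``.  Returns (point, lower, upper).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    theta = float(statistic_fn(train_data, test_data))
    n_train = 0 if train_data is None else len(train_data)
    n_test = len(test_data)
    boot = np.empty(B)
    for b in range(B):
        tr = None
        if train_data is not None:
            tr = _take(train_data, _strat_resample(n_train, train_strata, rng))
        te = _take(test_data, _strat_resample(n_test, test_strata, rng))
        try:
            boot[b] = statistic_fn(tr, te)
        except (FitError, DataError):
            boot[b] = np.nan
    boot = boot[np.isfinite(boot)]
    if len(boot) < B // 2:
        raise FitError("bc_bootstrap_ci: too many degenerate bootstrap replicates")
    if np.all(boot == boot[0]):
        warnings.warn("degenerate bootstrap distribution; interval collapses to the point")
        return theta, theta, theta
    prop = np.clip(np.mean(boot < theta), 1.0 / (len(boot) + 1),
                   1.0 - 1.0 / (len(boot) + 1))
    z0 = norm.ppf(prop)
    zq = norm.ppf(1.0 - alpha / 2.0)
    lo_q = norm.cdf(2 * z0 - zq)
    hi_q = norm.cdf(2 * z0 + zq)
    lower, upper = np.quantile(boot, [lo_q, hi_q])
    return theta, float(lower), float(upper)
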