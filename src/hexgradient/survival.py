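"""Patient-level survival statistics.

Implements the downstream analysis stack for the computed spatial
indicators: optimal-cutpoint dichotomization (minimum log-rank p scan),
Kaplan-Meier estimation, log-rank tests, Cox proportional-hazards models
(univariate and multivariate with leave-one-out subset selection), and the
combined CD8 Immunogradient prognostic score.

Cutpoint-selected p-values are NOT corrected for the scan over candidate
cutoffs; they are labeled selection-biased and should be read as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats as sps

from hexgradient.errors import EmptyInputError, ParameterError, UndefinedIndicatorError

#: default score components and the direction that earns a point (good prognosis)
SCORE_DIRECTIONS = {"CD8_CM": "high", "CD8_d_T": "high", "CD8_d_TE_sd": "low"}


@dataclass
class KMEstimate:
    """Product-limit survival estimate with step lookup."""

    times: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t) from the right-continuous step function."""
        pos = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[pos]) if pos >= 0 else 1.0


@dataclass
class CutpointResult:
    """Optimal cutpoint from the minimum-p log-rank scan."""

    cutoff: float
    direction: str  # 'high' or 'low': which side is good prognosis
    statistic: float
    p_value: float  # uncorrected, cutpoint-selected
    n_low: int
    n_high: int


@dataclass
class ScoreResult:
    """Combined prognostic score: per-patient components, totals, and
    per-stratum Kaplan-Meier summaries."""

    scores: pd.DataFrame = field(repr=False)
    survival_at_60: dict[int, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator with right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise EmptyInputError("no observations for Kaplan-Meier estimate")
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square statistic, p)."""
    if len(groups) < 2:
        raise ParameterError("log-rank test needs at least 2 groups")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=int) for _, e in groups])
    labels = np.concatenate(
        [np.full(len(t), i) for i, (t, _) in enumerate(groups)]
    )
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def _logrank_2sample(times: np.ndarray, events: np.ndarray, in_high: np.ndarray) -> tuple[float, float]:
    """Two-sample log-rank statistic, vectorized (used by the cutpoint scan).

    Equivalent to the standard observed-minus-expected form with the
    hypergeometric variance at each distinct event time.
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    g = in_high[order].astype(float)
    n = len(t)
    # at-risk counts just before each row's time
    at_risk_total = n - np.arange(n)
    at_risk_high = g[::-1].cumsum()[::-1]
    # collapse to distinct event times
    ev = e == 1
    if not ev.any():
        return 0.0, 1.0
    uniq_t = np.unique(t[ev])
    idx0 = np.searchsorted(t, uniq_t, side="left")
    d_total = np.add.reduceat(e, idx0)
    d_high = np.add.reduceat(e * g, idx0)
    n_total = at_risk_total[idx0]
    n_high = at_risk_high[idx0]
    frac = n_high / n_total
    expected = d_total * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(
            n_total > 1,
            d_total * frac * (1 - frac) * (n_total - d_total) / (n_total - 1),
            0.0,
        )
    O_minus_E = float((d_high - expected).sum())
    V = float(var.sum())
    if V <= 0:
        return 0.0, 1.0
    stat = O_minus_E**2 / V
    return stat, float(sps.chi2.sf(stat, df=1))


def find_cutoff(
    values, times, events, min_group_frac: float = 0.10
) -> CutpointResult:
    """Optimal cutpoint by minimum log-rank p over all valid candidates.

    Candidates are midpoints of consecutive sorted unique values for which
    both resulting groups hold at least ``min_group_frac`` of the cohort.
    The winning p-value is selection-biased (no correction for the scan).
    The good-prognosis direction is the group with the higher Kaplan-Meier
    survival at the median follow-up.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ok = np.isfinite(values)
    values, times, events = values[ok], times[ok], events[ok]
    n = len(values)
    if n < 20:
        raise ParameterError("cutpoint scan needs >= 20 patients with values")
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise UndefinedIndicatorError("all values identical: no candidate cutoff")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    floor = int(np.ceil(min_group_frac * n))
    best = None
    for c in candidates:
        high = values > c
        n_high = int(high.sum())
        if n_high < floor or n - n_high < floor:
            continue
        stat, p = _logrank_2sample(times, events, high)
        if best is None or p < best[1]:
            best = (stat, p, float(c), n_high)
    if best is None:
        raise UndefinedIndicatorError("no candidate cutoff satisfies the group-size floor")
    stat, p, cutoff, n_high = best
    high = values > cutoff
    t_med = float(np.median(times))
    s_high = km_estimate(times[high], events[high]).survival_at(t_med)
    s_low = km_estimate(times[~high], events[~high]).survival_at(t_med)
    direction = "high" if s_high >= s_low else "low"
    return CutpointResult(
        cutoff=cutoff, direction=direction, statistic=stat, p_value=p,
        n_low=n - n_high, n_high=n_high,
    )


def cox_fit(
    frame: pd.DataFrame,
    covariates: list[str],
    time_col: str = "followup_months",
    event_col: str = "death",
    ties: str = "efron",
) -> dict:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Returns per-covariate hazard ratios with 95% Wald CIs and p-values plus
    the model likelihood-ratio statistic.  Non-convergence or separation is
    reported via the 'flags' entry rather than raised.
    """
    if ties != "efron":
        raise ParameterError("only Efron tie handling is implemented")
    data = frame[[time_col, event_col, *covariates]].dropna()
    cph = CoxPHFitter()
    flags: list[str] = []
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # convergence / separation diagnostics
        return {"covariates": None, "lr_statistic": np.nan, "lr_p": np.nan,
                "flags": [f"fit failed: {exc}"], "n": len(data)}
    summ = cph.summary
    table = pd.DataFrame(
        {
            "HR": np.exp(summ["coef"]),
            "CI_low": np.exp(summ["coef lower 95%"]),
            "CI_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    lr = float(cph.log_likelihood_ratio_test().test_statistic)
    lr_p = float(cph.log_likelihood_ratio_test().p_value)
    return {
        "covariates": table,
        "lr_statistic": lr,
        "lr_p": lr_p,
        "flags": flags,
        "n": len(data),
        "model": cph,
    }


def _cox_newton(
    X: np.ndarray, times: np.ndarray, events: np.ndarray,
    max_iter: int = 25, tol: float = 1e-9,
) -> np.ndarray:
    """Minimal Newton-Raphson Cox solver (Breslow ties) for the inner
    leave-one-out loop, where refitting with a full-featured fitter would
    dominate runtime."""
    order = np.argsort(-times, kind="stable")  # descending: risk sets by cumsum
    X = X[order]
    ev = events[order].astype(bool)
    t = times[order]
    n, p = X.shape
    # Breslow: all events at the same time share the risk set of that time
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        eta -= eta.max()
        w = np.exp(eta)
        S0 = np.cumsum(w)
        S1 = np.cumsum(w[:, None] * X, axis=0)
        S2 = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
        # index of last row sharing each row's time (largest risk set for ties)
        last = np.searchsorted(-t, -t, side="right") - 1
        S0e, S1e, S2e = S0[last][ev], S1[last][ev], S2[last][ev]
        S0e = np.maximum(S0e, 1e-300)
        xb = S1e / S0e[:, None]
        grad = (X[ev] - xb).sum(axis=0)
        hess = (S2e / S0e[:, None, None] - xb[:, :, None] * xb[:, None, :]).sum(axis=0)
        hess += 1e-9 * np.eye(p)  # ridge guards singular information
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        if not np.isfinite(step).all():
            break
        # step clipping keeps separation (divergent MLE) from overflowing
        biggest = np.abs(step).max()
        if biggest > 5.0:
            step *= 5.0 / biggest
        beta = beta + step
        if np.abs(beta).max() > 30.0:
            break
        if biggest < tol:
            break
    return beta


def loo_cox_concordance(
    frame: pd.DataFrame,
    covariates: list[str],
    time_col: str = "followup_months",
    event_col: str = "death",
) -> float:
    """Leave-one-out cross-validated concordance of a Cox model.

    Each patient's risk score is predicted from a model fitted without them;
    the concordance index is computed on the pooled out-of-fold scores.
    """
    data = frame[[time_col, event_col, *covariates]].dropna()
    X = data[covariates].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    t = data[time_col].to_numpy(dtype=float)
    e = data[event_col].to_numpy(dtype=int)
    n = len(t)
    risk = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        beta = _cox_newton(X[keep], t[keep], e[keep])
        risk[i] = X[i] @ beta if np.isfinite(beta).all() else 0.0
        keep[i] = True
    risk = np.nan_to_num(risk)
    return float(concordance_index(t, -risk, e))


def loo_subset_select(
    frame: pd.DataFrame,
    candidates: list[str],
    time_col: str = "followup_months",
    event_col: str = "death",
    k_max: int = 5,
) -> dict:
    """Best covariate subset by leave-one-out cross-validated concordance.

    Subsets up to size ``k_max`` are enumerated exhaustively when there are
    at most 15 candidates; otherwise a greedy forward search is used.  The
    winning subset is refitted with :func:`cox_fit` as the final model.
    """
    if not candidates:
        return {"subset": [], "concordance": np.nan, "model": None,
                "notice": "no candidate covariates"}
    best_subset: tuple[str, ...] | None = None
    best_score = -np.inf
    if len(candidates) <= 15:
        for k in range(1, min(k_max, len(candidates)) + 1):
            for subset in combinations(candidates, k):
                score = loo_cox_concordance(frame, list(subset), time_col, event_col)
                if score > best_score:
                    best_score, best_subset = score, subset
    else:
        chosen: list[str] = []
        while len(chosen) < k_max:
            step_best = None
            for c in candidates:
                if c in chosen:
                    continue
                score = loo_cox_concordance(frame, chosen + [c], time_col, event_col)
                if step_best is None or score > step_best[0]:
                    step_best = (score, c)
            if step_best is None or step_best[0] <= best_score:
                break
            best_score = step_best[0]
            chosen.append(step_best[1])
            best_subset = tuple(chosen)
    assert best_subset is not None
    model = cox_fit(frame, list(best_subset), time_col, event_col)
    return {"subset": list(best_subset), "concordance": best_score, "model": model}


def immunogradient_score(
    frame: pd.DataFrame,
    cutpoints: dict[str, float],
    directions: dict[str, str] | None = None,
    time_col: str = "followup_months",
    event_col: str = "death",
    horizon_months: float = 60.0,
) -> ScoreResult:
    """Combined CD8 Immunogradient prognostic score.

    Each patient scores 0/1 per component (1 = good prognosis: above the
    cutpoint for a 'high' component, at-or-below for a 'low' component);
    the total is the sum over CD8_CM, CD8_d_T and CD8_d_TE_sd.  Per-stratum
    Kaplan-Meier survival at ``horizon_months`` (5 years by default) is
    reported.  Patients missing any component are excluded with notice.
    """
    directions = dict(SCORE_DIRECTIONS if directions is None else directions)
    components = list(cutpoints)
    missing = frame[components].isna().any(axis=1)
    excluded = (
        frame.loc[missing, "patient_id"].astype(str).tolist()
        if "patient_id" in frame.columns
        else [str(i) for i in frame.index[missing]]
    )
    sub = frame.loc[~missing].copy()
    total = np.zeros(len(sub), dtype=int)
    for name in components:
        v = sub[name].to_numpy(dtype=float)
        good = v > cutpoints[name] if directions[name] == "high" else v <= cutpoints[name]
        sub[f"score_{name}"] = good.astype(int)
        total += good.astype(int)
    sub["score_total"] = total
    surv60: dict[int, float] = {}
    for s in sorted(sub["score_total"].unique()):
        grp = sub[sub["score_total"] == s]
        km = km_estimate(grp[time_col], grp[event_col])
        surv60[int(s)] = km.survival_at(horizon_months)
    return ScoreResult(scores=sub, survival_at_60=surv60, excluded=excluded)
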