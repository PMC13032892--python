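"""Survival model evaluation: concordance, IPCW metrics, KM, log-rank.

Conventions, fixed across the module:

* Harrell's C counts a pair comparable when the earlier time belongs to an
  event; pairs tied on survival time where both are events score 0.5; an
  event tied in time with a censored subject treats the censored subject
  as surviving longer; tied predicted risks also score 0.5.
* Uno's C reweights event-anchored pairs by ``G(t_i)^-2`` where ``G`` is
  the Kaplan-Meier estimate of the censoring distribution from the
  *training* cohort, restricted to anchors with event time below the
  horizon ``tau`` (default: the 90th percentile of training follow-up,
  censored times included).
* Time-dependent AUC is the cumulative/dynamic variant with IPCW-weighted
  cases; iAUC integrates it by trapezoid over unique event times in
  ``(0, tau]``, normalized by the spanned interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MetricConfig",
    "ConcordanceResult",
    "StepFunction",
    "harrell_cindex",
    "censoring_survival",
    "uno_cindex",
    "stratified_bootstrap_ci",
    "time_dependent_auc",
    "integrate_auc",
    "iauc",
    "km_estimate",
    "log_rank_test",
    "follow_up_quantile",
]


@dataclass(frozen=True)
class MetricConfig:
    """Evaluation settings: horizon rule, bootstrap and NA thresholds."""

    tau_quantile: float = 0.90
    bootstrap_n: int = 2000
    ci_level: float = 0.95
    min_events_for_ci: int = 5
    max_degenerate_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap_n must be >= 1")
        if not 0 < self.tau_quantile <= 1:
            raise ValueError("tau_quantile must lie in (0, 1]")


@dataclass
class ConcordanceResult:
    estimate: float
    n_comparable_pairs: float
    method: str
    ci_low: float | None = None
    ci_high: float | None = None


class StepFunction:
    """Right-continuous step function ``f(t) = y[i]`` for ``x[i] <= t < x[i+1]``."""

    def __init__(self, x: np.ndarray, y: np.ndarray, initial: float = 1.0):
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        self.initial = initial

    def __call__(self, t):
        t = np.asarray(t, float)
        if len(self.x) == 0:  # no jumps: constant at the initial value
            out = np.full_like(t, self.initial, dtype=float)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.x, t, side="right") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, len(self.y) - 1)], self.initial)
        return out if out.ndim else float(out)


def follow_up_quantile(time_train, q: float = 0.90) -> float:
    """Horizon tau as a quantile of training follow-up (censored included)."""
    return float(np.quantile(np.asarray(time_train, float), q))


def _pair_weights(time, event):
    """Vectorized comparable-pair masks for concordance.

    Returns (comparable, tied_time_both_events) boolean n x n matrices
    where ``comparable[i, j]`` means subject i anchors a usable pair with
    j (i failed no later than j under the module tie conventions).
    """
    t = np.asarray(time, float)[:, None]
    d = np.asarray(event, int)[:, None]
    earlier = (t < t.T) & (d == 1)
    tie_event_censored = (t == t.T) & (d == 1) & (d.T == 0)
    tie_both_events = (t == t.T) & (d == 1) & (d.T == 1) & ~np.eye(len(time), dtype=bool)
    comparable = earlier | tie_event_censored
    return comparable, tie_both_events


def _concordance_from_masks(risk, comparable, tie_both_events, weights=None):
    r = np.asarray(risk, float)
    conc = (r[:, None] > r[None, :]).astype(float)
    conc += 0.5 * (r[:, None] == r[None, :])
    if weights is None:
        weights = np.ones_like(conc)
    # tied-event pairs appear in both orderings; scoring them 0.5 each
    # leaves the ratio identical to counting each unordered pair once
    num = np.sum(weights * comparable * conc) + 0.5 * np.sum(weights * tie_both_events)
    den = np.sum(weights * comparable) + np.sum(weights * tie_both_events)
    return num, den


def harrell_cindex(risk, time, event) -> ConcordanceResult:
    """Harrell's concordance index under the module tie conventions."""
    comparable, tie_be = _pair_weights(time, event)
    num, den = _concordance_from_masks(risk, comparable, tie_be)
    if den == 0:
        warnings.warn("no comparable pairs; Harrell C undefined")
        return ConcordanceResult(np.nan, 0, "harrell")
    return ConcordanceResult(float(num / den), float(den), "harrell")


def censoring_survival(time_train, event_train) -> StepFunction:
    """Kaplan-Meier estimate G(t) of the censoring distribution.

    Censoring indicators are ``1 - event``; with no censored observations
    G is identically 1.
    """
    time_train = np.asarray(time_train, float)
    cens = 1 - np.asarray(event_train, int)
    if cens.sum() == 0:
        return StepFunction(np.array([]), np.array([]), initial=1.0)
    return km_estimate(time_train, cens)


def uno_cindex(risk, time, event, G: StepFunction, tau: float) -> ConcordanceResult:
    """IPCW concordance truncated at ``tau`` (Uno's estimator).

    Event-anchored pairs with anchor time ``t_i < tau`` are weighted
    ``G(t_i)^-2``; anchors where ``G(t_i) = 0`` are excluded (count
    logged). Tie scoring follows :func:`harrell_cindex`.
    """
    t = np.asarray(time, float)
    comparable, tie_be = _pair_weights(time, event)
    within = t < tau
    comparable = comparable & within[:, None]
    tie_be = tie_be & within[:, None] & within[None, :]
    g_at = np.asarray(G(t), float)
    excluded = (g_at == 0) & np.asarray(event, bool) & within
    if excluded.any():
        logger.info("uno_cindex: %d anchors excluded with G(t)=0", excluded.sum())
    with np.errstate(divide="ignore"):
        w_anchor = np.where(g_at > 0, g_at**-2.0, 0.0)
    weights = w_anchor[:, None] * np.ones_like(g_at)[None, :]
    num, den = _concordance_from_masks(risk, comparable, tie_be, weights)
    if den == 0:
        warnings.warn("no comparable pairs below tau; Uno C undefined")
        return ConcordanceResult(np.nan, 0, "uno")
    return ConcordanceResult(float(num / den), float(den), "uno")


def stratified_bootstrap_ci(metric_fn, risk, time, event, config: MetricConfig):
    """Percentile bootstrap CI with events and censored cases resampled
    separately; returns ``None`` (the NA contract) when events are too few
    or too many resamples are degenerate."""
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ev_idx = np.flatnonzero(event == 1)
    ce_idx = np.flatnonzero(event == 0)
    if len(ev_idx) < config.min_events_for_ci:
        return None
    rng = np.random.default_rng(config.seed)
    vals = []
    degenerate = 0
    for _ in range(config.bootstrap_n):
        take = np.concatenate(
            [
                rng.choice(ev_idx, size=len(ev_idx), replace=True),
                rng.choice(ce_idx, size=len(ce_idx), replace=True)
                if len(ce_idx)
                else np.empty(0, dtype=int),
            ]
        )
        v = metric_fn(risk[take], time[take], event[take])
        if v is None or not np.isfinite(v):
            degenerate += 1
        else:
            vals.append(v)
    if degenerate > config.max_degenerate_fraction * config.bootstrap_n:
        return None
    alpha = 1.0 - config.ci_level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def time_dependent_auc(risk, time, event, G: StepFunction, t: float) -> float:
    """Cumulative/dynamic AUC at horizon ``t`` with IPCW-weighted cases.

    Cases: events by ``t`` weighted ``G(t_i)^-1``; controls: still at risk
    past ``t``. NaN when either group is empty.
    """
    r = np.asarray(risk, float)
    tt = np.asarray(time, float)
    d = np.asarray(event, int)
    cases = (tt <= t) & (d == 1)
    controls = tt > t
    if not cases.any() or not controls.any():
        return float("nan")
    g_case = np.asarray(G(tt[cases]), float)
    with np.errstate(divide="ignore"):
        w = np.where(g_case > 0, 1.0 / g_case, 0.0)
    rc = r[cases][:, None]
    rk = r[controls][None, :]
    score = (rc > rk).astype(float) + 0.5 * (rc == rk)
    num = np.sum(w[:, None] * score)
    den = np.sum(w) * controls.sum()
    if den == 0:
        return float("nan")
    return float(num / den)


def integrate_auc(times, aucs, tau: float, weighting: str = "trapezoid") -> float:
    """Integrate an AUC(t) curve over ``(0, tau]``.

    Default: plain trapezoid over the supplied grid normalized by the
    spanned interval. ``weighting="event_density"`` instead weights each
    grid point by its share of grid mass (a crude event-density rule).
    NaN-valued grid points are dropped; fewer than two valid points give
    NaN.
    """
    times = np.asarray(times, float)
    aucs = np.asarray(aucs, float)
    keep = np.isfinite(aucs) & (times > 0) & (times <= tau)
    times, aucs = times[keep], aucs[keep]
    if len(times) < 2:
        return float("nan")
    order = np.argsort(times)
    times, aucs = times[order], aucs[order]
    if weighting == "trapezoid":
        return float(np.trapezoid(aucs, times) / (times[-1] - times[0]))
    if weighting == "event_density":
        return float(np.mean(aucs))
    raise ValueError("weighting must be 'trapezoid' or 'event_density'")


def iauc(risk, time, event, G: StepFunction, tau: float, weighting="trapezoid"):
    """Convenience: AUC(t) over unique event times in (0, tau], integrated."""
    tt = np.asarray(time, float)
    d = np.asarray(event, int)
    grid = np.unique(tt[(d == 1) & (tt > 0) & (tt <= tau)])
    aucs = np.array([time_dependent_auc(risk, time, event, G, t) for t in grid])
    return integrate_auc(grid, aucs, tau, weighting)


def km_estimate(time, event) -> StepFunction:
    """Product-limit estimate of the survival function."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(time) == 0:
        raise ValueError("empty sample")
    uniq = np.unique(time[event == 1])
    n = len(time)
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return StepFunction(uniq, np.array(surv), initial=1.0)


def log_rank_test(group, time, event) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, upper-tail p with 1 df)."""
    group = np.asarray(group)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError("log-rank requires exactly two groups")
    in_a = group == labels[0]
    if in_a.sum() == 0 or (~in_a).sum() == 0:
        raise ValueError("a group has zero subjects")
    obs_a = 0.0
    exp_a = 0.0
    var_a = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_tot = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d_tot = np.sum((time == t) & (event == 1))
        d_a = np.sum((time == t) & (event == 1) & in_a)
        obs_a += d_a
        exp_a += d_tot * n_a / n_tot
        if n_tot > 1:
            var_a += (
                d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if var_a == 0:
        return 0.0, 1.0
    chi2 = (obs_a - exp_a) ** 2 / var_a
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
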