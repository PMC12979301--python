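"""Index validation against cancer incidence: Cox models and
two-stage random-effects meta-analysis.

Cohort-specific Cox proportional-hazards models relate the lifestyle
index (continuously and in quintiles, lowest quintile as reference) to
the hazard of diagnosis; a trend test replaces the quintile indicators
by each quintile's median score as a single continuous covariate.
Per-cohort log hazard ratios are pooled with inverse-variance
random-effects weights, the between-cohort variance tau^2 estimated by
DerSimonian-Laird and heterogeneity tested with Cochran's Q.

The Cox fitter maximizes the Breslow partial likelihood by
Newton-Raphson with step-halving, stopping when the gradient norm falls
below 1e-8; standard errors come from the observed information.
Confidence intervals use the fixed z = 1.96 convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import (
    CollinearityError,
    ConvergenceError,
    NoEventsError,
    ValidationError,
)

Z95 = 1.96


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ---------------------------------------------------------------------------

def cox_loglik(beta: np.ndarray, time, event, X) -> float:
    """Breslow log partial likelihood at ``beta`` (exposed for oracle
    checks against hand-enumerated risk-set expressions)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    order = np.argsort(-time, kind="stable")
    t, d, x = time[order], event[order], X[order]
    eta = x @ beta
    log_cum = np.logaddexp.accumulate(eta)
    # risk set of an event at t_i: all subjects with time >= t_i.
    # after descending sort, that is the prefix up to the last index
    # sharing t_i.
    ll = 0.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        log_s0 = log_cum[j]
        for idx in range(i, j + 1):
            if d[idx]:
                ll += eta[idx] - log_s0
        i = j + 1
    return float(ll)


def _cox_quantities(beta, t, d, x):
    """Negative log-likelihood derivatives with Breslow risk sets.

    ``t`` must be sorted descending; returns (loglik, gradient, hessian).
    """
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta - eta.max())
    logw_shift = eta.max()
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)

    # index of the last subject sharing each time (prefix end of risk set)
    last = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        last[i:j + 1] = j
        i = j + 1

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    ev = np.flatnonzero(d == 1)
    for idx in ev:
        j = last[idx]
        m0 = s0[j]
        m1 = s1[j] / m0
        m2 = s2[j] / m0
        ll += eta[idx] - (np.log(m0) + logw_shift)
        grad += x[idx] - m1
        hess -= m2 - np.outer(m1, m1)
    return ll, grad, hess


@dataclass
class CoxResult:
    """One Cox model term (or a set of terms) on the log-hazard scale."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    n_events: int
    n_participants: int
    p_value: np.ndarray = field(init=False)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        z = self.beta / self.se
        self.p_value = 2 * scipy.stats.norm.sf(np.abs(z))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    def ci(self) -> np.ndarray:
        lo = np.exp(self.beta - Z95 * self.se)
        hi = np.exp(self.beta + Z95 * self.se)
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.ci()
        return pd.DataFrame({
            "beta": self.beta, "se": self.se, "hr": self.hr,
            "ci_low": ci[:, 0], "ci_high": ci[:, 1], "p": self.p_value,
        }, index=self.terms)


def cox_fit(
    time,
    event,
    design,
    max_iter: int = 50,
    grad_tol: float = 1e-8,
) -> CoxResult:
    """Fit a Cox proportional-hazards model (Breslow tie handling).

    ``design`` is a DataFrame or array of covariates (no intercept; the
    baseline hazard absorbs it).  Monotone-likelihood behaviour (a
    coefficient drifting beyond +-25) is flagged, not raised.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event must be 0/1")
    event = event.astype(int)
    if np.any(time <= 0):
        raise ValidationError("times must be positive")
    X = pd.DataFrame(design)
    terms = [str(c) for c in X.columns]
    x = X.to_numpy(dtype=float)
    n, p = x.shape
    if event.sum() == 0:
        raise NoEventsError("no events in the data")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < p:
        raise CollinearityError("Cox design matrix is rank deficient")

    order = np.argsort(-time, kind="stable")
    t, d, xs = time[order], event[order], x[order]
    center = xs.mean(axis=0)
    xs = xs - center                       # numerical conditioning only

    beta = np.zeros(p)
    ll, grad, hess = _cox_quantities(beta, t, d, xs)
    flags: list[str] = []
    # gradient entries are sums over events, so the tolerance scales with
    # the event count to stay meaningful at any cohort size
    gtol = grad_tol * (1.0 + d.sum())
    for _ in range(max_iter):
        if np.linalg.norm(grad) < gtol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        if np.linalg.norm(step) < 1e-12:
            break                      # at numerical precision already
        scale = 1.0
        ll_tol = 1e-10 * (1.0 + abs(ll))   # relative: ll is O(n) in size
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _cox_quantities(cand, t, d, xs)
            if ll_new >= ll - ll_tol:
                break
            scale /= 2
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 25:
            flags.append("monotone_likelihood")
            break
    else:
        raise ConvergenceError(
            f"Cox Newton-Raphson did not converge in {max_iter} iterations")
    if np.max(np.abs(beta)) > 10 and "monotone_likelihood" not in flags:
        # a |log HR| beyond ~10 per unit covariate is a boundary drift,
        # not a plausible estimate: perfect separation in the risk sets
        flags.append("monotone_likelihood")

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return CoxResult(terms, beta, se, int(event.sum()), n, flags=flags)


# ---------------------------------------------------------------------------
# Quintile and trend models
# ---------------------------------------------------------------------------

def quintile_model(time, event, quintiles, covariates=None) -> pd.DataFrame:
    """Cox model with quintile indicators, lowest quintile as reference.

    Returns a Table-2-shaped frame (one row per quintile with HR, CI and
    p; the reference has HR fixed at 1).  Quintiles without events are
    flagged and their estimates omitted.
    """
    from .assoc import _as_design

    quintiles = np.asarray(quintiles)
    event = np.asarray(event).astype(int)
    levels = np.unique(quintiles)
    if len(levels) < 2:
        raise ValidationError("need at least 2 quintile levels")
    events_per_q = {q: int(event[quintiles == q].sum()) for q in levels}
    usable = [q for q in levels if events_per_q[q] > 0]
    if len(usable) < 2:
        raise NoEventsError("fewer than 2 quintiles contain events")

    ref = levels[0]
    keep = np.isin(quintiles, usable)
    design = pd.DataFrame({
        f"Q{q}": (quintiles == q).astype(float)[keep]
        for q in usable if q != ref})
    cov = _as_design(covariates)
    if cov is not None:
        design = pd.concat(
            [design, cov.loc[keep].reset_index(drop=True)], axis=1)
    fit = cox_fit(np.asarray(time, float)[keep], event[keep], design)

    rows = [{"quintile": ref, "hr": 1.0, "ci_low": np.nan,
             "ci_high": np.nan, "p": np.nan,
             "n_events": events_per_q[ref], "flag": "reference"}]
    summary = fit.summary()
    for q in levels:
        if q == ref:
            continue
        name = f"Q{q}"
        if name in summary.index:
            row = summary.loc[name]
            rows.append({"quintile": q, "hr": row["hr"],
                         "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                         "p": row["p"], "n_events": events_per_q[q],
                         "flag": ""})
        else:
            rows.append({"quintile": q, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan,
                         "n_events": events_per_q[q], "flag": "no_events"})
    return pd.DataFrame(rows).set_index("quintile")


def trend_test(time, event, quintiles, scores, covariates=None) -> CoxResult:
    """p-for-trend: quintile median scores as a continuous covariate."""
    from .assoc import _as_design

    quintiles = np.asarray(quintiles)
    scores = np.asarray(scores, dtype=float)
    medians = {q: float(np.median(scores[quintiles == q]))
               for q in np.unique(quintiles)}
    if len(set(medians.values())) < len(medians):
        warnings.warn("quintiles share a median score; trend covariate is "
                      "reduced rank", stacklevel=2)
    trend = np.array([medians[q] for q in quintiles])
    design = pd.DataFrame({"trend": trend})
    cov = _as_design(covariates)
    if cov is not None:
        design = pd.concat([design, cov.reset_index(drop=True)], axis=1)
    return cox_fit(time, event, design)


# ---------------------------------------------------------------------------
# Random-effects meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaResult:
    """Inverse-variance random-effects pooling of per-cohort log HRs."""

    pooled_beta: float
    se: float
    tau2: float
    q_statistic: float
    q_df: int
    p_heterogeneity: float
    weights: np.ndarray            # normalized random-effects weights

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_beta))

    def ci(self) -> tuple[float, float]:
        return (float(np.exp(self.pooled_beta - Z95 * self.se)),
                float(np.exp(self.pooled_beta + Z95 * self.se)))

    @property
    def p_value(self) -> float:
        z = self.pooled_beta / self.se
        return float(2 * scipy.stats.norm.sf(abs(z)))


def meta_pool(betas, variances) -> MetaResult:
    """DerSimonian-Laird random-effects pooling with Cochran's Q.

    ``Q = sum w_i (b_i - b_FE)^2`` with fixed-effect weights
    ``w_i = 1/v_i``; ``tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum
    w))``; the pooled estimate uses weights ``1 / (v_i + tau^2)``.
    """
    b = np.asarray(betas, dtype=float)
    v = np.asarray(variances, dtype=float)
    if b.size < 2:
        raise ValidationError("meta-analysis needs at least 2 cohorts")
    if np.any(v <= 0):
        raise ValidationError("variances must be positive")
    w = 1.0 / v
    b_fe = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_fe) ** 2))
    df = b.size - 1
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (v + tau2)
    pooled = float(np.sum(w_re * b) / np.sum(w_re))
    se = float(np.sqrt(1.0 / np.sum(w_re)))
    p_het = float(scipy.stats.chi2.sf(q, df))
    return MetaResult(pooled, se, tau2, q, df, p_het,
                      weights=w_re / w_re.sum())
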