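"""Cox proportional-hazards analysis of within-bout outcomes.

Within a bout of interaction, solving and abandonment are competing
terminal events.  Each is analysed as a separate Cox model on bout
duration: for the abandonment analysis solved bouts are censored, and
vice versa.  Covariates are frozen at bout start and describe the
individual's prior experience (successes and failures at the same and
the other option-type, whether it ever solved the same option-type,
observed feeding successes) plus a bounded recency transform
``exp(-rho * dt)`` of the time since another individual last manipulated
the same option at the same box (0 if never this session).

Evidence for each covariate is judged by all-subsets AIC model
averaging: every combination of candidate covariates is fitted, Akaike
weights w_m = exp(-0.5 dAIC_m) / sum exp(-0.5 dAIC) are computed over
the model set, and effects are reported as model-averaged coefficients
with unconditional standard errors (Burnham & Anderson), back-transformed
to hazard-ratio multipliers with 95% unconditional confidence intervals.

The partial likelihood uses the Efron approximation for tied event
times by default (Breslow available); fits are fixed-effects only, by
Newton-Raphson with analytic gradient and Hessian.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_model import (EventLog, ExperienceTimeline, OPTION_TYPES,
                          build_experience_timeline)

__all__ = ["BOUT_COVARIATES", "build_bout_table", "cox_partial_loglik",
           "fit_cox", "CoxFit", "all_subsets_average", "ModelAverage",
           "akaike_weights"]

#: Default candidate covariates for the all-subsets averaging.
BOUT_COVARIATES = ("prior_success_same", "prior_success_other",
                   "prior_fail_same", "prior_fail_other",
                   "solved_before_same", "obs_feeding_same",
                   "obs_feeding_other", "recency_same_option_box")


def _other(option_type: str) -> str:
    return OPTION_TYPES[1 - OPTION_TYPES.index(option_type)]


def build_bout_table(log: EventLog, timeline: ExperienceTimeline | None =
                     None, outcome: str = "abandonment",
                     rho: float = math.log(2) / 20.0) -> pd.DataFrame:
    """One record per non-demonstrator flap/tube bout, covariates at start.

    ``outcome="abandonment"`` marks abandoned bouts as events and solved
    bouts as censored; ``outcome="solving"`` reverses the roles.  ``rho``
    is the decay rate used for the recency covariate, normally taken from
    the fitted rate model.
    """
    if outcome not in ("abandonment", "solving"):
        raise ValueError("outcome must be 'abandonment' or 'solving'")
    timeline = timeline or build_experience_timeline(log)
    inds = log._ind_index()
    rows = []
    for b in log.bouts:
        ind = inds[b.individual_id]
        if ind.is_demonstrator or b.option_type not in OPTION_TYPES:
            continue
        k, other = b.option_type, _other(b.option_type)
        t, sid, iid = b.t_start, b.session_id, b.individual_id
        lo = timeline.last_observation_times(iid, sid, t,
                                             condition="all_present")
        tau = lo["option_box"][(k, b.box_side)]
        recency = math.exp(-rho * (t - tau)) if tau is not None else 0.0
        row = {
            "bout_id": b.bout_id, "individual_id": iid,
            "group_id": ind.group_id, "age_class": ind.age_class,
            "sex": ind.sex, "dominance": ind.dominance,
            "session_id": sid, "option_type": k, "box_side": b.box_side,
            "t_start": t, "duration": b.t_end - b.t_start,
            "event": int((b.outcome == "abandoned") ==
                         (outcome == "abandonment")),
            "prior_success_same": timeline.reward_count(iid, k, sid, t),
            "prior_success_other": timeline.reward_count(iid, other, sid, t),
            "prior_fail_same": timeline.failure_count(iid, k, sid, t),
            "prior_fail_other": timeline.failure_count(iid, other, sid, t),
            "solved_before_same": int(timeline.solved_ever(iid, k, sid, t)),
            "obs_feeding_same": timeline.observation_count(
                iid, k, "feeding", sid, t),
            "obs_feeding_other": timeline.observation_count(
                iid, other, "feeding", sid, t),
            "recency_same_option_box": recency,
        }
        row["prior_success_total"] = (row["prior_success_same"] +
                                      row["prior_success_other"])
        row["prior_fail_total"] = (row["prior_fail_same"] +
                                   row["prior_fail_other"])
        row["obs_feeding_total"] = (row["obs_feeding_same"] +
                                    row["obs_feeding_other"])
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and (df["duration"] <= 0).any():
        raise ValueError("bout durations must be positive")
    return df


# ---------------------------------------------------------------------------
# Partial likelihood
# ---------------------------------------------------------------------------

def _prepare(durations, events, X):
    t = np.asarray(durations, dtype=float)
    d = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.shape[0] != len(t) or len(d) != len(t):
        raise ValueError("durations, events and X must align")
    if (t <= 0).any():
        raise ValueError("durations must be positive")
    order = np.argsort(-t, kind="stable")  # descending time
    return t[order], d[order], X[order]


def _cox_ll_grad_hess(durations, events, X, beta, ties="efron"):
    """Efron/Breslow partial log-likelihood with analytic derivatives.

    Subjects are scanned in order of decreasing duration so the risk set
    accumulates; ties in event times are handled per *ties*.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t, d, X = _prepare(durations, events, X)
    n, p = X.shape
    beta = np.asarray(beta, dtype=float).reshape(p) if p else \
        np.zeros(0)
    eta = X @ beta if p else np.zeros(n)
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        for m in range(i, j):  # everyone at this time enters the risk set
            S0 += w[m]
            if p:
                S1 += w[m] * X[m]
                S2 += w[m] * np.outer(X[m], X[m])
        ev = [m for m in range(i, j) if d[m] == 1]
        nd = len(ev)
        if nd:
            s0d = sum(w[m] for m in ev)
            s1d = np.sum([w[m] * X[m] for m in ev], axis=0) if p else 0.0
            s2d = np.sum([w[m] * np.outer(X[m], X[m]) for m in ev],
                         axis=0) if p else 0.0
            for m in ev:
                ll += eta[m]
                if p:
                    grad += X[m]
            for r in range(nd):
                frac = r / nd if ties == "efron" else 0.0
                phi0 = S0 - frac * s0d
                ll -= math.log(phi0)
                if p:
                    phi1 = S1 - frac * s1d
                    phi2 = S2 - frac * s2d
                    grad -= phi1 / phi0
                    hess -= phi2 / phi0 - np.outer(phi1, phi1) / phi0 ** 2
        i = j
    return ll, grad, hess


def cox_partial_loglik(durations, events, X=None, beta=None,
                       ties: str = "efron") -> float:
    """Cox partial log-likelihood at *beta* (zeros if omitted)."""
    d = np.asarray(events, dtype=int)
    if d.sum() == 0:
        raise ValueError("no events: the partial likelihood is undefined")
    if X is None:
        X = np.zeros((len(d), 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if beta is None:
        beta = np.zeros(X.shape[1])
    ll, _, _ = _cox_ll_grad_hess(durations, events, X, beta, ties)
    return ll


@dataclass
class CoxFit:
    """A maximized Cox partial likelihood (AIC = -2 loglik + 2 k)."""

    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    names: tuple
    n: int
    n_events: int
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)) if self.cov.size else \
            np.zeros(0)


def fit_cox(table: pd.DataFrame, covariates, duration_col: str = "duration",
            event_col: str = "event", ties: str = "efron",
            max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson maximization of the partial likelihood.

    Raises on an all-censored table or a rank-deficient design; a fit
    that fails to converge (e.g. separation) is returned flagged so the
    averaging step can exclude it with a warning.
    """
    covariates = tuple(covariates)
    t = table[duration_col].to_numpy(dtype=float)
    d = table[event_col].to_numpy(dtype=int)
    if d.sum() == 0:
        raise ValueError("no events: cannot fit a Cox model")
    X = table[list(covariates)].to_numpy(dtype=float) if covariates else \
        np.zeros((len(t), 0))
    p = X.shape[1]
    if p:
        Xc = X - X.mean(axis=0)
        if np.linalg.matrix_rank(Xc) < p:
            raise ValueError("rank-deficient design matrix for "
                             f"{covariates}")
    beta = np.zeros(p)
    ll, grad, hess = _cox_ll_grad_hess(t, d, X, beta, ties)
    converged = p == 0
    for _ in range(max_iter if p else 0):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        new = beta + step
        ll_new, grad_new, hess_new = _cox_ll_grad_hess(t, d, X, new, ties)
        halvings = 0
        while ll_new < ll and halvings < 10:
            step *= 0.5
            new = beta + step
            ll_new, grad_new, hess_new = _cox_ll_grad_hess(t, d, X, new,
                                                           ties)
            halvings += 1
        beta, ll, grad, hess = new, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < 1e-8 or np.max(np.abs(step)) < tol:
            converged = True
            break
    if p:
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            converged = False
    else:
        cov = np.zeros((0, 0))
    if p and not np.all(np.isfinite(cov)):
        converged = False
    return CoxFit(coef=beta, cov=cov, loglik=ll, aic=-2.0 * ll + 2.0 * p,
                  names=covariates, n=len(t), n_events=int(d.sum()),
                  converged=converged)


# ---------------------------------------------------------------------------
# All-subsets AIC model averaging
# ---------------------------------------------------------------------------

def akaike_weights(aics) -> np.ndarray:
    """exp(-dAIC/2) normalized; invariant to adding a constant to all AICs."""
    a = np.asarray(aics, dtype=float)
    w = np.exp(-0.5 * (a - a.min()))
    return w / w.sum()


@dataclass
class ModelAverage:
    """Summary of all-subsets averaging on the hazard-ratio scale."""

    covariates: pd.DataFrame       # per-covariate weight/estimate/UCI
    models: pd.DataFrame           # per-model AIC and weight
    outcome: str = ""
    dropped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"outcome": self.outcome,
                "covariates": self.covariates.to_dict(orient="index"),
                "n_models": int(len(self.models)),
                "dropped": list(self.dropped)}


def all_subsets_average(table: pd.DataFrame, candidates=None,
                        duration_col: str = "duration",
                        event_col: str = "event", ties: str = "efron",
                        outcome: str = "",
                        z_crit: float = 1.959963984540054) -> ModelAverage:
    """Fit every subset of the candidate covariates and average by AIC.

    Per covariate the report gives its total Akaike weight (summed over
    the models containing it), the model-averaged coefficient (absent
    models contribute 0), the unconditional standard error
    ``sum_m w_m * sqrt(var_m + (b_m - b_avg)^2)`` and the back-transformed
    multiplier with its 95% unconditional confidence interval.
    """
    candidates = tuple(candidates if candidates is not None
                       else BOUT_COVARIATES)
    if len(candidates) > 20:
        raise ValueError("more than 20 candidate covariates would require "
                         f"2^{len(candidates)} fits; trim the candidate set")
    fits = []
    dropped = []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            try:
                fit = fit_cox(table, subset, duration_col, event_col, ties)
            except ValueError as e:
                dropped.append((subset, str(e)))
                continue
            if not fit.converged:
                dropped.append((subset, "did not converge"))
                continue
            fits.append(fit)
    if not fits:
        raise ValueError("no Cox model could be fitted")
    aics = np.array([f.aic for f in fits])
    w = akaike_weights(aics)
    models = pd.DataFrame({
        "covariates": [",".join(f.names) for f in fits],
        "k": [len(f.names) for f in fits],
        "loglik": [f.loglik for f in fits],
        "aic": aics, "weight": w})
    rows = {}
    for name in candidates:
        b = np.zeros(len(fits))
        v = np.zeros(len(fits))
        present = np.zeros(len(fits), dtype=bool)
        for m, f in enumerate(fits):
            if name in f.names:
                j = f.names.index(name)
                b[m] = f.coef[j]
                v[m] = f.cov[j, j]
                present[m] = True
        b_avg = float(np.sum(w * b))
        se_u = float(np.sum(w * np.sqrt(v + (b - b_avg) ** 2)))
        rows[name] = {
            "total_weight": float(np.sum(w[present])),
            "coef_avg": b_avg, "se_uncond": se_u,
            "multiplier": math.exp(b_avg),
            "uci_lo": math.exp(b_avg - z_crit * se_u),
            "uci_hi": math.exp(b_avg + z_crit * se_u)}
    return ModelAverage(covariates=pd.DataFrame(rows).T, models=models,
                        outcome=outcome, dropped=dropped)
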