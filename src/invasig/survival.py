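"""Survival-analysis primitives: Kaplan-Meier, weighted log-rank, Cox PH.

The Cox fitter maximizes the partial likelihood by Newton-Raphson with
step-halving and uses the Efron approximation for tied event times
(Breslow available).  A vectorized batch mode fits one univariate model
per gene simultaneously, which is what makes leave-one-out
cross-validation and thousand-signature null distributions tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate over distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only times contribute to the risk sets but produce no steps.
    With no censoring the estimate equals one minus the empirical CDF.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival data")
    if time.shape != event.shape:
        raise ValueError("time and event lengths differ")
    if (time <= 0).any():
        raise ValueError("times must be positive")

    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for u in uniq:
        n_risk = int(np.sum(t >= u))
        d = int(np.sum((t == u) & (e == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        n_ev.append(d)
    return KMCurve(
        event_times=uniq,
        survival=np.array(surv),
        n_at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
    )


# ---------------------------------------------------------------------------
# Weighted log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    weight_scheme: str


def weighted_logrank(group, time, event, weight_scheme: str = "logrank") -> LogRankResult:
    """K-sample (weighted) log-rank test.

    At each distinct event time the observed minus hypergeometric-expected
    event count per group is accumulated with weight w(t) = 1 (``logrank``)
    or w(t) = total number at risk (``gehan-breslow-wilcoxon``, sensitive
    to early separation).  The statistic is the quadratic form of the
    first k-1 group sums against their estimated covariance; df = k - 1.
    """
    if weight_scheme not in ("logrank", "gehan-breslow-wilcoxon"):
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    group = np.asarray(group)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    levels, gidx = np.unique(group, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 non-empty groups")

    event_times = np.unique(time[event == 1])
    z = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        at_risk = time >= u
        n = at_risk.sum()
        d = int(np.sum((time == u) & (event == 1)))
        if n <= 1:
            continue
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(time == u) & (event == 1)], minlength=k).astype(float)
        w = 1.0 if weight_scheme == "logrank" else float(n)
        e_g = d * n_g / n
        z += w * (d_g - e_g)
        # multivariate hypergeometric covariance of d_g
        factor = d * (n - d) / (n - 1) / n**2
        V += w**2 * factor * (n * np.diag(n_g) - np.outer(n_g, n_g))

    z1, V1 = z[:-1], V[:-1, :-1]
    try:
        chi2 = float(z1 @ np.linalg.solve(V1, z1))
    except np.linalg.LinAlgError:
        chi2 = float(z1 @ np.linalg.pinv(V1) @ z1)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2=chi2, df=df, p=p, weight_scheme=weight_scheme)


# ---------------------------------------------------------------------------
# Cox proportional hazards (partial likelihood)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``coefficients`` are log hazard ratios per covariate; Wald standard
    errors come from the observed information at the maximum.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_partial_likelihood: float
    converged: bool
    ties_method: str
    covariate_names: list = field(default_factory=list)
    n: int = 0
    n_events: int = 0

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.coefficients - 1.96 * self.standard_errors)
        hi = np.exp(self.coefficients + 1.96 * self.standard_errors)
        return np.column_stack([lo, hi])

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            zval = self.coefficients / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(zval))

    def summary(self) -> dict:
        names = self.covariate_names or [f"x{i}" for i in range(len(self.coefficients))]
        ci = self.ci95
        return {
            name: {
                "coef": float(b), "se": float(s), "hr": float(np.exp(b)),
                "ci95": [float(ci[i, 0]), float(ci[i, 1])], "p": float(p),
            }
            for i, (name, b, s, p) in enumerate(
                zip(names, self.coefficients, self.standard_errors, self.wald_p))
        }


MAX_ABS_BETA = 10.0  # separation guard: |beta| capped here, fit flagged


def _prepare(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    return time[order], event[order], order


def _event_groups(t, e):
    """Distinct event times -> (first risk-set index, tied-event row indices)."""
    groups = []
    for u in np.unique(t[e == 1]):
        risk_start = int(np.searchsorted(t, u, side="left"))
        tied = np.flatnonzero((t == u) & (e == 1))
        groups.append((risk_start, tied))
    return groups


def _cox_loglik_grad_hess(beta, X, t, e, groups, ties_method):
    """Log partial likelihood with analytic gradient and Hessian.

    X is n x p in time-sorted order.  Efron: the l-th tied event at a time
    with d ties sees the risk-set sums reduced by (l/d) of the tied sums.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # suffix sums over the time-sorted risk sets
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for risk_start, tied in groups:
        d = len(tied)
        s0, s1, s2 = S0[risk_start], S1[risk_start], S2[risk_start]
        ll += float(eta[tied].sum())
        grad += X[tied].sum(axis=0)
        if ties_method == "breslow" or d == 1:
            reps = d
            for _ in range(reps):
                ll -= np.log(s0)
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        else:  # efron
            t0 = w[tied].sum()
            t1 = (w[tied, None] * X[tied]).sum(axis=0)
            t2 = (w[tied, None, None] * (X[tied, :, None] * X[tied, None, :])).sum(axis=0)
            for l in range(d):
                f = l / d
                a0 = s0 - f * t0
                a1 = s1 - f * t1
                a2 = s2 - f * t2
                ll -= np.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
    return ll, grad, hess


def cox_fit(covariates, time, event, ties_method: str = "efron",
            covariate_names=None, max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Fit a Cox PH model by Newton-Raphson with step-halving.

    Raises on a covariate constant over the whole sample in the univariate
    case; drops constant columns with a warning in the multivariate case.
    Monotone likelihood (separation) caps |beta| at 10 and clears the
    ``converged`` flag.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties_method {ties_method!r}")
    names = list(covariate_names) if covariate_names is not None else [f"x{i}" for i in range(p)]

    const = np.ptp(X, axis=0) == 0
    if const.any():
        if p == 1:
            raise ValueError("covariate is constant across patients")
        warnings.warn(f"dropping constant covariates: {[names[i] for i in np.flatnonzero(const)]}")
        keep = ~const
        X, names = X[:, keep], [nm for nm, k in zip(names, keep) if k]
        p = X.shape[1]

    t, e, order = _prepare(time, event)
    Xs = X[order]
    groups = _event_groups(t, e)
    if not groups:
        raise ValueError("no events in the data")

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_grad_hess(beta, Xs, t, e, groups, ties_method)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving until the log-likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = _cox_loglik_grad_hess(cand, Xs, t, e, groups, ties_method)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll_prev, ll = cand, ll, ll_new
        grad, hess = g_new, h_new
        if np.abs(ll - ll_prev) < tol * (np.abs(ll_prev) + tol):
            converged = True
            break

    separated = np.abs(beta) > MAX_ABS_BETA
    if separated.any():
        beta = np.clip(beta, -MAX_ABS_BETA, MAX_ABS_BETA)
        ll, grad, hess = _cox_loglik_grad_hess(beta, Xs, t, e, groups, ties_method)
        converged = False

    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
            converged = False

    return CoxFit(
        coefficients=beta, standard_errors=se, log_partial_likelihood=float(ll),
        converged=converged, ties_method=ties_method, covariate_names=names,
        n=n, n_events=int(e.sum()),
    )


def cox_fit_univariate_batch(X, time, event, max_iter: int = 30,
                             tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Fit one univariate Cox model per column of X, vectorized.

    Returns (beta, converged_flags).  Efron correction for ties.  Columns
    that fail to converge or separate (|beta| > 10) are flagged; callers
    decide how to treat them (the LOOCV risk index zeroes them out).

    This is the inner loop of LOOCV and of the random-signature null, so
    everything is done as whole-matrix numpy ops across genes.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    t, e, order = _prepare(time, event)
    Xs = X[order]

    ev_idx = np.flatnonzero(e == 1)
    if ev_idx.size == 0:
        raise ValueError("no events in the data")
    uniq_times = np.unique(t[ev_idx])
    risk_start = np.searchsorted(t, uniq_times, side="left")
    # tied event rows per distinct time, padded structure avoided: compute
    # per-group slices once
    tied_groups = [np.flatnonzero((t == u) & (e == 1)) for u in uniq_times]
    d_max = max(len(g) for g in tied_groups)
    sum_x_events = Xs[ev_idx].sum(axis=0)

    beta = np.zeros(p)
    active = np.ones(p, dtype=bool)
    converged = np.zeros(p, dtype=bool)

    for _ in range(max_iter):
        eta = np.clip(Xs * beta, -500, 500)
        w = np.exp(eta)
        wx = w * Xs
        wxx = wx * Xs
        S0 = np.cumsum(w[::-1], axis=0)[::-1]
        S1 = np.cumsum(wx[::-1], axis=0)[::-1]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

        grad = sum_x_events.copy()
        info = np.zeros(p)
        for k, (rs, tied) in enumerate(zip(risk_start, tied_groups)):
            d = len(tied)
            s0, s1, s2 = S0[rs], S1[rs], S2[rs]
            if d == 1:
                grad -= s1 / s0
                info += s2 / s0 - (s1 / s0) ** 2
            else:
                t0 = w[tied].sum(axis=0)
                t1 = wx[tied].sum(axis=0)
                t2 = wxx[tied].sum(axis=0)
                for l in range(d):
                    f = l / d
                    a0 = s0 - f * t0
                    a1 = s1 - f * t1
                    a2 = s2 - f * t2
                    grad -= a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2

        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 1e-12, grad / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)  # damp huge early steps
        step = np.where(active, step, 0.0)
        beta = beta + step
        newly = active & (np.abs(step) < tol * (1 + np.abs(beta)))
        converged |= newly
        active &= ~newly
        over = np.abs(beta) > MAX_ABS_BETA
        if over.any():
            beta = np.clip(beta, -MAX_ABS_BETA, MAX_ABS_BETA)
            converged &= ~over
            active &= ~over
        if not active.any():
            break

    return beta, converged
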