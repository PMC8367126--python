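"""Kaplan-Meier estimation, log-rank testing and Cox regression.

All estimators are implemented directly on the standard formulas:

* Kaplan-Meier product-limit estimator ``S(t) = prod_{t_i <= t} (1 - d_i/n_i)``
  with Greenwood variance and log-scale confidence bands.
* Two-group log-rank (Cox-Mantel) test with the hypergeometric variance.
* Cox proportional-hazards partial likelihood, maximized by Newton-Raphson
  with the Efron tie correction (Breslow selectable), Wald per-covariate
  tests and a likelihood-ratio global test.
* Grambsch-Therneau proportional-hazards assumption test on scaled
  Schoenfeld residuals with the Kaplan-Meier time transform.

Cohorts smaller than 40 samples trigger a :class:`SmallSampleWarning`,
because the Cox model's asymptotics are unreliable there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    ConstantVariableError,
    DegenerateGroupError,
    InsufficientEventsError,
    NoEventsWarning,
    NonConvergenceError,
    SmallSampleWarning,
)

SMALL_SAMPLE_N = 40
Z_95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``survival[i]`` is S(t) just after ``event_times[i]``; the curve is a
    right-continuous step function equal to 1 before the first event.
    ``ci_low``/``ci_high`` are 95% log-transformed Greenwood bands.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    censoring_times: np.ndarray
    ci_low: np.ndarray = field(default=None)
    ci_high: np.ndarray = field(default=None)
    n: int = 0

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_survival(self) -> tuple[float | None, str]:
        """Smallest event time with S(t) <= 0.5 (inclusive).

        Returns ``(time, "median")``, or the upper-quartile survival
        ``(time, "upper_quartile")`` when the curve never reaches 0.5, or
        ``(None, "undefined")`` when it does not even reach 0.75.
        """
        for threshold, kind in ((0.5, "median"), (0.75, "upper_quartile")):
            hit = np.nonzero(self.survival <= threshold + 1e-12)[0]
            if hit.size:
                return float(self.event_times[hit[0]]), kind
        return None, "undefined"

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({
            "time": self.event_times, "n_risk": self.at_risk,
            "n_event": self.events, "survival": self.survival,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })

    def to_plot_series(self) -> dict:
        """Step-plot coordinates (starting at (0, 1)) plus censor marks."""
        times = np.concatenate([[0.0], self.event_times])
        surv = np.concatenate([[1.0], self.survival])
        return {"time": times.tolist(), "survival": surv.tolist(),
                "censoring_times": self.censoring_times.tolist()}


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate from follow-up times and 0/1 event flags.

    Censored observations leave the risk set after their time; events at
    t=0 are kept with the full sample at risk.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.size == 0:
        raise ValueError("time and event must be equal-length, non-empty")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        warnings.warn("no events observed; survival curve stays at 1",
                      NoEventsWarning, stacklevel=2)
        return KMCurve(event_times=np.empty(0), at_risk=np.empty(0, int),
                       events=np.empty(0, int), survival=np.empty(0),
                       censoring_times=np.unique(time[event == 0]),
                       ci_low=np.empty(0), ci_high=np.empty(0), n=time.size)

    n = time.size
    # at risk at t = number with follow-up >= t
    at_risk = n - np.searchsorted(time, event_times, side="left")
    d = np.array([int(((time == t) & (event == 1)).sum()) for t in event_times])
    frac = 1.0 - d / at_risk
    survival = np.cumprod(frac)

    # Greenwood variance on log S; 95% bands exp(log S +/- z * se(log S))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(d / (at_risk * (at_risk - d)), dtype=float)
        se_log = np.sqrt(gw)
        ci_low = np.where(survival > 0, survival * np.exp(-Z_95 * se_log), 0.0)
        ci_high = np.where(survival > 0,
                           np.minimum(1.0, survival * np.exp(Z_95 * se_log)),
                           0.0)

    return KMCurve(event_times=event_times, at_risk=at_risk.astype(int),
                   events=d, survival=survival,
                   censoring_times=np.unique(time[event == 0]),
                   ci_low=ci_low, ci_high=ci_high, n=n)


def median_survival(curve: KMCurve):
    """Module-level convenience; see :meth:`KMCurve.median_survival`."""
    return curve.median_survival()


def survival_at(curve: KMCurve, t: float) -> float:
    if t < 0:
        raise ValueError("t must be nonnegative")
    return curve.survival_at(t)


# ---------------------------------------------------------------------------
# log-rank test

def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank (Cox-Mantel) test.

    Returns ``(chi2, p)`` with one degree of freedom, using the pooled
    hypergeometric variance at each distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise DegenerateGroupError(
            f"log-rank needs exactly 2 non-empty groups, got {labels.size}")
    g1 = group == labels[1]
    if event.sum() < 1:
        raise InsufficientEventsError("log-rank requires at least one event")

    order = np.argsort(time, kind="stable")
    time, event, in1 = time[order], event[order], g1[order].astype(float)

    event_times = np.unique(time[event == 1])
    starts = np.searchsorted(time, event_times, side="left")
    n_t = time.size - starts                      # at risk (pooled)
    n1_t = np.cumsum(in1[::-1])[::-1][starts]     # at risk in group 1

    ev_idx = np.nonzero(event == 1)[0]
    blk = np.searchsorted(time[ev_idx], event_times, side="left")
    d_t = np.add.reduceat(np.ones_like(ev_idx, dtype=float), blk)
    d1_t = np.add.reduceat(in1[ev_idx], blk)

    o1 = d1_t.sum()
    e1 = (d_t * n1_t / n_t).sum()
    frac = n1_t / n_t
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = d_t * frac * (1 - frac) * (n_t - d_t) / (n_t - 1)
    v = float(np.nansum(np.where(n_t > 1, terms, 0.0)))
    if v <= 0:
        return 0.0, 1.0
    chi2 = (o1 - e1) ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards

@dataclass
class CoxResult:
    """Cox partial-likelihood fit.

    Per-covariate arrays are aligned with ``names``; ``var`` is the inverse
    observed information (the covariance of beta) and ``global_p`` the
    likelihood-ratio test against the null model.
    """

    coefficients: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    global_p: float
    loglik: float
    loglik_null: float
    ties_method: str
    n: int
    n_events: int
    names: list[str]
    var: np.ndarray
    inverted: bool = False
    # retained inputs (sorted by time) for residual-based diagnostics
    _time: np.ndarray = field(default=None, repr=False)
    _event: np.ndarray = field(default=None, repr=False)
    _X: np.ndarray = field(default=None, repr=False)

    @property
    def n_covariates(self) -> int:
        return len(self.coefficients)

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({
            "variable": self.names, "coef": self.coefficients, "se": self.se,
            "HR": self.hr, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p,
        })

    def summary(self) -> str:
        lines = [f"Cox proportional hazards ({self.ties_method} ties): "
                 f"n={self.n}, events={self.n_events}",
                 f"{'variable':<24}{'HR':>10}{'95% CI':>22}{'p':>12}"]
        for i, name in enumerate(self.names):
            ci = f"[{self.ci_low[i]:.4g}, {self.ci_high[i]:.4g}]"
            lines.append(f"{name:<24}{self.hr[i]:>10.4g}{ci:>22}"
                         f"{self.p[i]:>12.3g}")
        lines.append(f"likelihood-ratio global p = {self.global_p:.3g}")
        return "\n".join(lines)


def _cox_quantities(beta, time, event, X, ties):
    """Compute (loglik, gradient, information) of the Cox partial likelihood.

    Inputs must be sorted by ascending time.  Efron's correction subtracts
    l/d of the tied-death sums from the risk-set sums for the l-th of d
    tied events; Breslow uses the plain risk-set sums for all of them.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guards overflow; cancels in all ratios
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]

    # suffix sums -> risk-set sums for any time t via first index with >= t
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ev_idx = np.nonzero(event == 1)[0]
    ev_times = time[ev_idx]
    uniq, block_start = np.unique(ev_times, return_index=True)
    d = np.diff(np.append(block_start, ev_idx.size))  # events per tied time
    risk_first = np.searchsorted(time, uniq, side="left")

    S0r = S0[risk_first]                       # (K,)
    S1r = S1[risk_first]                       # (K, p)
    S2r = S2[risk_first]                       # (K, p, p)

    # tied-death sums per distinct event time
    S0d = np.add.reduceat(w[ev_idx], block_start)
    S1d = np.add.reduceat(wX[ev_idx], block_start, axis=0)
    S2d = np.add.reduceat(wXX[ev_idx], block_start, axis=0)

    # expand each distinct time into its d Efron terms
    rep = np.repeat(np.arange(uniq.size), d)
    frac = (np.concatenate([np.arange(k) for k in d]) /
            np.repeat(d.astype(float), d))
    if ties == "breslow":
        frac = np.zeros_like(frac)

    phi = S0r[rep] - frac * S0d[rep]                      # (m,)
    z1 = S1r[rep] - frac[:, None] * S1d[rep]              # (m, p)
    z2 = S2r[rep] - frac[:, None, None] * S2d[rep]        # (m, p, p)

    xbar = z1 / phi[:, None]
    loglik = float(eta[ev_idx].sum() - np.log(phi).sum())
    grad = X[ev_idx].sum(axis=0) - xbar.sum(axis=0)
    info = (z2 / phi[:, None, None]).sum(axis=0) - \
        np.einsum("mi,mj->ij", xbar, xbar)
    return loglik, grad, info


def cox_fit(time, event, covariates, ties: str = "efron",
            names: list[str] | None = None, max_iter: int = 50,
            tol: float = 1e-9, warn_small: bool = True) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    time, event : follow-up times and 0/1 event indicators.
    covariates : (n,) or (n, p) numeric design matrix.
    ties : ``"efron"`` (default) or ``"breslow"`` tie correction.

    Covariates are mean-centered internally (the estimate is invariant).
    Step-halving is applied whenever a Newton step decreases the partial
    likelihood.  Monotone likelihoods (perfect separation of events)
    raise :class:`NonConvergenceError` with the diverging direction.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if n < 2:
        raise ValueError("Cox fit needs at least 2 samples")
    if event.sum() < 1:
        raise InsufficientEventsError("Cox fit requires at least one event")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.nonzero(sd == 0)[0]]
        raise ConstantVariableError(f"constant covariate(s): {bad}")
    if warn_small and n < SMALL_SAMPLE_N:
        warnings.warn(
            f"Cox model fitted on n={n} < {SMALL_SAMPLE_N} samples; the "
            "model is not suitable for small sample sizes",
            SmallSampleWarning, stacklevel=2)

    order = np.argsort(time, kind="stable")
    time, event, X = time[order], event[order], X[order]
    center = X.mean(axis=0)
    Xc = X - center

    beta = np.zeros(p)
    loglik_null, _, _ = _cox_quantities(beta, time, event, Xc, ties)
    loglik = loglik_null
    converged = False
    for _ in range(max_iter):
        ll, grad, info = _cox_quantities(beta, time, event, Xc, ties)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise NonConvergenceError(
                "singular information matrix during Newton-Raphson",
                direction=np.sign(grad)) from None
        # step-halving if the likelihood would decrease
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new, _, _ = _cox_quantities(cand, time, event, Xc, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        # a coefficient of 10 per covariate SD means an astronomically
        # large HR: the partial likelihood is monotone (perfect separation)
        if np.max(np.abs(beta * sd)) > 10:
            raise NonConvergenceError(
                "monotone partial likelihood: a coefficient diverges "
                "(all events concentrate in one cohort, infinite HR)",
                direction=np.sign(beta))
        if np.max(np.abs(scale * step)) < tol or \
                abs(ll_new - ll) < tol * (abs(ll) + tol):
            loglik = ll_new
            converged = True
            break
        loglik = ll_new
    if not converged:
        raise NonConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations",
            direction=np.sign(beta))

    loglik, grad, info = _cox_quantities(beta, time, event, Xc, ties)
    try:
        var = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise NonConvergenceError("information matrix singular at optimum",
                                  direction=np.sign(beta)) from None
    se = np.sqrt(np.diag(var))
    zstat = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    lr = 2 * (loglik - loglik_null)
    global_p = float(stats.chi2.sf(max(lr, 0.0), df=p))

    return CoxResult(
        coefficients=beta, se=se, hr=np.exp(beta),
        ci_low=np.exp(beta - Z_95 * se), ci_high=np.exp(beta + Z_95 * se),
        p=pvals, global_p=global_p, loglik=loglik, loglik_null=loglik_null,
        ties_method=ties, n=n, n_events=int(event.sum()), names=list(names),
        var=var, _time=time, _event=event, _X=Xc,
    )


def cox_score_test(time, event, covariates, ties: str = "efron"):
    """Score (Rao) test of beta = 0; asymptotically the log-rank test for a
    single binary covariate.  Returns (chi2, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(time, kind="stable")
    time, event, X = time[order], event[order], X[order] - X.mean(axis=0)
    _, grad, info = _cox_quantities(np.zeros(X.shape[1]), time, event, X, ties)
    chi2 = float(grad @ np.linalg.solve(info, grad))
    return chi2, float(stats.chi2.sf(chi2, df=X.shape[1]))


def invert_hr(result: CoxResult) -> CoxResult:
    """Flip a univariate HR below 1 to its reciprocal above 1.

    A hazard ratio is a comparison against a baseline, so an HR of 0.5 for
    "high vs low" equals an HR of 2 for "low vs high"; the p-value is
    unchanged.  No-op when HR >= 1 or for multivariate fits.
    """
    if result.n_covariates != 1:
        raise ValueError("invert_hr applies to univariate results only")
    if result.hr[0] >= 1.0:
        return result
    return CoxResult(
        coefficients=-result.coefficients, se=result.se,
        hr=1.0 / result.hr,
        ci_low=1.0 / result.ci_high, ci_high=1.0 / result.ci_low,
        p=result.p, global_p=result.global_p, loglik=result.loglik,
        loglik_null=result.loglik_null, ties_method=result.ties_method,
        n=result.n, n_events=result.n_events, names=result.names,
        var=result.var, inverted=not result.inverted,
        _time=result._time, _event=result._event,
        _X=None if result._X is None else -result._X,
    )


# ---------------------------------------------------------------------------
# proportional-hazards assumption

@dataclass
class PHTestResult:
    """Grambsch-Therneau test on scaled Schoenfeld residuals."""

    p: np.ndarray          # per covariate
    chi2: np.ndarray
    global_p: float
    global_chi2: float
    transform: str
    names: list[str]

    def violations(self, alpha: float = 0.05) -> list[str]:
        return [n for n, pv in zip(self.names, self.p) if pv < alpha]


def schoenfeld_residuals(fit: CoxResult):
    """Raw Schoenfeld residuals ``x_i - xbar(t_i)`` at each event.

    With Efron ties each of the d tied events uses the average of the d
    Efron-weighted risk-set means.  Returns ``(event_times, residuals)``
    with one row per event, ordered by time.
    """
    time, event, X = fit._time, fit._event, fit._X
    if time is None:
        raise ValueError("fit does not retain its data")
    beta = fit.coefficients
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    wX = w[:, None] * X
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]

    ev_idx = np.nonzero(event == 1)[0]
    ev_times = time[ev_idx]
    uniq, block_start = np.unique(ev_times, return_index=True)
    d = np.diff(np.append(block_start, ev_idx.size))
    risk_first = np.searchsorted(time, uniq, side="left")
    S0r, S1r = S0[risk_first], S1[risk_first]
    S0d = np.add.reduceat(w[ev_idx], block_start)
    S1d = np.add.reduceat(wX[ev_idx], block_start, axis=0)

    xbar = np.empty((uniq.size, X.shape[1]))
    for k in range(uniq.size):
        if fit.ties_method == "breslow" or d[k] == 1:
            xbar[k] = S1r[k] / S0r[k]
        else:
            fr = np.arange(d[k]) / d[k]
            num = S1r[k][None, :] - fr[:, None] * S1d[k][None, :]
            den = S0r[k] - fr * S0d[k]
            xbar[k] = (num / den[:, None]).mean(axis=0)

    resid = X[ev_idx] - xbar[np.repeat(np.arange(uniq.size), d)]
    return ev_times, resid


def ph_assumption_test(fit: CoxResult, transform: str = "km") -> PHTestResult:
    """Test proportional hazards via scaled Schoenfeld residuals.

    The statistic correlates the residuals with a transform g(t) of the
    event times (``"km"``: left-continuous 1 - KM estimate, the default;
    ``"identity"``: raw time).  Per-covariate chi-square statistics use the
    fit's covariance; the global statistic pools all covariates.  A small
    p indicates a hazard ratio that changes with time.
    """
    if fit._time is None:
        raise ValueError("fit does not retain its data")
    m = int(fit._event.sum())
    if m < 3:
        raise InsufficientEventsError(
            f"proportional-hazards test needs >= 3 events, got {m}")
    ev_times, resid = schoenfeld_residuals(fit)

    if transform == "km":
        curve = km_estimate(fit._time, fit._event)
        # left-continuous S(t-): survival just before each event time
        idx = np.searchsorted(curve.event_times, ev_times, side="left") - 1
        s_minus = np.where(idx < 0, 1.0, curve.survival[np.maximum(idx, 0)])
        g = 1.0 - s_minus
    elif transform == "identity":
        g = ev_times.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    gss = float(gc @ gc)
    if gss <= 0:
        raise InsufficientEventsError("degenerate time transform (all events "
                                      "at one time)")

    V = fit.var
    u = resid.T @ gc                                  # (p,)
    test = gc @ (resid @ V) * m                       # per-covariate score
    per_chi2 = test ** 2 / (np.diag(V) * m * gss)
    per_p = stats.chi2.sf(per_chi2, df=1)
    global_chi2 = float(u @ V @ u * m / gss)
    global_p = float(stats.chi2.sf(global_chi2, df=fit.n_covariates))
    return PHTestResult(p=per_p, chi2=per_chi2, global_p=global_p,
                        global_chi2=global_chi2, transform=transform,
                        names=list(fit.names))
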