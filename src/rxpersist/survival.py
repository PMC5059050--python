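"""Kaplan-Meier and Cox proportional-hazards estimation.

Both estimators are implemented here from first principles; external
survival packages are used in the test suite only, as independent
cross-checks.

Kaplan-Meier
------------
The product-limit estimator of the survivor function,

.. math:: \\hat S(t) = \\prod_{t_k \\le t} \\Bigl(1 - \\frac{d_k}{n_k}\\Bigr),

with :math:`d_k` events and :math:`n_k` subjects at risk at the
:math:`k`-th distinct event time.  Censored observations leave the risk
set just after their time.  The running product is accumulated in exact
rational arithmetic and exposed as floats, and each step carries the
Greenwood standard error

.. math:: \\widehat{se}(t) = \\hat S(t)
          \\sqrt{\\sum_{t_k \\le t} \\frac{d_k}{n_k (n_k - d_k)}}.

Cox regression
--------------
Newton-Raphson maximization of the log partial likelihood with either
the Efron (default) or Breslow correction for tied event times.
Standard errors come from the inverse observed information at the
maximum; confidence intervals are Wald intervals on the log-hazard
scale, and P values are two-tailed Wald tests.  Day-resolution
discontinuation data produce many ties, which is why Efron is the
default: it is the more accurate of the two standard corrections when
ties are common, and the two agree exactly on tie-free data.

Newton steps use step-halving, so the log partial likelihood is
non-decreasing across iterations; convergence requires the gradient
max-norm below ``tol`` (default 1e-9) or a relative log-likelihood
change below 1e-12.  Non-convergence is flagged on the returned fit,
never silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import CollinearityError

logger = logging.getLogger("rxpersist.survival")

Z975 = float(stats.norm.ppf(0.975))  # 1.959964...: 95% Wald multiplier


@dataclass(frozen=True)
class SurvivalSample:
    """One subject: follow-up time (days), event flag, named covariates."""

    time: float
    event: bool
    covariates: dict[str, float] = field(default_factory=dict)


def _unpack(samples_or_durations, events=None):
    if events is None:
        samples = list(samples_or_durations)
        durations = np.asarray([s.time for s in samples], dtype=float)
        observed = np.asarray([s.event for s in samples], dtype=bool)
    else:
        durations = np.asarray(samples_or_durations, dtype=float)
        observed = np.asarray(events, dtype=bool)
    return durations, observed


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_samples: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function evaluation of S(t)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
                "greenwood_se": self.greenwood_se,
            }
        )


def km_estimate(samples_or_durations, events=None) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Accepts either a list of :class:`SurvivalSample` or two arrays
    ``(durations, events)``.
    """
    durations, observed = _unpack(samples_or_durations, events)
    if durations.size == 0:
        raise ValueError("km_estimate requires at least one sample")
    if np.any(durations <= 0):
        raise ValueError("survival times must be positive")

    order = np.argsort(durations, kind="stable")
    t_sorted = durations[order]
    e_sorted = observed[order]
    n = t_sorted.size

    event_times = np.unique(t_sorted[e_sorted])
    n_at_risk = n - np.searchsorted(t_sorted, event_times, side="left")
    n_events = np.array(
        [int(np.sum(e_sorted[t_sorted == t])) for t in event_times], dtype=int
    )

    surv = np.empty(event_times.size, dtype=float)
    se = np.empty(event_times.size, dtype=float)
    prod = Fraction(1)
    gw = 0.0
    for k, (nk, dk) in enumerate(zip(n_at_risk, n_events)):
        prod *= Fraction(int(nk) - int(dk), int(nk))
        surv[k] = float(prod)
        if nk > dk:
            gw += dk / (nk * (nk - dk))
            se[k] = surv[k] * np.sqrt(gw)
        else:
            se[k] = np.nan  # S has hit zero; Greenwood variance is undefined
    return KMCurve(
        event_times=event_times.astype(float),
        n_at_risk=n_at_risk.astype(int),
        n_events=n_events,
        survival=surv,
        greenwood_se=se,
        n_samples=n,
    )


def km_survival_at(curve: KMCurve, t_days: float) -> float:
    """Survivor-function readout at ``t_days`` (right-continuous)."""
    return curve.survival_at(t_days)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_samples: int
    n_events: int
    converged: bool
    ties_method: str
    n_iter: int
    loglik_path: list[float]

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        return np.exp(self.coef - Z975 * self.se), np.exp(self.coef + Z975 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        z = np.abs(self.coef) / self.se
        return 2.0 * stats.norm.sf(z)

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci95
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_lower": lo,
                "hr_ci_upper": hi,
                "p": self.p_values,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    Xc = X - X.mean(axis=0)
    _, R, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size and diag[0] > 0 else 1.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in sorted(piv[rank:])]
        raise CollinearityError(bad)


def _loglik_grad_info(beta, Xs, ts, es, ties_method):
    """Log partial likelihood, gradient and observed information.

    ``Xs``/``ts``/``es`` must be sorted by ascending time.  The linear
    predictor is shifted by its maximum before exponentiation so risk
    sums never overflow.
    """
    n, p = Xs.shape
    eta = Xs @ beta
    c = eta.max() if n else 0.0
    w = np.exp(eta - c)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    # suffix sums: index i holds the sum over the risk set {j : t_j >= t_i}
    cum0 = np.cumsum(w[::-1])[::-1]
    cum1 = np.cumsum(wx[::-1], axis=0)[::-1]
    cum2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    et = ts[es]
    uniq, starts, counts = np.unique(et, return_index=True, return_counts=True)
    ex = Xs[es]
    sum_x = np.add.reduceat(ex, starts, axis=0)
    sum_eta = np.add.reduceat(eta[es], starts)
    r = np.searchsorted(ts, uniq, side="left")
    S0R = cum0[r]
    S1R = cum1[r]
    S2R = cum2[r]

    ll = float(np.sum(sum_eta))
    grad = sum_x.sum(axis=0).astype(float)
    info = np.zeros((p, p))

    singles = counts == 1
    if np.any(singles):
        phi = S0R[singles]
        Zbar = S1R[singles] / phi[:, None]
        ll -= float(np.sum(np.log(phi) + c))
        grad -= Zbar.sum(axis=0)
        info += np.einsum("kij,k->ij", S2R[singles], 1.0 / phi)
        info -= np.einsum("ki,kj->ij", Zbar, Zbar)

    for g in np.nonzero(~singles)[0]:
        d = int(counts[g])
        lo = starts[g]
        idx = slice(lo, lo + d)
        S0D = float(np.sum(w[es][idx]))
        S1D = wx[es][idx].sum(axis=0)
        S2D = wxx[es][idx].sum(axis=0)
        for l in range(d):
            if ties_method == "efron":
                f = l / d
            else:  # breslow
                f = 0.0
            phi = S0R[g] - f * S0D
            Z = S1R[g] - f * S1D
            M = S2R[g] - f * S2D
            ll -= float(np.log(phi) + c)
            grad -= Z / phi
            info += M / phi - np.outer(Z, Z) / phi**2
    return ll, grad, info


def cox_fit(
    X,
    durations=None,
    events=None,
    ties_method: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
    names: Optional[Sequence[str]] = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``X`` may be a pandas DataFrame (column names become covariate
    names) or a 2-D array.  Alternatively pass a list of
    :class:`SurvivalSample` as the only positional argument.
    Raises on empty input, zero events, or a rank-deficient design
    (naming the collinear columns); flags non-convergence on the result.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties_method: {ties_method!r}")
    if durations is None and events is None and not isinstance(X, (pd.DataFrame, np.ndarray)):
        samples = list(X)
        if not samples:
            raise ValueError("cox_fit requires at least one sample")
        names = list(samples[0].covariates.keys())
        X = np.array([[s.covariates[k] for k in names] for s in samples], dtype=float)
        durations = np.array([s.time for s in samples], dtype=float)
        events = np.array([s.event for s in samples], dtype=bool)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("cox_fit requires at least one sample")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("survival times must be positive and finite")
    if not np.any(e):
        raise ValueError("cox_fit requires at least one event")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    _check_rank(X, names)

    # fit on a centered/scaled design for well-conditioned Newton steps
    # (the partial likelihood is invariant to centering; coefficients and
    # standard errors are mapped back to the original scale afterwards)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xw = (X - center) / scale

    order = np.argsort(t, kind="stable")
    Xs, ts, es = Xw[order], t[order], e[order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _loglik_grad_info(beta, Xs, ts, es, ties_method)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        step_size = 1.0
        accepted = False
        for _ in range(40):
            cand = beta + step_size * step
            ll_new, grad_new, info_new = _loglik_grad_info(cand, Xs, ts, es, ties_method)
            if ll_new >= ll - 1e-13:
                accepted = True
                break
            step_size *= 0.5
        if not accepted:
            break
        rel_change = abs(ll_new - ll) / (abs(ll) + 1.0)
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        path.append(ll)
        if rel_change < 1e-12:
            converged = True
            break
    if np.max(np.abs(grad)) < tol:
        converged = True
    if not converged:
        logger.warning(
            "Cox fit did not converge after %d iterations (max |grad| = %.3e)",
            it, float(np.max(np.abs(grad))),
        )

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    # back-transform from the standardized to the original covariate scale
    beta = beta / scale
    se = se / scale
    return CoxFit(
        names=list(names),
        coef=beta,
        se=se,
        loglik=ll,
        n_samples=int(t.size),
        n_events=int(e.sum()),
        converged=converged,
        ties_method=ties_method,
        n_iter=it,
        loglik_path=path,
    )
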