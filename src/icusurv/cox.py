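"""Cox proportional-hazards machinery.

The survival model throughout the package is

    S(t | x) = S0(t) ** exp(psi(x))

with a baseline survival function ``S0`` shared by all subjects and a
per-subject log-relative-hazard ``psi``.  This module provides the pieces the
rest of the package composes:

* :func:`cox_partial_log_likelihood` — the Breslow (or Efron) log partial
  likelihood of a vector of risk scores; its negative is the training loss of
  the neural risk model.
* :func:`cox_partial_loglik_gradient` — the analytic gradient with respect to
  the scores, used both for Newton fitting and for backpropagation.
* :func:`fit_linear_cox` — Newton–Raphson maximum partial likelihood for the
  linear model ``psi(x) = x @ beta``, with Wald standard errors, hazard
  ratios, 95% confidence intervals and two-sided p-values.
* :func:`breslow_baseline` / :func:`survival_function` — the Breslow step
  estimator of ``S0`` and per-subject survival curves.

All functions take plain arrays: ``times`` (observed time, > 0), ``events``
(1 = death observed, 0 = censored) and ``scores``/``X``.  Ties are handled by
the Breslow approximation by default; Efron is available via ``ties=``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BaselineSurvival",
    "FittedCoxModel",
    "SurvivalCurve",
    "ConvergenceError",
    "cox_partial_log_likelihood",
    "cox_partial_loglik_gradient",
    "fit_linear_cox",
    "breslow_baseline",
    "survival_function",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last iterate in ``last_beta``."""

    def __init__(self, message: str, last_beta: np.ndarray | None = None):
        super().__init__(message)
        self.last_beta = last_beta


def _check_inputs(scores, times, events):
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not (scores.shape == times.shape == events.shape):
        raise ValueError(
            f"length mismatch: scores {scores.shape}, times {times.shape}, events {events.shape}"
        )
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite risk score")
    if events.sum() == 0:
        raise ValueError("no events: partial likelihood undefined")
    return scores, times, events.astype(bool)


def cox_partial_log_likelihood(scores, times, events, ties: str = "breslow") -> float:
    """Log partial likelihood of risk scores for right-censored outcomes.

    Invariant to adding a constant to all scores.  ``ties="breslow"`` (default)
    or ``"efron"``.
    """
    scores, times, events = _check_inputs(scores, times, events)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    shift = scores.max()
    s = scores - shift
    e = np.exp(s)
    ll = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        dead = events & (times == t)
        d = int(dead.sum())
        denom = e[at_risk].sum()
        ll += s[dead].sum()
        if ties == "breslow":
            ll -= d * np.log(denom)
        else:
            tied = e[dead].sum()
            ll -= sum(np.log(denom - (l / d) * tied) for l in range(d))
    return float(ll)


def cox_partial_loglik_gradient(scores, times, events) -> np.ndarray:
    """d(log partial likelihood)/d(score_i), Breslow ties.

    For each subject i:  delta_i − sum over event times t_k <= y_i of
    d_k * exp(psi_i) / sum_{j at risk at t_k} exp(psi_j).
    """
    scores, times, events = _check_inputs(scores, times, events)
    shift = scores.max()
    e = np.exp(scores - shift)
    grad = events.astype(float).copy()
    event_times, d_k = np.unique(times[events], return_counts=True)
    # denominators per event time
    denoms = np.array([e[times >= t].sum() for t in event_times])
    # subject i is in the risk set of every event time <= y_i
    # accumulate d_k/denom_k over k with t_k <= y_i
    ratio = d_k / denoms
    cum = np.concatenate([[0.0], np.cumsum(ratio)])
    idx = np.searchsorted(event_times, times, side="right")
    grad -= e * cum[idx]
    return grad


def _breslow_score_stats(X, beta, times, events):
    """Log-lik, score vector and observed information for linear psi = X @ beta."""
    psi = X @ beta
    shift = psi.max()
    e = np.exp(psi - shift)
    n, p = X.shape
    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    for t in np.unique(times[events]):
        at_risk = times >= t
        dead = events & (times == t)
        d = int(dead.sum())
        w = e[at_risk]
        Xr = X[at_risk]
        S0 = w.sum()
        S1 = w @ Xr
        S2 = (Xr * w[:, None]).T @ Xr
        xbar = S1 / S0
        ll += (psi[dead] - shift).sum() - d * np.log(S0)
        U += X[dead].sum(axis=0) - d * xbar
        I += d * (S2 / S0 - np.outer(xbar, xbar))
    return ll, U, I


@dataclass
class BaselineSurvival:
    """Breslow baseline survival step function (right-continuous).

    ``times`` are the ordered distinct event times; ``s0[k]`` is S0 at
    ``times[k]``; S0 = 1 before the first event time.
    """

    times: np.ndarray
    s0: np.ndarray

    def at(self, t) -> np.ndarray:
        """Evaluate S0 at time(s) t (1 before the first event)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[1.0], self.s0])
        return vals[idx]


@dataclass
class SurvivalCurve:
    """A subject's survival function evaluated on the baseline's event grid."""

    times: np.ndarray
    values: np.ndarray

    def at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]


@dataclass
class FittedCoxModel:
    """A fitted linear Cox model with Wald inference.

    ``hazard_ratios == exp(coefficients)``; confidence intervals are
    ``exp(beta ± z * se)`` at the configured level; p-values are two-sided
    Wald tests of beta = 0.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    baseline: BaselineSurvival
    convergence_info: dict
    names: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        names = self.names or [f"x{i}" for i in range(len(self.coefficients))]
        return pd.DataFrame(
            {
                "covariate": names,
                "coef": self.coefficients,
                "se": self.standard_errors,
                "hazard_ratio": self.hazard_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_values,
            }
        )

    def to_json(self) -> str:
        payload = {
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "hazard_ratios": self.hazard_ratios.tolist(),
            "ci_lower": self.ci_lower.tolist(),
            "ci_upper": self.ci_upper.tolist(),
            "p_values": self.p_values.tolist(),
            "names": self.names,
            "convergence_info": self.convergence_info,
        }
        return json.dumps(payload, indent=2)

    def hr_table(self) -> pd.DataFrame:
        """One row per covariate: Abnormality, Hazard ratio, 95% CI, P."""
        names = self.names or [f"x{i}" for i in range(len(self.coefficients))]
        return pd.DataFrame(
            {
                "Abnormality": names,
                "Hazard ratio": np.round(self.hazard_ratios, 2),
                "95% CI": [
                    f"{lo:.2f}-{hi:.2f}" for lo, hi in zip(self.ci_lower, self.ci_upper)
                ],
                "P": [f"{p:.2g}" for p in self.p_values],
            }
        )

    def predict_risk(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients


def fit_linear_cox(
    X,
    times,
    events,
    *,
    names: Sequence[str] | None = None,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
    alpha: float = 0.05,
) -> FittedCoxModel:
    """Maximum partial likelihood fit of ``psi(x) = x @ beta``.

    Newton–Raphson with step-halving until the gradient norm drops below
    ``tol * sqrt(max(1, number of events))`` (the score scales with the event
    count, so the tolerance must too); Wald standard errors from the inverse
    observed information.

    Raises ``ValueError`` for degenerate design matrices (n <= p, constant
    columns) and :class:`ConvergenceError` (carrying the last iterate) on
    non-convergence or separation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if events.sum() == 0:
        raise ValueError("no events")
    span = X.max(axis=0) - X.min(axis=0)
    if np.any(span == 0):
        bad = int(np.argmax(span == 0))
        raise ValueError(f"covariate column {bad} has zero variance")
    if ties == "efron":
        return _fit_efron(X, times, events, names, max_iter, tol, alpha)
    if ties != "breslow":
        raise ValueError(f"unknown tie method {ties!r}")

    beta = np.zeros(p)
    tol_eff = tol * np.sqrt(max(1.0, float(events.sum())))
    ll, U, I = _breslow_score_stats(X, beta, times, events)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}", beta) from exc
        # step-halving line search: accept only likelihood increases
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, U_new, I_new = _breslow_score_stats(X, cand, times, events)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        else:
            raise ConvergenceError("line search failed to increase likelihood", beta)
        beta, ll, U, I = cand, ll_new, U_new, I_new
        if np.abs(beta).max() > 30:
            raise ConvergenceError(
                "coefficients diverging (|beta| > 30): likely separation / monotone likelihood",
                beta,
            )
        if np.linalg.norm(U) < tol_eff:
            break
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (grad norm {np.linalg.norm(U):.2e})",
            beta,
        )

    cov = np.linalg.inv(I)
    se = np.sqrt(np.diag(cov))
    # monotone likelihood: gradient can vanish numerically while the MLE is
    # unbounded; the information collapses, so flag absurd SEs on the scale
    # of the covariate span
    if np.any(se * span > 50):
        bad = int(np.argmax(se * span))
        raise ConvergenceError(
            f"separation suspected: covariate {bad} has essentially infinite SE",
            beta,
        )
    z = stats.norm.ppf(1 - alpha / 2)
    hr = np.exp(beta)
    pvals = 2 * stats.norm.sf(np.abs(beta / se))
    baseline = breslow_baseline(X @ beta, times, events)
    with np.errstate(over="ignore"):  # huge SEs legitimately give inf CI bounds
        ci_lo, ci_hi = np.exp(beta - z * se), np.exp(beta + z * se)
    return FittedCoxModel(
        coefficients=beta,
        standard_errors=se,
        hazard_ratios=hr,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p_values=pvals,
        baseline=baseline,
        convergence_info={
            "iterations": n_iter,
            "final_gradient_norm": float(np.linalg.norm(U)),
            "log_partial_likelihood": float(ll),
            "ties": "breslow",
        },
        names=list(names) if names is not None else [],
    )


def _efron_stats(X, beta, times, events):
    psi = X @ beta
    shift = psi.max()
    e = np.exp(psi - shift)
    p = X.shape[1]
    ll, U, I = 0.0, np.zeros(p), np.zeros((p, p))
    for t in np.unique(times[events]):
        at_risk = times >= t
        dead = events & (times == t)
        d = int(dead.sum())
        w = e[at_risk]
        Xr = X[at_risk]
        S0, S1 = w.sum(), w @ Xr
        S2 = (Xr * w[:, None]).T @ Xr
        wd = e[dead]
        Xd = X[dead]
        T0, T1 = wd.sum(), wd @ Xd
        T2 = (Xd * wd[:, None]).T @ Xd
        ll += (psi[dead] - shift).sum()
        for l in range(d):
            f = l / d
            D0 = S0 - f * T0
            D1 = S1 - f * T1
            D2 = S2 - f * T2
            xbar = D1 / D0
            ll -= np.log(D0)
            U += -xbar
            I += D2 / D0 - np.outer(xbar, xbar)
        U += Xd.sum(axis=0)
    return ll, U, I


def _fit_efron(X, times, events, names, max_iter, tol, alpha):
    p = X.shape[1]
    beta = np.zeros(p)
    tol = tol * np.sqrt(max(1.0, float(events.sum())))
    ll, U, I = _efron_stats(X, beta, times, events)
    for n_iter in range(1, max_iter + 1):
        step = np.linalg.solve(I, U)
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, U_new, I_new = _efron_stats(X, cand, times, events)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        beta, ll, U, I = cand, ll_new, U_new, I_new
        if np.abs(beta).max() > 30:
            raise ConvergenceError("separation suspected", beta)
        if np.linalg.norm(U) < tol:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", beta)
    cov = np.linalg.inv(I)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(1 - alpha / 2)
    baseline = breslow_baseline(X @ beta, times, events)
    return FittedCoxModel(
        coefficients=beta,
        standard_errors=se,
        hazard_ratios=np.exp(beta),
        ci_lower=np.exp(beta - z * se),
        ci_upper=np.exp(beta + z * se),
        p_values=2 * stats.norm.sf(np.abs(beta / se)),
        baseline=baseline,
        convergence_info={
            "iterations": n_iter,
            "final_gradient_norm": float(np.linalg.norm(U)),
            "log_partial_likelihood": float(ll),
            "ties": "efron",
        },
        names=list(names) if names is not None else [],
    )


def breslow_baseline(scores, times, events) -> BaselineSurvival:
    """Breslow estimator of the baseline survival function.

    H0(t) = sum over event times t_k <= t of d_k / sum_{j at risk} exp(psi_j),
    and S0 = exp(−H0).  Scores enter unshifted: the baseline is tied to the
    scale of psi (psi = 0 is the reference subject).
    """
    scores, times, events = _check_inputs(scores, times, events)
    e = np.exp(scores)
    event_times, d_k = np.unique(times[events], return_counts=True)
    denoms = np.array([e[times >= t].sum() for t in event_times])
    h0 = np.cumsum(d_k / denoms)
    return BaselineSurvival(times=event_times, s0=np.exp(-h0))


def survival_function(baseline: BaselineSurvival, score: float) -> SurvivalCurve:
    """Per-subject survival curve S(t | x) = S0(t) ** exp(psi)."""
    score = float(score)
    if not np.isfinite(score):
        raise ValueError("non-finite risk score")
    return SurvivalCurve(times=baseline.times, values=baseline.s0 ** np.exp(score))
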