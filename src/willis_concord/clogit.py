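"""Exact conditional logistic regression for matched events/trials pairs.

Each stratum is a matched pair of binomial arms: an index arm with ``a``
events in ``n1`` trials and a comparison arm with ``b`` events in ``n2``
trials. Conditioning on the stratum total ``t = a + b`` eliminates the
stratum nuisance parameter and leaves Fisher's noncentral hypergeometric
likelihood for the common log odds ratio beta:

    P(A = a | t) = C(n1, a) C(n2, t - a) e^{beta a}
                   / sum_u C(n1, u) C(n2, t - u) e^{beta u},

with ``u`` ranging over ``max(0, t - n2) .. min(n1, t)``. Strata with
``t = 0`` or ``t = n1 + n2`` carry no information and contribute zero
log-likelihood. The maximum-likelihood estimate solves the score equation
``sum_s a_s = sum_s E_beta[U_s]`` and is found by Newton iteration with the
conditional variance as information; the Wald confidence interval is taken
on the log-odds scale.

All binomial coefficients are handled in log space and the normalising sums
with log-sum-exp, so trials in the hundreds are safe.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import FitError, UsageError

__all__ = ["Stratum", "FitResult", "stratum_loglik", "fit", "Z_95"]

Z_95 = 1.959964  # two-sided 95% normal quantile, fixed


@dataclass(frozen=True)
class Stratum:
    """One matched index/comparison pair as two events/trials counts."""

    index_events: int
    index_trials: int
    comparison_events: int
    comparison_trials: int

    def __post_init__(self) -> None:
        for events, trials, arm in (
            (self.index_events, self.index_trials, "index"),
            (self.comparison_events, self.comparison_trials, "comparison"),
        ):
            if trials < 1:
                raise UsageError(f"{arm} trials must be >= 1")
            if not 0 <= events <= trials:
                raise UsageError(f"{arm} events must be in [0, trials]")

    @property
    def total(self) -> int:
        return self.index_events + self.comparison_events

    @property
    def informative(self) -> bool:
        """A stratum constrains beta only if 0 < t < n1 + n2."""
        return 0 < self.total < self.index_trials + self.comparison_trials

    @property
    def support(self) -> tuple[int, int]:
        """Range of possible index-arm event counts given the total."""
        t = self.total
        return max(0, t - self.comparison_trials), min(self.index_trials, t)


@dataclass(frozen=True)
class FitResult:
    """Common odds ratio estimate with a Wald 95% CI on the log scale."""

    beta_hat: float
    se: float
    or_hat: float
    ci_low: float
    ci_high: float
    converged: bool
    n_informative_strata: int

    def __str__(self) -> str:
        status = "" if self.converged else " [not converged]"
        return f"OR {self.or_hat:.3g} (95% CI {self.ci_low:.3g}-{self.ci_high:.3g}){status}"


def _log_weights(s: Stratum) -> tuple[np.ndarray, np.ndarray]:
    """Support values u and log[C(n1,u) C(n2,t-u)] for one stratum."""
    lo, hi = s.support
    u = np.arange(lo, hi + 1)
    n1, n2, t = s.index_trials, s.comparison_trials, s.total
    logw = (
        gammaln(n1 + 1) - gammaln(u + 1) - gammaln(n1 - u + 1)
        + gammaln(n2 + 1) - gammaln(t - u + 1) - gammaln(n2 - (t - u) + 1)
    )
    return u, logw


def stratum_loglik(beta: float, s: Stratum) -> float:
    """Conditional log-likelihood contribution of one stratum at ``beta``."""
    if not s.informative:
        return 0.0
    u, logw = _log_weights(s)
    a = s.index_events
    return float(logw[a - u[0]] + beta * a - logsumexp(logw + beta * u))


def _prepare(strata: Sequence[Stratum]):
    """Pad per-stratum supports into rectangular arrays for vectorised Newton."""
    widths = [s.support[1] - s.support[0] + 1 for s in strata]
    w = max(widths)
    n = len(strata)
    u_mat = np.zeros((n, w))
    logw_mat = np.full((n, w), -np.inf)
    a = np.empty(n)
    for i, s in enumerate(strata):
        u, logw = _log_weights(s)
        u_mat[i, : u.size] = u
        logw_mat[i, : u.size] = logw
        a[i] = s.index_events
    return a, u_mat, logw_mat


def _moments(beta: float, a, u_mat, logw_mat):
    """Score and information of the conditional likelihood at ``beta``."""
    eta = logw_mat + beta * u_mat
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    e = (p * u_mat).sum(axis=1)
    var = (p * u_mat**2).sum(axis=1) - e**2
    return float(a.sum() - e.sum()), float(var.sum())


def fit(strata: Sequence[Stratum], max_iter: int = 50) -> FitResult:
    """Maximum conditional likelihood common odds ratio over matched strata.

    Raises
    ------
    FitError
        If no stratum is informative.

    Notes
    -----
    When every informative stratum sits at the same extreme of its support
    (complete separation), no finite maximiser exists; the result carries
    ``converged=False`` and a signed-infinite ``beta_hat`` indicating the
    direction.
    """
    informative = [s for s in strata if s.informative]
    if not informative:
        raise FitError("no informative strata (every total is 0 or n1+n2)")

    total = sum(s.index_events for s in informative)
    t_min = sum(s.support[0] for s in informative)
    t_max = sum(s.support[1] for s in informative)
    if total == t_max or total == t_min:
        sign = 1.0 if total == t_max else -1.0
        return FitResult(
            beta_hat=sign * math.inf,
            se=math.nan,
            or_hat=math.inf if sign > 0 else 0.0,
            ci_low=math.nan,
            ci_high=math.nan,
            converged=False,
            n_informative_strata=len(informative),
        )

    a, u_mat, logw_mat = _prepare(informative)
    beta = 0.0
    converged = False
    info = math.nan
    for _ in range(max_iter):
        score, info = _moments(beta, a, u_mat, logw_mat)
        step = score / info
        beta += step
        if abs(score) < 1e-8 or abs(step) < 1e-10:
            converged = True
            break
    # se at the final estimate
    _, info = _moments(beta, a, u_mat, logw_mat)
    se = 1.0 / math.sqrt(info)
    return FitResult(
        beta_hat=beta,
        se=se,
        or_hat=math.exp(beta),
        ci_low=math.exp(beta - Z_95 * se),
        ci_high=math.exp(beta + Z_95 * se),
        converged=converged,
        n_informative_strata=len(informative),
    )
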