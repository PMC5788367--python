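"""Conditional logistic events/trials fit against independent oracles.

Two oracles are used: a direct summation of the conditional likelihood with
exact integer binomial coefficients (for the per-stratum log-likelihood)
and a dense grid search maximising that same likelihood (for the
estimate). A third, fully external route expands each stratum into one
binary row per trial and fits statsmodels' ConditionalLogit, which
maximises the identical conditional likelihood.
"""
import math

import numpy as np
import pytest

from willis_concord import FitResult, Stratum, fit, stratum_loglik
from willis_concord.errors import FitError, UsageError


def oracle_loglik(beta: float, s: Stratum) -> float:
    """Direct summation with exact binomial coefficients."""
    n1, n2 = s.index_trials, s.comparison_trials
    a, t = s.index_events, s.total
    if t == 0 or t == n1 + n2:
        return 0.0
    denom = sum(
        math.comb(n1, u) * math.comb(n2, t - u) * math.exp(beta * u)
        for u in range(max(0, t - n2), min(n1, t) + 1)
    )
    num = math.comb(n1, a) * math.comb(n2, t - a) * math.exp(beta * a)
    return math.log(num / denom)


def grid_argmax(strata, lo=-10.0, hi=10.0, step=1e-4):
    """Vectorised grid search of the summed conditional log-likelihood."""
    betas = np.arange(lo, hi + step, step)
    total = np.zeros_like(betas)
    for s in strata:
        if not s.informative:
            continue
        u_lo, u_hi = s.support
        u = np.arange(u_lo, u_hi + 1)
        logw = np.array(
            [math.log(math.comb(s.index_trials, v) * math.comb(s.comparison_trials, s.total - v)) for v in u]
        )
        eta = logw[None, :] + betas[:, None] * u[None, :]
        m = eta.max(axis=1)
        total += logw[np.searchsorted(u, s.index_events)] + betas * s.index_events
        total -= m + np.log(np.exp(eta - m[:, None]).sum(axis=1))
    return betas[int(np.argmax(total))]


@pytest.mark.parametrize("beta", [-2.0, -0.5, 0.0, 0.5, 1.7])
@pytest.mark.parametrize(
    "stratum",
    [
        Stratum(3, 5, 1, 4),
        Stratum(0, 3, 2, 4),
        Stratum(2, 2, 3, 6),
        Stratum(1, 1, 0, 1),
    ],
)
def test_stratum_loglik_matches_direct_summation(beta, stratum):
    assert stratum_loglik(beta, stratum) == pytest.approx(oracle_loglik(beta, stratum), abs=1e-12)


@pytest.mark.parametrize("stratum", [Stratum(0, 3, 0, 4), Stratum(5, 5, 4, 4)])
def test_degenerate_stratum_contributes_zero(stratum):
    for beta in (-3.0, 0.0, 2.5):
        assert stratum_loglik(beta, stratum) == 0.0


def test_loglik_at_zero_is_central_hypergeometric():
    s = Stratum(2, 5, 1, 4)
    # P(A=2 | t=3) under the central hypergeometric
    t = s.total
    p = math.comb(5, 2) * math.comb(4, 1) / sum(
        math.comb(5, u) * math.comb(4, t - u) for u in range(0, t + 1)
    )
    assert stratum_loglik(0.0, s) == pytest.approx(math.log(p), abs=1e-12)
    assert stratum_loglik(0.0, s) <= 0.0


def all_single_stratum_configs(max_trials=6):
    """Every informative, non-separated single stratum with trials <= max_trials."""
    configs = []
    for n1 in range(1, max_trials + 1):
        for n2 in range(1, max_trials + 1):
            for a in range(n1 + 1):
                for b in range(n2 + 1):
                    s = Stratum(a, n1, b, n2)
                    if not s.informative:
                        continue
                    lo, hi = s.support
                    if a in (lo, hi):  # separated: no finite maximiser
                        continue
                    configs.append(s)
    return configs


def test_fit_matches_grid_search_on_all_small_strata():
    """Newton estimate equals the dense-grid maximiser (step 1e-4) for every
    informative non-separated stratum with both arms at most 6 trials."""
    configs = all_single_stratum_configs(6)
    assert len(configs) > 100
    for s in configs:
        result = fit([s])
        assert result.converged
        assert result.beta_hat == pytest.approx(grid_argmax([s]), abs=2e-4)


def test_fit_matches_grid_search_on_multi_strata():
    strata = [Stratum(3, 5, 1, 4), Stratum(2, 3, 2, 5), Stratum(0, 2, 1, 2)]
    result = fit(strata)
    assert result.beta_hat == pytest.approx(grid_argmax(strata), abs=2e-4)


def test_antisymmetry_under_arm_swap():
    strata = [Stratum(3, 5, 1, 4), Stratum(2, 3, 2, 5), Stratum(1, 2, 1, 3)]
    swapped = [
        Stratum(s.comparison_events, s.comparison_trials, s.index_events, s.index_trials)
        for s in strata
    ]
    r1, r2 = fit(strata), fit(swapped)
    assert r1.beta_hat == pytest.approx(-r2.beta_hat, abs=1e-9)
    assert r1.se == pytest.approx(r2.se, abs=1e-9)


def test_degenerate_strata_do_not_shift_the_fit():
    strata = [Stratum(3, 5, 1, 4), Stratum(1, 3, 2, 4)]
    padded = strata + [Stratum(0, 3, 0, 4), Stratum(5, 5, 4, 4)]
    r1, r2 = fit(strata), fit(padded)
    assert r1.beta_hat == pytest.approx(r2.beta_hat, abs=1e-12)
    assert r1.se == pytest.approx(r2.se, abs=1e-12)


def test_score_equation_holds_at_optimum():
    """For a single stratum the MLE satisfies a = E_beta[U]."""
    s = Stratum(3, 5, 1, 4)
    r = fit([s])
    u = np.arange(s.support[0], s.support[1] + 1)
    w = np.array(
        [math.comb(s.index_trials, v) * math.comb(s.comparison_trials, s.total - v) for v in u]
    ) * np.exp(r.beta_hat * u)
    assert (w * u).sum() / w.sum() == pytest.approx(s.index_events, abs=1e-6)


def test_symmetric_strata_give_or_one():
    r = fit([Stratum(2, 4, 2, 4), Stratum(1, 3, 1, 3)])
    assert r.beta_hat == pytest.approx(0.0, abs=1e-9)
    assert r.or_hat == pytest.approx(1.0, abs=1e-9)


def test_separation_is_flagged():
    r = fit([Stratum(5, 5, 0, 4)])
    assert not r.converged
    assert r.beta_hat == math.inf
    r = fit([Stratum(0, 5, 4, 4)])
    assert not r.converged
    assert r.beta_hat == -math.inf


def test_no_informative_strata_raises():
    with pytest.raises(FitError):
        fit([Stratum(0, 3, 0, 4), Stratum(5, 5, 4, 4)])


def test_invalid_counts_rejected():
    with pytest.raises(UsageError):
        Stratum(4, 3, 0, 1)
    with pytest.raises(UsageError):
        Stratum(0, 0, 0, 1)


def test_wald_ci_construction():
    r = fit([Stratum(3, 5, 1, 4), Stratum(2, 3, 1, 5)])
    assert r.ci_low == pytest.approx(math.exp(r.beta_hat - 1.959964 * r.se), rel=1e-12)
    assert r.ci_high == pytest.approx(math.exp(r.beta_hat + 1.959964 * r.se), rel=1e-12)
    assert r.ci_low < r.or_hat < r.ci_high


def test_matches_statsmodels_conditional_logit():
    """Expanding events/trials to per-subject binary rows and fitting
    statsmodels' ConditionalLogit (same conditional likelihood, independent
    implementation) reproduces the estimate and standard error."""
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.conditional_models import ConditionalLogit

    strata = [Stratum(3, 5, 1, 4), Stratum(2, 3, 2, 5), Stratum(1, 2, 1, 3), Stratum(0, 4, 2, 3)]
    y, x, groups = [], [], []
    for g, s in enumerate(strata):
        for arm, events, trials in (
            (1, s.index_events, s.index_trials),
            (0, s.comparison_events, s.comparison_trials),
        ):
            for i in range(trials):
                y.append(1 if i < events else 0)
                x.append(arm)
                groups.append(g)
    model = ConditionalLogit(np.array(y), np.array(x)[:, None], groups=np.array(groups))
    ref = model.fit(disp=False)
    ours = fit(strata)
    assert ours.beta_hat == pytest.approx(ref.params[0], abs=1e-5)
    assert ours.se == pytest.approx(ref.bse[0], abs=1e-5)


def test_consistency_recovers_known_odds_ratio():
    """With many strata generated at a known common OR, the estimate
    concentrates near the truth."""
    from willis_concord import simulate_strata

    rng = np.random.default_rng(42)
    strata = simulate_strata(500, psi=2.0, rng=rng)
    r = fit(strata)
    assert r.converged
    assert abs(r.beta_hat - math.log(2.0)) < 3 * r.se
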