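"""Statistical primitives used across the screen.

The empirical-Bayes machinery (variance-prior estimation by moment matching
on log sample variances, moderated two-sample t-test) is implemented here;
classical tests delegate to scipy behind stable, spec-shaped surfaces.
All functions are pure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "VariancePrior",
    "ModeratedTestResult",
    "AnovaResult",
    "bh_adjust",
    "fisher_exact_one_sided",
    "fit_variance_prior",
    "moderated_t_test",
    "one_way_anova_f",
    "ks_two_sample",
    "wilcoxon_rank_sum",
    "pearson_r",
]


@dataclass(frozen=True)
class VariancePrior:
    """Prior for per-feature variances: d0 prior degrees of freedom
    (may be ``inf``), s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


class ModeratedTestResult(NamedTuple):
    effect: float  # log2 fold change (difference of group means)
    t_mod: float
    df_total: float
    p: float
    q: float  # NaN until BH adjustment over a family


class AnovaResult(NamedTuple):
    f: float
    p: float
    degenerate: bool  # True when within-group variance vanished (0/0 F)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Missing p-values propagate as NaN and do not count toward the number of
    hypotheses.  Output is elementwise >= input, <= 1, order-preserving
    under the original indexing.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pm = p[mask]
    if pm.size == 0:
        return q
    if pm.min() < 0 or pm.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = pm.size
    order = np.argsort(pm, kind="mergesort")
    scaled = pm[order] * n / np.arange(1, n + 1)
    qv = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(n)
    out[order] = qv
    q[mask] = out
    return q


# ---------------------------------------------------------------------------
# Fisher exact (enrichment, one-sided)
# ---------------------------------------------------------------------------


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment of cell ``a``) Fisher exact p for [[a, b], [c, d]].

    Equals the hypergeometric upper tail P(X >= a) with population a+b+c+d,
    a+c successes and a+b draws; evaluated through log-space survival
    functions for numerical stability.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"table cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if a == 0:
        return 1.0  # P(X >= 0) = 1, also for empty margins
    return float(sps.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(
    sample_variances: Sequence[float], residual_df: Sequence[float] | float
) -> VariancePrior:
    """Estimate (d0, s0_sq) from observed per-feature sample variances.

    Moment matching on z = log(s^2): under a scaled-F model the mean and
    variance of z are known through digamma/trigamma functions of the
    residual and prior degrees of freedom; the trigamma equation is solved
    by Newton iteration.  When the observed spread of z does not exceed the
    chi-square expectation the prior is degenerate: d0 = inf and every
    feature shrinks completely to s0_sq.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    df = np.broadcast_to(np.asarray(residual_df, dtype=float), s2.shape).astype(float)
    keep = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    s2, df = s2[keep], df[keep]
    if s2.size < 2:
        raise ValueError("need at least 2 finite positive sample variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if math.isinf(d0):
            return VariancePrior(math.inf, float(np.exp(emean)))
        s0_sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
        return VariancePrior(d0, s0_sq)
    return VariancePrior(math.inf, float(np.exp(emean)))


def moderated_t_test(
    group_a: Sequence[float], group_b: Sequence[float], prior: VariancePrior
) -> ModeratedTestResult:
    """Two-sample moderated t-test with variance shrinkage toward the prior.

    effect = mean(a) - mean(b); the pooled sample variance (df = n_a+n_b-2)
    is shrunk to s~^2 = (d0 s0^2 + df s^2)/(d0 + df); the statistic is
    referred to a t distribution with df + d0 degrees of freedom (standard
    normal when d0 is infinite).  Two-sided p.
    """
    xa = np.asarray(group_a, dtype=float)
    xb = np.asarray(group_b, dtype=float)
    xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs at least 2 present values")
    na, nb = xa.size, xb.size
    df = na + nb - 2
    effect = float(xa.mean() - xb.mean())
    s2 = float(((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / df)
    if math.isinf(prior.d0):
        s2_post = prior.s0_sq
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    se = math.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t_mod = effect / se if se > 0 else math.copysign(math.inf, effect)
    if math.isinf(df_total):
        p = 2.0 * float(sps.norm.sf(abs(t_mod)))
    else:
        p = 2.0 * float(sps.t.sf(abs(t_mod), df_total))
    return ModeratedTestResult(effect, float(t_mod), df_total, min(p, 1.0), math.nan)


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------


def one_way_anova_f(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA F-test across k groups.

    Degenerate conventions: if the within-group variance is zero everywhere
    and the between-group variance is also zero (all values equal), F is the
    0/0 form and (F=nan, p=1, degenerate=True) is returned; zero
    between-group variance alone gives F=0, p=1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[np.isfinite(a)] for a in arrs]
    arrs = [a for a in arrs if a.size >= 2]
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    if k < 2 or n_total - k < 1:
        raise ValueError("need >= 2 groups with >= 2 values each and residual df")
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, n_total - k
    if ss_within <= 0:
        if ss_between <= 0:
            return AnovaResult(math.nan, 1.0, True)
        return AnovaResult(math.inf, 0.0, True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, False)


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    ``alternative="greater"`` tests whether the values of ``x`` are
    stochastically greater than those of ``y`` (its ECDF lies below).
    Exact small-sample p when n*m <= 10,000, asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    # our sidedness speaks about the sample values; scipy's about the ECDFs
    scipy_alt = {"two-sided": "two-sided", "greater": "less", "less": "greater"}[
        alternative
    ]
    method = "exact" if x.size * y.size <= 10_000 else "asymp"
    res = sps.ks_2samp(x, y, alternative=scipy_alt, method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact null distribution for small untied samples (both n <= 25),
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size == 1 and y.size == 1:
        return 1.0
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN pairs dropped pairwise.

    Returns NaN (undefined flag) for fewer than 3 complete pairs or a
    zero-variance margin rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])
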