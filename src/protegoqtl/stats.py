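"""Shared statistical primitives: BH FDR, rank-sum tests, variance moderation.

The variance-moderation routines implement empirical-Bayes shrinkage of
per-gene residual variances toward a scaled inverse-chi-square prior whose
hyperparameters (prior degrees of freedom ``d0`` and prior variance ``s0_sq``)
are fitted by moment-matching of log sample variances against a scaled-F
marginal (Smyth-style moderation). The moderated t-statistic for a gene is
its ordinary t rescaled by the ratio of its residual standard deviation to
the posterior standard deviation, referred to a t distribution with
``d0 + d_g`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "wilcoxon_rank_sum",
    "RankSumResult",
    "ModerationResult",
    "fit_variance_prior",
    "moderate_variances",
    "trigamma_inverse",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries (untested hypotheses) are passed through as NaN and do not
    count toward the family size. Raises ``ValueError`` for p outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum() > 0:
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass
class RankSumResult:
    """Two-sided two-sample Wilcoxon rank-sum (Mann-Whitney) test result."""

    u_statistic: float  # U for the first sample
    p_value: float
    method: str  # "exact" or "normal"
    n1: int
    n2: int


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x against y via midranks (ties counted half)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def wilcoxon_rank_sum(x, y, exact_max: int = 10) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    When both groups have at most ``exact_max`` observations, the p-value is
    computed by exhaustive enumeration of all C(n1+n2, n1) assignments of the
    pooled values (valid under ties); the two-sided p is the probability of a
    U at least as far from its null mean n1*n2/2 as the observed one.
    Otherwise a normal approximation with midranks, tie correction, and
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _rank_sum_u(x, y)
    mu = n1 * n2 / 2.0

    if n1 <= exact_max and n2 <= exact_max:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        dev_obs = abs(u_obs - mu)
        hits = 0
        for pick in combinations(idx, n1):
            xs = pooled[list(pick)]
            ys = np.delete(pooled, list(pick))
            u = _rank_sum_u(xs, ys)
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / comb(n1 + n2, n1)
        return RankSumResult(u_obs, p, "exact", n1, n2)

    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all values identical
        return RankSumResult(u_obs, 1.0, "normal", n1, n2)
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return RankSumResult(u_obs, p, "normal", n1, n2)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Mirrors the standard monotone-convergent scheme used for fitting the
    scaled-F prior. Returns inf for x <= 0.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


@dataclass
class ModerationResult:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    posterior_var: np.ndarray  # per-gene posterior (shrunken) variances
    df_total: np.ndarray  # d0 + d_g, capped at a large finite value


def fit_variance_prior(sigma2, df) -> tuple[float, float]:
    """Fit (d0, s0_sq) of a scaled-F prior to sample variances by moments.

    Works on log variances: for s_g^2 ~ s0^2 * F(d_g, d0),
    E[log s_g^2] = log s0^2 + psi(d_g/2) - log(d_g/2) - psi(d0/2) + log(d0/2)
    and Var[log s_g^2] = psi'(d_g/2) + psi'(d0/2). Genes with non-positive
    variance or df are excluded from the fit.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (sigma2 > 0) & (df > 0)
    s2, d = sigma2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need at least 2 positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = e.mean()
    n = len(e)
    excess = ((e - ebar) ** 2 * n / (n - 1) - special.polygamma(1, d / 2.0)).mean()
    if not np.isfinite(excess):
        raise ValueError("degenerate variance distribution")
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion beyond sampling: infinite prior df; the
        # posterior is then the pooled (df-weighted) variance, which is also
        # exact in the zero-dispersion limit of identical variances
        d0 = np.inf
        s0_sq = float((d * s2).sum() / d.sum())
    return d0, s0_sq


def moderate_variances(sigma2, df, d0: float | None = None,
                       s0_sq: float | None = None) -> ModerationResult:
    """Shrink per-gene variances toward the fitted prior.

    Posterior variance: (d0*s0^2 + d_g*s_g^2) / (d0 + d_g); with d0 = inf the
    posterior is s0^2 for every gene, with d0 = 0 no shrinkage occurs.
    Hyperparameters are fitted unless supplied. Raises if every variance is 0.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.all(sigma2[df > 0] == 0):
        raise ValueError("all residual variances are zero; nothing to moderate")
    if d0 is None or s0_sq is None:
        d0, s0_sq = fit_variance_prior(sigma2, df)
    if np.isinf(d0):
        post = np.full_like(sigma2, s0_sq)
        df_total = np.full_like(sigma2, np.inf)
    elif d0 == 0:
        post = sigma2.copy()
        df_total = df.copy()
    else:
        post = (d0 * s0_sq + df * sigma2) / (d0 + df)
        df_total = d0 + df
    return ModerationResult(d0=d0, s0_sq=s0_sq, posterior_var=post, df_total=df_total)
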