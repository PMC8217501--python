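"""Statistical primitives shared across the pipeline.

Allelic counts are modelled as beta-binomial draws conditioned on per-sample
SNP-read totals: for a gene with maternal fraction p and overdispersion
rho in [0, 1), a sample with t informative reads contributes m maternal reads
with E[m] = t*p and Var[m] = t*p*(1-p)*(1 + (t-1)*rho). rho = 0 recovers the
binomial. All tests below condition on the totals, so no library-size
normalisation is involved.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

LOG2 = np.log(2.0)

__all__ = [
    "bh_adjust",
    "estimate_overdispersion",
    "betabinom_score_test",
    "pooled_log2fc",
    "log2fc_and_se",
    "tost_equivalence",
    "betabinom_loglik",
    "two_sample_bb_lrt",
]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untestable genes) are excluded from the family and returned
    as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def estimate_overdispersion(
    m: np.ndarray, t: np.ndarray, shrink: float = 0.3
) -> np.ndarray:
    """Method-of-moments beta-binomial overdispersion per gene, shrunk
    toward the pooled across-gene estimate.

    Parameters
    ----------
    m, t
        (genes, samples) maternal and total SNP-read counts.
    shrink
        Weight of the gene-wise estimate; ``1 - shrink`` goes to the median.
        With few samples the raw moment estimator is noisy, and a
        data-dependent variance distorts test calibration, hence the pull
        toward the shared value.
    """
    m = np.asarray(m, float)
    t = np.asarray(t, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = t.sum(axis=1)
        phat = np.where(tot > 0, m.sum(axis=1) / np.maximum(tot, 1), 0.5)
        usable = (phat > 0) & (phat < 1) & (tot > 0)
        pq = phat * (1 - phat)
        resid = (m - t * phat[:, None]) ** 2
        denom = t * pq[:, None]
        chi2 = np.where(t > 0, resid / np.maximum(denom, 1e-12), 0.0).sum(axis=1)
        n_eff = (t > 0).sum(axis=1)
        # estimating the pooled fraction from the same counts removes one
        # degree of freedom: E[chi2] = (n-1) + rho * (sum(t-1) - sum(t(t-1))/T)
        slack = (t - 1).clip(min=0).sum(axis=1) - (t * (t - 1).clip(min=0)).sum(
            axis=1
        ) / np.maximum(tot, 1)
        rho = np.where(
            usable & (slack > 0), (chi2 - (n_eff - 1)) / np.maximum(slack, 1e-12), 0.0
        )
    rho = np.clip(rho, 0.0, 0.99)
    # shared target: pooled moment estimate across genes (summing the excess
    # chi-square mass before dividing); the median of the right-skewed
    # per-gene estimates sits below the true value and would inflate z
    ok = usable & (slack > 0)
    if ok.any():
        target = float((chi2[ok] - (n_eff[ok] - 1)).sum() / slack[ok].sum())
        target = min(max(target, 0.0), 0.99)
    else:
        target = 0.0
    return np.clip(shrink * rho + (1.0 - shrink) * target, 0.0, 0.99)


def betabinom_score_test(
    m: np.ndarray, t: np.ndarray, rho: np.ndarray, p0: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Score test of H0: maternal fraction = p0 under the beta-binomial.

    Returns (z, p) per gene; two-sided normal p-value. Genes with zero total
    SNP reads get z = NaN, p = NaN (untestable).
    """
    m = np.asarray(m, float)
    t = np.asarray(t, float)
    rho = np.asarray(rho, float)
    num = m.sum(axis=1) - p0 * t.sum(axis=1)
    var = (t * p0 * (1 - p0) * (1 + (t - 1).clip(min=0) * rho[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, num / np.sqrt(var), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(z), np.nan, np.minimum(p, 1.0))
    return z, p


def pooled_log2fc(m_sum: np.ndarray, p_sum: np.ndarray, pseudo: float = 0.5) -> np.ndarray:
    """log2((maternal + pseudo) / (paternal + pseudo)) on pooled counts."""
    return np.log2(np.asarray(m_sum, float) + pseudo) - np.log2(
        np.asarray(p_sum, float) + pseudo
    )


def log2fc_and_se(
    m: np.ndarray, t: np.ndarray, rho: np.ndarray, pseudo: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled log2 allelic ratio and its delta-method standard error.

    The estimate is log2(f/(1-f)) at the pooled maternal fraction f (with
    pseudocounts); the variance of f comes from the beta-binomial model and
    propagates with d/df log2(f/(1-f)) = 1/(ln2 * f * (1-f)).
    """
    m = np.asarray(m, float)
    t = np.asarray(t, float)
    rho = np.asarray(rho, float)
    msum = m.sum(axis=1)
    tsum = t.sum(axis=1)
    f = (msum + pseudo) / (tsum + 2 * pseudo)
    lfc = np.log2(msum + pseudo) - np.log2(tsum - msum + pseudo)
    var_sum = (t * (f * (1 - f))[:, None] * (1 + (t - 1).clip(min=0) * rho[:, None])).sum(
        axis=1
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        se_f = np.sqrt(var_sum) / np.maximum(tsum, 1e-12)
        se = se_f / (LOG2 * f * (1 - f))
    se = np.where(tsum > 0, se, np.nan)
    return lfc, se


def tost_equivalence(
    lfc: np.ndarray, se: np.ndarray, margin: float = 1.0
) -> np.ndarray:
    """Two one-sided tests of H0: |log2FC| >= margin.

    p_equiv = max of the two one-sided normal p-values; small p_equiv
    supports equivalence (biallelic expression).
    """
    lfc = np.asarray(lfc, float)
    se = np.asarray(se, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_low = stats.norm.sf((lfc + margin) / se)   # H0: lfc <= -margin
        p_high = stats.norm.cdf((lfc - margin) / se)  # H0: lfc >= +margin
    p = np.maximum(p_low, p_high)
    return np.where(np.isfinite(se) & (se > 0), p, np.nan)


def betabinom_loglik(p: float, m: np.ndarray, t: np.ndarray, rho: float) -> float:
    """Beta-binomial log-likelihood of maternal fraction p (binomial if rho=0)."""
    m = np.asarray(m, float)
    t = np.asarray(t, float)
    p = float(min(max(p, 1e-9), 1 - 1e-9))
    if rho <= 1e-9:
        return float(
            np.sum(m * np.log(p) + (t - m) * np.log1p(-p))
        )  # combinatorial terms drop in likelihood ratios
    k = 1.0 / rho - 1.0
    a, b = p * k, (1 - p) * k
    ll = (
        special.betaln(m + a, t - m + b)
        - special.betaln(a, b)
    )
    return float(ll.sum())


def _bb_mle(m: np.ndarray, t: np.ndarray, rho: float) -> tuple[float, float]:
    res = optimize.minimize_scalar(
        lambda p: -betabinom_loglik(p, m, t, rho),
        bounds=(1e-6, 1 - 1e-6),
        method="bounded",
    )
    return float(res.x), float(-res.fun)


def two_sample_bb_lrt(
    m1: np.ndarray, t1: np.ndarray, m2: np.ndarray, t2: np.ndarray, rho: float
) -> tuple[float, float]:
    """Likelihood-ratio test of equal maternal fraction in two sample groups.

    Returns (lrt_statistic, p) with a chi-square(1) reference. Overdispersion
    rho is held fixed (plug-in), shared between groups.
    """
    if np.sum(t1) == 0 or np.sum(t2) == 0:
        return np.nan, np.nan
    _, ll1 = _bb_mle(np.asarray(m1), np.asarray(t1), rho)
    _, ll2 = _bb_mle(np.asarray(m2), np.asarray(t2), rho)
    _, ll0 = _bb_mle(
        np.concatenate([np.ravel(m1), np.ravel(m2)]),
        np.concatenate([np.ravel(t1), np.ravel(t2)]),
        rho,
    )
    lrt = max(0.0, 2.0 * (ll1 + ll2 - ll0))
    return lrt, float(stats.chi2.sf(lrt, df=1))
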