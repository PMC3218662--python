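"""Exact conditioned test for differential expression between two conditions.

For gene *i* the per-condition count sums K_A and K_B are compared,
conditioning on the total K_S = K_A + K_B.  Under the null hypothesis of
equal expression strength, each sum is approximated by a negative binomial
whose mean and variance follow from the pooled common-scale mean q0 and the
fitted raw-variance function:

    mu_A    = sum_{j in A} s_j * q0
    sigma2_A = sum_{j in A} [ s_j * q0 + s_j^2 * v_A(q0) ]

The p-value is the probability, over all splits a + b = k_S, of outcomes at
most as probable as the observed one:

    p = sum_{p(a,b) <= p(kA,kB)} p(a,b)  /  sum_{a+b=kS} p(a,b)

with p(a,b) = Pr(K_A = a) Pr(K_B = b), evaluated in log space.  This is the
count analogue of Fisher's exact test, with the hypergeometric replaced by
the product of two overdispersed count distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .count_data import CountDataError, Design
from .variance_estimation import VarianceFunction

__all__ = [
    "NBParams",
    "pooled_mean",
    "condition_sum_params",
    "exact_pvalue",
    "test_two_conditions",
    "adjust_bh",
    "write_results",
    "read_results",
]

# full enumeration of all splits up to this total; beyond it, terms more
# than 36 decades below the peak are dropped before normalization
FULL_ENUMERATION_MAX = 10_000
_LOG_WINDOW = 36 * np.log(10.0)
_TIE_RTOL = 1e-8


@dataclass(frozen=True)
class NBParams:
    """Mean/variance parameterization of a count distribution.

    When the variance exceeds the mean this is a negative binomial with
    size ``r = mu^2 / (sigma^2 - mu)`` and success probability
    ``r / (r + mu)`` (plain moment matching, isolated here so that a
    bias-corrected matching rule could be swapped in).  When
    ``sigma^2 <= mu`` the Poisson limit is used, and a zero mean denotes
    the degenerate distribution at 0.
    """

    mean: float
    variance: float

    @property
    def is_degenerate(self) -> bool:
        return self.mean == 0.0

    @property
    def is_poisson(self) -> bool:
        return (not self.is_degenerate) and self.variance <= self.mean

    @property
    def size(self) -> float:
        """NB size parameter r (infinite in the Poisson limit)."""
        if self.is_degenerate or self.is_poisson:
            return np.inf
        return self.mean**2 / (self.variance - self.mean)

    @classmethod
    def from_moments(cls, mean: float, variance: float) -> "NBParams":
        if mean < 0 or not np.isfinite(mean):
            raise ValueError(f"invalid mean {mean!r}")
        return cls(float(mean), float(variance))

    def logpmf(self, k) -> np.ndarray:
        k = np.asarray(k)
        if self.is_degenerate:
            return np.where(k == 0, 0.0, -np.inf)
        if self.is_poisson:
            return stats.poisson.logpmf(k, self.mean)
        r = self.size
        p = r / (r + self.mean)
        return stats.nbinom.logpmf(k, r, p)

    def logpmf_range(self, kmax: int) -> np.ndarray:
        """log pmf on 0..kmax.

        Uses scipy directly up to :data:`FULL_ENUMERATION_MAX`; for larger
        supports a cumulative log-ratio recurrence is used, which is an
        order of magnitude faster and accurate to ~1e-10 in the log.
        """
        if self.is_degenerate:
            out = np.full(kmax + 1, -np.inf)
            out[0] = 0.0
            return out
        if kmax <= FULL_ENUMERATION_MAX:
            return self.logpmf(np.arange(kmax + 1))
        k = np.arange(kmax, dtype=float)
        if self.is_poisson:
            lam = self.mean
            ratios = np.log(lam / (k + 1.0))
            log0 = -lam
        else:
            r = self.size
            p = r / (r + self.mean)
            ratios = np.log((k + r) / (k + 1.0)) + np.log1p(-p)
            log0 = r * np.log(p)
        out = np.empty(kmax + 1)
        out[0] = log0
        np.cumsum(ratios, out=out[1:])
        out[1:] += log0
        return out


def pooled_mean(counts_row, size_factors: pd.Series, samples) -> float:
    """Pooled common-scale mean over the union of both conditions' samples.

    The per-sample mean of k/s over the pooled group: the sum of
    common-scale counts divided by the number of samples.  (The division
    keeps the quantity on the same per-sample scale as the per-condition
    base means, consistent with its later multiplication by per-sample
    size factors.)
    """
    samples = list(samples)
    if not samples:
        raise CountDataError("pooled mean over empty sample set")
    row = pd.Series(counts_row, index=samples) if not isinstance(counts_row, pd.Series) else counts_row
    sf = size_factors.reindex(samples).to_numpy(dtype=float)
    vals = row.reindex(samples).to_numpy(dtype=float)
    return float((vals / sf).sum() / len(samples))


def condition_sum_params(q0: float, sf_subset: np.ndarray,
                         vf: VarianceFunction) -> NBParams:
    """NB parameters of one condition's count sum at pooled mean ``q0``."""
    sf = np.asarray(sf_subset, dtype=float)
    if q0 < 0:
        raise ValueError("pooled mean must be non-negative")
    v = float(vf.raw_variance(q0))
    mean = float(q0 * sf.sum())
    variance = float(q0 * sf.sum() + v * (sf**2).sum())
    return NBParams.from_moments(mean, variance)


def _exact_pvalue_from_logpmfs(log_a: np.ndarray, log_b_rev: np.ndarray,
                               k_obs: int) -> float:
    """Conditional p-value from the two margins' log pmfs over 0..kS."""
    logp = log_a + log_b_rev
    lmax = logp.max()
    if not np.isfinite(lmax):
        return 1.0
    keep = logp >= lmax - _LOG_WINDOW
    keep[k_obs] = True
    logp_obs = logp[k_obs]
    tol = _TIE_RTOL * abs(logp_obs)
    num_mask = keep & (logp <= logp_obs + tol)
    denom = logsumexp(logp[keep])
    numer = logsumexp(logp[num_mask])
    return float(min(1.0, np.exp(numer - denom)))


def exact_pvalue(kA: int, kB: int, pA: NBParams, pB: NBParams) -> float:
    """Exact conditional p-value of the observed split (kA, kB).

    Sums p(a, b) = Pr(K_A = a) Pr(K_B = b) over all splits a + b = kA + kB
    with p(a, b) <= p(kA, kB), normalized by the sum over all splits; all
    arithmetic in log space.  A tie tolerance of 1e-8 (relative, on the
    log) keeps mathematically exact ties from being dropped by
    floating-point noise.
    """
    if kA < 0 or kB < 0:
        raise ValueError("counts must be non-negative")
    ks = int(kA) + int(kB)
    if ks == 0:
        return 1.0
    if pA.is_degenerate and pB.is_degenerate:
        return 1.0
    log_a = pA.logpmf_range(ks)
    log_b = pB.logpmf_range(ks)
    return _exact_pvalue_from_logpmfs(log_a, log_b[::-1], int(kA))


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clamped to [0, 1]."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_two_conditions(
    counts: pd.DataFrame,
    design: Design,
    size_factors: pd.Series,
    variance_functions: dict[str, VarianceFunction],
    cond_a: str,
    cond_b: str,
) -> pd.DataFrame:
    """Per-gene exact test of condition ``cond_a`` versus ``cond_b``.

    Returns a result table indexed by gene ID with columns ``baseMean``
    (pooled common-scale mean), ``baseMeanA``, ``baseMeanB``,
    ``foldChange`` (B over A; ``inf`` when A is zero, undefined for 0/0),
    ``log2FoldChange``, ``pval`` and BH-adjusted ``padj``.  Genes with no
    counts in either condition get p = 1 and are kept in the BH
    denominator.
    """
    for cond in (cond_a, cond_b):
        if cond not in design.replicate_count:
            raise CountDataError(f"condition {cond!r} not in design")
        if cond not in variance_functions:
            raise CountDataError(f"no variance function for condition {cond!r}")
    samples_a = design.samples_of(cond_a)
    samples_b = design.samples_of(cond_b)
    sf_a = size_factors.reindex(samples_a).to_numpy(dtype=float)
    sf_b = size_factors.reindex(samples_b).to_numpy(dtype=float)
    arr_a = counts[samples_a].to_numpy(dtype=np.int64)
    arr_b = counts[samples_b].to_numpy(dtype=np.int64)
    k_a = arr_a.sum(axis=1)
    k_b = arr_b.sum(axis=1)
    cs_a = arr_a / sf_a
    cs_b = arr_b / sf_b
    base_a = cs_a.mean(axis=1)
    base_b = cs_b.mean(axis=1)
    m_tot = len(samples_a) + len(samples_b)
    q0 = (cs_a.sum(axis=1) + cs_b.sum(axis=1)) / m_tot

    vf_a = variance_functions[cond_a]
    vf_b = variance_functions[cond_b]
    v_a = vf_a.raw_variance(q0)
    v_b = vf_b.raw_variance(q0)
    s1a, s2a = sf_a.sum(), (sf_a**2).sum()
    s1b, s2b = sf_b.sum(), (sf_b**2).sum()
    mu_a = q0 * s1a
    var_a = q0 * s1a + v_a * s2a
    mu_b = q0 * s1b
    var_b = q0 * s1b + v_b * s2b

    n = counts.shape[0]
    pvals = np.ones(n)
    for i in range(n):
        ks = int(k_a[i] + k_b[i])
        if ks == 0:
            continue
        pa = NBParams.from_moments(mu_a[i], var_a[i])
        pb = NBParams.from_moments(mu_b[i], var_b[i])
        pvals[i] = exact_pvalue(int(k_a[i]), int(k_b[i]), pa, pb)

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = base_b / base_a
        fold[(base_a == 0) & (base_b == 0)] = np.nan
        log2fc = np.log2(fold)
    padj = adjust_bh(pvals)
    return pd.DataFrame(
        {
            "baseMean": q0,
            "baseMeanA": base_a,
            "baseMeanB": base_b,
            "foldChange": fold,
            "log2FoldChange": log2fc,
            "pval": pvals,
            "padj": padj,
        },
        index=counts.index.rename("id"),
    )


def write_results(results: pd.DataFrame, path) -> None:
    """Serialize a result table as TSV (Inf/-Inf for infinities, NA for
    undefined values)."""
    out = results.copy()
    for col in out.columns:
        vals = out[col].astype(object)
        arr = results[col].to_numpy()
        vals[np.isposinf(arr)] = "Inf"
        vals[np.isneginf(arr)] = "-Inf"
        vals[np.isnan(arr)] = "NA"
        out[col] = vals
    out.to_csv(path, sep="\t", index_label="id")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id",
                     na_values=["NA"], keep_default_na=False)
    return df.replace({"Inf": np.inf, "-Inf": -np.inf}).astype(float)
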