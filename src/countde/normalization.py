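"""Median-of-ratios size factors and the common count scale.

Samples sequenced to different depths are made comparable by a per-sample
*size factor* s_j: the median, over genes, of the ratio of the sample's
counts to a pseudo-reference sample formed by the per-gene geometric mean
across samples,

    s_j = median_i  k_ij / (prod_v k_iv)^(1/m).

Genes with a zero count in any sample are excluded (their geometric mean
is zero, leaving the ratio undefined).  Dividing counts by s_j puts all
samples on the *common scale*.  Total-count ratios are a known but less
robust alternative: a few highly expressed, differentially expressed genes
can dominate library totals, whereas the median is insensitive to them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .count_data import CountDataError

__all__ = [
    "estimate_size_factors",
    "common_scale",
    "read_size_factors",
    "write_size_factors",
]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Estimate per-sample size factors by the median-of-ratios method.

    Parameters
    ----------
    counts
        Genes x samples table of non-negative integer counts.

    Returns
    -------
    pandas.Series
        Strictly positive factor per sample, indexed by sample name.

    Raises
    ------
    CountDataError
        If no gene has strictly positive counts in every sample, in which
        case the pseudo-reference is undefined and size factors must be
        supplied externally.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.size == 0:
        raise CountDataError("empty count table: cannot estimate size factors")
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise CountDataError(
            "no gene has positive counts in all samples; "
            "size factors cannot be estimated by median-of-ratios -- "
            "supply size factors manually"
        )
    pos = arr[eligible]
    # geometric mean via logs to avoid overflow of the row product
    log_geomean = np.log(pos).mean(axis=1)
    ratios = pos / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise CountDataError("internal error: non-positive or non-finite size factor")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def common_scale(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    missing = [s for s in counts.columns if s not in size_factors.index]
    if missing:
        raise CountDataError(f"no size factor for sample {missing[0]!r}")
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    return counts / sf


def write_size_factors(size_factors: pd.Series, path) -> None:
    sf = size_factors.rename("size_factor")
    sf.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def read_size_factors(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    ser = pd.Series(df.iloc[:, 1].astype(float).to_numpy(),
                    index=df.iloc[:, 0], name="size_factor")
    if (ser <= 0).any() or not np.isfinite(ser).all():
        raise CountDataError("size factors must be positive and finite")
    return ser
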