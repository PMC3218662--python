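"""Scikit-learn-style estimators over the count-based analysis pipeline.

These classes follow the sklearn convention (``fit``/``transform``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore) with samples as rows and genes as columns, so they compose
with :class:`sklearn.pipeline.Pipeline` and model-selection utilities.
The module-level functions in :mod:`countde.normalization`,
:mod:`countde.vst` and :mod:`countde.nb_exact_test` are the underlying
engines; these estimators add state handling on top.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .count_data import CountDataError, Design, validate_design
from . import normalization
from .variance_estimation import FitSettings, pooled_variance_function
from .nb_exact_test import test_two_conditions
from .vst import build_vst

__all__ = ["SizeFactorScaler", "VarianceStabilizer", "NBExactTest"]

_DEFAULTS = FitSettings()


def _as_counts_frame(X) -> pd.DataFrame:
    """Samples-by-genes input -> genes-by-samples integer count frame."""
    if isinstance(X, pd.DataFrame):
        df = X.T.copy()
    else:
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D samples-by-genes array")
        df = pd.DataFrame(arr.T,
                          index=[f"gene_{i}" for i in range(arr.shape[1])],
                          columns=[f"sample_{j}" for j in range(arr.shape[0])])
    vals = df.to_numpy()
    if np.any(vals < 0) or np.any(vals != np.floor(vals)):
        raise ValueError("counts must be non-negative integers")
    return df.astype(np.int64)


def _median_ratio_factors(arr: np.ndarray, log_ref: np.ndarray) -> np.ndarray:
    """Per-row size factors of samples-by-genes ``arr`` against a stored
    log-geometric-mean pseudo-reference."""
    factors = np.empty(arr.shape[0])
    for j in range(arr.shape[0]):
        ok = np.isfinite(log_ref) & (arr[j] > 0)
        if not ok.any():
            raise CountDataError(
                "sample shares no positive gene with the reference")
        factors[j] = np.median(arr[j, ok] / np.exp(log_ref[ok]))
    return factors


class SizeFactorScaler(TransformerMixin, BaseEstimator):
    """Median-of-ratios depth normalization as a transformer.

    ``fit`` stores the per-gene geometric-mean pseudo-reference of the
    training samples; ``transform`` computes each sample's size factor
    against that reference and divides the counts by it, yielding
    common-scale values.  New samples can therefore be normalized
    consistently with the fitted cohort.
    """

    def fit(self, X, y=None):
        counts = _as_counts_frame(X)
        arr = counts.to_numpy(dtype=float).T  # samples x genes
        with np.errstate(divide="ignore"):
            self.log_reference_ = np.where(
                (arr > 0).all(axis=0), np.log(arr).mean(axis=0), -np.inf)
        if not np.isfinite(self.log_reference_).any():
            raise CountDataError(
                "no gene has positive counts in all samples; "
                "supply size factors manually")
        self.size_factors_ = _median_ratio_factors(arr, self.log_reference_)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "log_reference_")
        counts = _as_counts_frame(X)
        arr = counts.to_numpy(dtype=float).T
        factors = _median_ratio_factors(arr, self.log_reference_)
        out = arr / factors[:, None]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


class VarianceStabilizer(TransformerMixin, BaseEstimator):
    """Variance-stabilizing transformation as a transformer.

    ``fit`` estimates size factors, fits a single variance-mean function
    across all training samples treated as replicates (blind mode, the
    label-free choice appropriate for an unsupervised transform) and
    builds the monotone map tau; ``transform`` applies tau to the
    common-scale counts.  Output values have approximately
    mean-independent variance, making them suitable for Euclidean
    distances, clustering or PCA downstream.
    """

    def __init__(self, span: float = _DEFAULTS.span,
                 n_knots: int = _DEFAULTS.n_knots,
                 min_genes: int = _DEFAULTS.min_genes):
        self.span = span
        self.n_knots = n_knots
        self.min_genes = min_genes

    def _settings(self) -> FitSettings:
        return FitSettings(span=self.span, n_knots=self.n_knots,
                           min_genes=self.min_genes)

    def fit(self, X, y=None):
        counts = _as_counts_frame(X)
        sf = normalization.estimate_size_factors(counts)
        design = Design({s: "all" for s in counts.columns})
        vfs = pooled_variance_function(counts, design, sf, mode="blind",
                                       settings=self._settings())
        self.scaler_ = SizeFactorScaler().fit(X)
        self.size_factors_ = self.scaler_.size_factors_
        self.variance_function_ = vfs["all"]
        kmax = float((counts.to_numpy() / sf.to_numpy()).max()) * 2 + 10
        self.transform_ = build_vst(self.variance_function_, kappa_max=kmax)
        self.n_features_in_ = counts.shape[0]
        return self

    def transform(self, X):
        check_is_fitted(self, "transform_")
        cs = self.scaler_.transform(X)
        out = self.transform_(np.asarray(cs, dtype=float))
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


class NBExactTest(BaseEstimator):
    """Two-condition differential expression analysis as an estimator.

    ``fit(X, y)`` takes a samples-by-genes count matrix and a condition
    label per sample, runs the full pipeline (median-of-ratios size
    factors, variance-mean fit under ``variance_mode``, exact conditioned
    test, BH adjustment) and exposes the per-gene result table as
    ``results_``.

    Parameters
    ----------
    variance_mode
        'per-condition', 'pooled', 'shared-from-replicated' or 'blind'.
    fdr
        False-discovery-rate threshold used by :meth:`significant`.
    """

    def __init__(self, variance_mode: str = "per-condition",
                 fdr: float = 0.10, span: float = _DEFAULTS.span,
                 n_knots: int = _DEFAULTS.n_knots,
                 min_genes: int = _DEFAULTS.min_genes):
        self.variance_mode = variance_mode
        self.fdr = fdr
        self.span = span
        self.n_knots = n_knots
        self.min_genes = min_genes

    def fit(self, X, y):
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        counts = _as_counts_frame(X)
        y = np.asarray(y)
        if y.shape[0] != counts.shape[1]:
            raise ValueError("one condition label per sample required")
        labels = [str(v) for v in y]
        conds = list(dict.fromkeys(labels))
        if len(conds) != 2:
            raise ValueError(
                f"exactly two conditions required, got {conds!r}; "
                "run pairwise contrasts for multi-condition designs")
        design = validate_design(counts,
                                 Design.from_labels(counts.columns, labels))
        settings = FitSettings(span=self.span, n_knots=self.n_knots,
                               min_genes=self.min_genes)
        sf = normalization.estimate_size_factors(counts)
        vfs = pooled_variance_function(counts, design, sf,
                                       mode=self.variance_mode,
                                       settings=settings)
        self.conditions_ = tuple(conds)
        self.size_factors_ = sf
        self.variance_functions_ = vfs
        self.results_ = test_two_conditions(counts, design, sf, vfs,
                                            conds[0], conds[1])
        self.n_features_in_ = counts.shape[0]
        return self

    def significant(self, fdr: float | None = None) -> pd.DataFrame:
        """Genes called differentially expressed at the given (or the
        configured) BH false-discovery rate."""
        check_is_fitted(self, "results_")
        level = self.fdr if fdr is None else fdr
        return self.results_[self.results_["padj"] <= level]
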