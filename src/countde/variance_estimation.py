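"""Variance-mean dependence estimated by gamma-family local regression.

For each condition the per-gene common-scale mean ``q`` and sample variance
``w`` are computed from the replicates.  ``w`` decomposes into shot noise
(the Poisson part, whose expected contribution is the *bias term*
``z = (q/m) * sum_j 1/s_j``) and the biological *raw variance* ``v(q)``;
``w - z`` is an unbiased estimator of ``v``.  Because ``w`` from a handful
of replicates is far too noisy per gene, the smooth function ``w(q)`` is
fitted by local regression of ``w`` on ``log q`` across all genes, using a
gamma-family generalized linear model: sample variances are sums of squares
with strongly right-skewed residuals, and a gamma likelihood keeps the fit
from being dragged by that skew.  The raw-variance function is then

    v_hat(q) = max(0, w(q) - q * b),    b = sum_j (1/s_j) / m,

clamped at zero so that the negative-binomial constraint sigma^2 >= mu
always holds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .count_data import CountDataError, Design
from .normalization import common_scale

__all__ = [
    "ConditionMoments",
    "FitSettings",
    "VarianceFunction",
    "VarianceFitError",
    "condition_moments",
    "unbiased_raw_variance",
    "fit_variance_function",
    "pooled_variance_function",
    "fit_diagnostics",
]

logger = logging.getLogger(__name__)

BLIND_LABEL = "__blind__"


class VarianceFitError(RuntimeError):
    """Raised when the variance-mean relationship cannot be fitted."""


@dataclass
class ConditionMoments:
    """Per-gene first and second moments of one condition, on the common scale."""

    condition: str
    gene_ids: pd.Index
    m_rho: int
    base_mean: np.ndarray          # q_hat, per-sample mean of k/s
    sample_variance: np.ndarray | None   # w, unbiased variance of k/s (m >= 2)
    bias_term: np.ndarray          # z = (q_hat/m) * sum 1/s_j
    bias_coefficient: float        # sum(1/s_j)/m, so z = q_hat * bias_coefficient


def condition_moments(
    counts: pd.DataFrame,
    design: Design,
    size_factors: pd.Series,
    condition: str,
) -> ConditionMoments:
    """Common-scale mean, sample variance and shot-noise bias term.

    ``sample_variance`` is ``None`` when the condition has a single sample;
    operations that need it raise an explicit no-replicates error.
    """
    samples = design.samples_of(condition)
    if not samples:
        raise CountDataError(f"condition {condition!r} not present in design")
    sub = common_scale(counts[samples], size_factors)
    arr = sub.to_numpy(dtype=float)
    m = len(samples)
    q_hat = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1) if m >= 2 else None
    inv_sf = float(np.sum(1.0 / size_factors.reindex(samples).to_numpy()))
    bias_coeff = inv_sf / m
    z = q_hat * bias_coeff
    return ConditionMoments(
        condition=condition,
        gene_ids=counts.index,
        m_rho=m,
        base_mean=q_hat,
        sample_variance=w,
        bias_term=z,
        bias_coefficient=bias_coeff,
    )


def unbiased_raw_variance(moments: ConditionMoments) -> np.ndarray:
    """Per-gene unbiased raw-variance estimate ``w - z``.

    Individual values may be negative (shot-noise-dominated genes); no
    clamping is applied here — the clamp belongs to the fitted function.
    """
    if moments.sample_variance is None:
        raise VarianceFitError(
            f"condition {moments.condition!r} has no replicates; sample "
            "variance undefined -- use the 'blind' or "
            "'shared-from-replicated' variance mode"
        )
    return moments.sample_variance - moments.bias_term


@dataclass
class FitSettings:
    """Tuning of the local gamma regression of w on log q.

    span
        Nearest-neighbour bandwidth as a fraction of the fitting points.
    degree
        Degree of the local polynomial in log q (2 matches common locfit
        usage; with the wide bandwidths used here, degree 1 oversmooths
        the curvature at the shot-noise/raw-variance crossover).
    n_knots
        Evaluation-grid size, equally spaced in log q.
    min_genes
        Minimum number of genes with positive mean required to fit.
    grid_quantiles
        Quantiles of q bounding the knot grid (and the fit domain).
    """

    span: float = 0.3
    degree: int = 2
    n_knots: int = 200
    min_genes: int = 50
    grid_quantiles: tuple[float, float] = (0.001, 0.999)
    max_iter: int = 50
    tol: float = 1e-10


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return out**3


def _wls_poly(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray | None:
    """Weighted least squares for y ~ X @ beta; None on a singular system."""
    Xw = X * w[:, None]
    try:
        beta = np.linalg.solve(Xw.T @ X, Xw.T @ y)
    except np.linalg.LinAlgError:
        return None
    return beta if np.all(np.isfinite(beta)) else None


def _gamma_irls_at(x: np.ndarray, y: np.ndarray, kw: np.ndarray,
                   settings: FitSettings) -> float:
    """Local gamma-family GLM (log link, polynomial predictor in x) at x = 0.

    Returns the fitted mean exp(beta_0).  Falls back to kernel-weighted
    least squares on log y with a half-residual-variance back-transform
    when the IRLS does not converge.
    """
    ybar = (kw * y).sum() / kw.sum()
    if ybar <= 0:
        return 0.0
    X = np.vander(x, settings.degree + 1, increasing=True)
    beta = np.zeros(settings.degree + 1)
    beta[0] = np.log(ybar)
    for _ in range(settings.max_iter):
        eta = np.clip(X @ beta, -300.0, 300.0)
        mu = np.exp(eta)
        zwork = eta + (y - mu) / mu
        new = _wls_poly(X, zwork, kw)
        if new is None:
            break
        step = np.max(np.abs(new - beta))
        beta = new
        if step < settings.tol * (1.0 + np.sum(np.abs(beta))):
            return float(np.exp(np.clip(beta[0], -300.0, 300.0)))
    # fallback: WLS on log y (positive part) with bias correction
    pos = y > 0
    if pos.sum() <= settings.degree or kw[pos].sum() <= 0:
        return float(max(ybar, 0.0))
    ly = np.log(y[pos])
    beta = _wls_poly(X[pos], ly, kw[pos])
    if beta is None:
        return float(max(ybar, 0.0))
    resid = ly - X[pos] @ beta
    s2 = float((kw[pos] * resid**2).sum() / kw[pos].sum())
    logger.warning("local gamma GLM did not converge at a knot; "
                   "using log-scale WLS fallback")
    return float(np.exp(np.clip(beta[0] + 0.5 * s2, -300.0, 300.0)))


def _local_gamma_regression(log_q: np.ndarray, w: np.ndarray,
                            knots: np.ndarray, settings: FitSettings) -> np.ndarray:
    n = log_q.size
    k = max(2, int(np.ceil(settings.span * n)))
    k = min(k, n)
    fitted = np.empty_like(knots)
    for i, t in enumerate(knots):
        d = np.abs(log_q - t)
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            h = max(d.max(), 1e-9)
        kw = _tricube(d / h)
        mask = kw > 0
        fitted[i] = _gamma_irls_at(log_q[mask] - t, w[mask], kw[mask], settings)
    return fitted


class VarianceFunction:
    """Fitted smooth variance-mean function of one condition (or cohort).

    Stores the local-regression fit of the common-scale sample variance
    ``w`` as knots ``(log q, w)`` with linear interpolation in log q, plus
    the shot-noise bias coefficient ``b`` of the fitting cohort.  Outside
    the fit domain the function is continued at constant squared
    coefficient of variation: ``w(q) = scv_boundary * q**2 + b * q``,
    which avoids negative or explosive extrapolation for extreme counts.
    """

    def __init__(self, condition: str, log_q_knots: np.ndarray,
                 w_knots: np.ndarray, bias_coefficient: float,
                 settings: FitSettings | None = None) -> None:
        order = np.argsort(log_q_knots)
        self.condition = condition
        self.log_q_knots = np.asarray(log_q_knots, dtype=float)[order]
        self.w_knots = np.clip(np.asarray(w_knots, dtype=float)[order], 0.0, None)
        self.bias_coefficient = float(bias_coefficient)
        self.settings = settings or FitSettings()
        self.fit_domain = (float(np.exp(self.log_q_knots[0])),
                           float(np.exp(self.log_q_knots[-1])))

    def _boundary_scv(self, which: int) -> float:
        q_b = self.fit_domain[0] if which == 0 else self.fit_domain[1]
        w_b = self.w_knots[0] if which == 0 else self.w_knots[-1]
        return max(0.0, w_b - q_b * self.bias_coefficient) / q_b**2

    def fitted_w(self, q) -> np.ndarray:
        """Evaluate the fitted variance function w(q) (q > 0; w(0) = 0)."""
        q = np.asarray(q, dtype=float)
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        out = np.zeros_like(q)
        pos = q > 0
        qp = q[pos]
        with np.errstate(divide="ignore"):
            lq = np.log(qp)
        vals = np.interp(lq, self.log_q_knots, self.w_knots)
        lo, hi = self.fit_domain
        below = qp < lo
        above = qp > hi
        if below.any():
            vals[below] = (self._boundary_scv(0) * qp[below] ** 2
                           + self.bias_coefficient * qp[below])
        if above.any():
            vals[above] = (self._boundary_scv(1) * qp[above] ** 2
                           + self.bias_coefficient * qp[above])
        out[pos] = vals
        return out[0] if scalar else out

    def raw_variance(self, q) -> np.ndarray:
        """Biological raw-variance function v_hat(q) = max(0, w(q) - q*b)."""
        q = np.asarray(q, dtype=float)
        return np.clip(self.fitted_w(q) - q * self.bias_coefficient, 0.0, None)

    def scv(self, q) -> np.ndarray:
        """Squared coefficient of variation of the raw variance, v_hat(q)/q^2."""
        q = np.asarray(q, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(q > 0, self.raw_variance(q) / q**2, 0.0)

    # --- persistence -----------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write the knot grid as TSV with a JSON header comment line."""
        header = {
            "condition": self.condition,
            "bias_coefficient": self.bias_coefficient,
            "settings": asdict(self.settings),
        }
        q = np.exp(self.log_q_knots)
        df = pd.DataFrame({
            "q": q,
            "fitted_w": self.w_knots,
            "v_hat": self.raw_variance(q),
        })
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VarianceFunction":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise CountDataError("variance-function file lacks JSON header")
            header = json.loads(first[1:])
            df = pd.read_csv(fh, sep="\t")
        settings = FitSettings(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in header["settings"].items()})
        return cls(header["condition"], np.log(df["q"].to_numpy()),
                   df["fitted_w"].to_numpy(), header["bias_coefficient"],
                   settings)


def fit_variance_function(
    moments: ConditionMoments,
    settings: FitSettings | None = None,
) -> VarianceFunction:
    """Fit the smooth variance-mean function from one cohort's moments.

    Genes with zero mean are excluded (the log-mean predictor is undefined
    and they carry no variance information); they are assigned raw
    variance 0 by the fitted function, which maps q = 0 to w = 0.
    """
    settings = settings or FitSettings()
    w_all = unbiased_raw_variance(moments)  # raises on m < 2
    del w_all
    q = moments.base_mean
    w = moments.sample_variance
    pos = q > 0
    n_pos = int(pos.sum())
    if n_pos < settings.min_genes:
        raise VarianceFitError(
            f"only {n_pos} genes with positive mean in condition "
            f"{moments.condition!r}; at least {settings.min_genes} required"
        )
    log_q = np.log(q[pos])
    w_pos = w[pos]
    qlo, qhi = np.quantile(log_q, settings.grid_quantiles)
    if qhi <= qlo:
        qhi = qlo + 1e-6
    knots = np.linspace(qlo, qhi, settings.n_knots)
    fitted = _local_gamma_regression(log_q, w_pos, knots, settings)
    if not np.all(np.isfinite(fitted)):
        raise VarianceFitError(
            f"variance fit produced non-finite values for condition "
            f"{moments.condition!r}"
        )
    return VarianceFunction(moments.condition, knots, fitted,
                            moments.bias_coefficient, settings)


def pooled_variance_function(
    counts: pd.DataFrame,
    design: Design,
    size_factors: pd.Series,
    mode: str = "per-condition",
    settings: FitSettings | None = None,
) -> dict[str, VarianceFunction]:
    """Fit variance functions under one of four replicate-sharing modes.

    per-condition
        One fit per condition from its own replicates; every condition
        must have at least two samples.
    pooled
        One fit from the (q, w) points of all replicated conditions
        combined, assigned to every condition.
    blind
        All samples are treated as replicates of a single pseudo-condition
        regardless of their labels; usable with no replication at all
        (m >= 2 total).  Conservative when true differences exist, since
        between-condition differences inflate the apparent variance.
    shared-from-replicated
        Like pooled, but intended for designs where only some conditions
        are replicated: the fit from the replicated conditions is assumed
        to hold for the unreplicated ones as well.
    """
    settings = settings or FitSettings()
    conditions = design.conditions
    if mode == "per-condition":
        out = {}
        for cond in conditions:
            if design.replicate_count[cond] < 2:
                raise VarianceFitError(
                    f"condition {cond!r} has no replicates; use mode "
                    "'pooled', 'shared-from-replicated' or 'blind'"
                )
            out[cond] = fit_variance_function(
                condition_moments(counts, design, size_factors, cond), settings)
        return out
    if mode in ("pooled", "shared-from-replicated"):
        replicated = [c for c in conditions if design.replicate_count[c] >= 2]
        if not replicated:
            raise VarianceFitError(
                "no replicated condition available; use mode 'blind'")
        per = [condition_moments(counts, design, size_factors, c)
               for c in replicated]
        q = np.concatenate([m.base_mean for m in per])
        w = np.concatenate([m.sample_variance for m in per])
        z = np.concatenate([m.bias_term for m in per])
        npts = np.array([m.base_mean.size for m in per], dtype=float)
        bias = float(np.average([m.bias_coefficient for m in per], weights=npts))
        pooled = ConditionMoments(
            condition="+".join(replicated),
            gene_ids=pd.Index(range(q.size)),
            m_rho=min(design.replicate_count[c] for c in replicated),
            base_mean=q, sample_variance=w, bias_term=z,
            bias_coefficient=bias)
        vf = fit_variance_function(pooled, settings)
        return {c: vf for c in conditions}
    if mode == "blind":
        if len(design.condition_of_sample) < 2:
            raise VarianceFitError("blind mode needs at least 2 samples")
        blind_design = Design({s: BLIND_LABEL for s in design.condition_of_sample})
        mom = condition_moments(counts, blind_design, size_factors, BLIND_LABEL)
        vf = fit_variance_function(mom, settings)
        return {c: vf for c in conditions}
    raise ValueError(f"unknown variance mode {mode!r}")


def fit_diagnostics(moments: ConditionMoments, vf: VarianceFunction) -> pd.DataFrame:
    """Residual diagnostics of the variance fit.

    For each gene with positive mean, reports the ratio of the observed
    sample variance to the fitted value and its theoretical quantile under
    the scaled sampling distribution of a variance with ``m - 1`` degrees
    of freedom (gamma with shape ``(m-1)/2`` and mean 1).  A well-
    calibrated fit yields approximately uniform quantiles; systematic
    under- (over-)estimation of the variance skews them high (low).
    """
    if moments.sample_variance is None:
        raise VarianceFitError("diagnostics need replicates")
    pos = moments.base_mean > 0
    q = moments.base_mean[pos]
    w = moments.sample_variance[pos]
    fitted = vf.fitted_w(q)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fitted > 0, w / fitted, np.nan)
    shape = (moments.m_rho - 1) / 2.0
    quant = stats.gamma.cdf(ratio, a=shape, scale=1.0 / shape)
    return pd.DataFrame(
        {"base_mean": q, "ratio": ratio, "quantile": quant},
        index=moments.gene_ids[pos],
    )
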