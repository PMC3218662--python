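"""Variance-stabilizing transformation derived from the fitted variance.

Given a variance-mean dependence w(q), the monotone map

    tau(kappa) = integral_0^kappa  dq / sqrt(w(q))

renders the variance of transformed common-scale counts approximately
independent of the mean.  The w used here is the full common-scale
variance at a reference size factor of 1, w(q) = q + v_hat(q): the
shot-noise part must be included because it dominates at low counts.

Two closed-form limits anchor the numerics: pure shot noise (w = q) gives
tau = 2*sqrt(kappa), and a constant squared coefficient of variation
(w = alpha*q^2) gives tau = ln(kappa)/sqrt(alpha) + const.  In the latter
case the integral diverges at 0; the zero anchor is then defined through
the near-zero linear-variance approximation and only differences of tau
are meaningful, which is all that distance computations use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson
from scipy.interpolate import PchipInterpolator
from scipy.spatial.distance import pdist, squareform

from .normalization import common_scale
from .variance_estimation import VarianceFunction

__all__ = ["VSTransform", "build_vst", "apply_vst", "sample_distances"]

_Q_ANCHOR = 1e-6          # below this, w(q) ~ c*q is integrated analytically
_POINTS_PER_LOG = 2000    # grid density per ln unit in the numeric region


class VSTransform:
    """Monotone variance-stabilizing map tau built from w(q).

    Evaluable on any non-negative argument; tau(0) = 0 and the knot grid
    extends itself on demand when values beyond the current domain are
    requested.
    """

    def __init__(self, w, kappa_max: float = 1e4, label: str = "") -> None:
        if callable(w):
            self._w = w
        elif isinstance(w, VarianceFunction):
            vf = w
            self._w = lambda q: np.asarray(q, dtype=float) + vf.raw_variance(q)
            label = label or vf.condition
        else:
            raise TypeError("w must be a VarianceFunction or a callable w(q)")
        self.label = label
        self._build(float(kappa_max))

    def _build(self, kappa_max: float) -> None:
        q_a = _Q_ANCHOR
        if kappa_max <= q_a * 10:
            kappa_max = q_a * 10
        n = int(_POINTS_PER_LOG * np.log(kappa_max / q_a)) + 1
        n = min(max(n, 4097), 400_000)
        t = np.linspace(np.log(q_a), np.log(kappa_max), n)
        q = np.exp(t)
        wq = np.asarray(self._w(q), dtype=float)
        if np.any(wq <= 0) or not np.all(np.isfinite(wq)):
            raise ValueError("variance function must be positive and finite "
                             "for all q > 0")
        # anchor: integral over [0, q_a] assuming w(q) ~ c*q there
        tau_a = 2.0 * q_a / np.sqrt(wq[0])
        integrand = q / np.sqrt(wq)            # dq/sqrt(w) in d(ln q)
        tau = tau_a + cumulative_simpson(integrand, x=t, initial=0.0)
        self.kappa_max = kappa_max
        self._t_knots = t
        self._tau_knots = tau
        self._tau_a = tau_a
        self._interp = PchipInterpolator(t, tau, extrapolate=False)

    def __call__(self, kappa) -> np.ndarray:
        kappa = np.asarray(kappa, dtype=float)
        scalar = kappa.ndim == 0
        kappa = np.atleast_1d(kappa)
        if np.any(kappa < 0):
            raise ValueError("tau is defined on non-negative arguments")
        finite_max = kappa.max(initial=0.0)
        if finite_max > self.kappa_max:
            self._build(finite_max * 2.0)
        out = np.zeros_like(kappa)
        small = (kappa > 0) & (kappa < _Q_ANCHOR)
        out[small] = self._tau_a * np.sqrt(kappa[small] / _Q_ANCHOR)
        big = kappa >= _Q_ANCHOR
        out[big] = self._interp(np.log(kappa[big]))
        return out[0] if scalar else out

    def knots(self, n: int = 1000) -> pd.DataFrame:
        """Subsampled (kappa, tau) knot table."""
        idx = np.unique(np.linspace(0, self._t_knots.size - 1, n).astype(int))
        return pd.DataFrame({"kappa": np.exp(self._t_knots[idx]),
                             "tau": self._tau_knots[idx]})

    def to_tsv(self, path, n: int = 1000) -> None:
        self.knots(n).to_csv(path, sep="\t", index=False)


def build_vst(vf, kappa_max: float = 1e4) -> VSTransform:
    """Build the variance-stabilizing transform from a fitted
    :class:`VarianceFunction` (or a raw callable w(q))."""
    return VSTransform(vf, kappa_max=kappa_max)


def apply_vst(transform: VSTransform, counts: pd.DataFrame,
              size_factors: pd.Series) -> pd.DataFrame:
    """Apply tau to the common-scale counts k_ij / s_j."""
    cs = common_scale(counts, size_factors)
    return pd.DataFrame(transform(cs.to_numpy()), index=counts.index,
                        columns=counts.columns)


def sample_distances(transformed: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance matrix between sample columns.

    The standard input for sample clustering and quality control: on
    variance-stabilized values, Euclidean distance treats all genes on a
    comparable footing across the dynamic range.
    """
    mat = np.asarray(transformed, dtype=float)
    dm = squareform(pdist(mat.T, metric="euclidean"))
    if isinstance(transformed, pd.DataFrame):
        return pd.DataFrame(dm, index=transformed.columns,
                            columns=transformed.columns)
    return pd.DataFrame(dm)
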