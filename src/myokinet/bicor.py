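"""Biweight midcorrelation (bicor) and its Student p-value.

The biweight midcorrelation is a robust alternative to Pearson correlation:
observations are centered on the median and downweighted by Tukey's biweight,
with anything further than 9 median absolute deviations (MAD) from the median
receiving zero weight.  For vector ``x`` with median ``m_x`` and MAD ``mad_x``,

    u_i = (x_i - m_x) / (9 * mad_x)
    w_i = (1 - u_i**2)**2 * 1[|u_i| < 1]

and the coefficient between ``x`` and ``y`` is the weighted cross-product of
the centered vectors, normalized by the weighted norms.  The MAD here is the
raw median absolute deviation (no 1.4826 consistency factor): the 9*MAD
window is defined on the raw MAD.

When a vector's MAD is zero (more than half the values tied at the median)
the biweight weights are undefined; that vector falls back to mean-centering
with unit weights (Pearson-style) and the fall-back is flagged.  A fully
constant vector has no correlation and yields NaN.

Significance uses the Student transform t = r*sqrt(n-2)/sqrt(1-r^2) with
n-2 degrees of freedom, two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bicor",
    "bicor_pvalue",
    "bicor_matrix",
    "CorrelationResult",
]


@dataclass
class CorrelationResult:
    """Pairwise correlation output of :func:`bicor_matrix`.

    Attributes
    ----------
    r : DataFrame
        Coefficients, predictor genes (rows of ``A``) by target genes
        (rows of ``B``).  Entries lie in [-1, 1] or are NaN for
        constant vectors.
    p : DataFrame
        Two-sided Student p-values, same shape as ``r``.
    n : int or DataFrame
        Samples used per pair.  A scalar when the input had no missing
        values; a per-pair matrix under pairwise-complete handling.
    row_fallback, col_fallback : list of str
        Genes for which the zero-MAD Pearson-style fall-back was used.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: int | pd.DataFrame
    row_fallback: list = field(default_factory=list)
    col_fallback: list = field(default_factory=list)


def _biweight_rows(X: np.ndarray):
    """Median-center rows of X and apply biweight weights.

    Returns (normalized rows with unit Euclidean norm, fallback mask,
    degenerate mask).  Rows with zero MAD use the mean/unit-weight
    fall-back; rows that are entirely constant are degenerate (NaN out).
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    d = X - med
    mad = np.median(np.abs(d), axis=1, keepdims=True)
    fallback = mad[:, 0] == 0.0

    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.divide(d, 9.0 * mad, out=np.zeros_like(d), where=mad > 0)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    a = w * d
    if fallback.any():
        Xf = X[fallback]
        a[fallback] = Xf - Xf.mean(axis=1, keepdims=True)

    norm = np.sqrt((a**2).sum(axis=1, keepdims=True))
    degenerate = norm[:, 0] == 0.0
    a = np.divide(a, norm, out=np.zeros_like(a), where=norm > 0)
    a[degenerate] = np.nan
    return a, fallback, degenerate


def bicor(x, y) -> float:
    """Biweight midcorrelation between two vectors.

    Missing values are handled pairwise-complete: positions where either
    vector is NaN are dropped before medians and weights are computed.
    Requires at least 4 complete pairs.  A constant vector yields NaN
    with a warning; a zero-MAD (but non-constant) vector falls back to
    Pearson-style weighting for that vector, with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("bicor expects 1-D vectors")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"length mismatch: {x.shape[0]} vs {y.shape[0]}"
        )
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.shape[0] < 4:
        raise ValueError("bicor requires at least 4 complete observations")

    a, fb, deg = _biweight_rows(np.vstack([x, y]))
    if deg.any():
        warnings.warn("constant vector in bicor; returning NaN", stacklevel=2)
        return float("nan")
    if fb.any():
        which = [name for name, f in zip("xy", fb) if f]
        warnings.warn(
            f"zero MAD in {','.join(which)}; Pearson-style fallback used",
            stacklevel=2,
        )
    return float(np.clip(a[0] @ a[1], -1.0, 1.0))


def bicor_pvalue(r, n):
    """Two-sided Student p-value for a correlation coefficient.

    t = r*sqrt(n-2)/sqrt(1-r^2), referred to a t distribution with n-2
    degrees of freedom.  |r| = 1 maps to p = 0.  ``r`` and ``n`` may be
    scalars or broadcastable arrays; NaN coefficients give NaN p-values.
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n)
    if np.any(n_arr <= 3):
        raise ValueError("p-value requires n >= 4")
    with np.errstate(invalid="ignore"):
        if np.nanmax(np.abs(r_arr), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("|r| must not exceed 1")
    rc = np.clip(r_arr, -1.0, 1.0)
    df = np.asarray(n_arr, dtype=float) - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rc * np.sqrt(df) / np.sqrt(1.0 - rc**2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(rc) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rc), np.nan, p)
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(p)
    return p


def _pairwise_complete(A: pd.DataFrame, B: pd.DataFrame) -> CorrelationResult:
    """Slow path: per-pair complete observations, per-pair n."""
    ra = np.empty((A.shape[0], B.shape[0]))
    pa = np.empty_like(ra)
    na = np.empty_like(ra, dtype=int)
    Av = A.to_numpy(dtype=float)
    Bv = B.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(Av.shape[0]):
            for j in range(Bv.shape[0]):
                ok = np.isfinite(Av[i]) & np.isfinite(Bv[j])
                n_ij = int(ok.sum())
                na[i, j] = n_ij
                if n_ij < 4:
                    ra[i, j] = np.nan
                    pa[i, j] = np.nan
                else:
                    ra[i, j] = bicor(Av[i, ok], Bv[j, ok])
                    pa[i, j] = (
                        bicor_pvalue(ra[i, j], n_ij)
                        if np.isfinite(ra[i, j])
                        else np.nan
                    )
    idx, cols = A.index, B.index
    return CorrelationResult(
        r=pd.DataFrame(ra, index=idx, columns=cols),
        p=pd.DataFrame(pa, index=idx, columns=cols),
        n=pd.DataFrame(na, index=idx, columns=cols),
    )


def bicor_matrix(A: pd.DataFrame, B: pd.DataFrame, sample_subset=None) -> CorrelationResult:
    """All-pairs biweight midcorrelation between rows of two matrices.

    ``A`` and ``B`` are gene-by-sample DataFrames sharing a sample index
    (columns).  ``sample_subset`` restricts the computation to the given
    sample IDs (e.g. one sex stratum).  Complete data use a fully
    vectorized path; matrices containing NaN fall back to per-pair
    pairwise-complete computation with a per-pair n.
    """
    if sample_subset is not None:
        sample_subset = pd.Index(sample_subset)
        missing = sample_subset.difference(A.columns).union(
            sample_subset.difference(B.columns)
        )
        if len(missing):
            raise KeyError(f"samples not present in both matrices: {list(missing)[:5]}")
        shared = sample_subset
    else:
        shared = A.columns.intersection(B.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between matrices")
    if len(shared) < 4:
        raise ValueError(
            f"bicor_matrix requires >= 4 shared samples, got {len(shared)}"
        )
    A = A.loc[:, shared]
    B = B.loc[:, shared]

    if A.isna().to_numpy().any() or B.isna().to_numpy().any():
        return _pairwise_complete(A, B)

    a, fa, dga = _biweight_rows(A.to_numpy(dtype=float))
    b, fb, dgb = _biweight_rows(B.to_numpy(dtype=float))
    r = np.clip(a @ b.T, -1.0, 1.0)
    n = len(shared)
    p = bicor_pvalue(r, n)
    return CorrelationResult(
        r=pd.DataFrame(r, index=A.index, columns=B.index),
        p=pd.DataFrame(p, index=A.index, columns=B.index),
        n=n,
        row_fallback=list(A.index[fa]),
        col_fallback=list(B.index[fb]),
    )
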