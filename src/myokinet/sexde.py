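"""Per-gene differential expression between sexes on count data.

The test is a negative-binomial Wald test of a two-group (male vs female)
contrast with log link, the convention a count-based DE tool applies for a
simple group design:

* library-size normalization by median-of-ratios against a pseudo-reference
  built over genes nonzero in every sample;
* per-gene dispersion by method-of-moments on normalized counts, pooled
  within groups, floored at 1e-8 (no empirical-Bayes shrinkage);
* per-group NB GLM means fit by Newton iteration (log link, size factors as
  offsets), Wald z-statistic on the male-minus-female log fold-change.

log2FC is male-positive.  Genes with no variation across samples (including
all-zero genes) are reported with missing p and excluded from the BH
adjustment.  Categories: ``male`` when p < alpha and log2FC > 0, ``female``
when p < alpha and log2FC < 0, else ``non_sex_specific``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "test_sex_de",
    "classify_sex_specificity",
    "bin_by_external_contrast",
    "CATEGORIES",
]

CATEGORIES = ("male", "female", "non_sex_specific")

_DISPERSION_FLOOR = 1e-8
_BETA_MIN = np.log(1e-8)
_BETA_MAX = np.log(1e12)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The pseudo-reference is the per-gene geometric mean over samples,
    restricted to genes with all counts positive; each sample's factor is
    the median ratio of its counts to the reference.  Falls back to total
    counts (scaled to geometric mean 1) if no gene is everywhere nonzero.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.sum() >= 1:
        logref = np.log(mat[all_pos]).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(mat[all_pos]) - logref, axis=0))
    else:
        tot = mat.sum(axis=0)
        if (tot <= 0).any():
            raise ValueError("sample with zero total counts")
        sf = tot / np.exp(np.mean(np.log(tot)))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _mom_dispersion(q: np.ndarray, groups: list[np.ndarray], inv_sf_mean: float) -> np.ndarray:
    """Method-of-moments dispersion per gene on normalized counts ``q``.

    Within-group residual variance v and overall normalized mean m give
    alpha = (v - m * mean(1/s)) / m^2, floored.
    """
    n_total = q.shape[1]
    ss = np.zeros(q.shape[0])
    for idx in groups:
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    v = ss / max(n_total - len(groups), 1)
    m = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m * inv_sf_mean) / m**2
    alpha = np.where(np.isfinite(alpha), alpha, _DISPERSION_FLOOR)
    return np.maximum(alpha, _DISPERSION_FLOOR)


def _fit_group_nb(y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50):
    """Per-gene NB log-mean for one group, with Wald variance.

    Solves the score equation sum_i (y_i - mu_i)/(1 + alpha*mu_i) = 0 for
    mu_i = s_i * exp(beta) by Newton iteration, vectorized over genes.
    Returns (beta, var_beta) with var from the expected information
    1 / sum_i mu_i/(1 + alpha*mu_i).
    """
    ybar = (y / s).mean(axis=1)
    beta = np.log(np.maximum(ybar, 1e-8))
    alpha_col = alpha[:, None]
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + alpha_col * mu
        score = ((y - mu) / denom).sum(axis=1)
        fisher = (mu * (1.0 + alpha_col * y) / denom**2).sum(axis=1)
        step = score / np.maximum(fisher, 1e-12)
        beta = np.clip(beta + np.clip(step, -5.0, 5.0), _BETA_MIN, _BETA_MAX)
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = s[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha_col * mu)).sum(axis=1)
    var = 1.0 / np.maximum(info, 1e-300)
    return beta, var


def test_sex_de(
    counts: pd.DataFrame,
    sex_labels,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Negative-binomial Wald test of sex for every gene.

    Parameters
    ----------
    counts : DataFrame
        Raw counts, genes by samples (pre-filtered for low expression).
    sex_labels : Series or array
        'male'/'female' per sample, aligned to ``counts`` columns.
    alpha : float
        Significance cutoff used for the category assignment.
    use_adjusted : bool
        Bin on BH-adjusted p instead of raw p.

    Returns a DataFrame with columns ``base_mean, log2FC, stat, pvalue,
    padj, category`` indexed by gene.
    """
    sex = pd.Series(np.asarray(sex_labels), index=counts.columns)
    bad = set(sex.unique()) - {"male", "female"}
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")
    male_idx = np.flatnonzero((sex == "male").to_numpy())
    female_idx = np.flatnonzero((sex == "female").to_numpy())
    for name, idx in (("male", male_idx), ("female", female_idx)):
        if len(idx) < 3:
            raise ValueError(f"need >= 3 {name} samples, got {len(idx)}")

    sf = size_factors(counts).to_numpy()
    y = counts.to_numpy(dtype=float)
    q = y / sf[None, :]

    variable = y.std(axis=1) > 0
    res = pd.DataFrame(
        index=counts.index,
        columns=["base_mean", "log2FC", "stat", "pvalue", "padj"],
        dtype=float,
    )
    res["base_mean"] = q.mean(axis=1)

    if variable.any():
        yv = y[variable]
        disp = _mom_dispersion(
            q[variable], [male_idx, female_idx], float(np.mean(1.0 / sf))
        )
        beta_m, var_m = _fit_group_nb(yv[:, male_idx], sf[male_idx], disp)
        beta_f, var_f = _fit_group_nb(yv[:, female_idx], sf[female_idx], disp)
        lfc = (beta_m - beta_f) / np.log(2.0)
        z = (beta_m - beta_f) / np.sqrt(var_m + var_f)
        pval = 2.0 * stats.norm.sf(np.abs(z))
        res.loc[variable, "log2FC"] = lfc
        res.loc[variable, "stat"] = z
        res.loc[variable, "pvalue"] = pval
        res.loc[variable, "padj"] = multipletests(pval, method="fdr_bh")[1]

    return classify_sex_specificity(res, alpha=alpha, use_adjusted=use_adjusted)[0]


def classify_sex_specificity(
    results: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = False
):
    """Three-way partition of DE results plus category proportions.

    A gene is ``male`` (respectively ``female``) when its p-value is below
    ``alpha`` with positive (negative) male-vs-female log2FC; everything
    else, including untested genes, is ``non_sex_specific``.
    Returns (results with a ``category`` column, proportions Series).
    """
    results = results.copy()
    pcol = results["padj"] if use_adjusted else results["pvalue"]
    sig = pcol.notna() & (pcol < alpha)
    category = np.where(
        sig & (results["log2FC"] > 0),
        "male",
        np.where(sig & (results["log2FC"] < 0), "female", "non_sex_specific"),
    )
    results["category"] = pd.Categorical(category, categories=list(CATEGORIES))
    proportions = (
        results["category"].value_counts(normalize=True).reindex(list(CATEGORIES)).fillna(0.0)
    )
    return results, proportions


def bin_by_external_contrast(categories_a: pd.Series, categories_b: pd.Series) -> pd.DataFrame:
    """Cross-tabulate two per-gene category assignments on shared genes.

    Typical use: sex-specificity categories from the human cohort against
    a dependent/independent label from an external knockout contrast,
    after ortholog intersection.  Empty intersection is an error.
    """
    shared = categories_a.index.intersection(categories_b.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the two contrasts")
    return pd.crosstab(
        categories_a.loc[shared].rename("contrast_a"),
        categories_b.loc[shared].rename("contrast_b"),
    )
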