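"""Cell-type signature construction and bulk deconvolution.

A signature is built from clustered single-cell counts: cells are CPM
normalized, genes are ranked per cluster by log2 fold-change of the cluster
mean over the mean of all other clusters (ties broken lexicographically by
gene name), and the union of each cluster's top-N markers forms the
signature rows, with entries the per-cluster mean CPM.

Three per-sample estimators of bulk composition are provided:

* ``nnls`` — nonnegative least squares;
* ``admixture`` — ordinary least squares with iterative removal of the
  most-negative coefficient's cell type and refitting until all remaining
  coefficients are nonnegative ("proportions in admixture");
* ``dcq`` — elastic-net regression with negative coefficients truncated
  at zero.

All estimates are renormalized to sum to one per sample; an all-zero
solution falls back to uniform fractions with a warning.  The deconvolution
functions fit bulk on the signature exactly as given — callers are
responsible for having both on a comparable scale (the pipeline CPM
normalizes bulk counts; the signature is already in CPM units).
``benchmark_methods`` runs all three on identical synthetic mixtures and
ranks them by RMSE against the known proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.linear_model import ElasticNet

from .synthetic import simulate_mixtures

__all__ = [
    "SignatureMatrix",
    "build_signature",
    "deconvolve_nnls",
    "deconvolve_admixture",
    "deconvolve_dcq",
    "benchmark_methods",
    "compare_proportions_by_sex",
]


@dataclass
class SignatureMatrix:
    """Marker-gene-by-cell-type mean expression with marker provenance."""

    matrix: pd.DataFrame  # marker genes x cell types, mean CPM
    markers: dict  # cell type -> ordered top-N marker genes
    ranking: pd.DataFrame  # gene, cell_type, log2fc for the selected markers

    def __post_init__(self):
        if self.matrix.index.has_duplicates:
            raise ValueError("duplicate genes in signature")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("signature entries must be nonnegative")
        empty = [ct for ct, g in self.markers.items() if len(g) == 0]
        if empty:
            raise ValueError(f"cell types without markers: {empty}")


def _cpm(counts: np.ndarray, axis: int) -> np.ndarray:
    totals = counts.sum(axis=axis, keepdims=True)
    totals = np.where(totals > 0, totals, 1.0)
    return counts / totals * 1e6


def build_signature(sc_counts: pd.DataFrame, cluster_labels: pd.Series, top_n: int = 30) -> SignatureMatrix:
    """Top-N marker signature from clustered cell-by-gene counts.

    Requires >= 2 clusters with >= 3 cells each.  ``top_n`` larger than
    the gene count takes all genes with a warning.  A gene ranked top for
    two clusters appears once among the signature rows.
    """
    labels = pd.Series(cluster_labels).loc[sc_counts.index]
    clusters = labels.unique().tolist()
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    sizes = labels.value_counts()
    small = sizes[sizes < 3]
    if len(small):
        raise ValueError(f"clusters with < 3 cells: {small.index.tolist()}")
    if top_n > sc_counts.shape[1]:
        warnings.warn(
            f"top_n={top_n} exceeds {sc_counts.shape[1]} genes; using all genes",
            stacklevel=2,
        )
        top_n = sc_counts.shape[1]

    cpm = _cpm(sc_counts.to_numpy(dtype=float), axis=1)
    genes = sc_counts.columns
    mean_cpm = {}
    for ct in clusters:
        mean_cpm[ct] = cpm[(labels == ct).to_numpy()].mean(axis=0)
    means = pd.DataFrame(mean_cpm, index=genes)

    markers, rank_rows = {}, []
    for ct in clusters:
        others = means.drop(columns=ct).mean(axis=1)
        lfc = np.log2(means[ct] + 1.0) - np.log2(others + 1.0)
        order = lfc.sort_values(ascending=False, kind="stable")
        # lexicographic tie-break: stable sort on name within equal lfc
        order = (
            pd.DataFrame({"lfc": order})
            .assign(gene=order.index)
            .sort_values(["lfc", "gene"], ascending=[False, True], kind="stable")
        )
        top = order.head(top_n)
        markers[ct] = top["gene"].tolist()
        rank_rows += [
            {"gene": g, "cell_type": ct, "log2fc": l}
            for g, l in zip(top["gene"], top["lfc"])
        ]

    union = list(dict.fromkeys(g for ct in clusters for g in markers[ct]))
    return SignatureMatrix(
        matrix=means.loc[union, clusters],
        markers=markers,
        ranking=pd.DataFrame(rank_rows, columns=["gene", "cell_type", "log2fc"]),
    )


def _as_signature_frame(signature) -> pd.DataFrame:
    return signature.matrix if isinstance(signature, SignatureMatrix) else signature


def _align(bulk: pd.DataFrame, sig: pd.DataFrame):
    shared = bulk.index.intersection(sig.index)
    if len(shared) == 0:
        raise ValueError("bulk and signature share no marker genes")
    if len(shared) < sig.shape[1]:
        raise ValueError(
            f"only {len(shared)} shared marker genes for {sig.shape[1]} cell types"
        )
    return bulk.loc[shared].to_numpy(dtype=float), sig.loc[shared].to_numpy(dtype=float), shared


def _finalize(coefs: np.ndarray, bulk_cols, types, method: str) -> pd.DataFrame:
    coefs = np.maximum(coefs, 0.0)
    sums = coefs.sum(axis=1, keepdims=True)
    degenerate = sums[:, 0] <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} samples with all-zero solution; uniform fallback",
            stacklevel=3,
        )
        coefs[degenerate] = 1.0 / coefs.shape[1]
        sums = coefs.sum(axis=1, keepdims=True)
    props = coefs / sums
    out = pd.DataFrame(props, index=bulk_cols, columns=types)
    out.attrs["method"] = method
    return out


def deconvolve_nnls(bulk: pd.DataFrame, signature) -> pd.DataFrame:
    """Nonnegative least squares per sample, renormalized to sum 1."""
    sig = _as_signature_frame(signature)
    B, S, _ = _align(bulk, sig)
    coefs = np.empty((B.shape[1], S.shape[1]))
    for j in range(B.shape[1]):
        coefs[j], _ = optimize.nnls(S, B[:, j])
    return _finalize(coefs, bulk.columns, sig.columns, "nnls")


def deconvolve_admixture(bulk: pd.DataFrame, signature) -> pd.DataFrame:
    """Proportions-in-admixture: OLS with iterative negative-coefficient removal.

    Per sample, fit ordinary least squares on all cell types; while any
    coefficient is negative, drop the cell type with the most-negative
    coefficient and refit on the remainder; dropped types get zero.
    """
    sig = _as_signature_frame(signature)
    B, S, _ = _align(bulk, sig)
    n_types = S.shape[1]
    coefs = np.zeros((B.shape[1], n_types))
    for j in range(B.shape[1]):
        active = list(range(n_types))
        beta = np.array([])
        while active:
            beta, *_ = np.linalg.lstsq(S[:, active], B[:, j], rcond=None)
            if (beta >= -1e-12).all():
                break
            active.pop(int(np.argmin(beta)))
        if active:
            coefs[j, active] = np.maximum(beta, 0.0)
    return _finalize(coefs, bulk.columns, sig.columns, "admixture")


def deconvolve_dcq(
    bulk: pd.DataFrame, signature, l1_ratio: float = 0.05, penalty: float = 0.01
) -> pd.DataFrame:
    """Elastic-net deconvolution with truncation of negative coefficients.

    ``penalty`` is the elastic-net regularization strength applied after
    rescaling the problem to unit mean signature magnitude (so its effect
    is scale-free); ``penalty=0`` reduces to truncated OLS.
    """
    sig = _as_signature_frame(signature)
    B, S, _ = _align(bulk, sig)
    scale = S.mean() or 1.0
    Ss, Bs = S / scale, B / scale
    if penalty <= 0:
        beta, *_ = np.linalg.lstsq(Ss, Bs, rcond=None)
        coefs = beta.T
    else:
        model = ElasticNet(
            alpha=penalty,
            l1_ratio=l1_ratio,
            fit_intercept=False,
            positive=False,
            max_iter=50_000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Ss, Bs)
        coefs = np.atleast_2d(model.coef_)
    return _finalize(coefs, bulk.columns, sig.columns, "dcq")


_METHODS = {
    "nnls": deconvolve_nnls,
    "admixture": deconvolve_admixture,
    "dcq": deconvolve_dcq,
}


def benchmark_methods(signature, settings: dict) -> pd.DataFrame:
    """Compare the three estimators on identical synthetic mixtures.

    ``settings`` must carry ``n_samples``, ``dirichlet_alpha``,
    ``noise_sd`` and ``seed`` for :func:`simulate_mixtures`.  Returns a
    table sorted by RMSE (best first) with the mean per-type correlation;
    the chosen method is recorded in ``attrs['chosen']``.
    """
    if not settings:
        raise ValueError("empty benchmark settings")
    required = {"n_samples", "dirichlet_alpha", "noise_sd", "seed"}
    missing = required - settings.keys()
    if missing:
        raise ValueError(f"benchmark settings missing {sorted(missing)}")
    sig = _as_signature_frame(signature)
    bulk, truth = simulate_mixtures(
        sig,
        settings["n_samples"],
        settings["dirichlet_alpha"],
        settings["noise_sd"],
        settings["seed"],
    )
    rows = []
    for name, fn in _METHODS.items():
        est = fn(bulk, sig)
        err = est.to_numpy() - truth.to_numpy()
        rmse = float(np.sqrt(np.mean(err**2)))
        mae = float(np.mean(np.abs(err)))
        cors = []
        for k in range(truth.shape[1]):
            t = truth.to_numpy()[:, k]
            e = est.to_numpy()[:, k]
            if t.std() > 0 and e.std() > 0:
                cors.append(np.corrcoef(t, e)[0, 1])
        rows.append(
            {
                "method": name,
                "rmse": rmse,
                "mean_abs_error": mae,
                "mean_per_type_correlation": float(np.mean(cors)) if cors else np.nan,
            }
        )
    table = (
        pd.DataFrame(rows).sort_values(["rmse", "method"], kind="stable").reset_index(drop=True)
    )
    table.attrs["chosen"] = table.loc[0, "method"]
    return table


def compare_proportions_by_sex(proportions: pd.DataFrame, sex_labels: pd.Series) -> pd.DataFrame:
    """Two-sided rank-sum test of each cell type's fractions between sexes,
    BH-adjusted across cell types."""
    from scipy.stats import mannwhitneyu

    sex = pd.Series(sex_labels).reindex(proportions.index)
    male = proportions[sex == "male"]
    female = proportions[sex == "female"]
    rows = []
    for ct in proportions.columns:
        stat, p = mannwhitneyu(male[ct], female[ct], alternative="two-sided")
        rows.append(
            {
                "cell_type": ct,
                "mean_male": float(male[ct].mean()),
                "mean_female": float(female[ct].mean()),
                "statistic": float(stat),
                "pvalue": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = multipletests_bh(out["pvalue"].to_numpy())
    return out


def multipletests_bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
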