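"""Sex-stratified cross-tissue correlation survey and significance calls.

The survey correlates every muscle-secreted gene (myokine) with every gene
of every target tissue, separately within the male and female strata, using
the biweight midcorrelation.  Edges are then called significant either by

* the per-tissue **2SD rule**: |r| exceeding the mean plus two standard
  deviations of that (tissue, stratum)'s signed coefficient distribution, or
* a fixed Student p-value cutoff (0.01 for broad surveys, 1e-6 in the
  stringent mode used for direct-interaction claims), or
* an optional BH-adjusted cutoff.

Edges are classed ``male_only`` / ``female_only`` / ``shared`` (significant
in both sexes with matching sign) / ``none``; a double-significant pair with
opposite signs is classed ``none`` and flagged discordant.  Myokines are
additionally binned by whether their muscle expression tracks ESR1, AR,
both hormone receptors, or neither, and a generic hypergeometric
overrepresentation test covers pathway enrichment on user-supplied sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bicor import bicor_matrix
from .io_filter import GeneSet

__all__ = [
    "survey",
    "threshold_2sd",
    "apply_2sd",
    "apply_p_threshold",
    "apply_bh",
    "classify_edges",
    "bin_by_receptor",
    "count_significant",
    "ora_hypergeometric",
    "SEX_CLASSES",
]

SEX_CLASSES = ("male_only", "female_only", "shared", "none")
STRATA = ("male", "female")


def survey(
    muscle_matrix: pd.DataFrame,
    myokine_list,
    target_bundle,
    sex_labels: pd.Series,
) -> pd.DataFrame:
    """All (myokine, target tissue, target gene) correlations per sex.

    Parameters
    ----------
    muscle_matrix : DataFrame
        Muscle expression (log scale), genes by samples.
    myokine_list : sequence of str
        Myokine genes; must all be rows of ``muscle_matrix``.
    target_bundle : mapping tissue -> DataFrame, or TissueExpressionBundle
        Target-tissue expression matrices (log scale).
    sex_labels : Series
        'male'/'female' indexed by sample ID.

    A tissue with fewer than 4 shared individuals in either stratum is
    skipped with a warning.  Returns a long table with one row per
    (myokine, tissue, gene) carrying per-sex coefficients and p-values.
    """
    myokines = list(myokine_list)
    missing = [m for m in myokines if m not in muscle_matrix.index]
    if missing:
        raise KeyError(f"myokines absent from muscle matrix: {missing[:5]}")
    matrices = getattr(target_bundle, "matrices", target_bundle)
    sex_labels = pd.Series(sex_labels)

    blocks = []
    for tissue, target in matrices.items():
        if tissue == "muscle":
            continue
        shared = muscle_matrix.columns.intersection(target.columns)
        strata = {}
        skip = False
        for sex in STRATA:
            ids = shared[sex_labels.reindex(shared).to_numpy() == sex]
            if len(ids) < 4:
                warnings.warn(
                    f"tissue {tissue!r}: only {len(ids)} shared {sex} samples; skipped",
                    stacklevel=2,
                )
                skip = True
                break
            strata[sex] = ids
        if skip:
            continue

        per_sex = {}
        for sex, ids in strata.items():
            res = bicor_matrix(muscle_matrix.loc[myokines], target, sample_subset=ids)
            per_sex[sex] = res
        n_my, n_tg = len(myokines), target.shape[0]
        block = pd.DataFrame(
            {
                "myokine": pd.Categorical(np.repeat(myokines, n_tg)),
                "target_tissue": pd.Categorical([tissue] * (n_my * n_tg)),
                "target_gene": pd.Categorical(np.tile(target.index.to_numpy(), n_my)),
                "bicor_male": per_sex["male"].r.to_numpy().ravel(),
                "p_male": per_sex["male"].p.to_numpy().ravel(),
                "bicor_female": per_sex["female"].r.to_numpy().ravel(),
                "p_female": per_sex["female"].p.to_numpy().ravel(),
                "n_male": per_sex["male"].n,
                "n_female": per_sex["female"].n,
            }
        )
        blocks.append(block)
    if not blocks:
        raise ValueError("no target tissue had enough shared samples in both strata")
    return pd.concat(blocks, ignore_index=True)


def threshold_2sd(edges: pd.DataFrame, tissue: str, stratum: str):
    """Significance flags for one (tissue, stratum) under the 2SD rule.

    mu and sigma are computed on the *signed* coefficient distribution of
    that tissue/stratum; an edge is flagged when |r| > mu + 2*sigma.
    Returns (boolean Series aligned to ``edges``, mu, sigma).
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    col = f"bicor_{stratum}"
    in_tissue = edges["target_tissue"] == tissue
    r = edges.loc[in_tissue, col].to_numpy()
    r = r[np.isfinite(r)]
    if len(r) < 100:
        raise ValueError(
            f"2SD rule needs >= 100 edges for tissue {tissue!r}/{stratum}, got {len(r)}"
        )
    mu, sigma = float(np.mean(r)), float(np.std(r))
    if sigma == 0.0:
        raise ValueError(f"degenerate coefficient distribution in {tissue!r}/{stratum}")
    flags = pd.Series(False, index=edges.index)
    flags.loc[in_tissue] = (edges.loc[in_tissue, col].abs() > mu + 2 * sigma).to_numpy()
    return flags, mu, sigma


def apply_2sd(edges: pd.DataFrame) -> pd.DataFrame:
    """Set ``sig_male``/``sig_female`` by the per-tissue 2SD rule.

    The per-(tissue, stratum) mean and SD are recorded in
    ``result.attrs['2sd_stats']``.
    """
    edges = edges.copy()
    stats_rows = []
    for sex in STRATA:
        flags = pd.Series(False, index=edges.index)
        for tissue in edges["target_tissue"].unique():
            f, mu, sigma = threshold_2sd(edges, tissue, sex)
            flags |= f
            stats_rows.append({"target_tissue": tissue, "stratum": sex, "mu": mu, "sigma": sigma})
        edges[f"sig_{sex}"] = flags
    edges.attrs["2sd_stats"] = pd.DataFrame(stats_rows)
    return edges


def apply_p_threshold(edges: pd.DataFrame, p: float = 0.01) -> pd.DataFrame:
    """Set significance flags from the per-stratum Student p-values."""
    if not 0 < p <= 1:
        raise ValueError("p threshold must lie in (0, 1]")
    edges = edges.copy()
    for sex in STRATA:
        edges[f"sig_{sex}"] = edges[f"p_{sex}"].notna() & (edges[f"p_{sex}"] < p)
    return edges


def apply_bh(edges: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Optional BH mode: flag on per-stratum FDR-adjusted p-values."""
    edges = edges.copy()
    for sex in STRATA:
        p = edges[f"p_{sex}"]
        ok = p.notna()
        padj = pd.Series(np.nan, index=edges.index)
        padj.loc[ok] = multipletests(p[ok], method="fdr_bh")[1]
        edges[f"padj_{sex}"] = padj
        edges[f"sig_{sex}"] = padj.notna() & (padj < alpha)
    return edges


def classify_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Assign each flagged edge its sex class.

    male_only: significant in males only; female_only symmetric; shared:
    significant in both with matching coefficient sign; none otherwise.
    Opposite-sign double-significant edges are ``none`` with
    ``discordant=True``.
    """
    for col in ("sig_male", "sig_female"):
        if col not in edges.columns:
            raise ValueError("significance flags not set; run apply_2sd/apply_p_threshold first")
    edges = edges.copy()
    sm = edges["sig_male"].to_numpy()
    sf = edges["sig_female"].to_numpy()
    same_sign = np.sign(edges["bicor_male"].to_numpy()) == np.sign(
        edges["bicor_female"].to_numpy()
    )
    cls = np.full(len(edges), "none", dtype=object)
    cls[sm & ~sf] = "male_only"
    cls[~sm & sf] = "female_only"
    cls[sm & sf & same_sign] = "shared"
    edges["sex_class"] = pd.Categorical(cls, categories=list(SEX_CLASSES))
    edges["discordant"] = sm & sf & ~same_sign
    return edges


def bin_by_receptor(
    myokines,
    muscle_matrix: pd.DataFrame,
    sex_labels: pd.Series,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Bin each myokine by hormone-receptor coregulation, per sex stratum.

    For every myokine and stratum, the bicor p-values of myokine ~ ESR1
    and myokine ~ AR are computed in muscle; the bin is ``both`` when both
    pass ``p_threshold``, ``ESR1``/``AR`` when only one does, else
    ``neither``.  Returns one row per (myokine, sex).
    """
    for receptor in ("ESR1", "AR"):
        if receptor not in muscle_matrix.index:
            raise KeyError(f"receptor row {receptor!r} missing from muscle matrix")
    myokines = list(myokines)
    sex_labels = pd.Series(sex_labels)
    rows = []
    for sex in STRATA:
        ids = muscle_matrix.columns[
            sex_labels.reindex(muscle_matrix.columns).to_numpy() == sex
        ]
        res = bicor_matrix(
            muscle_matrix.loc[myokines], muscle_matrix.loc[["ESR1", "AR"]], sample_subset=ids
        )
        p_esr1 = res.p["ESR1"].to_numpy()
        p_ar = res.p["AR"].to_numpy()
        hit_e = np.nan_to_num(p_esr1, nan=1.0) < p_threshold
        hit_a = np.nan_to_num(p_ar, nan=1.0) < p_threshold
        bins = np.where(
            hit_e & hit_a, "both", np.where(hit_e, "ESR1", np.where(hit_a, "AR", "neither"))
        )
        rows.append(
            pd.DataFrame(
                {
                    "myokine": myokines,
                    "sex": sex,
                    "bicor_ESR1": res.r["ESR1"].to_numpy(),
                    "p_ESR1": p_esr1,
                    "bicor_AR": res.r["AR"].to_numpy(),
                    "p_AR": p_ar,
                    "bin": bins,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def count_significant(edges: pd.DataFrame, group_by=("target_tissue", "sex_class")) -> pd.DataFrame:
    """Tally classified edges (sex_class != none) over grouping keys.

    ``group_by`` draws from {target_tissue, sex_class, myokine}.  Output
    is order-invariant in the input rows.
    """
    allowed = {"target_tissue", "sex_class", "myokine"}
    group_by = list(group_by)
    unknown = set(group_by) - allowed
    if unknown:
        raise ValueError(f"unknown grouping keys {sorted(unknown)}; allowed {sorted(allowed)}")
    if "sex_class" not in edges.columns:
        raise ValueError("edges must be classified first")
    sig = edges[edges["sex_class"] != "none"]
    counts = (
        sig.groupby(group_by, observed=False)
        .size()
        .rename("n_significant")
        .reset_index()
        .sort_values(group_by, kind="stable")
        .reset_index(drop=True)
    )
    return counts


def ora_hypergeometric(hit_set: GeneSet, universe: GeneSet, pathways: dict) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``hit_set`` in each pathway.

    Pathway membership is intersected with the universe first; the
    upper-tail p-value is P(overlap >= observed) under sampling
    |hit_set| genes without replacement, BH-adjusted across pathways.
    The enrichment ratio is observed / expected overlap.
    """
    if not pathways:
        raise ValueError("no pathways supplied")
    uni = set(universe.genes)
    hits = set(hit_set.genes)
    offenders = sorted(hits - uni)
    if offenders:
        raise ValueError(f"hit genes outside the universe: {offenders[:10]}")
    M, N = len(uni), len(hits)
    rows = []
    for name, members in pathways.items():
        in_uni = set(members) & uni
        K = len(in_uni)
        k = len(in_uni & hits)
        expected = K * N / M if M else np.nan
        p = stats.hypergeom.sf(k - 1, M, K, N) if K else 1.0
        rows.append(
            {
                "pathway": name,
                "pathway_size": K,
                "n_hits": N,
                "overlap": k,
                "expected": expected,
                "enrichment_ratio": (k / expected) if expected else np.nan,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)
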