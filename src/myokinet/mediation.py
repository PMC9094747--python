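"""Adjusted-regression mediation screen.

The screen asks whether a candidate mediator (a muscle-secreted gene)
carries the association between an exposure (a muscle cell-type proportion)
and a target-tissue gene.  Two least-squares regressions are compared:

* unadjusted: target ~ exposure, two-sided t-test on the exposure slope;
* adjusted:   target ~ exposure + mediator, same test on the exposure slope.

Variables are standardized by default so slopes are comparable across
genes.  The mediated call is transparent and tunable: the unadjusted
association must pass a stringent p-value threshold (default 1e-6) and the
exposure slope's p-value must rise by more than ``delta_margin`` decades
(default 2) once the mediator is included.  No formal indirect-effect test
(Sobel, bootstrap) is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bicor import bicor_matrix

__all__ = [
    "RegressionComparison",
    "top_myokine_per_celltype",
    "adjusted_regression",
    "mediation_screen",
]

_P_FLOOR = 1e-300
STRATA = ("male", "female")


@dataclass
class RegressionComparison:
    """Exposure-slope inference before and after adjusting for a mediator."""

    beta_unadj: float
    p_unadj: float
    beta_adj: float
    p_adj: float
    delta_log10p: float
    unstable: bool = False

    def mediated(
        self,
        stringent_p: float = 1e-6,
        delta_margin: float = 2.0,
        adjusted_p_floor: float = 0.01,
    ) -> bool:
        """Mediated call: a stringent unadjusted association that loses
        more than ``delta_margin`` decades of significance AND collapses
        to non-significance (p_adj above ``adjusted_p_floor``).

        The collapse condition is essential: a mediator merely collinear
        with the exposure inflates the adjusted standard error and can
        cost many decades of a very strong association without carrying
        it, so a delta margin alone over-calls mediation.
        """
        if not np.isfinite(self.p_adj):
            return False
        return (
            self.p_unadj < stringent_p
            and self.delta_log10p > delta_margin
            and self.p_adj > adjusted_p_floor
        )


def _ols_slope_test(X: np.ndarray, y: np.ndarray):
    """Least-squares fit of y on X (with intercept prepended); returns the
    coefficient, t and two-sided p of X's *first* column."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    dof = n - Xd.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for the regression")
    s2 = resid @ resid / dof
    XtX_inv = np.linalg.pinv(Xd.T @ Xd)
    se = np.sqrt(max(s2 * XtX_inv[1, 1], 1e-300))
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(beta[1]), float(max(p, _P_FLOOR))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def adjusted_regression(
    target, exposure, mediator, standardize: bool = True
) -> RegressionComparison:
    """Compare the exposure slope with and without the mediator covariate.

    Requires n >= 8 finite observations in every vector.  An exposure and
    mediator correlated beyond |r| > 0.999 make the adjusted fit
    uninterpretable: it is flagged unstable and ``p_adj`` is missing.
    """
    target = np.asarray(target, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    if not (len(target) == len(exposure) == len(mediator)):
        raise ValueError("target, exposure and mediator must have equal length")
    if len(target) < 8:
        raise ValueError("mediation regression requires n >= 8")
    if not (
        np.isfinite(target).all() and np.isfinite(exposure).all() and np.isfinite(mediator).all()
    ):
        raise ValueError("non-finite values in regression inputs")
    if standardize:
        target, exposure, mediator = map(_standardize, (target, exposure, mediator))

    beta_u, p_u = _ols_slope_test(exposure[:, None], target)

    r_em = np.corrcoef(exposure, mediator)[0, 1]
    if abs(r_em) > 0.999:
        return RegressionComparison(
            beta_unadj=beta_u,
            p_unadj=p_u,
            beta_adj=np.nan,
            p_adj=np.nan,
            delta_log10p=np.nan,
            unstable=True,
        )
    beta_a, p_a = _ols_slope_test(np.column_stack([exposure, mediator]), target)
    return RegressionComparison(
        beta_unadj=beta_u,
        p_unadj=p_u,
        beta_adj=beta_a,
        p_adj=p_a,
        delta_log10p=float(np.log10(p_a) - np.log10(p_u)),
    )


def top_myokine_per_celltype(
    proportions: pd.DataFrame,
    myokine_matrix: pd.DataFrame,
    sex_labels: pd.Series,
) -> pd.DataFrame:
    """Rank myokines by strength of association with each cell proportion.

    For every (cell type, sex) the bicor p-value of each myokine against
    the proportion vector is computed over the stratum's shared samples
    (>= 8 required); rank 1 is the strongest.  Constant proportion vectors
    are skipped with a warning.  The coefficient's sign is carried so
    positive and inverse relationships are distinguishable.
    """
    sex_labels = pd.Series(sex_labels)
    shared = proportions.index.intersection(myokine_matrix.columns)
    rows = []
    for sex in STRATA:
        ids = shared[sex_labels.reindex(shared).to_numpy() == sex]
        if len(ids) < 8:
            raise ValueError(f"need >= 8 shared {sex} samples, got {len(ids)}")
        props = proportions.loc[ids]
        for ct in proportions.columns:
            vec = props[ct].to_numpy(dtype=float)
            if vec.std() == 0:
                warnings.warn(f"constant proportions for {ct!r} in {sex}; skipped", stacklevel=2)
                continue
            res = bicor_matrix(
                pd.DataFrame([vec], index=[ct], columns=ids),
                myokine_matrix,
                sample_subset=ids,
            )
            r = res.r.iloc[0]
            p = res.p.iloc[0]
            order = pd.DataFrame({"myokine": r.index, "bicor": r.to_numpy(), "p": p.to_numpy()})
            order = order.sort_values(["p", "myokine"], kind="stable").reset_index(drop=True)
            order["rank"] = np.arange(1, len(order) + 1)
            order.insert(0, "sex", sex)
            order.insert(0, "cell_type", ct)
            order["sign"] = np.where(order["bicor"] >= 0, "positive", "negative")
            rows.append(order)
    return pd.concat(rows, ignore_index=True)


def mediation_screen(
    proportions: pd.DataFrame,
    myokine_matrix: pd.DataFrame,
    edges: pd.DataFrame,
    target_bundle,
    sex_labels: pd.Series,
    stringent_p: float = 1e-6,
    delta_margin: float = 2.0,
    adjusted_p_floor: float = 0.01,
    top_k_targets: int | None = 5,
    exposures=None,
) -> pd.DataFrame:
    """Screen cell-proportion -> top myokine -> target-gene triplets.

    For each sex and each exposure cell type, the top-ranked myokine for
    that (cell type, sex) is the candidate mediator.  Target genes are
    taken from ``edges`` rows whose myokine is that mediator and whose
    Student p in the stratum passes ``stringent_p`` (optionally limited to
    the ``top_k_targets`` best per tissue).  Each triplet is run through
    :func:`adjusted_regression` on the stratum's samples, and flagged
    mediated when the unadjusted association is stringent-significant and
    adjustment costs more than ``delta_margin`` decades of significance.
    """
    matrices = getattr(target_bundle, "matrices", target_bundle)
    sex_labels = pd.Series(sex_labels)
    ranking = top_myokine_per_celltype(proportions, myokine_matrix, sex_labels)
    exposures = list(exposures) if exposures is not None else list(proportions.columns)

    shared = proportions.index.intersection(myokine_matrix.columns)
    records = []
    for sex in STRATA:
        ids = shared[sex_labels.reindex(shared).to_numpy() == sex]
        for ct in exposures:
            top = ranking[
                (ranking["sex"] == sex) & (ranking["cell_type"] == ct) & (ranking["rank"] == 1)
            ]
            if top.empty:
                continue
            mediator_gene = top["myokine"].iloc[0]
            pcol = f"p_{sex}"
            sel = edges[
                (edges["myokine"] == mediator_gene)
                & edges[pcol].notna()
                & (edges[pcol] < stringent_p)
            ]
            if top_k_targets is not None and len(sel):
                sel = (
                    sel.sort_values(pcol, kind="stable")
                    .groupby("target_tissue", observed=True)
                    .head(top_k_targets)
                )
            for _, row in sel.iterrows():
                tissue, gene = str(row["target_tissue"]), str(row["target_gene"])
                tmat = matrices[tissue]
                tids = ids[ids.isin(tmat.columns)]
                if len(tids) < 8:
                    continue
                cmp = adjusted_regression(
                    tmat.loc[gene, tids].to_numpy(dtype=float),
                    proportions.loc[tids, ct].to_numpy(dtype=float),
                    myokine_matrix.loc[mediator_gene, tids].to_numpy(dtype=float),
                )
                records.append(
                    {
                        "sex": sex,
                        "exposure": ct,
                        "mediator": mediator_gene,
                        "target_tissue": tissue,
                        "target_gene": gene,
                        "beta_unadj": cmp.beta_unadj,
                        "p_unadj": cmp.p_unadj,
                        "beta_adj": cmp.beta_adj,
                        "p_adj": cmp.p_adj,
                        "delta_log10p": cmp.delta_log10p,
                        "unstable": cmp.unstable,
                        "mediated": cmp.mediated(stringent_p, delta_margin, adjusted_p_floor),
                    }
                )
    if not records:
        raise ValueError("no stringent-significant edges for any candidate mediator")
    return pd.DataFrame(records)
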