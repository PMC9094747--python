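"""Synthetic two-sex multi-tissue cohorts with exported ground truth.

The generator emulates the statistical structure every downstream stage
consumes, without any external data:

* a cohort of unequal male/female sample size with one muscle matrix
  (muscle-secreted genes, the hormone receptors ESR1 and AR, cell-type
  marker genes, filler genes) and several target-tissue matrices;
* planted myokine -> (tissue, gene) correlations induced by shared
  per-individual latent factors, so a configured edge strength is the
  population correlation of the pair (edge strength = product of factor
  loadings).  Sex-specific edges carry a zero target loading in the other
  sex; ``null``-class edges carry zero loadings in both;
* a subset of myokines coregulated with ESR1 and/or AR through receptor
  latent variables;
* sex-differential myokines with a configured log2 fold-change;
* muscle cell composition drawn from a Dirichlet, with marker genes
  composed as signature x proportions, and mediation triplets
  cell-proportion -> myokine -> target-tissue gene;
* a clustered single-cell reference with planted marker genes.

All continuous latent structure is mapped through ``exp`` to a
negative-binomial mean with common dispersion, so the count matrices match
the DE module's model.  Because the count layer adds observation noise on
the log scale, planted loadings are analytically inflated by the predicted
attenuation factor so that the *observed* log-expression correlation of a
planted pair matches the configured strength.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .io_filter import TissueExpressionBundle, write_bundle

__all__ = [
    "PlantedEdge",
    "MediationTriplet",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_single_cell_reference",
    "simulate_mixtures",
    "simulate_mediation_triplet",
    "write_cohort",
    "write_single_cell",
    "read_single_cell",
]

EDGE_CLASSES = ("male_only", "female_only", "shared", "null")
RECEPTOR_BINS = ("ESR1", "AR", "both", "neither")


@dataclass(frozen=True)
class PlantedEdge:
    myokine: str
    target_tissue: str
    target_gene: str
    strength: float
    sex_class: str

    def __post_init__(self):
        if not -1.0 < self.strength < 1.0:
            raise ValueError(f"edge strength must lie strictly in (-1, 1): {self.strength}")
        if self.sex_class not in EDGE_CLASSES:
            raise ValueError(f"unknown sex_class {self.sex_class!r}")


@dataclass(frozen=True)
class MediationTriplet:
    cell_type: str
    myokine: str
    target_tissue: str
    target_gene: str
    a: float  # exposure -> mediator path
    b: float  # mediator -> target path (full) / direct strength factor (independent)
    kind: str  # "full_mediation" | "independent"

    def __post_init__(self):
        if self.kind not in ("full_mediation", "independent"):
            raise ValueError(f"unknown mediation kind {self.kind!r}")


def _myokine_name(i: int) -> str:
    return f"MYOK_{i + 1:04d}"


def _tissue_gene(tissue: str, i: int) -> str:
    return f"{tissue[:3].upper()}_G{i + 1:04d}"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the desk-scale fixture: 100 male / 50 female individuals,
    muscle plus three target tissues, 2000 genes per tissue, 200 myokines.
    ``default()`` additionally plants the standard truth structure (edges
    at strength 0.4 across classes, receptor-driven and sex-differential
    myokine sets, mediation triplets).
    """

    seed: int = 0
    n_male: int = 100
    n_female: int = 50
    tissues: tuple = ("muscle", "liver", "pancreas", "adipose")
    genes_per_tissue: int = 2000
    n_myokines: int = 200
    # receptor coregulation
    receptor_driven_fraction: float = 0.3
    receptor_split: tuple = (0.6, 0.2, 0.2)  # ESR1-only, AR-only, both
    receptor_coupling: float = 0.6  # target observed correlation with the receptor
    receptor_coupling_both: float = 0.55
    # planted cross-tissue edges
    planted_edges: tuple = ()
    # sex-differential myokines
    n_de_myokines: int = 40
    de_log2fc: float = 2.0
    # muscle composition / single-cell reference
    cell_types: tuple = ("fast_glycolytic", "slow_oxidative", "endothelial", "immune", "satellite")
    dirichlet_alpha: tuple = (8.0, 6.0, 2.0, 1.5, 1.0)
    markers_per_cell_type: int = 10
    cells_per_type: int = 50
    sc_background_genes: int = 100
    sc_marker_high: float = 20.0
    sc_marker_low: float = 2.0
    sc_background_mean: float = 5.0
    sc_dispersion: float = 0.1
    bulk_marker_scale: float = 25.0
    mixture_noise_sd: float = 0.1  # as a fraction of the mean signature entry
    # observation layer
    nb_dispersion: float = 0.05
    latent_sd: float = 1.2  # natural-log-scale biological spread
    base_log_mean: float = float(np.log(500.0))  # planted genes
    filler_log_mean: float = float(np.log(80.0))
    filler_log_sd: float = 1.0
    # mediation
    mediation_triplets: tuple = ()

    def __post_init__(self):
        self.tissues = tuple(self.tissues)
        self.cell_types = tuple(self.cell_types)
        self.dirichlet_alpha = tuple(float(a) for a in self.dirichlet_alpha)
        self.receptor_split = tuple(float(x) for x in self.receptor_split)
        self.planted_edges = tuple(
            e if isinstance(e, PlantedEdge) else PlantedEdge(**e) for e in self.planted_edges
        )
        self.mediation_triplets = tuple(
            t if isinstance(t, MediationTriplet) else MediationTriplet(**t)
            for t in self.mediation_triplets
        )
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self):
        if self.n_male < 4 or self.n_female < 4:
            raise ValueError("need at least 4 samples per sex")
        if len(self.tissues) < 2 or self.tissues[0] != "muscle":
            raise ValueError("tissues must start with 'muscle' and include a target")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("duplicate tissue names")
        if self.n_myokines > self.genes_per_tissue:
            raise ValueError("n_myokines exceeds genes_per_tissue")
        n_markers = self.markers_per_cell_type * len(self.cell_types)
        if self.n_myokines + 2 + n_markers > self.genes_per_tissue:
            raise ValueError("genes_per_tissue too small for myokines + receptors + markers")
        if not 0.0 <= self.receptor_driven_fraction <= 1.0:
            raise ValueError("receptor_driven_fraction must lie in [0, 1]")
        if abs(sum(self.receptor_split) - 1.0) > 1e-9:
            raise ValueError("receptor_split must sum to 1")
        if len(self.dirichlet_alpha) != len(self.cell_types):
            raise ValueError("dirichlet_alpha length must match cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("Dirichlet parameters must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.mixture_noise_sd < 0:
            raise ValueError("mixture_noise_sd must be nonnegative")
        myok = {_myokine_name(i) for i in range(self.n_myokines)}
        target_genes = {
            t: {_tissue_gene(t, i) for i in range(self.genes_per_tissue)}
            for t in self.tissues[1:]
        }
        for e in self.planted_edges:
            if e.myokine not in myok:
                raise ValueError(f"planted edge names unknown myokine {e.myokine!r}")
            if e.target_tissue not in target_genes:
                raise ValueError(f"planted edge names unknown tissue {e.target_tissue!r}")
            if e.target_gene not in target_genes[e.target_tissue]:
                raise ValueError(f"planted edge names unknown gene {e.target_gene!r}")
        for t in self.mediation_triplets:
            if t.cell_type not in self.cell_types:
                raise ValueError(f"mediation triplet names unknown cell type {t.cell_type!r}")
            if t.myokine not in myok:
                raise ValueError(f"mediation triplet names unknown myokine {t.myokine!r}")
            if t.target_tissue not in target_genes:
                raise ValueError(f"mediation triplet names unknown tissue {t.target_tissue!r}")
            if t.target_gene not in target_genes[t.target_tissue]:
                raise ValueError(f"mediation triplet names unknown gene {t.target_gene!r}")

    # -- factory with the standard planted truth ----------------------
    @classmethod
    def default(
        cls,
        seed: int = 0,
        edge_strength: float = 0.4,
        edges_per_class: tuple = (20, 20, 20, 10),
        n_triplets: int = 10,
        **overrides,
    ) -> "SimulationConfig":
        """The default planted-truth cohort.

        Plants ``edges_per_class`` (male_only, female_only, shared, null)
        edges at the given strength (every fourth edge negative), spread
        round-robin over the target tissues, plus ``n_triplets`` mediation
        triplets (half full-mediation, half independent).  Myokine roles
        (edge source, DE, receptor-driven, mediator) are disjoint so truth
        classes are unambiguous.
        """
        base = cls(seed=seed, **overrides)
        targets = base.tissues[1:]
        edges = []
        k = 0
        per_tissue = {t: 0 for t in targets}
        class_sizes = zip(("male_only", "female_only", "shared", "null"), edges_per_class)
        for sex_class, n_cls in class_sizes:
            for _ in range(n_cls):
                t = targets[k % len(targets)]
                sign = -1.0 if k % 4 == 3 else 1.0
                edges.append(
                    PlantedEdge(
                        myokine=_myokine_name(k),
                        target_tissue=t,
                        target_gene=_tissue_gene(t, per_tissue[t]),
                        strength=sign * edge_strength,
                        sex_class=sex_class,
                    )
                )
                per_tissue[t] += 1
                k += 1
        n_edge_myok = k
        mediators_start = n_edge_myok + base.n_de_myokines + int(
            round(base.receptor_driven_fraction * base.n_myokines)
        )
        if mediators_start + n_triplets > base.n_myokines:
            raise ValueError(
                "n_myokines too small for the planted roles: need "
                f">= {mediators_start + n_triplets}, have {base.n_myokines}"
            )
        triplets = []
        med_gene_start = base.genes_per_tissue - 2 * n_triplets
        for j in range(n_triplets):
            kind = "full_mediation" if j < (n_triplets + 1) // 2 else "independent"
            t = targets[j % len(targets)]
            triplets.append(
                MediationTriplet(
                    cell_type=base.cell_types[j % 2],
                    myokine=_myokine_name(mediators_start + j),
                    target_tissue=t,
                    target_gene=_tissue_gene(t, med_gene_start + j),
                    a=0.85,
                    b=0.85,
                    kind=kind,
                )
            )
        return cls(
            seed=seed,
            planted_edges=tuple(edges),
            mediation_triplets=tuple(triplets),
            **overrides,
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_edges"] = [asdict(e) for e in self.planted_edges]
        d["mediation_triplets"] = [asdict(t) for t in self.mediation_triplets]
        for key in ("tissues", "cell_types", "dirichlet_alpha", "receptor_split"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort — the acceptance surface."""

    de_table: pd.DataFrame  # index myokine; log2FC (male-positive), category
    receptor_map: pd.DataFrame  # index myokine; bin in RECEPTOR_BINS
    edge_table: pd.DataFrame  # myokine, target_tissue, target_gene, strength, sex_class
    true_proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    mediation_table: pd.DataFrame  # triplet fields + kind
    markers: dict = field(default_factory=dict)  # cell type -> planted marker genes

    def __post_init__(self):
        rowsum = self.true_proportions.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-12):
            raise ValueError("true_proportions rows must sum to 1")
        bad = set(self.edge_table["sex_class"]) - set(EDGE_CLASSES)
        if bad:
            raise ValueError(f"unknown edge classes {bad}")
        bad = set(self.receptor_map["bin"]) - set(RECEPTOR_BINS)
        if bad:
            raise ValueError(f"unknown receptor bins {bad}")


# ---------------------------------------------------------------------------


def _attenuation(cfg: SimulationConfig, log_mean: float) -> float:
    """Predicted correlation attenuation of one variable by the count layer.

    On the log scale the NB observation noise has variance ~ alpha + 1/mu
    (delta method), so the observed log-expression correlates with the
    latent at s / sqrt(s^2 + sigma^2).
    """
    s2 = cfg.latent_sd**2
    sigma2 = cfg.nb_dispersion + 1.0 / float(np.exp(log_mean))
    return float(np.sqrt(s2 / (s2 + sigma2)))


def _compensated(cfg: SimulationConfig, rho: float) -> float:
    """Latent correlation delivering observed correlation ``rho`` for a
    pair of planted genes at the standard base expression."""
    att = _attenuation(cfg, cfg.base_log_mean)
    return float(np.clip(rho / (att * att), -0.98, 0.98))


def _nb_counts(rng, log_mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.exp(np.clip(log_mu, None, 25.0))
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _assign_roles(cfg: SimulationConfig):
    """Deterministic disjoint myokine role assignment.

    Myokines referenced by planted edges or mediation triplets keep those
    roles; sex-DE and receptor-driven myokines are drawn in order from the
    remaining pool.
    """
    names = [_myokine_name(i) for i in range(cfg.n_myokines)]
    edge_myok = {e.myokine for e in cfg.planted_edges}
    med_myok = {t.myokine for t in cfg.mediation_triplets}
    free = [m for m in names if m not in edge_myok and m not in med_myok]
    n_recep = int(round(cfg.receptor_driven_fraction * cfg.n_myokines))
    if cfg.n_de_myokines + n_recep > len(free):
        raise ValueError("not enough unassigned myokines for DE and receptor roles")
    de = free[: cfg.n_de_myokines]
    pool = free[cfg.n_de_myokines : cfg.n_de_myokines + n_recep]
    n_esr1 = int(round(cfg.receptor_split[0] * n_recep))
    n_ar = int(round(cfg.receptor_split[1] * n_recep))
    receptor = {}
    for j, m in enumerate(pool):
        receptor[m] = "ESR1" if j < n_esr1 else ("AR" if j < n_esr1 + n_ar else "both")
    return names, de, receptor


def simulate_cohort(cfg: SimulationConfig):
    """Generate (bundle, sample table, ground truth) for one cohort.

    The muscle matrix contains all myokines, ESR1, AR, the cell-type
    marker genes (composed as signature x true proportions) and filler
    genes; each target tissue contains planted edge/mediation target genes
    plus fillers.  All matrices are nonnegative-integer counts under the
    NB observation layer.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_male + cfg.n_female
    sample_ids = [f"IND{i + 1:04d}" for i in range(n)]
    sex = np.array(["male"] * cfg.n_male + ["female"] * cfg.n_female)
    male_mask = sex == "male"
    samples = pd.DataFrame({"sex": sex}, index=pd.Index(sample_ids, name="sample_id"))

    names, de_myok, receptor_roles = _assign_roles(cfg)
    myok_pos = {m: i for i, m in enumerate(names)}

    # --- latent building blocks (fixed draw order for determinism) ----
    proportions = rng.dirichlet(cfg.dirichlet_alpha, size=n)
    proportions /= proportions.sum(axis=1, keepdims=True)
    esr1_lat = rng.standard_normal(n)
    ar_lat = rng.standard_normal(n)
    edge_myokines = sorted({e.myokine for e in cfg.planted_edges})
    factors = {m: rng.standard_normal(n) for m in edge_myokines}
    eps_myok = rng.standard_normal((cfg.n_myokines, n))

    prop_df = pd.DataFrame(proportions, index=samples.index, columns=list(cfg.cell_types))
    prop_std = (proportions - proportions.mean(axis=0)) / proportions.std(axis=0)
    type_pos = {c: k for k, c in enumerate(cfg.cell_types)}

    # --- myokine latent matrix ----------------------------------------
    z_myok = np.zeros((cfg.n_myokines, n))
    load2 = np.zeros(cfg.n_myokines)  # accumulated squared loading

    # receptor coupling (compensated for count-layer attenuation)
    lam_single = _compensated(cfg, cfg.receptor_coupling)
    lam_both = _compensated(cfg, cfg.receptor_coupling_both)
    for m, role in receptor_roles.items():
        i = myok_pos[m]
        if role == "ESR1":
            z_myok[i] += lam_single * esr1_lat
            load2[i] += lam_single**2
        elif role == "AR":
            z_myok[i] += lam_single * ar_lat
            load2[i] += lam_single**2
        else:
            z_myok[i] += lam_both * (esr1_lat + ar_lat)
            load2[i] += 2 * lam_both**2

    # edge-source loading: one shared factor per myokine, loading set by
    # its strongest edge; per-edge target loadings divide out below
    myok_edge_loading = {}
    for m in edge_myokines:
        strengths = [
            abs(_compensated(cfg, e.strength))
            for e in cfg.planted_edges
            if e.myokine == m and e.sex_class != "null"
        ]
        u = float(np.sqrt(max(strengths))) if strengths else 0.0
        myok_edge_loading[m] = u
        i = myok_pos[m]
        z_myok[i] += u * factors[m]
        load2[i] += u**2

    # mediation mediators ride on the (standardized) exposure proportion
    lam_med = {}
    att = _attenuation(cfg, cfg.base_log_mean)
    for t in cfg.mediation_triplets:
        i = myok_pos[t.myokine]
        a_lat = float(np.clip(t.a / att, -0.98, 0.98))
        lam_med[t.myokine] = a_lat
        z_myok[i] += a_lat * prop_std[:, type_pos[t.cell_type]]
        load2[i] += a_lat**2

    if (load2 > 1.0).any():
        raise ValueError("combined latent loadings exceed unit variance for some myokine")
    z_myok += np.sqrt(1.0 - load2)[:, None] * eps_myok

    # sex-DE shifts (male-positive log2FC convention)
    de_lfc = {}
    for j, m in enumerate(de_myok):
        de_lfc[m] = cfg.de_log2fc if j % 2 == 0 else -cfg.de_log2fc

    # --- muscle matrix -------------------------------------------------
    n_markers = cfg.markers_per_cell_type * len(cfg.cell_types)
    marker_names, markers_by_type = [], {}
    for ct in cfg.cell_types:
        markers_by_type[ct] = [
            f"MRK_{ct}_{j + 1:02d}" for j in range(cfg.markers_per_cell_type)
        ]
        marker_names += markers_by_type[ct]
    n_filler = cfg.genes_per_tissue - cfg.n_myokines - 2 - n_markers
    filler_names = [f"MUS_G{i + 1:04d}" for i in range(n_filler)]

    log_mu_myok = cfg.base_log_mean + cfg.latent_sd * z_myok
    for m, lfc in de_lfc.items():
        i = myok_pos[m]
        if lfc > 0:
            log_mu_myok[i, male_mask] += np.log(2.0) * lfc
        else:
            log_mu_myok[i, ~male_mask] += np.log(2.0) * (-lfc)

    log_mu_receptors = cfg.base_log_mean + cfg.latent_sd * np.vstack([esr1_lat, ar_lat])

    # markers: signature x proportions on the count-mean scale
    profile = np.full((n_markers, len(cfg.cell_types)), cfg.sc_marker_low)
    for k, ct in enumerate(cfg.cell_types):
        rows = [marker_names.index(g) for g in markers_by_type[ct]]
        profile[rows, k] = cfg.sc_marker_high
    mu_markers = cfg.bulk_marker_scale * (profile @ proportions.T)

    filler_base = rng.normal(cfg.filler_log_mean, cfg.filler_log_sd, size=n_filler)
    log_mu_filler = filler_base[:, None] + cfg.latent_sd * rng.standard_normal((n_filler, n))

    muscle_counts = np.vstack(
        [
            _nb_counts(rng, log_mu_myok, cfg.nb_dispersion),
            _nb_counts(rng, log_mu_receptors, cfg.nb_dispersion),
            _nb_counts(rng, np.log(np.maximum(mu_markers, 1e-8)), cfg.nb_dispersion),
            _nb_counts(rng, log_mu_filler, cfg.nb_dispersion),
        ]
    )
    muscle_genes = names + ["ESR1", "AR"] + marker_names + filler_names
    matrices = {
        "muscle": pd.DataFrame(muscle_counts, index=muscle_genes, columns=samples.index)
    }

    # --- target tissues -------------------------------------------------
    edges_by_tissue = {}
    for e in cfg.planted_edges:
        edges_by_tissue.setdefault(e.target_tissue, {})[e.target_gene] = e
    med_by_tissue = {}
    for t in cfg.mediation_triplets:
        med_by_tissue.setdefault(t.target_tissue, {})[t.target_gene] = t

    for tissue in cfg.tissues[1:]:
        genes = [_tissue_gene(tissue, i) for i in range(cfg.genes_per_tissue)]
        z = rng.standard_normal((cfg.genes_per_tissue, n))  # base noise draws
        base = np.full(cfg.genes_per_tissue, cfg.filler_log_mean)
        planted_here = edges_by_tissue.get(tissue, {})
        med_here = med_by_tissue.get(tissue, {})
        for gi, g in enumerate(genes):
            if g in planted_here:
                e = planted_here[g]
                base[gi] = cfg.base_log_mean
                if e.sex_class == "null":
                    continue
                u = myok_edge_loading[e.myokine]
                v = _compensated(cfg, e.strength) / u
                if abs(v) > 1.0:
                    raise ValueError("inconsistent edge loadings")
                active = np.ones(n, dtype=bool)
                if e.sex_class == "male_only":
                    active = male_mask
                elif e.sex_class == "female_only":
                    active = ~male_mask
                zi = z[gi].copy()
                zi[active] = v * factors[e.myokine][active] + np.sqrt(1 - v**2) * z[gi][active]
                z[gi] = zi
            elif g in med_here:
                t = med_here[g]
                base[gi] = cfg.base_log_mean
                if t.kind == "full_mediation":
                    b_lat = float(np.clip(t.b / att, -0.98, 0.98))
                    mediator = z_myok[myok_pos[t.myokine]]
                    z[gi] = b_lat * mediator + np.sqrt(1 - b_lat**2) * z[gi]
                else:
                    c_lat = float(np.clip(t.a * t.b / att, -0.98, 0.98))
                    x = prop_std[:, type_pos[t.cell_type]]
                    z[gi] = c_lat * x + np.sqrt(1 - c_lat**2) * z[gi]
        base_noise = rng.normal(0.0, cfg.filler_log_sd, size=cfg.genes_per_tissue)
        planted_mask = np.array([g in planted_here or g in med_here for g in genes])
        base = base + np.where(planted_mask, 0.0, base_noise)
        log_mu = base[:, None] + cfg.latent_sd * z
        matrices[tissue] = pd.DataFrame(
            _nb_counts(rng, log_mu, cfg.nb_dispersion), index=genes, columns=samples.index
        )

    bundle = TissueExpressionBundle(matrices=matrices, samples=samples, units="counts")

    # --- ground truth ---------------------------------------------------
    de_rows = [
        {"myokine": m, "log2FC": lfc, "category": "male" if lfc > 0 else "female"}
        for m, lfc in de_lfc.items()
    ]
    de_table = pd.DataFrame(de_rows, columns=["myokine", "log2FC", "category"]).set_index(
        "myokine"
    )
    receptor_map = pd.DataFrame(
        {"bin": [receptor_roles.get(m, "neither") for m in names]},
        index=pd.Index(names, name="myokine"),
    )
    edge_table = pd.DataFrame(
        [asdict(e) for e in cfg.planted_edges],
        columns=["myokine", "target_tissue", "target_gene", "strength", "sex_class"],
    )
    mediation_table = pd.DataFrame(
        [asdict(t) for t in cfg.mediation_triplets],
        columns=["cell_type", "myokine", "target_tissue", "target_gene", "a", "b", "kind"],
    )
    truth = GroundTruth(
        de_table=de_table,
        receptor_map=receptor_map,
        edge_table=edge_table,
        true_proportions=prop_df,
        mediation_table=mediation_table,
        markers=markers_by_type,
    )
    return bundle, samples, truth


def simulate_single_cell_reference(cfg: SimulationConfig):
    """Clustered single-cell counts with planted marker genes.

    Each cell type's markers have mean expression ``sc_marker_high`` in
    that type versus ``sc_marker_low`` elsewhere (a >= 5-fold separation at
    the defaults); background genes are flat.  Returns (cell-by-gene
    counts DataFrame, cluster label Series aligned to rows).
    """
    if len(cfg.cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if cfg.markers_per_cell_type < 1:
        raise ValueError("markers_per_cell_type must be >= 1")
    if cfg.cells_per_type < 1:
        raise ValueError("cells_per_type must be >= 1")
    rng = np.random.default_rng(cfg.seed + 1)

    marker_names, markers_by_type = [], {}
    for ct in cfg.cell_types:
        markers_by_type[ct] = [
            f"MRK_{ct}_{j + 1:02d}" for j in range(cfg.markers_per_cell_type)
        ]
        marker_names += markers_by_type[ct]
    genes = marker_names + [f"SCBG_{i + 1:03d}" for i in range(cfg.sc_background_genes)]

    rows, labels, cells = [], [], []
    for ct in cfg.cell_types:
        mu = np.full(len(genes), cfg.sc_background_mean)
        for g in marker_names:
            mu[genes.index(g)] = cfg.sc_marker_low
        for g in markers_by_type[ct]:
            mu[genes.index(g)] = cfg.sc_marker_high
        block = _nb_counts(
            rng, np.log(np.tile(mu, (cfg.cells_per_type, 1))), cfg.sc_dispersion
        )
        rows.append(block)
        labels += [ct] * cfg.cells_per_type
        cells += [f"{ct}_c{j + 1:03d}" for j in range(cfg.cells_per_type)]

    counts = pd.DataFrame(np.vstack(rows), index=pd.Index(cells, name="cell"), columns=genes)
    return counts, pd.Series(labels, index=counts.index, name="cluster")


def simulate_mixtures(
    signature: pd.DataFrame,
    n_samples: int,
    dirichlet_alpha,
    noise_sd: float,
    seed: int,
):
    """Bulk mixtures bulk = signature x proportions^T + truncated noise.

    ``signature`` is genes x cell types.  Gaussian noise with the given sd
    is added and truncated at zero; true proportion rows sum to 1.
    Returns (bulk genes x samples, proportions samples x cell types).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape != (signature.shape[1],):
        raise ValueError(
            f"dirichlet_alpha length {alpha.shape[0]} != {signature.shape[1]} cell types"
        )
    if (alpha <= 0).any():
        raise ValueError("Dirichlet parameters must be positive")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(alpha, size=n_samples)
    props /= props.sum(axis=1, keepdims=True)
    bulk = signature.to_numpy(dtype=float) @ props.T
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd, size=bulk.shape)
    bulk = np.maximum(bulk, 0.0)
    sample_ids = [f"MIX{i + 1:04d}" for i in range(n_samples)]
    return (
        pd.DataFrame(bulk, index=signature.index, columns=sample_ids),
        pd.DataFrame(props, index=sample_ids, columns=signature.columns),
    )


def simulate_mediation_triplet(n: int, a: float, b: float, kind: str, seed: int):
    """One (exposure, mediator, target) draw for mediation benchmarking.

    ``full_mediation``: mediator = a*exposure + noise, target = b*mediator
    + noise, so the exposure-target association flows entirely through the
    mediator.  ``independent``: the mediator still tracks the exposure but
    the target is tied to the exposure directly with matched marginal
    strength a*b.
    """
    if kind not in ("full_mediation", "independent"):
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    exposure = rng.standard_normal(n)
    mediator = a * exposure + np.sqrt(1 - a**2) * rng.standard_normal(n)
    if kind == "full_mediation":
        target = b * mediator + np.sqrt(1 - b**2) * rng.standard_normal(n)
    else:
        c = a * b
        target = c * exposure + np.sqrt(1 - c**2) * rng.standard_normal(n)
    return exposure, mediator, target


# ---------------------------------------------------------------------------
# disk round-trips


def write_cohort(bundle, truth: GroundTruth, cfg: SimulationConfig, outdir):
    """Write the cohort (TSV per tissue + samples.tsv), truth tables and a
    YAML echo of the configuration."""
    outdir = Path(outdir)
    write_bundle(bundle, outdir)
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    truth.de_table.to_csv(tdir / "de_table.tsv", sep="\t")
    truth.receptor_map.to_csv(tdir / "receptor_map.tsv", sep="\t")
    truth.edge_table.to_csv(tdir / "edge_table.tsv", sep="\t", index=False)
    truth.true_proportions.to_csv(tdir / "true_proportions.tsv", sep="\t")
    truth.mediation_table.to_csv(tdir / "mediation_table.tsv", sep="\t", index=False)
    pd.Series(
        {ct: ",".join(gs) for ct, gs in truth.markers.items()}, name="markers"
    ).to_csv(tdir / "markers.tsv", sep="\t", index_label="cell_type")
    cfg.to_yaml(outdir / "config.yaml")
    return outdir


def write_single_cell(counts: pd.DataFrame, labels: pd.Series, outdir):
    """MatrixMarket export: matrix.mtx (cells x genes) + genes/barcodes/clusters TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.columns).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.index).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    labels.to_csv(outdir / "clusters.tsv", sep="\t", index_label="cell", header=["cluster"])
    return outdir


def read_single_cell(indir):
    """Read the MatrixMarket layout written by :func:`write_single_cell`."""
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").toarray()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    clusters = pd.read_csv(indir / "clusters.tsv", sep="\t", index_col=0)["cluster"]
    counts = pd.DataFrame(mat, index=pd.Index(cells, name="cell"), columns=genes)
    return counts, clusters.loc[counts.index]
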