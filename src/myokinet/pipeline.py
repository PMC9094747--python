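"""End-to-end pipeline: simulate/load -> filter -> sex DE -> cross-tissue
survey -> deconvolution -> mediation -> machine-readable summary.

Every stage is a pure function of its declared inputs plus the seed, so a
rerun with the same configuration writes byte-identical outputs.  Stage
failures are re-raised with the stage name and a fingerprint of the inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import crosstissue, deconv, io_filter, mediation, sexde
from .synthetic import (
    SimulationConfig,
    simulate_cohort,
    simulate_single_cell_reference,
    write_cohort,
    write_single_cell,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

EDGE_MODES = ("2sd", "p01", "p1e6", "bh")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and an input fingerprint."""


@dataclass
class PipelineConfig:
    """Thresholds and data source for one pipeline run.

    Either ``simulate`` (a :class:`SimulationConfig`) or ``bundle_dir``
    (a directory of per-tissue TSVs, samples.tsv and a myokine list) must
    be given.  Threshold defaults follow the analysis conventions: DE
    binning at p < 0.05, receptor binning at p < 0.01, stringent direct-
    interaction calls at p < 1e-6, top-30 signature markers.
    """

    seed: int = 0
    outdir: str | Path = "myokinet_out"
    simulate: SimulationConfig | None = None
    bundle_dir: str | Path | None = None
    myokine_file: str | Path | None = None
    de_alpha: float = 0.05
    edge_mode: str = "2sd"
    receptor_p: float = 0.01
    stringent_p: float = 1e-6
    top_n_markers: int = 30
    top_k_genes: int = 1000
    mstn_p: float = 1e-4
    delta_margin: float = 2.0
    min_count: int = 10
    min_individuals: int = 50
    min_nonzero_combinations: int = 0
    benchmark_samples: int = 100

    def __post_init__(self):
        if self.edge_mode not in EDGE_MODES:
            raise ValueError(f"edge_mode must be one of {EDGE_MODES}")
        for name in ("de_alpha", "receptor_p", "stringent_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.simulate is None and self.bundle_dir is None:
            self.simulate = SimulationConfig.default(seed=self.seed)
        if self.simulate is not None and not isinstance(self.simulate, SimulationConfig):
            self.simulate = SimulationConfig.from_dict(dict(self.simulate))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def to_dict(self) -> dict:
        d = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
            if k != "simulate"
        }
        d["simulate"] = self.simulate.to_dict() if self.simulate else None
        return d


def _stage(name, fn, *args, fingerprint="", **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {name!r} failed ({fingerprint}): {exc}") from exc


def _fingerprint_bundle(bundle) -> str:
    shapes = {t: m.shape for t, m in bundle.matrices.items()}
    return f"tissues={shapes}, n_samples={len(bundle.samples)}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the summary dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage: data -------------------------------------------------
    if config.simulate is not None:
        sim_cfg = config.simulate
        bundle, samples, truth = _stage(
            "simulate", simulate_cohort, sim_cfg, fingerprint=f"seed={sim_cfg.seed}"
        )
        myokines = list(truth.receptor_map.index)
        write_cohort(bundle, truth, sim_cfg, outdir / "cohort")
        sc_counts, sc_labels = simulate_single_cell_reference(sim_cfg)
        write_single_cell(sc_counts, sc_labels, outdir / "single_cell")
    else:
        bdir = Path(config.bundle_dir)
        if not bdir.is_dir():
            raise PipelineError(f"stage 'load' failed: bundle directory {bdir} does not exist")
        tissue_paths = {
            p.stem: p for p in sorted(bdir.glob("*.tsv")) if p.stem != "samples"
        }
        bundle = _stage(
            "load", io_filter.load_bundle, tissue_paths, bdir / "samples.tsv",
            fingerprint=str(bdir),
        )
        if config.myokine_file is None:
            raise PipelineError("stage 'load' failed: myokine_file required in non-simulate mode")
        myokines = list(io_filter.load_gene_set(config.myokine_file).genes)
        truth = None
        sc_counts = sc_labels = None

    # ---- stage: filter -----------------------------------------------
    fp = _fingerprint_bundle(bundle)
    if config.min_nonzero_combinations > 0:
        bundle = _stage(
            "filter_individuals",
            io_filter.filter_individuals_cross_tissue,
            bundle,
            config.min_nonzero_combinations,
            fingerprint=fp,
        )
    filtered = {}
    for tissue, mat in bundle.matrices.items():
        min_ind = min(config.min_individuals, mat.shape[1])
        filtered[tissue] = _stage(
            "filter_genes",
            io_filter.filter_genes_min_counts,
            mat,
            config.min_count,
            min_ind,
            fingerprint=f"{tissue}: {mat.shape}",
        )
    bundle = io_filter.TissueExpressionBundle(
        matrices=filtered, samples=bundle.samples, units="counts"
    )
    myokines = [m for m in myokines if m in bundle.matrices["muscle"].index]
    sex_labels = bundle.samples["sex"]

    # ---- stage: sex DE -----------------------------------------------
    de = _stage(
        "sexde",
        sexde.test_sex_de,
        bundle.matrices["muscle"].loc[myokines],
        sex_labels.loc[bundle.matrices["muscle"].columns],
        config.de_alpha,
        fingerprint=f"{len(myokines)} myokines",
    )
    de_props = de["category"].value_counts(normalize=True)
    de.to_csv(outdir / "sex_de.tsv", sep="\t", index_label="gene")

    # ---- stage: cross-tissue survey ----------------------------------
    logged = {t: io_filter.log_cpm(m) for t, m in bundle.matrices.items()}
    edges = _stage(
        "survey",
        crosstissue.survey,
        logged["muscle"],
        myokines,
        {t: m for t, m in logged.items() if t != "muscle"},
        sex_labels,
        fingerprint=fp,
    )
    if config.edge_mode == "2sd":
        edges = crosstissue.apply_2sd(edges)
    elif config.edge_mode == "p01":
        edges = crosstissue.apply_p_threshold(edges, 0.01)
    elif config.edge_mode == "p1e6":
        edges = crosstissue.apply_p_threshold(edges, config.stringent_p)
    else:
        edges = crosstissue.apply_bh(edges)
    edges = crosstissue.classify_edges(edges)
    edge_counts = crosstissue.count_significant(edges, ["target_tissue", "sex_class"])
    edge_counts.to_csv(outdir / "edge_counts.tsv", sep="\t", index=False)
    edges[edges["sex_class"] != "none"].to_csv(
        outdir / "significant_edges.tsv", sep="\t", index=False
    )

    receptor_bins = _stage(
        "receptor_bins",
        crosstissue.bin_by_receptor,
        myokines,
        logged["muscle"],
        sex_labels,
        config.receptor_p,
        fingerprint=f"{len(myokines)} myokines",
    )
    receptor_bins.to_csv(outdir / "receptor_bins.tsv", sep="\t", index=False)

    # ---- stage: deconvolution ----------------------------------------
    summary_deconv = None
    proportions = None
    if sc_counts is not None:
        signature = _stage(
            "signature",
            deconv.build_signature,
            sc_counts,
            sc_labels,
            config.top_n_markers,
            fingerprint=f"sc={sc_counts.shape}",
        )
        noise_sd = float(config.simulate.mixture_noise_sd * signature.matrix.to_numpy().mean())
        bench = deconv.benchmark_methods(
            signature,
            {
                "n_samples": config.benchmark_samples,
                "dirichlet_alpha": config.simulate.dirichlet_alpha,
                "noise_sd": noise_sd,
                "seed": config.seed + 101,
            },
        )
        bench.to_csv(outdir / "deconv_benchmark.tsv", sep="\t", index=False)
        best = bench.attrs["chosen"]
        muscle_counts = bundle.matrices["muscle"]
        bulk_cpm = muscle_counts.div(muscle_counts.sum(axis=0), axis=1) * 1e6
        method_fn = {
            "nnls": deconv.deconvolve_nnls,
            "admixture": deconv.deconvolve_admixture,
            "dcq": deconv.deconvolve_dcq,
        }[best]
        proportions = _stage(
            "deconvolve", method_fn, bulk_cpm, signature, fingerprint=f"method={best}"
        )
        proportions.to_csv(outdir / "proportions.tsv", sep="\t", index_label="sample_id")
        sex_cmp = deconv.compare_proportions_by_sex(proportions, sex_labels)
        sex_cmp.to_csv(outdir / "proportions_by_sex.tsv", sep="\t", index=False)
        summary_deconv = {
            "benchmark": bench.drop(columns=["mean_per_type_correlation"]).to_dict("records"),
            "chosen_method": best,
            "sex_difference_min_padj": float(sex_cmp["padj"].min()),
        }

    # ---- stage: mediation --------------------------------------------
    summary_mediation = None
    if proportions is not None:
        try:
            med = _stage(
                "mediation",
                mediation.mediation_screen,
                proportions,
                logged["muscle"].loc[myokines],
                edges,
                {t: m for t, m in logged.items() if t != "muscle"},
                sex_labels,
                config.stringent_p,
                config.delta_margin,
                fingerprint=f"{len(edges)} edges",
            )
            med.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
            summary_mediation = {
                "n_records": int(len(med)),
                "n_mediated": int(med["mediated"].sum()),
            }
        except PipelineError as exc:
            if "no stringent-significant edges" not in str(exc):
                raise
            summary_mediation = {"n_records": 0, "n_mediated": 0}

    # ---- summary ------------------------------------------------------
    summary = {
        "config": config.to_dict(),
        "n_samples": {
            "male": int((sex_labels == "male").sum()),
            "female": int((sex_labels == "female").sum()),
        },
        "n_myokines_tested": len(myokines),
        "de_category_proportions": {
            k: round(float(v), 6) for k, v in de_props.sort_index().items()
        },
        "edge_mode": config.edge_mode,
        "edge_counts": edge_counts.assign(
            target_tissue=edge_counts["target_tissue"].astype(str),
            sex_class=edge_counts["sex_class"].astype(str),
        ).to_dict("records"),
        "receptor_bin_counts": {
            sex: receptor_bins[receptor_bins["sex"] == sex]["bin"]
            .value_counts()
            .sort_index()
            .astype(int)
            .to_dict()
            for sex in ("male", "female")
        },
        "deconvolution": summary_deconv,
        "mediation": summary_mediation,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
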