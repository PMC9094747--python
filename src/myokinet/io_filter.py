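"""Expression-bundle I/O and gene/sample retention filters.

A cohort is held as a :class:`TissueExpressionBundle`: one gene-by-sample
matrix per tissue, all referencing a shared individual index, plus a sample
table carrying biological sex.  Matrices are plain TSV on disk (genes as
rows, first column the gene ID, header row of sample IDs).

The retention rules implemented here are deliberately strict-inequality:

* gene kept when its count exceeds ``min_count`` (strictly) in at least
  ``min_individuals`` samples;
* gene dropped when its fraction of zero counts strictly exceeds
  ``max_zero_fraction``;
* individual kept when its number of nonzero (gene, tissue) entries summed
  over all tissues reaches ``min_nonzero_combinations``.

Expression unit for downstream correlation work is log2(CPM + 1) computed
per tissue (:func:`log_cpm`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TissueExpressionBundle",
    "GeneSet",
    "load_matrix",
    "load_bundle",
    "write_bundle",
    "filter_individuals_cross_tissue",
    "filter_genes_min_counts",
    "filter_genes_zero_fraction",
    "log_cpm",
    "load_gene_set",
    "load_homology_table",
    "intersect_orthologs",
    "read_gmt",
]

SEXES = ("male", "female")


@dataclass
class TissueExpressionBundle:
    """Per-tissue gene-by-sample matrices over a shared individual index."""

    matrices: dict[str, pd.DataFrame]
    samples: pd.DataFrame  # index: sample_id; column: sex
    units: str = "counts"  # "counts" | "log_cpm"

    def __post_init__(self):
        if "sex" not in self.samples.columns:
            raise ValueError("sample table must have a 'sex' column")
        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample IDs in sample table")
        for tissue, mat in self.matrices.items():
            if mat.index.has_duplicates:
                dup = mat.index[mat.index.duplicated()][0]
                raise ValueError(f"duplicate gene row {dup!r} in tissue {tissue!r}")
            if mat.columns.has_duplicates:
                raise ValueError(f"duplicate sample column in tissue {tissue!r}")
            unknown = mat.columns.difference(self.samples.index)
            if len(unknown):
                raise ValueError(
                    f"samples in tissue {tissue!r} missing from sample table: "
                    f"{list(unknown)[:5]}"
                )

    @property
    def tissues(self) -> list[str]:
        return list(self.matrices)

    def sex_of(self, sample_ids) -> pd.Series:
        return self.samples.loc[sample_ids, "sex"]

    def stratum(self, sex: str) -> pd.Index:
        """Sample IDs of one sex."""
        return self.samples.index[self.samples["sex"] == sex]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols, deduplicated preserving order."""

    name: str
    genes: tuple = ()

    def __post_init__(self):
        seen, uniq = set(), []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                uniq.append(g)
        object.__setattr__(self, "genes", tuple(uniq))

    def __len__(self):
        return len(self.genes)

    def __contains__(self, gene):
        return gene in set(self.genes)


def load_matrix(path) -> pd.DataFrame:
    """Read a genes-by-samples TSV (first column gene IDs)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()][0]
        raise ValueError(f"duplicate gene row {dup!r} in {path}")
    return mat


def load_bundle(tissue_paths: Mapping[str, str | Path], sample_table_path) -> TissueExpressionBundle:
    """Assemble a bundle from per-tissue TSVs and a sample table.

    Genes absent from one tissue are simply absent from that matrix; sample
    IDs appearing in a matrix but not the sample table are an error.
    """
    samples = pd.read_csv(sample_table_path, sep="\t", index_col=0)
    matrices = {t: load_matrix(p) for t, p in tissue_paths.items()}
    return TissueExpressionBundle(matrices=matrices, samples=samples)


def write_bundle(bundle: TissueExpressionBundle, outdir) -> dict:
    """Write one TSV per tissue plus samples.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tissue, mat in bundle.matrices.items():
        p = outdir / f"{tissue}.tsv"
        mat.to_csv(p, sep="\t", index_label="gene")
        paths[tissue] = p
    sp = outdir / "samples.tsv"
    bundle.samples.to_csv(sp, sep="\t", index_label="sample_id")
    paths["samples"] = sp
    return paths


def filter_individuals_cross_tissue(
    bundle: TissueExpressionBundle, min_nonzero_combinations: int
) -> TissueExpressionBundle:
    """Drop individuals detected in too few (gene, tissue) combinations.

    For every individual the number of strictly positive entries is summed
    over all tissue matrices in which the individual appears; individuals
    below ``min_nonzero_combinations`` are removed everywhere.  Order of the
    survivors is preserved.
    """
    if bundle.units != "counts":
        raise ValueError("cross-tissue individual filter expects raw counts")
    total_combinations = sum(m.shape[0] for m in bundle.matrices.values())
    if min_nonzero_combinations > total_combinations:
        raise ValueError(
            f"threshold {min_nonzero_combinations} exceeds the "
            f"{total_combinations} available gene-tissue combinations"
        )
    counts = pd.Series(0, index=bundle.samples.index)
    for mat in bundle.matrices.values():
        nz = (mat > 0).sum(axis=0)
        counts = counts.add(nz, fill_value=0)
    keep = counts.index[counts >= min_nonzero_combinations]
    keep = bundle.samples.index[bundle.samples.index.isin(keep)]  # preserve order
    matrices = {
        t: m.loc[:, m.columns[m.columns.isin(keep)]] for t, m in bundle.matrices.items()
    }
    return TissueExpressionBundle(
        matrices=matrices, samples=bundle.samples.loc[keep], units=bundle.units
    )


def filter_genes_min_counts(
    matrix: pd.DataFrame, min_count: int = 10, min_individuals: int = 50
) -> pd.DataFrame:
    """Keep genes whose count strictly exceeds ``min_count`` in at least
    ``min_individuals`` samples."""
    if min_individuals > matrix.shape[1]:
        raise ValueError(
            f"min_individuals={min_individuals} exceeds {matrix.shape[1]} samples"
        )
    keep = (matrix > min_count).sum(axis=1) >= min_individuals
    return matrix.loc[keep]


def filter_genes_zero_fraction(
    matrix: pd.DataFrame, max_zero_fraction: float = 0.8
) -> pd.DataFrame:
    """Drop genes whose fraction of zero counts strictly exceeds the threshold."""
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must lie in [0, 1]")
    zero_frac = (matrix == 0).mean(axis=1)
    return matrix.loc[zero_frac <= max_zero_fraction]


def log_cpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(counts-per-million + 1), computed per sample column."""
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total counts")
    return np.log2(matrix.div(totals, axis=1) * 1e6 + 1.0)


def _normalize_symbol(sym: str, species: str) -> str:
    sym = sym.strip()
    return sym.upper() if species == "human" else sym


def load_gene_set(path, name: str | None = None, species: str = "human") -> GeneSet:
    """Read a one-symbol-per-line gene list.

    Human symbols are uppercase-normalized; mouse symbols are kept as
    written (cross-species matching must go through a homology table,
    never case-folding).
    """
    path = Path(path)
    genes = [
        _normalize_symbol(line, species)
        for line in path.read_text().splitlines()
        if line.strip()
    ]
    if not genes:
        raise ValueError(f"empty gene set file: {path}")
    return GeneSet(name=name or path.stem, genes=tuple(genes))


def load_homology_table(path) -> pd.DataFrame:
    """Two-column TSV mapping symbols of species A to species B."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] != 2:
        raise ValueError("homology table must have exactly two columns")
    return table


def intersect_orthologs(set_a: GeneSet, set_b: GeneSet, homology_table: pd.DataFrame) -> GeneSet:
    """Genes of ``set_a`` whose ortholog (per the table) lies in ``set_b``.

    Many-to-many mappings are expanded before deduplication.  A disjoint
    result is a warning, not an error.
    """
    if homology_table is None or len(homology_table) == 0:
        raise ValueError("empty homology table")
    a_col, b_col = homology_table.columns[:2]
    in_b = set(set_b.genes)
    hits = homology_table[
        homology_table[a_col].isin(set(set_a.genes))
        & homology_table[b_col].isin(in_b)
    ]
    genes = tuple(dict.fromkeys(hits[a_col]))
    if not genes:
        warnings.warn(
            f"no orthologs of {set_a.name!r} found in {set_b.name!r}", stacklevel=2
        )
    return GeneSet(name=f"{set_a.name}&{set_b.name}", genes=genes)


def read_gmt(path) -> dict[str, set]:
    """Read GMT pathway sets: name <tab> description <tab> genes..."""
    pathways = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        pathways[parts[0]] = {g for g in parts[2:] if g}
    if not pathways:
        raise ValueError(f"no pathways in {path}")
    return pathways
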