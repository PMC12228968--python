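"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: expression TSV (rows = genes, header = sample ids), sample
metadata TSV, GFF3 gene features, BED6, GWAS summary TSV, module
assignment TSV, and gene-set files (one id per line). Internal coordinates
are 1-based inclusive (the GFF3 dialect); BED input is converted on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .datatypes import (
    AtlasValidationError,
    ExpressionAtlas,
    GeneAnnotation,
    GeneSet,
    GwasSummary,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "read_gwas",
    "write_gwas",
    "read_module_assignments",
    "read_gene_set",
    "write_gene_set",
]


# --------------------------------------------------------------------------
# expression atlas
# --------------------------------------------------------------------------

def read_expression(path, meta_path) -> ExpressionAtlas:
    """Load an expression TSV and its sample-metadata TSV into an atlas.

    The expression file has gene ids in the first column and one column
    per sample; the metadata file has columns ``sample_id``, ``tissue``,
    ``stage``, ``timepoint``. Samples present in the matrix but absent
    from the metadata are an error (listed by id).
    """
    expr = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise AtlasValidationError("metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    missing = expr.columns.difference(meta.index)
    if len(missing):
        raise AtlasValidationError(
            f"samples missing from metadata: {sorted(missing)}"
        )
    return ExpressionAtlas(expr, meta)


def write_expression(atlas: ExpressionAtlas, path, meta_path) -> None:
    atlas.expression.rename_axis("gene_id").to_csv(path, sep="\t")
    atlas.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


# --------------------------------------------------------------------------
# gene annotation
# --------------------------------------------------------------------------

def read_gff3(path) -> GeneAnnotation:
    """Read gene features from a GFF3 file (1-based inclusive, as GFF3 is)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand or "."))
    if not rows:
        raise AtlasValidationError(f"no gene features in {path}")
    table = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")
    return GeneAnnotation(table)


def write_gff3(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, row in ann.table.iterrows():
            fh.write(
                f"{row['chrom']}\tdevatlas\tgene\t{row['start']}\t{row['end']}"
                f"\t.\t{row['strand']}\t.\tID={gid}\n"
            )


def read_bed(path) -> GeneAnnotation:
    """Read a BED6 file, converting 0-based half-open to 1-based inclusive."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    table = pd.DataFrame(
        {
            "chrom": bed["chrom"].astype(str).to_numpy(),
            "start": bed["start"].astype(int).to_numpy() + 1,  # 0-based -> 1-based
            "end": bed["end"].astype(int).to_numpy(),  # half-open end == inclusive end
            "strand": bed["strand"].fillna(".").astype(str).to_numpy(),
        },
        index=pd.Index(bed["name"], name="gene_id"),
    )
    return GeneAnnotation(table)


# --------------------------------------------------------------------------
# GWAS summary statistics
# --------------------------------------------------------------------------

def read_gwas(path) -> GwasSummary:
    """Read a GWAS summary TSV with columns snp_id, chrom, pos, beta.

    Extra columns are preserved but ignored by the pipeline.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp_id", "chrom", "pos", "beta"}
    missing = required - set(tab.columns)
    if missing:
        raise AtlasValidationError(f"GWAS summary lacks columns {sorted(missing)}")
    return GwasSummary(tab.set_index("snp_id"))


def write_gwas(gwas: GwasSummary, path) -> None:
    gwas.table.rename_axis("snp_id").to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# modules and gene sets
# --------------------------------------------------------------------------

def read_module_assignments(path) -> dict:
    """Read a module assignment TSV (gene_id, module_id[, method, tissue]).

    Returns a mapping module_id -> set of gene ids. A gene may appear in
    several modules (matrix-factorization methods produce overlapping
    modules).
    """
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "module_id"} <= set(tab.columns):
        raise AtlasValidationError(
            "module assignment file needs gene_id and module_id columns"
        )
    return {
        mid: set(group["gene_id"]) for mid, group in tab.groupby("module_id", sort=True)
    }


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a gene-set file: one gene id per line, '#' lines are comments.

    A comment of the form ``# provenance: ...`` restores provenance.
    """
    genes, provenance = [], "user"
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line[1:].strip().lower().startswith("provenance:"):
                provenance = line.split(":", 1)[1].strip()
            continue
        genes.append(line)
    return GeneSet(name or Path(path).stem, frozenset(genes), provenance)


def write_gene_set(gs: GeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# provenance: {gs.provenance}\n")
        for g in sorted(gs.genes):
            fh.write(f"{g}\n")
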