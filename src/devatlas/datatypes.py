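"""Core in-memory containers for the atlas/GWAS pipeline.

The pipeline operates on four objects: an expression atlas (genes x samples
TPM matrix with per-sample tissue/stage/timepoint metadata), a gene
annotation (1-based inclusive genomic intervals), a GWAS summary table
(per-SNP marginal effects), and named gene sets with provenance. All are
thin wrappers over pandas objects so downstream code can use ordinary
DataFrame operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionAtlas",
    "GeneAnnotation",
    "GwasSummary",
    "GeneSet",
    "DevAtlasError",
    "AtlasValidationError",
    "ChromosomeMismatchError",
    "UntestableSetError",
]


class DevAtlasError(Exception):
    """Base class for package errors."""


class AtlasValidationError(DevAtlasError):
    """Raised when an atlas, annotation or GWAS table violates its contract."""


class ChromosomeMismatchError(DevAtlasError):
    """Raised when annotation and GWAS share no chromosome names."""


class UntestableSetError(DevAtlasError):
    """Raised when a gene set maps to zero SNPs and cannot be tested."""


#: metadata columns every atlas must carry
META_COLUMNS = ("tissue", "stage", "timepoint")


@dataclass
class ExpressionAtlas:
    """Genes x samples TPM matrix plus per-sample metadata.

    Parameters
    ----------
    expression
        DataFrame indexed by gene id, columns are sample ids, values are
        TPM (non-negative).
    sample_meta
        DataFrame indexed by sample id with at least ``tissue``, ``stage``
        and ``timepoint`` columns. ``stage`` should be an ordered
        categorical (or will be treated in first-appearance order).
    """

    expression: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        expr, meta = self.expression, self.sample_meta
        if expr.index.has_duplicates:
            dups = expr.index[expr.index.duplicated()].unique().tolist()
            raise AtlasValidationError(f"duplicate gene ids: {dups[:5]}")
        if expr.columns.has_duplicates:
            dups = expr.columns[expr.columns.duplicated()].unique().tolist()
            raise AtlasValidationError(f"duplicate sample ids: {dups[:5]}")
        if (expr.to_numpy() < 0).any():
            raise AtlasValidationError("negative TPM values in expression matrix")
        missing = expr.columns.difference(meta.index)
        if len(missing):
            raise AtlasValidationError(
                f"samples missing from metadata: {sorted(missing)}"
            )
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise AtlasValidationError(f"sample metadata lacks column {col!r}")
        # align metadata rows to the expression column order
        self.sample_meta = meta.loc[expr.columns]

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def stage_order(self) -> list:
        """Ordered stage labels (categorical order, else first appearance)."""
        stages = self.sample_meta["stage"]
        if isinstance(stages.dtype, pd.CategoricalDtype):
            return [s for s in stages.cat.categories if s in set(stages)]
        return list(dict.fromkeys(stages))

    def subset_samples(self, sample_ids) -> "ExpressionAtlas":
        ids = pd.Index(sample_ids)
        return ExpressionAtlas(self.expression[ids], self.sample_meta.loc[ids])

    def subset_genes(self, gene_ids) -> "ExpressionAtlas":
        return ExpressionAtlas(self.expression.loc[pd.Index(gene_ids)], self.sample_meta)

    def subset_tissue(self, tissue: str) -> "ExpressionAtlas":
        keep = self.sample_meta.index[self.sample_meta["tissue"] == tissue]
        if not len(keep):
            raise AtlasValidationError(f"no samples for tissue {tissue!r}")
        return self.subset_samples(keep)


@dataclass
class GeneAnnotation:
    """Gene body intervals, 1-based inclusive.

    ``table`` is indexed by gene id with columns ``chrom``, ``start``,
    ``end``, ``strand``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise AtlasValidationError("duplicate gene ids in annotation")
        required = {"chrom", "start", "end", "strand"}
        missing = required - set(t.columns)
        if missing:
            raise AtlasValidationError(f"annotation lacks columns {sorted(missing)}")
        if (t["start"] > t["end"]).any():
            bad = t.index[t["start"] > t["end"]].tolist()
            raise AtlasValidationError(f"start > end for genes {bad[:5]}")
        if (t["start"] < 1).any():
            raise AtlasValidationError("annotation coordinates must be 1-based (>= 1)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def chromosomes(self) -> set:
        return set(self.table["chrom"].unique())


@dataclass
class GwasSummary:
    """Per-SNP marginal effects from a single-marker association scan.

    ``table`` is indexed by snp_id with columns ``chrom``, ``pos`` (1-based)
    and ``beta`` (the marginal effect b entering the sum-of-squares set
    statistic).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise AtlasValidationError("duplicate SNP ids in GWAS summary")
        required = {"chrom", "pos", "beta"}
        missing = required - set(t.columns)
        if missing:
            raise AtlasValidationError(f"GWAS summary lacks columns {sorted(missing)}")
        if len(t):
            if (t["pos"] < 1).any():
                raise AtlasValidationError("SNP positions must be 1-based (>= 1)")
            if not np.isfinite(t["beta"].to_numpy(dtype=float)).all():
                raise AtlasValidationError("non-finite SNP effects")

    @property
    def snp_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def chromosomes(self) -> set:
        return set(self.table["chrom"].unique())


@dataclass
class GeneSet:
    """A named collection of gene ids with provenance.

    ``provenance`` records where the set came from, e.g.
    ``tissue-specific:liver``, ``stage-specific:muscle,adult``,
    ``cluster:3`` or ``user``.
    """

    name: str
    genes: frozenset = field(default_factory=frozenset)
    provenance: str = "user"

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))
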