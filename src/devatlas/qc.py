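"""Expression-level quality control and normalization.

The atlas QC used throughout the pipeline, applied in a fixed order:

1. drop genes never expressed (TPM >= 0.1 in no sample);
2. drop samples expressing fewer than 40% of the retained genes;
3. drop tissues left with fewer than 3 samples.

"Expressed" means TPM >= 0.1 everywhere; removal thresholds are strict
(a sample at exactly 40% breadth, or a tissue with exactly 3 samples, is
kept). Each filter is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AtlasValidationError, DevAtlasError, ExpressionAtlas

logger = logging.getLogger(__name__)

#: TPM at or above which a gene counts as expressed in a sample
EXPRESSED_TPM = 0.1

__all__ = [
    "EXPRESSED_TPM",
    "QCReport",
    "filter_unexpressed_genes",
    "filter_low_breadth_samples",
    "filter_small_tissues",
    "exclude_samples",
    "run_qc",
    "log_transform",
    "top_variance_genes",
    "sample_distance",
]


@dataclass
class QCReport:
    """Counts removed by each QC rule, for logging and manifests."""

    genes_removed: int = 0
    samples_removed_breadth: int = 0
    samples_removed_tissue: int = 0
    samples_excluded: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_unexpressed_genes(atlas: ExpressionAtlas, min_tpm: float = EXPRESSED_TPM) -> ExpressionAtlas:
    """Keep genes expressed (TPM >= ``min_tpm``) in at least one sample."""
    keep = (atlas.expression >= min_tpm).any(axis=1)
    return atlas.subset_genes(atlas.gene_ids[keep])


def filter_low_breadth_samples(
    atlas: ExpressionAtlas,
    min_fraction: float = 0.40,
    min_tpm: float = EXPRESSED_TPM,
) -> ExpressionAtlas:
    """Drop samples expressing strictly less than ``min_fraction`` of genes.

    The denominator is the number of genes currently in the atlas.
    """
    frac = (atlas.expression >= min_tpm).mean(axis=0)
    keep = atlas.sample_ids[frac >= min_fraction]
    return atlas.subset_samples(keep)


def filter_small_tissues(atlas: ExpressionAtlas, min_n: int = 3) -> ExpressionAtlas:
    """Drop every sample of a tissue represented by fewer than ``min_n`` samples."""
    counts = atlas.sample_meta["tissue"].value_counts()
    good = set(counts.index[counts >= min_n])
    keep = atlas.sample_ids[atlas.sample_meta["tissue"].isin(good)]
    return atlas.subset_samples(keep)


def exclude_samples(atlas: ExpressionAtlas, exclude: list) -> ExpressionAtlas:
    """Manually remove samples by id (outlier exclude-list).

    Cohort-level outlier removal by clustering has no fixed rule; callers
    provide the list explicitly.
    """
    keep = atlas.sample_ids.difference(pd.Index(exclude))
    return atlas.subset_samples(atlas.sample_ids[atlas.sample_ids.isin(keep)])


def run_qc(
    atlas: ExpressionAtlas,
    min_tpm: float = EXPRESSED_TPM,
    min_breadth: float = 0.40,
    min_tissue_n: int = 3,
    exclude: list | None = None,
) -> tuple[ExpressionAtlas, QCReport]:
    """Apply the standard QC composition: genes -> samples -> tissues."""
    report = QCReport()
    if exclude:
        before = atlas.n_samples
        atlas = exclude_samples(atlas, exclude)
        report.samples_excluded = before - atlas.n_samples
    n0 = atlas.n_genes
    atlas = filter_unexpressed_genes(atlas, min_tpm)
    report.genes_removed = n0 - atlas.n_genes
    s0 = atlas.n_samples
    atlas = filter_low_breadth_samples(atlas, min_breadth, min_tpm)
    report.samples_removed_breadth = s0 - atlas.n_samples
    s1 = atlas.n_samples
    atlas = filter_small_tissues(atlas, min_tissue_n)
    report.samples_removed_tissue = s1 - atlas.n_samples
    logger.info("QC report: %s", report.as_dict())
    return atlas, report


def log_transform(values, pseudocount: float = 0.25):
    """Elementwise log2(TPM + pseudocount); the pipeline's analysis scale.

    Accepts an atlas, a DataFrame or an ndarray and returns the same kind.
    """
    if isinstance(values, ExpressionAtlas):
        values = values.expression
    arr = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values)
    if (arr < 0).any():
        raise AtlasValidationError("negative expression values; TPM must be >= 0")
    if isinstance(values, pd.DataFrame):
        return np.log2(values + pseudocount)
    return np.log2(arr + pseudocount)


def top_variance_genes(atlas: ExpressionAtlas, k: int = 6000) -> list:
    """Gene ids of the ``k`` genes with the highest SD of TPM across samples.

    Ties are broken by gene id lexicographic order so output is
    deterministic.
    """
    if k > atlas.n_genes:
        raise DevAtlasError(f"k={k} exceeds gene count {atlas.n_genes}")
    sd = atlas.expression.std(axis=1, ddof=1)
    # stable sort over a lexicographically pre-sorted index fixes tie order
    sd_sorted = sd.loc[sorted(sd.index)].sort_values(ascending=False, kind="mergesort")
    return sd_sorted.index[:k].tolist()


def sample_distance(logmat: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample columns.

    This is the distance used for hierarchical clustering of samples.
    A zero-variance sample column has undefined correlation and is an
    error (named in the message).
    """
    if logmat.shape[1] < 2:
        raise DevAtlasError("need at least 2 samples for a distance matrix")
    sds = logmat.std(axis=0, ddof=0)
    bad = sds.index[sds == 0].tolist()
    if bad:
        raise DevAtlasError(f"zero-variance sample columns: {bad}")
    r = np.corrcoef(logmat.to_numpy().T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=logmat.columns, columns=logmat.columns)
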