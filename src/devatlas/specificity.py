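"""Tissue-specificity scoring and tissue/stage-specific gene-set calling.

Two complementary notions of specificity are computed:

* the tau index, a scalar in [0, 1] per gene (0 = uniform across tissues,
  1 = expressed in a single tissue), computed here from per-tissue median
  TPM on the log2(x + 1) scale;
* one-vs-rest differential expression (Welch t-test on log2(TPM + 0.25)),
  from which tissue-specific sets are the top 5% of upregulated genes by
  FDR, and stage-specific sets are genes with log2FC > 2 and FDR < 0.05
  within a tissue.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DevAtlasError, ExpressionAtlas, GeneSet
from .qc import log_transform

logger = logging.getLogger(__name__)

__all__ = [
    "tau",
    "tissue_tau",
    "one_vs_rest_de",
    "tissue_specific_genes",
    "stage_specific_genes",
]


def tau(profile) -> float:
    """Tissue-specificity index of a non-negative per-group profile.

    tau = sum_i(1 - x_i / max(x)) / (N - 1) for an N-group profile x.
    Returns 1 for single-group expression, 0 for a uniform profile.
    The caller chooses the scale of x; the pipeline feeds log2(median
    TPM + 1) per tissue (see :func:`tissue_tau`).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DevAtlasError("tau needs a 1-d profile over >= 2 groups")
    if (x < 0).any():
        raise DevAtlasError("tau is defined for non-negative profiles")
    m = x.max()
    if m == 0:
        raise DevAtlasError("tau undefined for an all-zero profile")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def tissue_tau(atlas: ExpressionAtlas) -> pd.Series:
    """Per-gene tau over per-tissue median TPM, on the log2(x + 1) scale.

    Genes with zero median in every tissue get NaN (tau undefined).
    """
    med = atlas.expression.T.groupby(atlas.sample_meta["tissue"], observed=True).median().T
    x = np.log2(med.to_numpy() + 1.0)
    m = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.sum(1.0 - x / m[:, None], axis=1) / (x.shape[1] - 1)
    vals[m == 0] = np.nan
    return pd.Series(vals, index=atlas.gene_ids, name="tau")


def one_vs_rest_de(
    atlas: ExpressionAtlas,
    group_label: str,
    grouping: str = "tissue",
    pseudocount: float = 0.25,
) -> pd.DataFrame:
    """Differential expression of one group against all remaining samples.

    Per gene: log2FC = mean log2(TPM + 0.25) in the group minus the mean in
    the complement; two-sided Welch t-test on the same transformed values;
    Benjamini-Hochberg FDR across genes. Returns a DataFrame indexed by
    gene id with columns log2fc, p, fdr, direction.
    """
    labels = atlas.sample_meta[grouping].astype(str)
    in_group = (labels == str(group_label)).to_numpy()
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise DevAtlasError(
            f"group {group_label!r} needs >= 2 samples on each side "
            f"(got {int(in_group.sum())} vs {int((~in_group).sum())})"
        )
    logmat = log_transform(atlas.expression.to_numpy(), pseudocount)
    a, b = logmat[:, in_group], logmat[:, ~in_group]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance degenerate rows
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=atlas.gene_ids,
    )


def tissue_specific_genes(
    atlas: ExpressionAtlas,
    tissue: str,
    fraction: float = 0.05,
    de: pd.DataFrame | None = None,
) -> GeneSet:
    """Top-``fraction`` upregulated genes (by FDR) for one tissue.

    The quota is ceil(fraction * genes tested). Only upregulated genes
    (log2FC > 0) are eligible; ties are broken by ascending p, then
    descending log2FC, then gene id, so output is deterministic. If fewer
    upregulated genes exist than the quota, all of them are returned with
    a warning.
    """
    if de is None:
        de = one_vs_rest_de(atlas, tissue, grouping="tissue")
    quota = math.ceil(fraction * len(de))
    up = de[de["log2fc"] > 0].copy()
    up["_gene"] = up.index
    up = up.sort_values(
        by=["fdr", "p", "log2fc", "_gene"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    if len(up) < quota:
        logger.warning(
            "tissue %s: only %d upregulated genes for a quota of %d",
            tissue, len(up), quota,
        )
    chosen = up.index[:quota]
    return GeneSet(
        f"tissue_specific_{tissue}",
        frozenset(chosen),
        provenance=f"tissue-specific:{tissue}",
    )


def stage_specific_genes(
    atlas: ExpressionAtlas,
    tissue: str,
    stage: str,
    min_log2fc: float = 2.0,
    max_fdr: float = 0.05,
    min_samples: int = 3,
) -> GeneSet:
    """Developmental-stage-specific genes within one tissue.

    One-vs-rest DE of the stage against the remaining stages of the same
    tissue; genes pass with log2FC strictly above ``min_log2fc`` AND FDR
    strictly below ``max_fdr``. Both the stage and its complement must
    have at least ``min_samples`` samples.
    """
    sub = atlas.subset_tissue(tissue)
    in_stage = (sub.sample_meta["stage"].astype(str) == str(stage)).to_numpy()
    if in_stage.sum() < min_samples or (~in_stage).sum() < min_samples:
        raise DevAtlasError(
            f"tissue {tissue!r} stage {stage!r}: need >= {min_samples} samples "
            f"per side, got {int(in_stage.sum())} vs {int((~in_stage).sum())}"
        )
    de = one_vs_rest_de(sub, stage, grouping="stage")
    passing = de.index[(de["log2fc"] > min_log2fc) & (de["fdr"] < max_fdr)]
    return GeneSet(
        f"stage_specific_{tissue}_{stage}",
        frozenset(passing),
        provenance=f"stage-specific:{tissue},{stage}",
    )
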