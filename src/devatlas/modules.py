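"""Comparison of externally detected co-expression modules.

Module detection itself (WGCNA, ICA, PEER, MEGENA, GWENA, CEMiTool, ...)
is out of scope: assignments arrive as gene -> module tables, possibly
overlapping (matrix-factorization methods). This module compares two
assignments by the Jaccard module-sharing index, summarizes a module as
its eigengene (first principal component of the standardized expression
submatrix), and associates modules with developmental stages by
point-biserial correlation of the eigengene with per-stage indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DevAtlasError, ExpressionAtlas
from .qc import log_transform

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleAssignment",
    "module_sharing_index",
    "module_eigengene",
    "module_stage_association",
]


@dataclass
class ModuleAssignment:
    """Named module -> gene-set mapping from one detection method.

    Gene sets may overlap across modules; that is a property of
    factorization-based detectors, not an error.
    """

    method: str
    modules: dict = field(default_factory=dict)
    tissue: str = ""

    def __post_init__(self) -> None:
        self.modules = {k: set(v) for k, v in self.modules.items()}
        if not self.modules:
            raise DevAtlasError("module assignment must contain >= 1 module")


def module_sharing_index(A: ModuleAssignment, B: ModuleAssignment) -> pd.DataFrame:
    """Jaccard similarity |a & b| / |a | b| for every module pair.

    Rows are A's modules, columns B's. Two empty modules share index 0
    (with a warning) rather than raising.
    """
    out = pd.DataFrame(
        0.0, index=sorted(A.modules), columns=sorted(B.modules), dtype=float
    )
    for ka, ga in A.modules.items():
        for kb, gb in B.modules.items():
            union = ga | gb
            if not union:
                logger.warning("modules %s and %s are both empty; J set to 0", ka, kb)
                continue
            out.loc[ka, kb] = len(ga & gb) / len(union)
    return out


def module_eigengene(atlas: ExpressionAtlas, module_genes) -> pd.Series:
    """First principal component of the module's expression across samples.

    Genes are row-standardized on the log2(TPM + 0.25) scale; the
    eigengene is the first right-singular vector of the genes x samples
    submatrix, with its sign fixed so it correlates non-negatively with
    the module's mean standardized profile.
    """
    genes = [g for g in module_genes if g in atlas.gene_ids]
    missing = set(module_genes) - set(genes)
    if not genes:
        raise DevAtlasError("no module genes present in the atlas")
    if missing:
        logger.info("%d module genes absent from atlas", len(missing))
    if len(genes) < 2:
        raise DevAtlasError("module eigengene needs >= 2 genes present")
    if atlas.n_samples < 3:
        raise DevAtlasError("module eigengene needs >= 3 samples")
    sub = log_transform(atlas.expression.loc[genes]).to_numpy()
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0  # constant genes contribute a flat profile
    z = (sub - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=atlas.sample_ids, name="eigengene")


def module_stage_association(
    eigengenes: dict, sample_meta: pd.DataFrame
) -> pd.DataFrame:
    """Correlate module eigengenes with developmental stages.

    For each (module, stage): Pearson correlation between the eigengene
    and the stage's one-hot indicator over samples (point-biserial), a
    two-sided p from the t transform of r, and BH FDR across all
    (module, stage) pairs in the call. Requires >= 2 stages with >= 2
    samples each.
    """
    stages = [
        s for s, n in sample_meta["stage"].astype(str).value_counts().items() if n >= 2
    ]
    if isinstance(sample_meta["stage"].dtype, pd.CategoricalDtype):
        order = [str(s) for s in sample_meta["stage"].cat.categories]
        stages = [s for s in order if s in set(stages)]
    else:
        stages = [s for s in dict.fromkeys(sample_meta["stage"].astype(str)) if s in set(stages)]
    if len(stages) < 2:
        raise DevAtlasError("need >= 2 stages with >= 2 samples each")
    rows = []
    for mod, eig in eigengenes.items():
        e = np.asarray(eig.loc[sample_meta.index], dtype=float)
        if e.std(ddof=0) == 0:
            raise DevAtlasError(f"constant eigengene for module {mod!r}")
        for s in stages:
            ind = (sample_meta["stage"].astype(str) == s).to_numpy(dtype=float)
            r, p = stats.pearsonr(e, ind)
            rows.append((mod, s, r, p))
    out = pd.DataFrame(rows, columns=["module", "stage", "r", "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
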