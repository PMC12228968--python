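"""Sum-based marker-set enrichment of GWAS signal in gene sets.

The statistic is T_sum = sum of squared marginal SNP effects b^2 over the
SNPs assigned to a gene set, where SNPs are assigned to a gene when they
fall within the gene body extended by a symmetric cis window (default
+/- 20 kb). Significance comes from a permutation null: random SNP sets
of the same size are drawn from all GWAS SNPs, and the one-tailed
empirical p is the pseudocounted proportion of permuted statistics at
least as large as the observed one,

    p = (1 + #{T_perm >= T_obs}) / (1 + n_perm).

Ties count against significance and the pseudocount keeps p > 0; both
choices are conservative. Because the statistic and its null scale
together, p is invariant to rescaling all effects by a constant, so raw
and standardized effects give identical inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ChromosomeMismatchError,
    DevAtlasError,
    GeneAnnotation,
    GeneSet,
    GwasSummary,
    UntestableSetError,
)

logger = logging.getLogger(__name__)

#: default symmetric cis window around the gene body, in bp
DEFAULT_WINDOW = 20_000
#: default number of permutations for the empirical null
DEFAULT_N_PERM = 10_000

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_N_PERM",
    "PermutationResult",
    "map_snps_to_genes",
    "geneset_snps",
    "t_sum",
    "empirical_p",
    "permutation_test",
    "permutation_p",
    "enrich",
]


def map_snps_to_genes(
    ann: GeneAnnotation, gwas: GwasSummary, window: int = DEFAULT_WINDOW
) -> dict:
    """Assign SNPs to genes by the symmetric cis-window rule.

    A SNP at position p maps to a gene [start, end] on the same chromosome
    when max(1, start - window) <= p <= end + window (1-based inclusive on
    both ends; strand-agnostic). A SNP may map to several genes. Raises
    :class:`ChromosomeMismatchError` when the two inputs share no
    chromosome names.
    """
    if window < 0:
        raise DevAtlasError("window must be >= 0")
    ann_chroms, gwas_chroms = ann.chromosomes(), gwas.chromosomes()
    if gwas.n_snps and not (ann_chroms & gwas_chroms):
        raise ChromosomeMismatchError(
            f"no shared chromosomes; annotation has {sorted(ann_chroms)}, "
            f"GWAS has {sorted(gwas_chroms)}"
        )
    snp_map: dict = {g: [] for g in ann.gene_ids}
    if not gwas.n_snps:
        return snp_map
    by_chrom = {}
    for chrom, sub in gwas.table.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        by_chrom[chrom] = (
            sub["pos"].to_numpy()[order],
            sub.index.to_numpy()[order],
        )
    for gid, row in ann.table.iterrows():
        entry = by_chrom.get(row["chrom"])
        if entry is None:
            continue
        pos, ids = entry
        lo = max(1, int(row["start"]) - window)
        hi = int(row["end"]) + window
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="right")
        snp_map[gid] = list(ids[i:j])
    return snp_map


def geneset_snps(snp_map: dict, gene_set: GeneSet) -> set:
    """Union of SNPs mapped to any gene of the set (each SNP counted once).

    Genes absent from the map are logged, not fatal. An empty union means
    the set is untestable and raises :class:`UntestableSetError`.
    """
    missing = [g for g in gene_set.genes if g not in snp_map]
    if missing:
        logger.info(
            "gene set %s: %d genes not in SNP map", gene_set.name, len(missing)
        )
    snps: set = set()
    for g in gene_set.genes:
        snps.update(snp_map.get(g, ()))
    if not snps:
        raise UntestableSetError(f"gene set {gene_set.name!r} maps to zero SNPs")
    return snps


def t_sum(effects) -> float:
    """Sum of squared SNP effects over a set's SNPs."""
    b = np.asarray(effects, dtype=float)
    if b.size == 0:
        raise DevAtlasError("t_sum needs a nonempty effect vector")
    return float(np.sum(b**2))


def empirical_p(T_obs: float, perm_stats) -> float:
    """Pseudocounted one-tailed empirical p against a permuted null."""
    t = np.asarray(perm_stats, dtype=float)
    if t.size == 0:
        raise DevAtlasError("need >= 1 permutation statistic")
    return float((1 + np.count_nonzero(t >= T_obs)) / (1 + t.size))


@dataclass
class PermutationResult:
    """Empirical test summary. ``z`` standardizes T_obs against the null
    and serves as a continuous tie-break for sets sharing the floor p."""

    p_emp: float
    n_perm: int
    null_mean: float
    null_sd: float
    z: float = np.nan


def _random_subset_sums(
    b2: np.ndarray, m: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """T_sum over ``n_perm`` uniform size-m SNP subsets without replacement.

    Subsets come from argpartition of i.i.d. uniform keys, which selects
    each m-subset with equal probability; chunked to bound memory.
    """
    n = b2.size
    if m > n:
        raise DevAtlasError(f"subset size {m} exceeds SNP count {n}")
    if m == n:
        return np.full(n_perm, b2.sum())
    out = np.empty(n_perm)
    chunk = max(1, 4_000_000 // n)
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        keys = rng.random((c, n))
        idx = np.argpartition(keys, m, axis=1)[:, :m]
        out[done:done + c] = b2[idx].sum(axis=1)
        done += c
    return out


def permutation_test(
    T_obs: float,
    m_g: int,
    all_effects,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Empirical one-tailed test of T_obs against random SNP sets of size m_g."""
    if n_perm < 1:
        raise DevAtlasError("n_perm must be >= 1")
    if m_g < 1:
        raise DevAtlasError("m_g must be >= 1")
    b = np.asarray(all_effects, dtype=float)
    if m_g > b.size:
        raise DevAtlasError(f"m_g={m_g} exceeds the number of SNPs {b.size}")
    if rng is None:
        rng = np.random.default_rng(seed)
    sums = _random_subset_sums(b**2, m_g, n_perm, rng)
    mu, sd = float(sums.mean()), float(sums.std(ddof=0))
    return PermutationResult(
        p_emp=empirical_p(T_obs, sums),
        n_perm=n_perm,
        null_mean=mu,
        null_sd=sd,
        z=(T_obs - mu) / sd if sd > 0 else np.nan,
    )


def permutation_p(
    T_obs: float, m_g: int, all_effects, n_perm: int = DEFAULT_N_PERM, seed: int = 0
) -> float:
    """Convenience wrapper returning only the empirical p."""
    return permutation_test(T_obs, m_g, all_effects, n_perm=n_perm, seed=seed).p_emp


def _gene_matched_null(
    snp_map: dict,
    b2_by_snp: pd.Series,
    n_genes: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null of random gene sets of matched gene count (their window union)."""
    gene_ids = np.array(sorted(snp_map), dtype=object)
    snp_arrays = [
        b2_by_snp.index.get_indexer(snp_map[g]) for g in gene_ids
    ]
    b2 = b2_by_snp.to_numpy()
    out = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(gene_ids), size=n_genes, replace=False)
        idx = np.unique(np.concatenate([snp_arrays[k] for k in pick]) if n_genes else [])
        out[i] = b2[idx].sum() if idx.size else 0.0
    return out


def enrich(
    gene_sets,
    ann: GeneAnnotation,
    gwas: GwasSummary,
    window: int = DEFAULT_WINDOW,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    null_mode: str = "snp",
) -> pd.DataFrame:
    """Test every gene set for GWAS-signal enrichment.

    Returns one row per set (columns: set, provenance, m_g, t_sum, z,
    p_emp, fdr, n_perm, testable). Untestable sets (zero mapped SNPs)
    carry null statistics and are excluded from the BH correction, which
    runs across all testable sets of the invocation.

    ``null_mode``: 'snp' draws random SNP sets of matched SNP count
    (the standard sum-based marker-set null); 'gene' draws random gene
    sets of matched gene count and uses their window union, which differs
    when genes vary in SNP density.
    """
    gene_sets = list(gene_sets)
    if not gene_sets:
        raise DevAtlasError("no gene sets supplied")
    if null_mode not in ("snp", "gene"):
        raise DevAtlasError(f"unknown null_mode {null_mode!r}")
    snp_map = map_snps_to_genes(ann, gwas, window)
    beta = gwas.table["beta"].astype(float)
    b2_by_snp = beta**2
    seeds = np.random.SeedSequence(seed).spawn(len(gene_sets))

    rows = []
    for gs, ss in zip(gene_sets, seeds):
        rng = np.random.default_rng(ss)
        try:
            snps = geneset_snps(snp_map, gs)
        except UntestableSetError:
            logger.warning("gene set %s untestable (no mapped SNPs)", gs.name)
            rows.append((gs.name, gs.provenance, 0, np.nan, np.nan, np.nan, False))
            continue
        T_obs = t_sum(beta.loc[sorted(snps)])
        if null_mode == "snp":
            res = permutation_test(T_obs, len(snps), beta, n_perm=n_perm, rng=rng)
            p, z = res.p_emp, res.z
        else:
            n_present = len([g for g in gs.genes if g in snp_map])
            sums = _gene_matched_null(snp_map, b2_by_snp, n_present, n_perm, rng)
            p = empirical_p(T_obs, sums)
            sd = sums.std(ddof=0)
            z = float((T_obs - sums.mean()) / sd) if sd > 0 else np.nan
        rows.append((gs.name, gs.provenance, len(snps), T_obs, z, p, True))

    out = pd.DataFrame(
        rows, columns=["set", "provenance", "m_g", "t_sum", "z", "p_emp", "testable"]
    )
    if not out["testable"].any():
        raise DevAtlasError("zero testable gene sets")
    out["fdr"] = np.nan
    mask = out["testable"].to_numpy()
    out.loc[mask, "fdr"] = multipletests(out.loc[mask, "p_emp"], method="fdr_bh")[1]
    out["n_perm"] = n_perm
    return out
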