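"""Synthetic atlas, genome and GWAS generators with known planted structure.

The generator emulates a multi-tissue, multi-stage bulk RNA-seq atlas: a
tissue x stage x timepoint x replicate sample grid with planted
tissue-specific genes, stage-specific genes and smooth developmental
trajectories, plus a deterministically tiled genome and a GWAS whose SNP
effects are inflated inside the cis windows of a chosen gene set. Every
planted fact is recorded in a :class:`SimTruth` so downstream recovery can
be scored exactly.

The noise model is log-normal on the log2 scale: the downstream statistics
all operate on TPM (not counts), and an additive model on log2(TPM) keeps
the planted effects exact on the analysis scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    DevAtlasError,
    ExpressionAtlas,
    GeneAnnotation,
    GeneSet,
    GwasSummary,
)

__all__ = [
    "AtlasSimConfig",
    "GenomeSimConfig",
    "SimTruth",
    "ARCHETYPES",
    "archetype_curve",
    "simulate_atlas",
    "simulate_trajectories",
    "simulate_genome_gwas",
]


class ConfigurationError(DevAtlasError):
    """Raised when a simulation config violates its own constraints."""


# --------------------------------------------------------------------------
# configs and truth
# --------------------------------------------------------------------------

@dataclass
class AtlasSimConfig:
    """Parameters of the synthetic expression atlas.

    Defaults describe a small but realistic design: 6 tissues observed over
    4 ordered developmental stages with 2 time points each and 5 replicates,
    1000 genes, tissue/stage effects of 4 log2 units (a 16-fold change,
    typical of a strongly tissue-restricted gene) and residual noise of
    0.3 log2 units.
    """

    n_tissues: int = 6
    n_stages: int = 4
    n_timepoints_per_stage: int = 2
    n_replicates: int = 5
    n_genes: int = 1000
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    n_specific_per_tissue: int = 50
    tissue_effect_log2: float = 4.0
    n_specific_per_stage: int = 20
    stage_effect_log2: float = 4.0
    n_trajectory_genes: int = 0
    n_archetypes: int = 4
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_tissues", "n_stages", "n_timepoints_per_stage",
            "n_replicates", "n_genes",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in (
            "n_specific_per_tissue", "n_specific_per_stage",
            "n_trajectory_genes", "n_archetypes",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("tissue_effect_log2", "stage_effect_log2", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        budget = (
            self.n_specific_per_tissue * self.n_tissues
            + self.n_specific_per_stage * self.n_stages
            + self.n_trajectory_genes
        )
        if budget > self.n_genes:
            raise ConfigurationError(
                f"planted gene budget {budget} exceeds n_genes={self.n_genes} "
                "(n_specific_per_tissue*n_tissues + n_specific_per_stage*n_stages "
                "+ n_trajectory_genes must be <= n_genes)"
            )
        if self.n_trajectory_genes > 0 and self.n_stages < 2:
            raise ConfigurationError("trajectory genes require n_stages >= 2")
        if self.n_trajectory_genes > 0 and self.n_archetypes < 1:
            raise ConfigurationError("n_archetypes must be >= 1 with trajectory genes")


@dataclass
class GenomeSimConfig:
    """Parameters of the synthetic genome and GWAS summary statistics.

    The enriched gene set's cis windows (gene body +/- ``window`` bp) draw
    SNP effects with ``enriched_effect_sd``; everything else draws
    ``background_effect_sd``. Setting the two equal yields an exchangeable
    (null) GWAS.
    """

    n_chromosomes: int = 3
    gene_length: int = 20_000
    intergenic_gap: int = 60_000
    n_snps: int = 20_000
    background_effect_sd: float = 0.1
    enriched_effect_sd: float = 0.1
    enriched_geneset: GeneSet | None = None
    window: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if self.gene_length <= 0:
            raise ConfigurationError("gene_length must be > 0")
        if self.intergenic_gap < 0:
            raise ConfigurationError("intergenic_gap must be >= 0")
        if self.n_snps < 0:
            raise ConfigurationError("n_snps must be >= 0")
        if self.background_effect_sd < 0 or self.enriched_effect_sd < 0:
            raise ConfigurationError("effect SDs must be >= 0")
        if self.window < 0:
            raise ConfigurationError("window must be >= 0")


@dataclass
class SimTruth:
    """Record of everything the generators planted."""

    tissue_specific: dict = field(default_factory=dict)
    stage_specific: dict = field(default_factory=dict)
    trajectory_archetype: dict = field(default_factory=dict)
    enriched_geneset: GeneSet | None = None
    snp_regime: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "tissue_specific": {k: sorted(v) for k, v in self.tissue_specific.items()},
            "stage_specific": {k: sorted(v) for k, v in self.stage_specific.items()},
            "trajectory_archetype": dict(sorted(self.trajectory_archetype.items())),
            "enriched_geneset": (
                sorted(self.enriched_geneset.genes) if self.enriched_geneset else None
            ),
            "snp_regime": dict(sorted(self.snp_regime.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# trajectory archetypes
# --------------------------------------------------------------------------

def _smoothstep(x):
    return 3 * x**2 - 2 * x**3


#: fixed, unit-amplitude trajectory shapes over normalized stage index x in [0,1]
ARCHETYPES: list[tuple[str, callable]] = [
    ("monotone_up", lambda x: x),
    ("monotone_down", lambda x: 1.0 - x),
    ("single_peak", lambda x: 1.0 - np.abs(2.0 * x - 1.0)),
    ("single_dip", lambda x: np.abs(2.0 * x - 1.0)),
    ("early_peak", lambda x: np.clip(1.0 - np.abs(x - 0.25) / 0.375, 0.0, 1.0)),
    ("late_peak", lambda x: np.clip(1.0 - np.abs(x - 0.75) / 0.375, 0.0, 1.0)),
    ("sigmoid_up", _smoothstep),
    ("sigmoid_down", lambda x: 1.0 - _smoothstep(x)),
]


def archetype_curve(index: int, n_stages: int) -> np.ndarray:
    """Evaluate archetype ``index`` (cycled through the fixed list) at the
    ``n_stages`` equally spaced stage fractions."""
    if n_stages < 2:
        raise ConfigurationError("archetype curves need >= 2 stages")
    name, fn = ARCHETYPES[index % len(ARCHETYPES)]
    x = np.linspace(0.0, 1.0, n_stages)
    return np.asarray(fn(x), dtype=float)


def simulate_trajectories(
    n_per_archetype: int,
    n_stages: int,
    noise_sd: float,
    n_archetypes: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Direct trajectory benchmark: archetype curves plus Gaussian noise.

    Returns a genes x stages matrix (rows ``traj0000``...) and the true
    archetype label per row. Used to benchmark trajectory clustering
    without building a full atlas.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_archetypes), n_per_archetype)
    curves = np.stack([archetype_curve(a, n_stages) for a in range(n_archetypes)])
    mat = curves[labels] + rng.normal(0.0, noise_sd, size=(len(labels), n_stages))
    idx = [f"traj{i:04d}" for i in range(len(labels))]
    cols = [f"S{j + 1}" for j in range(n_stages)]
    return pd.DataFrame(mat, index=idx, columns=cols), labels


# --------------------------------------------------------------------------
# atlas generator
# --------------------------------------------------------------------------

def simulate_atlas(cfg: AtlasSimConfig) -> tuple[ExpressionAtlas, SimTruth]:
    """Generate an expression atlas with planted structure.

    log2 expression = per-gene baseline + tissue effect (planted genes, in
    their tissue) + stage effect (planted genes, at their stage, in every
    tissue) + archetype curve (trajectory genes) + Gaussian noise. The
    result is exponentiated and every sample column rescaled so TPM sums
    to 1e6. Identical seeds give bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = max(4, len(str(cfg.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    tissues = [f"tissue{t + 1:02d}" for t in range(cfg.n_tissues)]
    stages = [f"S{s + 1}" for s in range(cfg.n_stages)]

    # sample grid: tissue x stage x timepoint x replicate
    rows = []
    for t in tissues:
        for si, s in enumerate(stages):
            for j in range(cfg.n_timepoints_per_stage):
                for r in range(cfg.n_replicates):
                    sid = f"{t}_{s}_tp{j + 1}_r{r + 1}"
                    rows.append((sid, t, s, f"{s}.tp{j + 1}", si))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "tissue", "stage", "timepoint", "_stage_idx"]
    ).set_index("sample_id")
    stage_idx = meta.pop("_stage_idx").to_numpy()
    meta["stage"] = pd.Categorical(meta["stage"], categories=stages, ordered=True)
    n_samples = len(meta)

    truth = SimTruth()
    cursor = 0
    tissue_gene_rows: list[tuple[int, int]] = []  # (gene row, tissue index)
    for ti, t in enumerate(tissues):
        ids = genes[cursor:cursor + cfg.n_specific_per_tissue]
        truth.tissue_specific[t] = list(ids)
        tissue_gene_rows += [(cursor + k, ti) for k in range(len(ids))]
        cursor += cfg.n_specific_per_tissue
    stage_gene_rows: list[tuple[int, int]] = []
    for si, s in enumerate(stages):
        ids = genes[cursor:cursor + cfg.n_specific_per_stage]
        truth.stage_specific[s] = list(ids)
        stage_gene_rows += [(cursor + k, si) for k in range(len(ids))]
        cursor += cfg.n_specific_per_stage
    traj_rows: list[tuple[int, int]] = []
    for k in range(cfg.n_trajectory_genes):
        arch = k % cfg.n_archetypes  # cycled in fixed order
        truth.trajectory_archetype[genes[cursor + k]] = arch
        traj_rows.append((cursor + k, arch))

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    log2 = np.tile(baseline[:, None], (1, n_samples))

    tissue_of_sample = meta["tissue"].to_numpy()
    for row, ti in tissue_gene_rows:
        log2[row, tissue_of_sample == tissues[ti]] += cfg.tissue_effect_log2
    for row, si in stage_gene_rows:
        log2[row, stage_idx == si] += cfg.stage_effect_log2
    if traj_rows:
        curves = np.stack(
            [archetype_curve(a, cfg.n_stages) for a in range(cfg.n_archetypes)]
        )
        for row, arch in traj_rows:
            log2[row, :] += curves[arch][stage_idx]

    log2 += rng.normal(0.0, cfg.noise_sd, size=log2.shape)

    tpm = np.exp2(log2)
    tpm *= 1e6 / tpm.sum(axis=0, keepdims=True)
    expr = pd.DataFrame(tpm, index=pd.Index(genes, name="gene_id"), columns=meta.index)
    return ExpressionAtlas(expr, meta), truth


# --------------------------------------------------------------------------
# genome + GWAS generator
# --------------------------------------------------------------------------

def simulate_genome_gwas(
    cfg: GenomeSimConfig, genes
) -> tuple[GeneAnnotation, GwasSummary, SimTruth]:
    """Tile ``genes`` across chromosomes and draw per-SNP GWAS effects.

    The layout is deterministic: chromosome ``chrN`` receives a contiguous
    block of genes, gene k on a chromosome occupies
    ``[k*(L+G)+1, k*(L+G)+L]`` with L = gene_length, G = intergenic_gap.
    SNP positions are uniform over the covered chromosome lengths; effects
    are Normal(0, background_effect_sd^2) except inside the enriched set's
    cis windows, where the SD is ``enriched_effect_sd``.
    """
    cfg.validate()
    genes = list(genes)
    if not genes:
        raise ConfigurationError("genes must be nonempty")
    if cfg.enriched_geneset is not None:
        unknown = set(cfg.enriched_geneset.genes) - set(genes)
        if unknown:
            raise ConfigurationError(
                f"enriched_geneset contains unknown gene ids: {sorted(unknown)[:5]}"
            )
    rng = np.random.default_rng(cfg.seed)

    blocks = np.array_split(np.arange(len(genes)), cfg.n_chromosomes)
    pitch = cfg.gene_length + cfg.intergenic_gap
    rows = []
    chrom_lengths = {}
    for ci, block in enumerate(blocks):
        chrom = f"chr{ci + 1}"
        for k, gi in enumerate(block):
            start = k * pitch + 1
            rows.append((genes[gi], chrom, start, start + cfg.gene_length - 1, "+"))
        chrom_lengths[chrom] = max(len(block), 1) * pitch
    ann = GeneAnnotation(
        pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand"]
        ).set_index("gene_id")
    )

    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])

    if cfg.n_snps == 0:
        gwas = GwasSummary(
            pd.DataFrame(columns=["chrom", "pos", "beta"], index=pd.Index([], name="snp_id"))
        )
        return ann, gwas, SimTruth(enriched_geneset=cfg.enriched_geneset)

    global_pos = np.sort(rng.integers(0, total, size=cfg.n_snps))
    chrom_idx = np.searchsorted(offsets, global_pos, side="right") - 1
    pos = (global_pos - offsets[chrom_idx] + 1).astype(np.int64)
    snp_chrom = np.array(chroms, dtype=object)[chrom_idx]
    snp_ids = [f"snp{i:06d}" for i in range(cfg.n_snps)]

    enriched_mask = np.zeros(cfg.n_snps, dtype=bool)
    if cfg.enriched_geneset is not None:
        tab = ann.table.loc[sorted(cfg.enriched_geneset.genes)]
        for chrom, sub in tab.groupby("chrom"):
            on = snp_chrom == chrom
            if not on.any():
                continue
            p = pos[on]
            hit = np.zeros(p.shape, dtype=bool)
            for start, end in zip(sub["start"], sub["end"]):
                hit |= (p >= max(1, start - cfg.window)) & (p <= end + cfg.window)
            enriched_mask[on] |= hit

    z = rng.normal(0.0, 1.0, size=cfg.n_snps)
    beta = z * np.where(
        enriched_mask, cfg.enriched_effect_sd, cfg.background_effect_sd
    )
    gwas = GwasSummary(
        pd.DataFrame(
            {"chrom": snp_chrom, "pos": pos, "beta": beta},
            index=pd.Index(snp_ids, name="snp_id"),
        )
    )
    truth = SimTruth(
        enriched_geneset=cfg.enriched_geneset,
        snp_regime={
            sid: ("enriched" if e else "background")
            for sid, e in zip(snp_ids, enriched_mask)
        },
    )
    return ann, gwas, truth
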