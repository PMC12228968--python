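"""Window mapping, the sum-of-squares set statistic, and its permutation null."""

import itertools

import numpy as np
import pandas as pd
import pytest

from devatlas import (
    GeneAnnotation,
    GeneSet,
    GenomeSimConfig,
    GwasSummary,
    empirical_p,
    enrich,
    geneset_snps,
    map_snps_to_genes,
    permutation_p,
    permutation_test,
    simulate_genome_gwas,
    t_sum,
)
from devatlas.datatypes import (
    ChromosomeMismatchError,
    DevAtlasError,
    UntestableSetError,
)


def make_ann(rows):
    return GeneAnnotation(
        pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand"]
        ).set_index("gene_id")
    )


def make_gwas(rows):
    return GwasSummary(
        pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "beta"]).set_index(
            "snp_id"
        )
    )


class TestWindowMapping:
    @pytest.mark.parametrize(
        "pos,mapped",
        [(42_000, True), (42_001, False), (1_000, True), (999, False)],
    )
    def test_inclusive_20kb_boundaries(self, pos, mapped):
        # gene body [21000, 22000] with +/- 20 kb -> window [1000, 42000]
        ann = make_ann([("g", "chr1", 21_000, 22_000, "+")])
        gwas = make_gwas([("rs1", "chr1", pos, 0.1)])
        got = map_snps_to_genes(ann, gwas, window=20_000)
        assert ("rs1" in got["g"]) == mapped

    def test_gene_body_edges(self):
        ann = make_ann([("g", "chr1", 1_000, 2_000, "+")])
        gwas = make_gwas(
            [("a", "chr1", 22_000, 0.1), ("b", "chr1", 22_001, 0.1)]
        )
        got = map_snps_to_genes(ann, gwas, window=20_000)
        assert got["g"] == ["a"]

    def test_window_clamped_at_position_one(self):
        ann = make_ann([("g", "chr1", 5_000, 6_000, "+")])
        gwas = make_gwas([("a", "chr1", 1, 0.1)])
        got = map_snps_to_genes(ann, gwas, window=20_000)
        assert got["g"] == ["a"]

    def test_snp_maps_to_multiple_overlapping_genes(self):
        ann = make_ann(
            [("g1", "chr1", 1_000, 2_000, "+"), ("g2", "chr1", 2_500, 3_500, "-")]
        )
        gwas = make_gwas([("a", "chr1", 2_200, 0.1)])
        got = map_snps_to_genes(ann, gwas, window=1_000)
        assert got["g1"] == ["a"] and got["g2"] == ["a"]

    def test_chromosome_mismatch_lists_names(self):
        ann = make_ann([("g", "chr1", 1_000, 2_000, "+")])
        gwas = make_gwas([("a", "2", 100, 0.1)])
        with pytest.raises(ChromosomeMismatchError, match="chr1"):
            map_snps_to_genes(ann, gwas)

    def test_negative_window_rejected(self):
        ann = make_ann([("g", "chr1", 1_000, 2_000, "+")])
        gwas = make_gwas([("a", "chr1", 100, 0.1)])
        with pytest.raises(DevAtlasError, match="window"):
            map_snps_to_genes(ann, gwas, window=-1)

    def test_matches_brute_force_scan_on_simulated_genome(self, tiled_genome):
        ann, gwas, _ = tiled_genome
        window = 20_000
        got = map_snps_to_genes(ann, gwas, window)
        tab = gwas.table
        for gid, row in ann.table.iterrows():
            expected = [
                sid
                for sid, srow in tab.iterrows()
                if srow["chrom"] == row["chrom"]
                and max(1, row["start"] - window) <= srow["pos"] <= row["end"] + window
            ]
            assert sorted(got[gid]) == sorted(expected)


class TestGenesetSnps:
    def test_shared_snp_counted_once(self):
        snp_map = {"g1": ["a", "b"], "g2": ["b", "c"]}
        got = geneset_snps(snp_map, GeneSet("s", {"g1", "g2"}))
        assert got == {"a", "b", "c"}

    def test_no_nearby_snps_is_untestable(self):
        with pytest.raises(UntestableSetError):
            geneset_snps({"g1": []}, GeneSet("s", {"g1"}))

    def test_missing_genes_logged_not_fatal(self, caplog):
        with caplog.at_level("INFO"):
            got = geneset_snps({"g1": ["a"]}, GeneSet("s", {"g1", "ghost"}))
        assert got == {"a"}


class TestTsum:
    def test_hand_computed_value(self):
        assert t_sum([0.1, -0.2, 0.3]) == pytest.approx(0.14)

    def test_all_zero_effects(self):
        assert t_sum([0.0, 0.0]) == 0.0

    def test_quadratic_homogeneity(self):
        b = np.array([0.3, -1.2, 0.7])
        assert t_sum(3 * b) == pytest.approx(9 * t_sum(b))

    def test_empty_vector_raises(self):
        with pytest.raises(DevAtlasError):
            t_sum([])


class TestEmpiricalP:
    def test_hand_counted_proportion(self):
        # 2 of 4 permuted stats are >= 2.5 -> (1+2)/(1+4)
        assert empirical_p(2.5, [1, 2, 3, 4]) == pytest.approx(0.6)

    def test_floor_of_the_estimator(self):
        stats = np.zeros(10_000)
        assert empirical_p(1.0, stats) == pytest.approx(1 / 10_001)

    def test_ties_count_against_significance(self):
        assert empirical_p(3.0, [3.0, 1.0]) == pytest.approx(2 / 3)


class TestPermutationNull:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=500)
        p1 = permutation_p(1.0, 10, b, n_perm=500, seed=42)
        p2 = permutation_p(1.0, 10, b, n_perm=500, seed=42)
        assert p1 == p2

    def test_invariant_to_effect_rescaling(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=300)
        T = t_sum(b[:7])
        p1 = permutation_p(T, 7, b, n_perm=400, seed=5)
        p2 = permutation_p(100.0 * T, 7, 10.0 * b, n_perm=400, seed=5)
        assert p1 == p2

    def test_converges_to_exact_enumeration(self):
        """On 8 SNPs / set size 3, the permutation p approaches the exact
        value enumerated over all C(8,3) = 56 subsets."""
        rng = np.random.default_rng(2)
        b = rng.normal(size=8)
        T_obs = t_sum(b[[0, 3, 5]])
        exact_stats = [t_sum(b[list(c)]) for c in itertools.combinations(range(8), 3)]
        exact = np.mean([t >= T_obs for t in exact_stats])
        p = permutation_p(T_obs, 3, b, n_perm=50_000, seed=0)
        assert p == pytest.approx(exact, abs=0.01)

    def test_subset_size_equal_to_pool(self):
        b = np.array([0.1, 0.2, 0.3])
        res = permutation_test(t_sum(b), 3, b, n_perm=10, seed=0)
        assert res.p_emp == 1.0  # every permutation ties the observed sum

    def test_m_exceeding_snp_count_raises(self):
        with pytest.raises(DevAtlasError, match="exceeds"):
            permutation_p(1.0, 5, np.ones(3), n_perm=10)


class TestEnrich:
    @pytest.fixture
    def planted(self):
        genes = [f"g{i:03d}" for i in range(100)]
        target = GeneSet("planted", set(genes[:10]), provenance="cluster:1")
        cfg = GenomeSimConfig(
            n_chromosomes=2, n_snps=4_000, background_effect_sd=0.1,
            enriched_effect_sd=0.4, enriched_geneset=target, seed=3,
        )
        ann, gwas, _ = simulate_genome_gwas(cfg, genes)
        return genes, target, ann, gwas

    def test_single_set_fdr_equals_p(self, planted):
        genes, target, ann, gwas = planted
        out = enrich([target], ann, gwas, n_perm=200, seed=0)
        assert out["fdr"].iloc[0] == out["p_emp"].iloc[0]

    def test_planted_set_beats_decoys(self, planted):
        genes, target, ann, gwas = planted
        rng = np.random.default_rng(0)
        decoys = [
            GeneSet(f"decoy{k}", set(rng.choice(genes[10:], 10, replace=False)))
            for k in range(5)
        ]
        out = enrich([target] + decoys, ann, gwas, n_perm=500, seed=1)
        best = out.sort_values(["p_emp", "z"], ascending=[True, False]).iloc[0]
        assert best["set"] == "planted"
        assert best["fdr"] < 0.05

    def test_untestable_set_excluded_from_fdr(self, planted):
        genes, target, ann, gwas = planted
        # a gene set whose genes exist but sit on a SNP-free chromosome
        ann2 = GeneAnnotation(
            pd.concat(
                [
                    ann.table,
                    pd.DataFrame(
                        {"chrom": ["chr9"], "start": [1], "end": [100], "strand": ["+"]},
                        index=pd.Index(["lonely"], name="gene_id"),
                    ),
                ]
            )
        )
        lonely = GeneSet("lonely_set", {"lonely"})
        out = enrich([target, lonely], ann2, gwas, n_perm=100, seed=0)
        row = out[out["set"] == "lonely_set"].iloc[0]
        assert not row["testable"] and np.isnan(row["fdr"])
        assert out[out["set"] == "planted"]["fdr"].notna().all()

    def test_zero_testable_sets_raises(self, planted):
        genes, _, ann, gwas = planted
        ann2 = GeneAnnotation(
            pd.DataFrame(
                {"chrom": ["chr9"], "start": [1], "end": [100], "strand": ["+"]},
                index=pd.Index(["lonely"], name="gene_id"),
            )
        )
        gwas9 = GwasSummary(
            pd.DataFrame(
                {"chrom": ["chr9"], "pos": [50_000_000], "beta": [0.1]},
                index=pd.Index(["far"], name="snp_id"),
            )
        )
        with pytest.raises(DevAtlasError, match="zero testable"):
            enrich([GeneSet("lonely_set", {"lonely"})], ann2, gwas9, n_perm=10)

    def test_gene_matched_null_mode_runs(self, planted):
        genes, target, ann, gwas = planted
        out = enrich([target], ann, gwas, n_perm=100, seed=2, null_mode="gene")
        p = out["p_emp"].iloc[0]
        assert 0 < p <= 1

    def test_stronger_planting_gives_smaller_p(self):
        """Raising the enriched effect SD stochastically lowers the
        planted set's empirical p."""
        genes = [f"g{i:03d}" for i in range(100)]
        target = GeneSet("planted", set(genes[:10]))
        ps = {}
        for sd in (0.1, 0.2, 0.4):
            vals = []
            for seed in range(3):
                cfg = GenomeSimConfig(
                    n_chromosomes=2, n_snps=4_000, background_effect_sd=0.1,
                    enriched_effect_sd=sd, enriched_geneset=target, seed=seed,
                )
                ann, gwas, _ = simulate_genome_gwas(cfg, genes)
                out = enrich([target], ann, gwas, n_perm=300, seed=seed)
                vals.append(out["p_emp"].iloc[0])
            ps[sd] = np.mean(vals)
        # p can floor at 1/(n_perm+1), so the chain is non-strict overall
        # but must strictly fall from null to strong planting
        assert ps[0.4] <= ps[0.2] <= ps[0.1]
        assert ps[0.4] < ps[0.1]
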