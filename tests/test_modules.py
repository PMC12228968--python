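"""Module sharing index, eigengene, and module-stage association."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_atlas
from devatlas import (
    AtlasSimConfig,
    ModuleAssignment,
    module_eigengene,
    module_sharing_index,
    module_stage_association,
    simulate_atlas,
)
from devatlas.datatypes import DevAtlasError
from devatlas.qc import log_transform


class TestSharingIndex:
    def test_identical_modules_share_one(self):
        A = ModuleAssignment("a", {"m": {"g1", "g2"}})
        assert module_sharing_index(A, A).loc["m", "m"] == 1.0

    def test_disjoint_modules_share_zero(self):
        A = ModuleAssignment("a", {"m": {"g1", "g2"}})
        B = ModuleAssignment("b", {"x": {"g3", "g4"}})
        assert module_sharing_index(A, B).loc["m", "x"] == 0.0

    def test_hand_computed_jaccard(self):
        A = ModuleAssignment("a", {"m": {"g1", "g2", "g3"}})
        B = ModuleAssignment("b", {"x": {"g2", "g3", "g4"}})
        assert module_sharing_index(A, B).loc["m", "x"] == pytest.approx(0.5)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        A = ModuleAssignment(
            "a", {f"m{k}": set(rng.choice(genes, 10, replace=False)) for k in range(3)}
        )
        B = ModuleAssignment(
            "b", {f"x{k}": set(rng.choice(genes, 8, replace=False)) for k in range(4)}
        )
        j_ab = module_sharing_index(A, B)
        j_ba = module_sharing_index(B, A)
        np.testing.assert_allclose(j_ab.to_numpy(), j_ba.to_numpy().T)

    def test_both_empty_modules_share_zero_with_warning(self, caplog):
        A = ModuleAssignment("a", {"m": set()})
        B = ModuleAssignment("b", {"x": set()})
        with caplog.at_level("WARNING"):
            j = module_sharing_index(A, B)
        assert j.loc["m", "x"] == 0.0
        assert "empty" in caplog.text


@pytest.fixture(scope="module")
def sim_atlas():
    return simulate_atlas(AtlasSimConfig(seed=21, n_genes=300,
                                         n_specific_per_tissue=10,
                                         n_specific_per_stage=10))


class TestEigengene:
    def test_rank_one_module_matches_member_profile(self):
        # perfectly correlated genes (identical profiles): the eigengene
        # must equal any member's standardized profile up to sign
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 50, 12)
        atlas = make_atlas(
            {f"g{i}": list(base) for i in range(4)},
            {f"s{j}": "A" for j in range(12)},
        )
        eig = module_eigengene(atlas, [f"g{i}" for i in range(4)])
        member = log_transform(atlas.expression.loc["g0"].to_numpy())
        member = (member - member.mean()) / member.std()
        r = np.corrcoef(eig, member)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_nonnegative_with_mean_profile(self, sim_atlas):
        atlas, truth = sim_atlas
        for tissue, genes in list(truth.tissue_specific.items())[:3]:
            eig = module_eigengene(atlas, genes)
            z = log_transform(atlas.expression.loc[list(genes)])
            z = (z - z.mean(axis=1).to_numpy()[:, None]) / z.std(axis=1, ddof=0).to_numpy()[:, None]
            assert np.corrcoef(eig, z.mean(axis=0))[0, 1] >= 0

    def test_matches_dense_svd_oracle(self, sim_atlas):
        atlas, _ = sim_atlas
        genes = list(atlas.gene_ids[:5])
        eig = module_eigengene(atlas, genes)
        # independent recomputation: standardize, full SVD, first right vector
        sub = np.log2(atlas.expression.loc[genes].to_numpy() + 0.25)
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(z)
        v = vt[0]
        if np.dot(v, z.mean(axis=0)) < 0:
            v = -v
        np.testing.assert_allclose(eig.to_numpy(), v, atol=1e-8)

    def test_duplicated_gene_row_barely_moves_eigengene(self, sim_atlas):
        # a coherent module (co-regulated planted genes) keeps essentially
        # the same eigengene when one member is duplicated
        atlas, truth = sim_atlas
        genes = list(truth.tissue_specific["tissue01"])
        eig1 = module_eigengene(atlas, genes)
        eig2 = module_eigengene(atlas, genes + [genes[0]])
        assert np.corrcoef(eig1, eig2)[0, 1] > 0.999

    def test_all_genes_missing_raises(self, sim_atlas):
        atlas, _ = sim_atlas
        with pytest.raises(DevAtlasError, match="no module genes"):
            module_eigengene(atlas, ["absent1", "absent2"])


class TestStageAssociation:
    def test_indicator_eigengene_has_r_one(self):
        meta = pd.DataFrame(
            {
                "tissue": "A",
                "stage": ["S1"] * 4 + ["S2"] * 4,
                "timepoint": "tp1",
            },
            index=pd.Index([f"s{i}" for i in range(8)], name="sample_id"),
        )
        eig = pd.Series([1.0] * 4 + [0.0] * 4, index=meta.index)
        out = module_stage_association({"m": eig}, meta)
        r_s1 = out.loc[(out["module"] == "m") & (out["stage"] == "S1"), "r"].iloc[0]
        assert r_s1 == pytest.approx(1.0)

    def test_balanced_permutation_mean_r_near_zero(self):
        rng = np.random.default_rng(3)
        meta = pd.DataFrame(
            {
                "tissue": "A",
                "stage": ["S1"] * 10 + ["S2"] * 10,
                "timepoint": "tp1",
            },
            index=pd.Index([f"s{i}" for i in range(20)], name="sample_id"),
        )
        rs = []
        for _ in range(200):
            eig = pd.Series(rng.permutation(np.linspace(-1, 1, 20)), index=meta.index)
            out = module_stage_association({"m": eig}, meta)
            rs.append(out["r"].iloc[0])
        assert abs(np.mean(rs)) < 0.05

    def test_planted_stage_module_detected(self):
        """A module upregulated in one stage gets its max correlation and
        FDR < 0.05 at that stage in nearly all simulation replicates."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            atlas, truth = simulate_atlas(
                AtlasSimConfig(
                    seed=100 + rep, n_genes=100, n_tissues=2,
                    n_specific_per_tissue=0, n_specific_per_stage=10,
                    stage_effect_log2=2.0, noise_sd=0.5,
                )
            )
            genes = truth.stage_specific["S3"]
            eig = module_eigengene(atlas, genes)
            out = module_stage_association({"m": eig}, atlas.sample_meta)
            best = out.loc[out["r"].idxmax()]
            if best["stage"] == "S3" and best["fdr"] < 0.05:
                hits += 1
        assert hits >= n_rep - 1

    def test_constant_eigengene_raises(self):
        meta = pd.DataFrame(
            {"tissue": "A", "stage": ["S1", "S1", "S2", "S2"], "timepoint": "tp1"},
            index=pd.Index(list("abcd"), name="sample_id"),
        )
        eig = pd.Series([1.0] * 4, index=meta.index)
        with pytest.raises(DevAtlasError, match="constant"):
            module_stage_association({"m": eig}, meta)
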