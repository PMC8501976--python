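"""TF-level decoding, gene-set selection, and QTL enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from protect.genome_io import Gene, GenomeAnnotation, GenomicInterval, TFPeakSet
from protect.interpretation import (
    cis_qtl_enrichment,
    gene_sets_by_feature,
    rank_tf_level,
    snp_summit_distance_test,
    trans_pairs,
    trans_qtl_test,
    TransPairRecord,
    _supported_mask,
)
from protect.ppi_modules import ModuleAssignment, ModuleFeature, ModuleFeatureCatalog


def catalog_ab():
    assignment = ModuleAssignment(s_module_of={"TFa": 0, "TFb": 1, "TFc": 0},
                                  l_module_of={"TFa": 0, "TFb": 0, "TFc": 0},
                                  S_max=2, L_max=3)
    features = [
        ModuleFeature("S0>S1", "S", "inter", (0, 1), (("TFa", "TFb"), ("TFc", "TFb"))),
        ModuleFeature("S1>S0", "S", "inter", (1, 0), (("TFb", "TFa"), ("TFb", "TFc"))),
    ]
    return ModuleFeatureCatalog(features=features, assignment=assignment)


class TestRankTFLevel:
    def test_abundance_is_fraction_of_predictions(self):
        tf = pd.DataFrame({"TFa|TFb": [1, 0, 1, 0], "TFc|TFb": [1, 1, 1, 0]})
        r = rank_tf_level(tf, catalog_ab(), "S0>S1", top_k=5)
        assert r.ranking[0] == ("TFc", "TFb", 0.75)
        assert r.ranking[1] == ("TFa", "TFb", 0.5)

    def test_absent_constituent_ranked_last_with_zero(self):
        tf = pd.DataFrame({"TFa|TFb": [1, 1]})
        r = rank_tf_level(tf, catalog_ab(), "S0>S1", top_k=5)
        assert r.ranking[-1] == ("TFc", "TFb", 0.0)

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            rank_tf_level(pd.DataFrame({"TFa|TFb": []}), catalog_ab(), "S0>S1")

    def test_top_k_truncates(self):
        tf = pd.DataFrame({"TFa|TFb": [1], "TFc|TFb": [1]})
        r = rank_tf_level(tf, catalog_ab(), "S0>S1", top_k=1)
        assert len(r.ranking) == 1


class TestGeneSets:
    def preds(self):
        return pd.DataFrame({
            "enhancer_id": ["E0", "E1", "E2", "E3"],
            "gene_id": ["G0", "G0", "G1", "G2"],
            "q_value": [0.01, 0.002, 0.03, 0.2],
            "significant": [True, True, True, False],
        })

    def test_distinct_genes_at_best_q(self):
        tf = pd.DataFrame({"TFa|TFb": [1, 1, 1, 1], "TFc|TFb": [0, 0, 0, 0]})
        out = gene_sets_by_feature(self.preds(), tf, catalog_ab(), ["S0>S1"],
                                   tf_top_k=2, n_genes=10)
        # G0 appears once (best q 0.002 ranks it first), G2 not significant
        assert out["S0>S1"] == ["G0", "G1"]

    def test_n_genes_cap(self):
        tf = pd.DataFrame({"TFa|TFb": [1, 1, 1, 1], "TFc|TFb": [0, 0, 0, 0]})
        out = gene_sets_by_feature(self.preds(), tf, catalog_ab(), ["S0>S1"],
                                   tf_top_k=2, n_genes=1)
        assert out["S0>S1"] == ["G0"]

    def test_feature_without_firing_constituents_is_empty(self):
        tf = pd.DataFrame({"TFa|TFb": [0, 0, 0, 0], "TFc|TFb": [0, 0, 0, 0]})
        out = gene_sets_by_feature(self.preds(), tf, catalog_ab(), ["S0>S1"],
                                   tf_top_k=2, n_genes=10)
        assert out["S0>S1"] == []


def qtl_genome():
    enhancers = [GenomicInterval("chr1", 1000, 2000, "E0"),
                 GenomicInterval("chr1", 5000, 6000, "E1")]
    genes = [Gene("G0", "chr1", 100_000, "+"), Gene("G1", "chr1", 200_000, "+")]
    peaks = {
        "TFa": TFPeakSet("TFa", [GenomicInterval("chr1", 1200, 1400, "p1", summit=100)]),
        "TFb": TFPeakSet("TFb", [GenomicInterval("chr1", 1000, 2000, "p2", summit=500)]),
    }
    return GenomeAnnotation(chrom_lengths={"chr1": 2_000_000},
                            tads=[GenomicInterval("chr1", 0, 2_000_000, "T0")],
                            enhancers=enhancers, genes=genes, peaks=peaks)


class TestCisSupport:
    def test_snp_in_enhancer_with_matching_gene(self):
        g = qtl_genome()
        pairs = pd.DataFrame({"enhancer_id": ["E0", "E0"], "gene_id": ["G0", "G1"]})
        qtls = pd.DataFrame({"snp_id": ["s1"], "chrom": ["chr1"], "pos": [1500],
                             "gene_id": ["G0"]})
        mask = _supported_mask(pairs, qtls, g)
        assert mask.tolist() == [True, False]  # gene must match

    def test_snp_outside_enhancer_not_supported(self):
        g = qtl_genome()
        pairs = pd.DataFrame({"enhancer_id": ["E0"], "gene_id": ["G0"]})
        qtls = pd.DataFrame({"snp_id": ["s1"], "chrom": ["chr1"], "pos": [2500],
                             "gene_id": ["G0"]})
        assert not _supported_mask(pairs, qtls, g).any()

    def test_enrichment_on_planted_qtls(self):
        g = qtl_genome()
        preds = pd.DataFrame({
            "enhancer_id": ["E0"], "gene_id": ["G0"],
            "distance_bp": [98_500], "q_value": [0.01], "significant": [True],
        })
        qtls = pd.DataFrame({"snp_id": ["s1"], "chrom": ["chr1"], "pos": [1500],
                             "gene_id": ["G0"]})
        res = cis_qtl_enrichment(preds, qtls, g, n_random=50, seed=0)
        assert res.observed_fraction == 1.0
        assert 0 < res.p_vs_random <= 1 and 0 < res.p_vs_matched <= 1

    def test_distance_matched_control_histogram(self):
        g = qtl_genome()
        preds = pd.DataFrame({
            "enhancer_id": ["E0", "E1"], "gene_id": ["G0", "G1"],
            "distance_bp": [98_500, 194_500], "q_value": [0.01, 0.02],
            "significant": [True, True],
        })
        qtls = pd.DataFrame({"snp_id": [], "chrom": [], "pos": [], "gene_id": []})
        res = cis_qtl_enrichment(preds, qtls, g, n_random=20, seed=0)
        assert res.observed_fraction == 0.0
        # with no QTLs anywhere, no control can beat... all fractions equal 0:
        assert (res.control_fractions_matched == 0).all()
        assert res.p_vs_matched == 1.0  # add-one estimator with all ties


class TestSummitDistances:
    def test_relative_distance_arithmetic(self):
        g = qtl_genome()
        # TFa peak [1200,1400) summit offset 100 -> absolute 1300, length 200
        res = snp_summit_distance_test([("chr1", 1300, "E0")], g, ["TFa"],
                                       background_tfs=["TFb"])
        assert res.foreground[0] == 0.0
        # TFb peak [1000,2000) summit 1500: |1300-1500|/1000 = 0.2
        assert res.background[0] == pytest.approx(0.2)

    def test_edge_snp_on_central_summit_is_half(self):
        g = qtl_genome()
        res = snp_summit_distance_test([("chr1", 1000, "E0")], g, ["TFb"],
                                       background_tfs=["TFa"])
        assert res.foreground[0] == pytest.approx(0.5)

    def test_identical_samples_ks_zero(self):
        g = qtl_genome()
        res = snp_summit_distance_test([("chr1", 1300, "E0")], g, ["TFa"],
                                       background_tfs=["TFa"])
        assert res.ks_statistic == 0.0 and res.p_value == 1.0

    def test_empty_sample_rejected(self):
        g = qtl_genome()
        with pytest.raises(ValueError):
            snp_summit_distance_test([("chr1", 1300, "E1")], g, ["TFa"],
                                     background_tfs=["TFb"])


class TestTransPairs:
    def preds_and_tf(self):
        preds = pd.DataFrame({
            "enhancer_id": ["E0", "E1"], "gene_id": ["G0", "G1"],
            "q_value": [0.01, 0.02], "significant": [True, True],
        })
        tf = pd.DataFrame({"TFa|TFb": [1, 1], "TFc|TFb": [0, 0]})
        return preds, tf

    def test_promoter_bound_gene_removed(self):
        g = qtl_genome()
        # make TFa bind G0's promoter too
        g.peaks["TFa"].peaks.append(
            GenomicInterval("chr1", 99_500, 99_700, "p3", summit=100))
        preds, tf = self.preds_and_tf()
        pairs, _ = trans_pairs(preds, tf, catalog_ab(), ["S0>S1"], g)
        assert ("TFa", "G0") not in pairs and ("TFa", "G1") in pairs

    def test_enhancer_only_binding_kept_and_deduplicated(self):
        g = qtl_genome()
        preds = pd.DataFrame({
            "enhancer_id": ["E0", "E1"], "gene_id": ["G0", "G0"],
            "q_value": [0.01, 0.02], "significant": [True, True],
        })
        tf = pd.DataFrame({"TFa|TFb": [1, 1], "TFc|TFb": [0, 0]})
        pairs, records = trans_pairs(preds, tf, catalog_ab(), ["S0>S1"], g)
        assert pairs == {("TFa", "G0")}
        assert len(records) == 2  # one record per mediating prediction


class TestTransQTL:
    def bodies(self):
        return pd.DataFrame({
            "tf": ["TFa"], "chrom": ["chr1"], "start": [500_000],
            "end": [510_000], "strand": ["+"],
        })

    def test_upstream_window_rule(self):
        g = qtl_genome()
        records = [TransPairRecord("TFa", "E0", "G0")]
        near = pd.DataFrame({"snp_id": ["s"], "chrom": ["chr1"], "pos": [495_000],
                             "gene_id": ["G0"]})
        far = pd.DataFrame({"snp_id": ["s"], "chrom": ["chr1"], "pos": [485_000],
                            "gene_id": ["G0"]})
        res_near = trans_qtl_test(records, near, self.bodies(), g, n_random=10, seed=0)
        res_far = trans_qtl_test(records, far, self.bodies(), g, n_random=10, seed=0)
        assert res_near.n_overlap == 1  # 5 kb upstream: inside the window
        assert res_far.n_overlap == 0   # 15 kb upstream: outside

    def test_hypergeometric_matches_tail_sum(self):
        from math import comb
        from scipy.stats import hypergeom
        M, K, n, k = 200, 20, 30, 8
        tail = sum(comb(K, i) * comb(M - K, n - i) for i in range(k, min(K, n) + 1))
        tail /= comb(M, n)
        assert hypergeom.sf(k - 1, M, K, n) == pytest.approx(tail, rel=1e-12)

    def test_controls_produced(self):
        g = qtl_genome()
        records = [TransPairRecord("TFa", "E0", "G0")]
        qtls = pd.DataFrame({"snp_id": ["s"], "chrom": ["chr1"], "pos": [505_000],
                             "gene_id": ["G0"]})
        res = trans_qtl_test(records, qtls, self.bodies(), g, n_random=25, seed=0)
        assert len(res.control_random_ps) == 25
        assert 0 < res.p_value <= 1 and 0 < res.control_nearest_p <= 1


def test_ks_oracle_on_fixed_samples():
    a = np.array([0.1, 0.2, 0.3, 0.4])
    b = np.array([0.6, 0.7, 0.8, 0.9])
    stat, _ = ks_2samp(a, b)
    assert stat == 1.0
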