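"""Peak enrichment, promoter/TSS statistics, mark-expression R, simple DE."""

import numpy as np
import pandas as pd
import pytest

from chromhier import (make_genome, mark_expression_correlation,
                       peak_feature_enrichment, plant_truth, promoter_stats,
                       simple_de, simulate_annotation_and_expression,
                       simulate_coupled_peaks, simulate_peaks,
                       tss_metaprofile)
from chromhier.genome import GenomeLayout
from chromhier.synth import PeakSet, simulate_count_matrix


def _peakset(rows, mark="H3ac"):
    return PeakSet(mark, "cond1",
                   pd.DataFrame(rows, columns=["chrom", "start", "end",
                                               "signal"]))


def _a_blocks(truth, genome):
    return pd.DataFrame(
        [(c, s, e) for c in genome.names
         for s, e, l in truth.compartment_blocks[c] if l == "A"],
        columns=["chrom", "start", "end"])


class TestPeakFeatureEnrichment:
    def test_empty_inputs_not_applicable(self, small_genome):
        empty = _peakset([])
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        assert not peak_feature_enrichment(empty, feats, small_genome).applicable
        peaks = _peakset([("chr1", 0, 100, 1.0)])
        none = pd.DataFrame(columns=["chrom", "start", "end"])
        assert not peak_feature_enrichment(peaks, none, small_genome).applicable

    def test_whole_genome_feature_flagged_undefined_odds(self, small_genome):
        feats = pd.DataFrame({"chrom": list(small_genome.names),
                              "start": 0,
                              "end": list(small_genome.lengths)})
        peaks = _peakset([("chr1", 1000, 2000, 1.0),
                          ("chr2", 5000, 9000, 1.0)])
        r = peak_feature_enrichment(peaks, feats, small_genome, seed=1)
        assert r.n_in_feature == r.n_peaks
        assert r.odds_ratio is None  # no outside-bp margin: undefined

    def test_biased_peaks_give_large_z(self, small_genome, truth):
        h3ac, _ = simulate_peaks(truth, small_genome, a_bias=0.9,
                                 n_peaks=500, seed=2)
        r = peak_feature_enrichment(h3ac, _a_blocks(truth, small_genome),
                                    small_genome, seed=3)
        assert r.perm_z > 3
        assert r.odds_ratio > 1
        assert r.fisher_p < 1e-6

    def test_unbiased_peaks_give_small_z(self, small_genome, truth):
        small = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rows = []
            for _ in range(200):
                c = small_genome.names[rng.integers(2)]
                s = int(rng.integers(0, small_genome.length_of(c) - 2000))
                rows.append((c, s, s + 1500, 1.0))
            r = peak_feature_enrichment(_peakset(rows),
                                        _a_blocks(truth, small_genome),
                                        small_genome, n_shuffles=500,
                                        seed=50 + seed)
            small += abs(r.perm_z) < 2
        assert small >= 9

    def test_null_z_is_standard_normal_like(self, small_genome, truth):
        # the permutation z over independent null datasets behaves like a
        # standard normal draw
        feats = _a_blocks(truth, small_genome)
        zs = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            rows = []
            for _ in range(100):
                c = small_genome.names[rng.integers(2)]
                s = int(rng.integers(0, small_genome.length_of(c) - 2000))
                rows.append((c, s, s + 1500, 1.0))
            r = peak_feature_enrichment(_peakset(rows), feats, small_genome,
                                        n_shuffles=250, seed=2000 + rep)
            zs.append(r.perm_z)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.1
        assert 0.9 <= zs.std() <= 1.1


class TestPromoterStats:
    def _genes(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2"],
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 50_000],
            "end": [14_000, 54_000],
            "strand": ["+", "-"],
            "tss": [10_000, 54_000],
        })

    def test_all_peaks_in_promoters(self):
        peaks = _peakset([("chr1", 9_400, 9_600, 1.0),
                          ("chr1", 54_400, 54_600, 1.0)])
        r = promoter_stats(peaks, self._genes())
        assert r["fraction"] == 1.0

    def test_peak_at_tss_not_upstream(self):
        # + strand promoter is [TSS-1kb, TSS): a peak centered at the TSS
        # itself is not upstream
        peaks = _peakset([("chr1", 9_950, 10_050, 1.0)])
        r = promoter_stats(peaks, self._genes())
        assert r["fraction"] == 0.0

    def test_uniform_peaks_match_promoter_bp_fraction(self):
        genome = GenomeLayout(("chr1",), (1_000_000,),
                              mac_threshold=50_000_000)
        rng = np.random.default_rng(4)
        genes = pd.DataFrame({
            "gene_id": [f"g{k}" for k in range(50)],
            "chrom": "chr1",
            "start": rng.integers(10_000, 900_000, 50),
            "strand": "+",
        })
        genes["end"] = genes["start"] + 4000
        genes["tss"] = genes["start"]
        rows = [("chr1", int(s), int(s) + 2, 1.0)
                for s in rng.integers(0, 999_000, 20_000)]
        r = promoter_stats(_peakset(rows), genes)
        # analytic expectation: merged promoter bp / chromosome bp
        from chromhier.integrate import promoter_intervals, _merged
        iv = _merged(promoter_intervals(genes))["chr1"]
        f = (iv[:, 1] - iv[:, 0]).sum() / 1_000_000
        assert abs(r["fraction"] - f) < 3 * np.sqrt(f * (1 - f) / 20_000) + 0.002


class TestTssMetaprofile:
    def _genes(self, n=20, strand="+"):
        return pd.DataFrame({
            "gene_id": [f"g{k}" for k in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 100_000 + 50_000,
            "end": np.arange(n) * 100_000 + 55_000,
            "strand": strand,
            "tss": np.arange(n) * 100_000 + 50_000,
        })

    def test_peaks_centered_at_tss_peak_centrally(self):
        genes = self._genes()
        rows = [("chr1", t - 150, t + 150, 1.0) for t in genes["tss"]]
        prof = tss_metaprofile(_peakset(rows), genes, flank=3000, bin_size=100)
        center = len(prof) // 2
        assert prof.argmax() in (center - 1, center)

    def test_no_peaks_gives_zero_profile(self):
        prof = tss_metaprofile(_peakset([]), self._genes())
        assert (prof == 0).all()

    def test_uniform_coverage_gives_flat_profile(self):
        genes = self._genes()
        rows = [("chr1", 0, 2_000_000, 1.0)]
        prof = tss_metaprofile(_peakset(rows), genes, flank=3000,
                               bin_size=100)
        assert np.allclose(prof, 100.0)

    def test_strand_orientation_flips_profile(self):
        gp = self._genes(strand="+")
        gm = self._genes(strand="-")
        rows = [("chr1", t - 1000, t - 500, 1.0) for t in gp["tss"]]
        pp = tss_metaprofile(_peakset(rows), gp)
        pm = tss_metaprofile(_peakset(rows), gm)
        assert np.allclose(pp, pm[::-1])


class TestMarkExpressionCorrelation:
    def test_signal_proportional_to_expression_gives_r_one(self):
        genes = pd.DataFrame({
            "gene_id": [f"g{k}" for k in range(30)],
            "chrom": "chr1",
            "start": np.arange(30) * 100_000 + 10_000,
            "strand": "+",
        })
        genes["end"] = genes["start"] + 50_000
        genes["tss"] = genes["start"]
        fpkm = 2.0 ** np.linspace(0, 8, 30) - 1
        expr = pd.DataFrame({"gene_id": genes["gene_id"],
                             "condition": "cond1", "count": 1,
                             "fpkm": fpkm})
        # peak bp exactly proportional to log2(FPKM+1)
        rows = [("chr1", int(s), int(s) + int(100 * np.log2(f + 1)) + 1, 1.0)
                for s, f in zip(genes["start"], fpkm)]
        r = mark_expression_correlation(_peakset(rows), genes, expr, "cond1")
        assert r["r"] > 0.999

    def test_target_r_recovered(self, small_genome, truth, genes_expr):
        genes, expr = genes_expr
        for mark, target in (("H3ac", 0.56), ("H3K27me3", -0.45)):
            ps = simulate_coupled_peaks(genes, expr, "cond1", mark, target,
                                        seed=6)
            r = mark_expression_correlation(ps, genes, expr, "cond1")
            assert abs(r["r"] - target) <= 0.1

    def test_independent_signal_uncorrelated(self):
        rng = np.random.default_rng(7)
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 2000
            genes = pd.DataFrame({
                "gene_id": [f"g{k}" for k in range(n)],
                "chrom": "chr1",
                "start": np.arange(n) * 10_000,
                "strand": "+",
            })
            genes["end"] = genes["start"] + 5_000
            genes["tss"] = genes["start"]
            expr = pd.DataFrame({"gene_id": genes["gene_id"],
                                 "condition": "cond1", "count": 1,
                                 "fpkm": rng.lognormal(2, 1, n)})
            lens = rng.integers(100, 2000, n)
            rows = [("chr1", int(s), int(s + l), 1.0)
                    for s, l in zip(genes["start"], lens)]
            r = mark_expression_correlation(_peakset(rows), genes, expr,
                                            "cond1")
            ok += abs(r["r"]) < 0.1
        assert ok >= 9

    def test_zero_variance_not_applicable(self):
        genes = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3"], "chrom": "chr1",
            "start": [0, 10_000, 20_000], "end": [5000, 15_000, 25_000],
            "strand": "+", "tss": [0, 10_000, 20_000]})
        expr = pd.DataFrame({"gene_id": genes["gene_id"],
                             "condition": "cond1", "count": 1, "fpkm": 5.0})
        rows = [("chr1", 0, 100, 1.0)]
        r = mark_expression_correlation(_peakset(rows), genes, expr, "cond1")
        assert not r["applicable"]


class TestSimpleDe:
    def test_identical_groups_no_calls(self):
        counts, groups = simulate_count_matrix(300, 3, np.zeros(300), seed=8)
        res = simple_de(counts, groups)
        assert (res["call"] != "up").all() and (res["call"] != "down").all()

    def test_four_fold_change_power(self):
        called = 0
        for seed in range(20):
            lfc = np.zeros(200)
            lfc[0] = 2.0  # one true 4-fold gene
            counts, groups = simulate_count_matrix(200, 3, lfc,
                                                   dispersion=0.05,
                                                   seed=seed)
            res = simple_de(counts, groups)
            called += res.iloc[0]["call"] == "up"
        assert called >= 19

    def test_infinite_lfc_threshold_no_calls(self):
        lfc = np.full(100, 3.0)
        counts, groups = simulate_count_matrix(100, 3, lfc, seed=9)
        res = simple_de(counts, groups, lfc_min=np.inf)
        assert (res["call"] == "unchanged").all()

    def test_all_zero_gene_excluded(self):
        counts, groups = simulate_count_matrix(50, 3, np.zeros(50), seed=10)
        counts[7] = 0.0
        res = simple_de(counts, groups)
        assert (res.loc[res["gene_id"] == "g7", "call"] == "excluded").all()
        assert len(res) == 50

    def test_bh_adjustment_monotone(self):
        counts, groups = simulate_count_matrix(300, 3,
                                               np.where(np.arange(300) < 30,
                                                        1.5, 0.0), seed=11)
        res = simple_de(counts, groups)
        res = res[res["call"] != "excluded"].sort_values("p_value")
        padj = res["padj"].to_numpy()
        assert (np.diff(padj) >= -1e-12).all()
        assert (res["padj"] >= res["p_value"] - 1e-12).all()

    def test_replicate_requirement(self):
        counts, _ = simulate_count_matrix(10, 1, np.zeros(10), seed=12)
        with pytest.raises(ValueError, match="replicates"):
            simple_de(counts, np.array([0, 1]))
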