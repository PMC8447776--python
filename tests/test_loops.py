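"""Donut-filter loop calling, clustering/merging, compartment and gene links."""

import numpy as np
import pandas as pd
import pytest

from chromhier import (assign_compartment, call_loops, cluster_and_merge,
                       ice_balance, loop_gene_coupling, make_genome,
                       plant_truth, simulate_contacts)
from chromhier.compartments import CompartmentProfile
from chromhier.loops import peak_loci_count, span_histogram


@pytest.fixture(scope="module")
def loop_calls(balanced_10k, tad_genome):
    out = []
    for chrom, bal in balanced_10k.items():
        out.append(call_loops(bal, 10_000, chrom))
    return pd.concat(out, ignore_index=True)


class TestCallLoops:
    def test_null_map_produces_almost_no_calls(self, tad_genome):
        hits = []
        for seed in range(5):
            truth = plant_truth(tad_genome, n_boundaries_per_chrom=0,
                                n_loops=0, seed=seed)
            cmap = simulate_contacts(tad_genome, truth, resolution=10_000,
                                     depth=5e6, comp_strength=1.0,
                                     tad_strength=1.0, loop_strength=1.0,
                                     seed=100 + seed)
            n = 0
            for chrom in tad_genome.names:
                bal = ice_balance(cmap.chrom_dense(chrom))
                n += len(call_loops(bal, 10_000, chrom))
            hits.append(n)
        # BH at fdr 0.1 across ~1e6 null pixels: a stray call is tolerated,
        # a systematic excess is not
        assert np.median(hits) <= 3
        assert max(hits) <= len(tad_genome.names) * 3

    def test_planted_loops_recovered(self, tad_genome, tad_truth,
                                     loop_calls):
        merged = cluster_and_merge(loop_calls)
        found = 0
        anchors = [(c, a1 // 10_000, a2 // 10_000)
                   for c, a1, a2 in tad_truth.loop_anchors]
        for chrom, a1, a2 in anchors:
            sub = merged[merged["chrom"] == chrom]
            hit = ((np.abs(sub["bin1"] - a1) <= 1)
                   & (np.abs(sub["bin2"] - a2) <= 1)).any()
            found += bool(hit)
        assert found / len(anchors) >= 0.8

    def test_span_cap_and_orientation(self, loop_calls):
        merged = cluster_and_merge(loop_calls)
        assert (merged["start1"] < merged["start2"]).all()
        assert (merged["span"] <= 1_000_000).all()
        assert (merged["q_value"].between(0, 1)).all()

    def test_matrix_smaller_than_donut_warns_empty(self):
        from chromhier.contacts import BalancedMatrix
        m = np.full((8, 8), 3.0)
        bal = BalancedMatrix(m, np.ones(8), np.zeros(8, dtype=bool))
        with pytest.warns(UserWarning, match="donut"):
            out = call_loops(bal, 10_000, "tiny")
        assert len(out) == 0

    def test_calls_invariant_to_consistent_rescaling(self, balanced_10k):
        from chromhier.contacts import BalancedMatrix
        chrom, bal = next(iter(balanced_10k.items()))
        a = call_loops(bal, 10_000, chrom)
        scaled = BalancedMatrix(bal.matrix * 10.0, bal.bias, bal.mask)
        readj = BalancedMatrix(scaled.matrix / 10.0, bal.bias, bal.mask)
        b = call_loops(readj, 10_000, chrom)
        pd.testing.assert_frame_equal(a, b)


class TestClusterAndMerge:
    def _cand(self, rows, res=10_000):
        df = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "q_value"])
        df["p_value"] = df["q_value"] / 2
        df["resolution"] = res
        df["start1"] = df["bin1"] * res
        df["end1"] = (df["bin1"] + 1) * res
        df["start2"] = df["bin2"] * res
        df["end2"] = (df["bin2"] + 1) * res
        df["observed"] = 10.0
        return df

    def test_adjacent_pixels_form_one_peak(self):
        c = self._cand([("chr1", 10, 50, 0.01), ("chr1", 11, 50, 0.02)])
        out = cluster_and_merge(c)
        assert len(out) == 1
        assert out.iloc[0]["bin1"] == 10  # most significant representative
        assert peak_loci_count(out) == 2

    def test_isolated_pixel_one_peak_two_loci(self):
        out = cluster_and_merge(self._cand([("chr1", 10, 50, 0.01)]))
        assert len(out) == 1 and peak_loci_count(out) == 2

    def test_distant_pixels_stay_separate(self):
        c = self._cand([("chr1", 10, 50, 0.01), ("chr1", 20, 50, 0.02)])
        assert len(cluster_and_merge(c)) == 2

    def test_fine_resolution_takes_precedence(self):
        fine = self._cand([("chr1", 10, 50, 0.01)], res=10_000)
        coarse = self._cand([("chr1", 4, 20, 0.02)], res=25_000)
        out = cluster_and_merge(pd.concat([fine, coarse], ignore_index=True))
        # coarse anchors [100k,125k) x [500k,525k) overlap the fine call
        assert len(out) == 1
        assert out.iloc[0]["resolution"] == 10_000

    def test_non_overlapping_coarse_call_kept(self):
        fine = self._cand([("chr1", 10, 50, 0.01)], res=10_000)
        coarse = self._cand([("chr1", 40, 70, 0.02)], res=25_000)
        out = cluster_and_merge(pd.concat([fine, coarse], ignore_index=True))
        assert len(out) == 2
        assert set(out["resolution"]) == {10_000, 25_000}

    def test_peak_count_bounds(self, loop_calls):
        merged = cluster_and_merge(loop_calls)
        assert len(merged) <= len(loop_calls)
        assert peak_loci_count(merged) <= 2 * len(merged)


class TestAssignCompartment:
    def _profile(self, genome, labels_fn):
        labs, evs, gds = {}, {}, {}
        for c in genome.names:
            n = genome.n_bins(c, 100_000)
            labs[c] = np.array([labels_fn(c, i) for i in range(n)],
                               dtype=object)
            evs[c] = np.where(labs[c] == "A", 1.0, -1.0)
            gds[c] = np.zeros(n)
        return CompartmentProfile(genome, 100_000, evs, labs, gds)

    def test_both_anchors_same_label(self, tad_genome):
        prof = self._profile(tad_genome, lambda c, i: "A")
        loops = pd.DataFrame({
            "chrom": [tad_genome.names[0]], "start1": [1_000_000],
            "end1": [1_010_000], "start2": [1_500_000], "end2": [1_510_000]})
        out = assign_compartment(loops, prof)
        assert out.iloc[0]["compartment"] == "A"

    def test_mixed_anchors(self, tad_genome):
        prof = self._profile(tad_genome,
                             lambda c, i: "A" if i < 12 else "B")
        loops = pd.DataFrame({
            "chrom": [tad_genome.names[0]], "start1": [1_000_000],
            "end1": [1_010_000], "start2": [1_500_000], "end2": [1_510_000]})
        out = assign_compartment(loops, prof)
        assert out.iloc[0]["compartment"] == "mixed"

    def test_masked_anchor_flagged(self, tad_genome):
        prof = self._profile(tad_genome,
                             lambda c, i: "." if i == 10 else "A")
        loops = pd.DataFrame({
            "chrom": [tad_genome.names[0]], "start1": [1_000_000],
            "end1": [1_010_000], "start2": [1_500_000], "end2": [1_510_000]})
        out = assign_compartment(loops, prof)
        assert out.iloc[0]["compartment"] == "mixed"
        assert out.iloc[0]["anchor_masked"]

    def test_planted_a_fraction_recovered(self, tad_genome, tad_truth,
                                          loop_calls):
        prof = self._profile(
            tad_genome,
            lambda c, i: tad_truth.bin_labels(tad_genome, c, 100_000)[i])
        merged = cluster_and_merge(loop_calls)
        # score only peaks that match a planted anchor pair
        matched = []
        for row in merged.itertuples(index=False):
            for c, a1, a2 in tad_truth.loop_anchors:
                if (c == row.chrom and abs(row.bin1 - a1 // 10_000) <= 1
                        and abs(row.bin2 - a2 // 10_000) <= 1):
                    matched.append(row)
                    break
        out = assign_compartment(pd.DataFrame(matched), prof)
        frac_a = (out["compartment"] == "A").mean()
        # generator plants both anchors in A with p_a = 0.7
        assert abs(frac_a - 0.7) < 0.15


class TestLoopGeneCoupling:
    def _toy(self):
        genes = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4"],
            "chrom": ["chr1"] * 4,
            "start": [100_000, 300_000, 500_000, 700_000],
            "end": [105_000, 305_000, 505_000, 705_000],
            "strand": ["+"] * 4,
            "tss": [100_000, 300_000, 500_000, 700_000],
        })
        expr = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4"],
            "condition": ["cond1"] * 4,
            "count": [100, 10, 200, 5],
            "fpkm": [50.0, 2.0, 80.0, 1.0],
        })
        return genes, expr

    def test_no_loops_not_applicable(self):
        genes, expr = self._toy()
        loops = pd.DataFrame(columns=["chrom", "start1", "end1", "start2",
                                      "end2"])
        r = loop_gene_coupling(loops, genes, expr, "cond1")
        assert r["n_coupled"] == 0 and r["frac_high_coupled"] is None

    def test_coupled_high_fraction(self):
        genes, expr = self._toy()
        loops = pd.DataFrame({
            "chrom": ["chr1"], "start1": [95_000], "end1": [105_000],
            "start2": [495_000], "end2": [505_000]})
        r = loop_gene_coupling(loops, genes, expr, "cond1", fpkm_high=20)
        assert r["n_coupled"] == 2 and r["n_uncoupled"] == 2
        assert r["frac_high_coupled"] == 1.0
        assert r["frac_high_uncoupled"] == 0.0

    def test_zero_threshold_saturates(self):
        genes, expr = self._toy()
        loops = pd.DataFrame({
            "chrom": ["chr1"], "start1": [95_000], "end1": [105_000],
            "start2": [495_000], "end2": [505_000]})
        r = loop_gene_coupling(loops, genes, expr, "cond1", fpkm_high=0)
        assert r["frac_high_coupled"] == 1.0
        assert r["frac_high_uncoupled"] == 1.0

    def test_boosted_anchor_genes_detected(self, tad_genome, tad_truth):
        # expression boosted +2 log2 at genes whose TSS sits in an anchor
        rng = np.random.default_rng(5)
        genes_rows, expr_rows = [], []
        anchors = {}
        for c, a1, a2 in tad_truth.loop_anchors:
            anchors.setdefault(c, []).extend([a1, a2])
        gid = 0
        for c in tad_genome.names:
            # genes at anchors
            for a in anchors.get(c, []):
                genes_rows.append((f"g{gid}", c, a + 2000, a + 6000, "+",
                                   a + 2000))
                gid += 1
            # background genes
            for _ in range(80):
                tss = int(rng.integers(0, tad_genome.length_of(c) - 10_000))
                genes_rows.append((f"g{gid}", c, tss, tss + 4000, "+", tss))
                gid += 1
        genes = pd.DataFrame(genes_rows, columns=["gene_id", "chrom",
                                                  "start", "end", "strand",
                                                  "tss"])
        at_anchor = genes["tss"].index < 0  # placeholder
        fpkm = 10.0 * 2 ** rng.normal(0, 1, len(genes))
        is_anchor_gene = np.array([
            any(abs(row.tss - a) < 8000 for a in anchors.get(row.chrom, []))
            for row in genes.itertuples(index=False)])
        fpkm[is_anchor_gene] *= 4.0
        expr = pd.DataFrame({"gene_id": genes["gene_id"],
                             "condition": "cond1",
                             "count": (fpkm * 20).astype(int),
                             "fpkm": fpkm})
        loops = pd.DataFrame([
            {"chrom": c, "start1": a1, "end1": a1 + 10_000,
             "start2": a2, "end2": a2 + 10_000}
            for c, a1, a2 in tad_truth.loop_anchors])
        r = loop_gene_coupling(loops, genes, expr, "cond1", fpkm_high=20)
        assert r["frac_high_coupled"] > r["frac_high_uncoupled"]
        assert r["p_two_proportion"] < 0.01


def test_span_histogram_bins(loop_calls):
    merged = cluster_and_merge(loop_calls)
    h = span_histogram(merged, 50_000)
    assert h.sum() == len(merged)
    assert all(k % 50_000 == 0 for k in h.index)
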