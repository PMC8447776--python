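"""End-to-end orchestration: simulate -> normalize -> compartments ->
switches -> TADs -> loops -> integrate, with a hashed output manifest.

Each stage reads the text artifacts of the previous one, so a run is fully
reproducible from its config and seed: the manifest records a SHA-256 per
output, and an identical config + seed yields identical hashes. The global
seed fans out to per-stage child seeds via ``numpy.random.SeedSequence``
in a fixed order (genome, truth, contacts x2, expression, peaks, coupled
peaks, enrichment shuffles).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as chio
from . import synth
from .compartments import call_compartments, switch_classify, switch_expression_test
from .config import RunConfig
from .contacts import (ContactMap, coarsen, ice_balance, interaction_summary,
                       normalize_library, read_contacts, write_contacts)
from .domains import (call_boundaries, count_features, derive_tads,
                      insulation_score, pad_boundaries)
from .genome import GenomeLayout
from .integrate import (mark_expression_correlation, peak_feature_enrichment,
                        promoter_stats, simple_de)
from .loops import (assign_compartment, call_loops, cluster_and_merge,
                    loop_gene_coupling, peak_loci_count)
from .synth import PeakSet

log = logging.getLogger("chromhier")


def _child_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _balance_per_chrom(cmap: ContactMap) -> dict:
    out = {}
    for chrom in cmap.genome.names:
        out[chrom] = ice_balance(cmap.chrom_dense(chrom))
    return out


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline; returns (and writes) the output manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = _child_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    files: list[Path] = []

    def stage_done(name: str, outputs: list[Path], **extra):
        log.info("stage=%s elapsed=%.1fs outputs=%d", name,
                 time.time() - t0, len(outputs))
        manifest["stages"][name] = {"outputs": [str(p) for p in outputs],
                                    **extra}
        files.extend(outputs)

    res = config.resolutions
    thr = config.thresholds

    # ---- simulate ---------------------------------------------------------
    if config.synthetic is not None:
        sc = config.synthetic
        genome = synth.make_genome(sc.n_mac, sc.n_mic, sc.mac_range,
                                   sc.mic_range, seed=seeds[0],
                                   mac_threshold=thr.mac)
        truth = synth.plant_truth(
            genome, sc.comp_block_bp, sc.n_boundaries_per_chrom, sc.n_loops,
            sc.max_loop_span, seed=seeds[1], switch_frac=sc.switch_frac,
            p_a=sc.p_a, min_loop_span=sc.min_loop_span,
            insulation_window_bp=thr.insulation_window)
        maps = {}
        for cond, s in ((1, seeds[2]), (2, seeds[3])):
            maps[cond] = synth.simulate_contacts(
                genome, truth, resolution=res.tad, depth=sc.depth,
                decay_alpha=sc.decay_alpha, comp_strength=sc.comp_strength,
                tad_strength=sc.tad_strength, loop_strength=sc.loop_strength,
                trans_level=sc.trans_level, mic_trans_boost=sc.mic_trans_boost,
                seed=s, condition=cond)
        genes, expression = synth.simulate_annotation_and_expression(
            genome, truth, sc.genes_per_mb_a, sc.genes_per_mb_b,
            sc.lfc_switch_effect, sc.dispersion, seed=seeds[4])
        h3ac, h3k27 = synth.simulate_peaks(truth, genome, sc.a_bias,
                                           sc.peak_len_mean, sc.n_peaks,
                                           seed=seeds[5])
        outs = []
        p = outdir / "chromsizes.tsv"; genome.to_chromsizes_tsv(p); outs.append(p)
        for cond, m in maps.items():
            p = outdir / f"contacts_cond{cond}.tsv"; write_contacts(m, p); outs.append(p)
        p = outdir / "genes.bed"; synth.write_genes_bed(genes, p); outs.append(p)
        p = outdir / "expression.tsv"; synth.write_expression_tsv(expression, p); outs.append(p)
        p = outdir / "h3ac.bed"; h3ac.to_bed(p); outs.append(p)
        p = outdir / "h3k27me3.bed"; h3k27.to_bed(p); outs.append(p)
        p = outdir / "truth.json"; truth.to_json(p); outs.append(p)
        stage_done("simulate", outs, n_chrom=len(genome))
    else:
        ip = config.inputs
        if not (ip.contacts and ip.chromsizes and ip.genes and ip.expression):
            raise ValueError("non-synthetic run requires contacts, chromsizes, "
                             "genes and expression inputs")
        genome = GenomeLayout.from_chromsizes_tsv(ip.chromsizes, thr.mac)
        maps = {1: read_contacts(ip.contacts, ip.chromsizes, res.tad, thr.mac)}
        if ip.contacts2:
            maps[2] = read_contacts(ip.contacts2, ip.chromsizes, res.tad, thr.mac)
        genes = synth.read_genes_bed(ip.genes)
        expression = synth.read_expression_tsv(ip.expression)
        h3ac = (PeakSet.from_bed(ip.h3ac_peaks, "H3ac", "cond1")
                if ip.h3ac_peaks else None)
        h3k27 = (PeakSet.from_bed(ip.h3k27me3_peaks, "H3K27me3", "cond1")
                 if ip.h3k27me3_peaks else None)
        truth = None
        stage_done("load", [])

    # ---- normalize --------------------------------------------------------
    norm = {c: normalize_library(m, thr.target_total) for c, m in maps.items()}
    summary = interaction_summary(norm[1]) if len(genome) >= 2 else None
    p = outdir / "interaction_summary.json"
    with open(p, "w") as fh:
        json.dump(summary if summary is None else
                  {k: v for k, v in summary.items() if k != "per_pair"},
                  fh, indent=1)
    stage_done("normalize", [p],
               total_after=norm[1].total())

    # ---- compartments -----------------------------------------------------
    factor = res.compartment // res.tad
    profiles = {}
    comp_outs = []
    for cond, m in maps.items():
        bal = _balance_per_chrom(coarsen(m, factor))
        profiles[cond] = call_compartments(bal, genes, genome, res.compartment)
        p1 = outdir / f"eigenvector_cond{cond}.bedgraph"
        p2 = outdir / f"compartments_cond{cond}.bed"
        chio.write_bedgraph_profile(profiles[cond], p1)
        chio.write_compartment_bed(profiles[cond], p2)
        comp_outs += [p1, p2]
    stage_done("compartments", comp_outs)

    # ---- switches ---------------------------------------------------------
    switch_outs = []
    if len(profiles) == 2:
        table = switch_classify(profiles[1], profiles[2])
        lfc = synth.expression_lfc(expression)
        test = switch_expression_test(table, lfc, genes)
        p1 = outdir / "switches.bed"; chio.write_switch_bed(table, p1)
        p2 = outdir / "switch_expression.tsv"
        test.to_csv(p2, sep="\t", index=False)
        p3 = outdir / "switch_fractions.json"
        with open(p3, "w") as fh:
            json.dump({"genome": table.fractions(),
                       "opposite": table.opposite_fraction()}, fh, indent=1)
        switch_outs = [p1, p2, p3]
    stage_done("switches", switch_outs)

    # ---- TADs -------------------------------------------------------------
    bal10 = _balance_per_chrom(maps[1])
    tracks, all_raw = {}, []
    for chrom, bal in bal10.items():
        tr = insulation_score(bal, thr.insulation_window, res.tad, chrom)
        tracks[chrom] = tr
        all_raw.append(call_boundaries(tr, thr.delta_window,
                                       thr.min_boundary_strength))
    raw = pd.concat(all_raw, ignore_index=True)
    boundaries = pad_boundaries(raw, genome, res.tad, thr.pad)
    tads = derive_tads(boundaries, genome, res.tad)
    feat_stats = count_features(tads, boundaries, genes)
    p1 = outdir / "insulation.bedgraph"; chio.write_insulation_bedgraph(tracks, p1)
    p2 = outdir / "boundaries.bed"; chio.write_boundaries_bed(boundaries, p2)
    p3 = outdir / "tads.bed"; chio.write_tads_bed(tads, p3)
    p4 = outdir / "tad_feature_counts.json"
    with open(p4, "w") as fh:
        json.dump(feat_stats, fh, indent=1)
    stage_done("tads", [p1, p2, p3, p4], n_boundaries=len(boundaries),
               n_tads=len(tads))

    # ---- loops ------------------------------------------------------------
    cands = []
    for loop_res in res.loop:
        f = loop_res // res.tad
        m = maps[1] if f == 1 else coarsen(maps[1], f)
        balr = _balance_per_chrom(m) if f != 1 else bal10
        for chrom, bal in balr.items():
            cands.append(call_loops(bal, loop_res, chrom,
                                    max_dist=thr.max_loop_dist,
                                    fdr=thr.fdr, min_fold=thr.min_fold))
    cands = pd.concat(cands, ignore_index=True)
    loopset = cluster_and_merge(cands)
    loopset = assign_compartment(loopset, profiles[1])
    coupling = loop_gene_coupling(loopset, genes, expression, "cond1",
                                  thr.fpkm_high)
    p1 = outdir / "loops.bedpe"; chio.write_loops_bedpe(loopset, p1)
    p2 = outdir / "loop_summary.json"
    with open(p2, "w") as fh:
        json.dump({
            "n_peaks": int(len(loopset)),
            "n_peak_loci": peak_loci_count(loopset),
            "by_compartment": loopset["compartment"].value_counts().to_dict()
            if len(loopset) else {},
            "max_span_bp": int(loopset["span"].max()) if len(loopset) else None,
            "coupling": coupling,
        }, fh, indent=1)
    stage_done("loops", [p1, p2], n_peaks=int(len(loopset)))

    # ---- integrate --------------------------------------------------------
    int_outs = []
    if h3ac is not None and h3k27 is not None:
        prof = profiles[1]
        a_bins, b_bins = [], []
        for chrom, labels in prof.labels.items():
            starts = genome.bin_starts(chrom, res.compartment)
            length = genome.length_of(chrom)
            for s, lab in zip(starts, labels):
                iv = (chrom, int(s), min(int(s) + res.compartment, length))
                if lab == "A":
                    a_bins.append(iv)
                elif lab == "B":
                    b_bins.append(iv)
        a_df = pd.DataFrame(a_bins, columns=["chrom", "start", "end"])
        b_df = pd.DataFrame(b_bins, columns=["chrom", "start", "end"])
        results = {}
        for peaks, feats, fname in ((h3ac, a_df, "A_compartment"),
                                    (h3k27, b_df, "B_compartment"),
                                    (h3ac, boundaries, "boundaries")):
            r = peak_feature_enrichment(peaks, feats, genome, seed=seeds[6],
                                        feature_name=fname)
            results[f"{peaks.mark}_in_{fname}"] = {
                "n_peaks": r.n_peaks, "n_in": r.n_in_feature,
                "odds_ratio": r.odds_ratio, "fisher_p": r.fisher_p,
                "perm_z": r.perm_z, "applicable": r.applicable,
            }
        results["promoter"] = {pk.mark: promoter_stats(pk, genes)
                               for pk in (h3ac, h3k27)}
        if config.synthetic is not None:
            r_ac, r_k27 = config.synthetic.mark_expression_r
            cp_ac = synth.simulate_coupled_peaks(genes, expression, "cond1",
                                                 "H3ac", r_ac, seed=seeds[7])
            cp_k27 = synth.simulate_coupled_peaks(genes, expression, "cond1",
                                                  "H3K27me3", r_k27,
                                                  seed=seeds[7] + 1)
            results["mark_expression_r"] = {
                pk.mark: mark_expression_correlation(pk, genes, expression,
                                                     "cond1")
                for pk in (cp_ac, cp_k27)
            }
        # stand-in DE on NB replicates around the two condition means
        wide = expression.pivot(index="gene_id", columns="condition",
                                values="count")
        rng = np.random.default_rng(seeds[7] + 2)
        reps = []
        for cond in ("cond1", "cond2"):
            mu = np.maximum(wide[cond].to_numpy(), 0.1)
            r_disp = 10.0
            for _ in range(3):
                reps.append(rng.negative_binomial(
                    r_disp, r_disp / (r_disp + mu)))
        counts = np.column_stack(reps).astype(float)
        de = simple_de(counts, np.array([0, 0, 0, 1, 1, 1]),
                       thr.lfc, thr.padj, list(wide.index))
        p_de = outdir / "differential_expression.tsv"
        de.to_csv(p_de, sep="\t", index=False)
        results["de_calls"] = de["call"].value_counts().to_dict()
        p_int = outdir / "integration.json"
        with open(p_int, "w") as fh:
            json.dump(results, fh, indent=1)
        int_outs = [p_int, p_de]
    stage_done("integrate", int_outs)

    manifest["files"] = {str(p): _sha256(p) for p in files}
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
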