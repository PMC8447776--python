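"""Synthetic genomes, contact maps, annotations, expression and peaks.

Every downstream caller in this package (compartments, domains, loops,
integration) is validated against data with *known planted structure*. The
generator emulates a snake-like karyotype — a few macro-chromosomes (> 50 Mb)
and a tail of micro-chromosomes — and plants the three structural layers the
callers detect:

* alternating A/B compartment blocks (checkerboard contact enrichment),
* TAD boundaries (block-diagonal contact enrichment between them),
* focal loops within 1 Mb, preferentially anchored in A blocks.

Contacts follow a multiplicative Poisson model: the expected intensity of an
intra-chromosomal bin pair at bin distance d is proportional to
``(1 + d) ** -decay_alpha``, multiplied by ``comp_strength`` when the bins
share a compartment label, ``tad_strength`` when they lie between the same
adjacent boundaries, and ``loop_strength`` in the one-bin neighborhood of a
planted anchor pair. Inter-chromosomal pairs get a flat ``trans_level``
fraction of the mean intra intensity, boosted among micro-chromosome pairs
(micro-chromosomes cluster spatially). Counts are Poisson with these means
and the genome-wide total is calibrated to ``depth`` read pairs.

Expression is negative-binomial with a compartment-switch fold-change effect;
histone peaks (H3ac active / H3K27me3 repressive) are placed with a tunable
compartment bias, and `simulate_coupled_peaks` ties per-gene peak coverage to
expression at a target Pearson correlation.

A single global seed fans out to per-component child seeds through
``numpy.random.SeedSequence.spawn`` in a fixed order (genome, truth,
contacts, expression, peaks, coupled peaks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import ContactMap
from .genome import GenomeLayout

__all__ = [
    "SyntheticTruth",
    "PeakSet",
    "make_genome",
    "plant_truth",
    "simulate_contacts",
    "simulate_annotation_and_expression",
    "simulate_peaks",
    "simulate_coupled_peaks",
    "simulate_count_matrix",
    "expression_lfc",
]

COMPARTMENT_BIN_BP = 100_000
TAD_BIN_BP = 10_000


@dataclass
class SyntheticTruth:
    """Planted structure: compartment blocks, boundaries, loop anchors.

    ``compartment_blocks`` maps chromosome -> list of (start, end, label)
    tiling the chromosome; ``compartment_blocks2`` is the second-condition
    labelling in which a fraction of blocks has flipped label (the planted
    compartment switches). ``boundary_positions`` are sorted interior bp
    positions; ``loop_anchors`` are (chrom, anchor1_bp, anchor2_bp) with
    anchor spans capped at the planting maximum.
    """

    compartment_blocks: dict[str, list[tuple[int, int, str]]]
    compartment_blocks2: dict[str, list[tuple[int, int, str]]]
    boundary_positions: dict[str, list[int]]
    loop_anchors: list[tuple[str, int, int]]
    params: dict = field(default_factory=dict)

    def blocks(self, condition: int = 1) -> dict[str, list[tuple[int, int, str]]]:
        if condition == 1:
            return self.compartment_blocks
        if condition == 2:
            return self.compartment_blocks2
        raise ValueError(f"condition must be 1 or 2, got {condition}")

    def bin_labels(self, genome: GenomeLayout, chrom: str, resolution: int,
                   condition: int = 1) -> np.ndarray:
        """Planted A/B label of each bin of ``chrom``, by bin midpoint."""
        blocks = self.blocks(condition)[chrom]
        edges = np.array([b[0] for b in blocks] + [blocks[-1][1]])
        labels = np.array([b[2] for b in blocks])
        mids = genome.bin_starts(chrom, resolution) + resolution // 2
        mids = np.minimum(mids, genome.length_of(chrom) - 1)
        idx = np.searchsorted(edges, mids, side="right") - 1
        return labels[np.clip(idx, 0, len(labels) - 1)]

    def domain_ids(self, genome: GenomeLayout, chrom: str, resolution: int) -> np.ndarray:
        """Planted domain index of each bin (0..n_boundaries)."""
        bounds = np.asarray(self.boundary_positions[chrom])
        mids = genome.bin_starts(chrom, resolution) + resolution // 2
        return np.searchsorted(bounds, mids)

    def label_at(self, chrom: str, pos: int, condition: int = 1) -> str:
        for start, end, lab in self.blocks(condition)[chrom]:
            if start <= pos < end:
                return lab
        raise ValueError(f"position {pos} outside {chrom}")

    # -- JSON round trip ---------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "compartment_blocks": self.compartment_blocks,
            "compartment_blocks2": self.compartment_blocks2,
            "boundary_positions": self.boundary_positions,
            "loop_anchors": self.loop_anchors,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            obj = json.load(fh)
        fix = lambda bl: {c: [tuple(b) for b in v] for c, v in bl.items()}
        return cls(
            compartment_blocks=fix(obj["compartment_blocks"]),
            compartment_blocks2=fix(obj["compartment_blocks2"]),
            boundary_positions={c: list(map(int, v))
                                for c, v in obj["boundary_positions"].items()},
            loop_anchors=[tuple(a) for a in obj["loop_anchors"]],
            params=obj.get("params", {}),
        )


@dataclass
class PeakSet:
    """Peak intervals for one histone mark in one condition."""

    mark: str
    condition: str
    intervals: pd.DataFrame  # columns: chrom, start, end, signal

    def to_bed(self, path) -> None:
        df = self.intervals
        with open(path, "w") as fh:
            for i, row in enumerate(df.itertuples(index=False)):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{self.mark}_{i}\t{row.signal:.2f}\t.\n")

    @classmethod
    def from_bed(cls, path, mark: str, condition: str) -> "PeakSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or line.startswith(("#", "track")):
                    continue
                signal = float(parts[4]) if len(parts) > 4 else 1.0
                rows.append((parts[0], int(parts[1]), int(parts[2]), signal))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])
        return cls(mark, condition, df)


# ---------------------------------------------------------------------------
# genome and truth
# ---------------------------------------------------------------------------

def make_genome(n_mac: int, n_mic: int,
                mac_range: tuple[int, int] | None = (60_000_000, 160_000_000),
                mic_range: tuple[int, int] | None = (10_000_000, 45_000_000),
                seed: int = 0,
                mac_threshold: int = 50_000_000) -> GenomeLayout:
    """Draw a karyotype with ``n_mac`` macro- and ``n_mic`` micro-chromosomes.

    Lengths are uniform over the stated ranges (which must sit strictly
    above / below the 50 Mb threshold); chromosomes are named chr1..chrN in
    decreasing length order.
    """
    if n_mac < 0 or n_mic < 0:
        raise ValueError("chromosome counts must be non-negative")
    if n_mac > 0 and (mac_range is None or mac_range[0] <= mac_threshold):
        raise ValueError("mac_range must lie strictly above the MAC threshold")
    if n_mic > 0 and (mic_range is None or mic_range[1] >= mac_threshold):
        raise ValueError("mic_range must lie strictly below the MAC threshold")
    rng = np.random.default_rng(seed)
    lengths: list[int] = []
    if n_mac:
        lengths += list(rng.integers(mac_range[0], mac_range[1] + 1, n_mac))
    if n_mic:
        lengths += list(rng.integers(mic_range[0], mic_range[1] + 1, n_mic))
    lengths = sorted((int(l) for l in lengths), reverse=True)
    names = tuple(f"chr{i + 1}" for i in range(len(lengths)))
    return GenomeLayout(names, tuple(lengths), mac_threshold)


def plant_truth(genome: GenomeLayout, comp_block_bp: int = 1_000_000,
                n_boundaries_per_chrom: int = 8, n_loops: int = 50,
                max_loop_span: int = 1_000_000, seed: int = 0,
                switch_frac: float = 0.2, p_a: float = 0.7,
                min_loop_span: int = 100_000,
                insulation_window_bp: int = 100_000) -> SyntheticTruth:
    """Plant compartment blocks, TAD boundaries and loop anchors.

    Compartment blocks alternate A/B at ~``comp_block_bp``; a ``switch_frac``
    fraction of blocks flips label in the second condition. Boundaries are
    kept at least two insulation windows from chromosome ends and snapped to
    the 10 kb TAD grid. Loops land with both anchors inside first-condition A
    blocks with probability ``p_a`` (euchromatic-loop predominance) and spans
    uniform in [``min_loop_span``, ``max_loop_span``].
    """
    if comp_block_bp % COMPARTMENT_BIN_BP != 0:
        raise ValueError("comp_block_bp must be a multiple of the 100 kb compartment bin")
    if max_loop_span > 1_000_000:
        raise ValueError("max_loop_span exceeds the 1 Mb loop-distance cap")
    rng = np.random.default_rng(seed)

    blocks1: dict[str, list[tuple[int, int, str]]] = {}
    blocks2: dict[str, list[tuple[int, int, str]]] = {}
    boundaries: dict[str, list[int]] = {}
    for name, length in zip(genome.names, genome.lengths):
        # alternating A/B tiling; final partial block keeps the alternation
        starts = list(range(0, length, comp_block_bp))
        bl = [(s, min(s + comp_block_bp, length), "A" if k % 2 == 0 else "B")
              for k, s in enumerate(starts)]
        blocks1[name] = bl
        flip = rng.random(len(bl)) < switch_frac
        blocks2[name] = [
            (s, e, ("B" if lab == "A" else "A") if f else lab)
            for (s, e, lab), f in zip(bl, flip)
        ]
        # boundaries: ≥ 2 insulation windows from ends, ≥ 300 kb apart
        margin = 2 * insulation_window_bp
        min_gap = 300_000
        lo = -(-margin // TAD_BIN_BP)
        hi = (length - margin) // TAD_BIN_BP
        span_bins = hi - lo
        need = n_boundaries_per_chrom * (min_gap // TAD_BIN_BP)
        if n_boundaries_per_chrom > 0 and span_bins < need:
            raise ValueError(
                f"chromosome {name} too short for {n_boundaries_per_chrom} boundaries"
            )
        if n_boundaries_per_chrom > 0:
            # draw gaps ≥ min_gap summing ≤ span via a stick-breaking draw
            slack = span_bins - need
            cuts = np.sort(rng.integers(0, slack + 1, n_boundaries_per_chrom))
            pos = lo + cuts + (np.arange(1, n_boundaries_per_chrom + 1)
                               * (min_gap // TAD_BIN_BP))
            boundaries[name] = [int(p) * TAD_BIN_BP for p in pos]
        else:
            boundaries[name] = []

    # loops: chromosome weighted by length, anchors snapped to 10 kb grid
    anchors: list[tuple[str, int, int]] = []
    lens = np.array(genome.lengths, dtype=float)
    weights = lens / lens.sum()
    for _ in range(n_loops):
        # decide the compartment target first, then draw anchors until it is
        # met — a joint rejection would bias the A fraction below p_a
        want_a = rng.random() < p_a
        for guard in range(10_000):
            ci = rng.choice(len(genome), p=weights)
            name, length = genome.names[ci], genome.lengths[ci]
            if length < max_loop_span + 2 * min_loop_span:
                continue
            span = int(rng.integers(min_loop_span // TAD_BIN_BP,
                                    max_loop_span // TAD_BIN_BP + 1)) * TAD_BIN_BP
            a1 = int(rng.integers(1, (length - span) // TAD_BIN_BP)) * TAD_BIN_BP
            a2 = a1 + span
            in_a = (_label_at(blocks1[name], a1) == "A"
                    and _label_at(blocks1[name], a2) == "A")
            if want_a == in_a:
                anchors.append((name, a1, a2))
                break
        else:
            raise ValueError("could not place requested loops; "
                             "chromosomes too short")

    return SyntheticTruth(
        compartment_blocks=blocks1,
        compartment_blocks2=blocks2,
        boundary_positions=boundaries,
        loop_anchors=anchors,
        params={
            "comp_block_bp": comp_block_bp,
            "n_boundaries_per_chrom": n_boundaries_per_chrom,
            "n_loops": n_loops,
            "max_loop_span": max_loop_span,
            "min_loop_span": min_loop_span,
            "switch_frac": switch_frac,
            "p_a": p_a,
            "seed": seed,
        },
    )


def _label_at(blocks: list[tuple[int, int, str]], pos: int) -> str:
    for s, e, lab in blocks:
        if s <= pos < e:
            return lab
    return blocks[-1][2]


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _intra_expected(genome: GenomeLayout, truth: SyntheticTruth, chrom: str,
                    resolution: int, decay_alpha: float, comp_strength: float,
                    tad_strength: float, loop_strength: float,
                    condition: int) -> np.ndarray:
    n = genome.n_bins(chrom, resolution)
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    exp = (1.0 + d) ** (-decay_alpha)
    if comp_strength != 1.0:
        labels = truth.bin_labels(genome, chrom, resolution, condition)
        same = np.equal.outer(labels, labels)
        exp = np.where(same, exp * comp_strength, exp)
    if tad_strength != 1.0:
        dom = truth.domain_ids(genome, chrom, resolution)
        same = np.equal.outer(dom, dom)
        exp = np.where(same, exp * tad_strength, exp)
    if loop_strength != 1.0:
        for cname, a1, a2 in truth.loop_anchors:
            if cname != chrom:
                continue
            i0, j0 = a1 // resolution, a2 // resolution
            lo_i, hi_i = max(i0 - 1, 0), min(i0 + 2, n)
            lo_j, hi_j = max(j0 - 1, 0), min(j0 + 2, n)
            exp[lo_i:hi_i, lo_j:hi_j] *= loop_strength
            exp[lo_j:hi_j, lo_i:hi_i] *= loop_strength
    return exp


def simulate_contacts(genome: GenomeLayout, truth: SyntheticTruth,
                      resolution: int = 10_000, depth: float = 1e7,
                      decay_alpha: float = 1.0, comp_strength: float = 2.5,
                      tad_strength: float = 2.0, loop_strength: float = 8.0,
                      trans_level: float = 0.01, mic_trans_boost: float = 2.0,
                      seed: int = 0, condition: int = 1) -> ContactMap:
    """Sample a Poisson contact map with the planted structure.

    See the module docstring for the expected-intensity model. The returned
    map is upper-triangular sparse over the genome-wide bin space and its
    total (off-diagonal twice, diagonal once) is Poisson around ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    res = resolution

    intra = {
        name: _intra_expected(genome, truth, name, res, decay_alpha,
                              comp_strength, tad_strength, loop_strength,
                              condition)
        for name in genome.names
    }
    intra_mean = float(np.mean([m.mean() for m in intra.values()]))
    trans_mean = trans_level * intra_mean

    offs = genome.bin_offsets(res)
    nb = genome.bin_counts(res)

    # expected genome-wide total with current (unscaled) intensities
    total_exp = 0.0
    for name, m in intra.items():
        total_exp += 2 * np.triu(m, 1).sum() + np.trace(m)
    for a in range(len(genome)):
        for b in range(a + 1, len(genome)):
            mu = trans_mean
            if not genome.is_mac(genome.names[a]) and not genome.is_mac(genome.names[b]):
                mu *= mic_trans_boost
            total_exp += 2 * mu * nb[a] * nb[b]
    if total_exp <= 0:
        raise ValueError("degenerate expected model")
    scale = depth / total_exp

    rows, cols, vals = [], [], []
    for ci, name in enumerate(genome.names):
        mu = np.triu(intra[name] * scale)
        counts = rng.poisson(mu)
        r, c = np.nonzero(counts)
        rows.append(r + offs[ci])
        cols.append(c + offs[ci])
        vals.append(counts[r, c])
    if trans_mean > 0:
        for a in range(len(genome)):
            for b in range(a + 1, len(genome)):
                mu = trans_mean * scale
                if not genome.is_mac(genome.names[a]) and not genome.is_mac(genome.names[b]):
                    mu *= mic_trans_boost
                counts = rng.poisson(mu, size=(int(nb[a]), int(nb[b])))
                r, c = np.nonzero(counts)
                rows.append(r + offs[a])
                cols.append(c + offs[b])
                vals.append(counts[r, c])
    n = genome.total_bins(res)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals).astype(float)
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return ContactMap(genome, res, m)


# ---------------------------------------------------------------------------
# annotation and expression
# ---------------------------------------------------------------------------

def simulate_annotation_and_expression(
        genome: GenomeLayout, truth: SyntheticTruth,
        genes_per_mb_a: float = 8.0, genes_per_mb_b: float = 3.0,
        lfc_switch_effect: float = 1.5, dispersion: float = 0.1,
        seed: int = 0, base_mean: float = 200.0,
        gene_len_range: tuple[int, int] = (2_000, 5_000),
        library_size: float = 5e6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place genes with compartment-biased density and simulate expression.

    Genes land Poisson along each chromosome with density ``genes_per_mb_a``
    in A blocks and ``genes_per_mb_b`` in B blocks (A is gene-dense). Two
    conditions are generated; a gene whose block flips B->A between
    conditions gets a mean log2 fold change of ``+lfc_switch_effect``, A->B
    gets ``-lfc_switch_effect``, stable genes 0. Counts are
    negative-binomial with the stated dispersion; FPKM is
    ``count / (gene_kb * library_size / 1e6)`` where ``library_size`` is the
    total mapped fragments of the library the simulated genes are drawn
    from — a whole transcriptome, not just the genes simulated here — so
    the conventional FPKM > 20 high-expression cut stays meaningful.

    Returns ``(genes, expression)``: a BED-like gene table
    (gene_id, chrom, start, end, strand, tss) and a long expression table
    (gene_id, condition, count, fpkm).
    """
    if genes_per_mb_a <= genes_per_mb_b:
        raise ValueError("A compartment must be gene-dense: genes_per_mb_a > genes_per_mb_b")
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    for name in genome.names:
        length = genome.length_of(name)
        for s, e, lab in truth.compartment_blocks[name]:
            dens = genes_per_mb_a if lab == "A" else genes_per_mb_b
            n = rng.poisson(dens * (e - s) / 1e6)
            for _ in range(n):
                glen = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
                tss = int(rng.integers(s, e))
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    start, end = tss, min(tss + glen, length)
                else:
                    start, end = max(tss - glen, 0), tss
                if end - start < 200:
                    continue
                rows.append((f"gene{gid:05d}", name, start, end, strand, tss))
                gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "tss"])

    # per-gene switch category from the planted block labellings
    delta = np.zeros(len(genes))
    for k, row in enumerate(genes.itertuples(index=False)):
        lab1 = truth.label_at(row.chrom, row.tss, condition=1)
        lab2 = truth.label_at(row.chrom, row.tss, condition=2)
        if lab1 == "B" and lab2 == "A":
            delta[k] = lfc_switch_effect
        elif lab1 == "A" and lab2 == "B":
            delta[k] = -lfc_switch_effect

    base = base_mean * 2.0 ** rng.normal(0.0, 1.0, len(genes))
    mean1 = base
    mean2 = base * 2.0 ** delta
    r = 1.0 / dispersion

    def nb_draw(mean):
        return rng.negative_binomial(r, r / (r + mean))

    expr_rows = []
    for cond, mean in (("cond1", mean1), ("cond2", mean2)):
        counts = nb_draw(mean).astype(float)
        gene_kb = (genes["end"] - genes["start"]).to_numpy() / 1_000.0
        fpkm = counts / (gene_kb * library_size / 1e6)
        for g, c, f in zip(genes["gene_id"], counts, fpkm):
            expr_rows.append((g, cond, c, f))
    expression = pd.DataFrame(expr_rows, columns=["gene_id", "condition",
                                                  "count", "fpkm"])
    return genes, expression


def expression_lfc(expression: pd.DataFrame, cond_num: str = "cond2",
                   cond_den: str = "cond1") -> pd.Series:
    """Per-gene log2 fold change of FPKM (pseudo-count 1) between conditions."""
    wide = expression.pivot(index="gene_id", columns="condition", values="fpkm")
    return np.log2(wide[cond_num] + 1.0) - np.log2(wide[cond_den] + 1.0)


def simulate_count_matrix(n_genes: int, n_reps: int, group_lfc: np.ndarray,
                          dispersion: float = 0.1, base_mean: float = 200.0,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two-group NB count matrix for differential-expression power checks.

    Returns ``(counts, groups)``: counts of shape (n_genes, 2*n_reps), group
    labels 0/1. Group 1 means are shifted by per-gene ``group_lfc`` (log2).
    """
    rng = np.random.default_rng(seed)
    group_lfc = np.broadcast_to(np.asarray(group_lfc, float), (n_genes,))
    base = base_mean * 2.0 ** rng.normal(0.0, 0.5, n_genes)
    r = 1.0 / dispersion
    means = np.column_stack([
        np.repeat(base[:, None], n_reps, axis=1),
        np.repeat((base * 2.0 ** group_lfc)[:, None], n_reps, axis=1),
    ])
    counts = rng.negative_binomial(r, r / (r + means))
    groups = np.array([0] * n_reps + [1] * n_reps)
    return counts.astype(float), groups


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def _place_peaks_in_blocks(rng, genome, blocks, target_label, a_bias,
                           peak_len_mean, n_peaks):
    rows = []
    # pre-index blocks by label, weighted by length
    by_label = {"A": [], "B": []}
    for name in genome.names:
        for s, e, lab in blocks[name]:
            by_label[lab].append((name, s, e))
    weights = {lab: np.array([e - s for _, s, e in v], float)
               for lab, v in by_label.items()}
    for lab in weights:
        if weights[lab].sum() > 0:
            weights[lab] /= weights[lab].sum()
    other = "B" if target_label == "A" else "A"
    for _ in range(n_peaks):
        lab = target_label if rng.random() < a_bias else other
        if not by_label[lab]:
            lab = other
        k = rng.choice(len(by_label[lab]), p=weights[lab])
        name, s, e = by_label[lab][k]
        mid = int(rng.integers(s, e))
        half = max(int(rng.exponential(peak_len_mean)) // 2, 25)
        start = max(mid - half, 0)
        end = min(mid + half, genome.length_of(name))
        rows.append((name, start, end, float(rng.lognormal(2.0, 0.5))))
    return rows


def _merge_overlaps(df: pd.DataFrame) -> pd.DataFrame:
    out = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None or row.start > cur[2]:
                if cur is not None:
                    out.append(cur)
                cur = [chrom, row.start, row.end, row.signal]
            else:
                cur[2] = max(cur[2], row.end)
                cur[3] = max(cur[3], row.signal)
        if cur is not None:
            out.append(cur)
    return (pd.DataFrame(out, columns=["chrom", "start", "end", "signal"])
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def simulate_peaks(truth: SyntheticTruth, genome: GenomeLayout,
                   a_bias: float = 0.9, peak_len_mean: int = 1_500,
                   n_peaks: int = 500, seed: int = 0,
                   condition: int = 1) -> tuple[PeakSet, PeakSet]:
    """Compartment-biased H3ac and H3K27me3 peak sets.

    H3ac (active) peaks fall in A blocks with probability ``a_bias``;
    H3K27me3 (repressive) peaks fall in B blocks with the same probability.
    Peak lengths are exponential around ``peak_len_mean``; overlapping peaks
    within a mark are merged so each set is non-overlapping.
    """
    if not (0.5 < a_bias <= 1.0):
        raise ValueError("a_bias must be in (0.5, 1]")
    rng = np.random.default_rng(seed)
    blocks = truth.blocks(condition)
    cond = f"cond{condition}"
    h3ac = _merge_overlaps(pd.DataFrame(
        _place_peaks_in_blocks(rng, genome, blocks, "A", a_bias,
                               peak_len_mean, n_peaks),
        columns=["chrom", "start", "end", "signal"]))
    h3k27 = _merge_overlaps(pd.DataFrame(
        _place_peaks_in_blocks(rng, genome, blocks, "B", a_bias,
                               peak_len_mean, n_peaks),
        columns=["chrom", "start", "end", "signal"]))
    return PeakSet("H3ac", cond, h3ac), PeakSet("H3K27me3", cond, h3k27)


def simulate_coupled_peaks(genes: pd.DataFrame, expression: pd.DataFrame,
                           condition: str, mark: str, target_r: float,
                           seed: int = 0, mean_len: float = 800.0,
                           sd_len: float = 250.0) -> PeakSet:
    """One peak per gene with bp-coverage correlated to expression.

    The peak length for each gene is an affine function of a latent variable
    with Pearson correlation ``target_r`` against log2(FPKM + 1), clipped to
    the gene body; placing the peak at the gene start keeps it inside the
    [TSS - 1 kb, gene end] window that mark–expression correlation scans, so
    the realized correlation matches the target up to clipping.
    """
    if not (-1.0 <= target_r <= 1.0):
        raise ValueError("target_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    expr = expression[expression["condition"] == condition].set_index("gene_id")
    x = np.log2(expr.loc[genes["gene_id"], "fpkm"].to_numpy() + 1.0)
    xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    # orthogonalize the noise against expression so the *sample* correlation
    # of the latent equals target_r exactly (before clipping)
    eps = rng.normal(size=len(xs))
    eps = eps - eps.mean()
    eps -= (eps @ xs) / (xs @ xs) * xs
    eps /= eps.std() if eps.std() > 0 else 1.0
    latent = target_r * xs + np.sqrt(max(0.0, 1 - target_r ** 2)) * eps
    glen = (genes["end"] - genes["start"]).to_numpy()
    desired = np.clip(mean_len + sd_len * latent, 0, glen)

    # measurement windows: 1 kb upstream of the TSS through the far gene end
    win_lo = np.where(genes["strand"] == "+",
                      np.maximum(genes["start"] - 1000, 0), genes["start"])
    win_hi = np.where(genes["strand"] == "+",
                      genes["end"], genes["end"] + 1000)
    chroms = genes["chrom"].to_numpy()
    starts = genes["start"].to_numpy()

    # fixed-point calibration: shrink each gene's own peak by the coverage
    # that neighboring genes' peaks leak into its window, so the total
    # window coverage matches the planted value
    lengths = desired.copy()
    for _ in range(3):
        leak = np.zeros(len(genes))
        for k in range(len(genes)):
            lo, hi = win_lo[k], win_hi[k]
            same = np.nonzero((chroms == chroms[k])
                              & (starts < hi) & (starts + lengths > lo))[0]
            for j in same:
                if j == k:
                    continue
                leak[k] += max(0.0, min(hi, starts[j] + lengths[j])
                               - max(lo, starts[j]))
        lengths = np.clip(desired - leak, 0, glen)

    rows = []
    for row, plen in zip(genes.itertuples(index=False), lengths):
        if plen < 25:
            continue
        rows.append((row.chrom, row.start, row.start + int(plen),
                     float(plen)))
    df = (pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])
          .sort_values(["chrom", "start"]).reset_index(drop=True))
    return PeakSet(mark, condition, df)


# ---------------------------------------------------------------------------
# writers for the pipeline's text formats
# ---------------------------------------------------------------------------

def write_genes_bed(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n")


def read_genes_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                continue
            chrom, start, end, name, _, strand = parts[:6]
            start, end = int(start), int(end)
            tss = start if strand == "+" else end
            rows.append((name, chrom, start, end, strand, tss))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "tss"])


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
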