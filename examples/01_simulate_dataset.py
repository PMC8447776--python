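"""Generate a synthetic dataset with planted chromatin architecture.

Builds a snake-like karyotype, plants A/B compartment blocks, TAD
boundaries and focal loops, then samples a Poisson contact map plus gene
annotation, expression and histone-mark peaks. Everything downstream of
the generator can be scored against this known truth.
"""

from chromhier import (make_genome, plant_truth, simulate_contacts,
                       simulate_annotation_and_expression, simulate_peaks)

genome = make_genome(n_mac=2, n_mic=4,
                     mac_range=(55_000_000, 70_000_000),
                     mic_range=(10_000_000, 20_000_000), seed=1)
print(f"karyotype: {len(genome)} chromosomes, "
      f"{len(genome.mac_names)} MACs (> 50 Mb), "
      f"{len(genome.mic_names)} MICs (< 50 Mb)")

truth = plant_truth(genome, comp_block_bp=1_000_000,
                    n_boundaries_per_chrom=8, n_loops=60, seed=2)
n_blocks = sum(len(b) for b in truth.compartment_blocks.values())
n_bounds = sum(len(b) for b in truth.boundary_positions.values())
print(f"planted: {n_blocks} compartment blocks, {n_bounds} TAD boundaries, "
      f"{len(truth.loop_anchors)} loops (spans <= 1 Mb)")

cmap = simulate_contacts(genome, truth, resolution=100_000, depth=5e6, seed=3)
print(f"contact map: {cmap.genome.total_bins(cmap.resolution)} bins at "
      f"{cmap.resolution//1000} kb, total {cmap.total():.3g} read pairs "
      "(Poisson around the requested depth)")

genes, expr = simulate_annotation_and_expression(genome, truth, seed=4)
h3ac, h3k27 = simulate_peaks(truth, genome, a_bias=0.9, n_peaks=500, seed=5)
print(f"annotation: {len(genes)} genes (A blocks are gene-dense), "
      f"{len(h3ac.intervals)} H3ac and {len(h3k27.intervals)} H3K27me3 peaks")
# The printed counts vary Poisson-style with the seed; structure (MAC/MIC
# split, loop-span cap, compartment-biased gene density) is guaranteed.
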