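"""Writers for the pipeline's text output formats (bedGraph, BED, BEDPE)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compartments import CompartmentProfile, SwitchTable
from .domains import InsulationTrack


def write_bedgraph_profile(profile: CompartmentProfile, path) -> None:
    """Compartment eigenvector as bedGraph."""
    with open(path, "w") as fh:
        for chrom, ev in profile.eigenvector.items():
            starts = profile.genome.bin_starts(chrom, profile.resolution)
            length = profile.genome.length_of(chrom)
            for s, v in zip(starts, ev):
                e = min(int(s) + profile.resolution, length)
                fh.write(f"{chrom}\t{int(s)}\t{e}\t{v:.6g}\n")


def write_compartment_bed(profile: CompartmentProfile, path) -> None:
    """A/B labels as BED4 (masked bins omitted)."""
    with open(path, "w") as fh:
        for chrom, labels in profile.labels.items():
            starts = profile.genome.bin_starts(chrom, profile.resolution)
            length = profile.genome.length_of(chrom)
            for s, lab in zip(starts, labels):
                if lab == ".":
                    continue
                e = min(int(s) + profile.resolution, length)
                fh.write(f"{chrom}\t{int(s)}\t{e}\t{lab}\n")


def write_switch_bed(switch: SwitchTable, path) -> None:
    df = switch.to_frame()
    df = df[df["category"] != "."]
    df.to_csv(path, sep="\t", header=False, index=False)


def write_insulation_bedgraph(tracks: dict[str, InsulationTrack], path) -> None:
    with open(path, "w") as fh:
        for chrom, tr in tracks.items():
            for b, (sc, m) in enumerate(zip(tr.scores, tr.mask)):
                if m:
                    continue
                s = b * tr.resolution
                fh.write(f"{chrom}\t{s}\t{s + tr.resolution}\t{sc:.6g}\n")


def write_boundaries_bed(boundaries: pd.DataFrame, path) -> None:
    """Boundary intervals as BED with strength and clipped-flag columns."""
    with open(path, "w") as fh:
        for k, row in enumerate(boundaries.itertuples(index=False)):
            flag = "clipped" if row.clipped else "ok"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tboundary_{k}\t"
                     f"{row.strength:.4f}\t{flag}\n")


def write_tads_bed(tads: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for k, row in enumerate(tads.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\ttad_{k}\n")


def write_loops_bedpe(loops: pd.DataFrame, path) -> None:
    """Loops as 10-column BEDPE: both anchors, name, q, label, resolution."""
    with open(path, "w") as fh:
        for k, row in enumerate(loops.itertuples(index=False)):
            label = getattr(row, "compartment", ".")
            fh.write(f"{row.chrom}\t{row.start1}\t{row.end1}\t"
                     f"{row.chrom}\t{row.start2}\t{row.end2}\t"
                     f"loop_{k}\t{row.q_value:.4g}\t{label}\t{row.resolution}\n")


def read_loops_bedpe(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            p = line.rstrip("\n").split("\t")
            if len(p) < 10:
                continue
            rows.append((p[0], int(p[1]), int(p[2]), int(p[4]), int(p[5]),
                         p[6], float(p[7]), p[8], int(p[9])))
    df = pd.DataFrame(rows, columns=["chrom", "start1", "end1", "start2",
                                     "end2", "name", "q_value", "compartment",
                                     "resolution"])
    df["span"] = df["start2"] - df["start1"]
    return df
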