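"""Genome layout and binning.

A :class:`GenomeLayout` holds an ordered set of chromosomes with their lengths
and the macro/micro classification threshold. Snake genomes (and bird genomes)
are bimodal: a handful of macro-chromosomes (MACs, > 50 Mb) and a tail of
micro-chromosomes (MICs, < 50 Mb). All bin arithmetic for contact maps runs
through this class so that every module agrees on the genome-wide bin index
space (the concatenation of per-chromosome bins in layout order).

Coordinates are 0-based half-open throughout; bin ``k`` at resolution ``res``
covers ``[k*res, (k+1)*res)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeLayout"]

DEFAULT_MAC_THRESHOLD = 50_000_000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths and a MAC/MIC size threshold.

    Parameters
    ----------
    names
        Unique chromosome identifiers, in layout order.
    lengths
        Chromosome lengths in base pairs, parallel to ``names``.
    mac_threshold
        Chromosomes strictly longer are macro-chromosomes (MACs), strictly
        shorter are micro-chromosomes (MICs). Lengths exactly equal to the
        threshold are rejected so the classification is total.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    mac_threshold: int = DEFAULT_MAC_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if any(l == self.mac_threshold for l in self.lengths):
            raise ValueError(
                "chromosome length equal to the MAC threshold makes the "
                "MAC/MIC classification ambiguous"
            )

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.names)

    def length_of(self, name: str) -> int:
        return self.lengths[self.index_of(name)]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def is_mac(self, name: str) -> bool:
        return self.length_of(name) > self.mac_threshold

    @property
    def mac_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.is_mac(n))

    @property
    def mic_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if not self.is_mac(n))

    # -- binning -----------------------------------------------------------

    def n_bins(self, name: str, resolution: int) -> int:
        return -(-self.length_of(name) // resolution)

    def bin_counts(self, resolution: int) -> np.ndarray:
        """Number of bins per chromosome, in layout order."""
        return np.array([-(-l // resolution) for l in self.lengths], dtype=np.int64)

    def bin_offsets(self, resolution: int) -> np.ndarray:
        """Genome-wide bin offset of each chromosome (length n_chrom + 1)."""
        return np.concatenate([[0], np.cumsum(self.bin_counts(resolution))])

    def total_bins(self, resolution: int) -> int:
        return int(self.bin_counts(resolution).sum())

    def bin_index(self, name: str, start_bp: int, resolution: int) -> int:
        """Genome-wide bin index of the bin whose start is ``start_bp``."""
        ci = self.index_of(name)
        if start_bp % resolution != 0:
            raise ValueError(
                f"coordinate {start_bp} is not aligned to resolution {resolution}"
            )
        local = start_bp // resolution
        if local >= self.n_bins(name, resolution):
            raise ValueError(f"coordinate {start_bp} beyond end of {name}")
        return int(self.bin_offsets(resolution)[ci] + local)

    def bin_chrom_of(self, bins: np.ndarray, resolution: int) -> np.ndarray:
        """Chromosome index of each genome-wide bin index."""
        offs = self.bin_offsets(resolution)
        return np.searchsorted(offs, np.asarray(bins), side="right") - 1

    def bin_starts(self, name: str, resolution: int) -> np.ndarray:
        """Start coordinate (bp) of each bin of one chromosome."""
        return np.arange(self.n_bins(name, resolution), dtype=np.int64) * resolution

    # -- serialization -----------------------------------------------------

    def to_chromsizes_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for n, l in zip(self.names, self.lengths):
                fh.write(f"{n}\t{l}\n")

    @classmethod
    def from_chromsizes_tsv(cls, path, mac_threshold: int = DEFAULT_MAC_THRESHOLD) -> "GenomeLayout":
        names, lengths = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                n, l = line.split("\t")[:2]
                names.append(n)
                lengths.append(int(l))
        return cls(tuple(names), tuple(lengths), mac_threshold)
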