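"""Contact-map container, normalization and interaction summaries.

The pipeline consumes binned genome-wide contact counts. Counts live in a
single scipy sparse matrix over the genome-wide bin index space, stored
upper-triangular with implied symmetry: off-diagonal entry (i, j), i < j,
represents the read pairs linking bin i and bin j, so the genome-wide total
counts it twice (once per read end) while diagonal entries count once.

Normalization follows the standard Hi-C stack:

* library-size scaling to a fixed input total (default 1e9 read pairs) so
  maps from different samples are comparable;
* per-chromosome ICE (iterative correction) equalizing bin coverage with a
  multiplicative bias per bin, masking low-coverage bins;
* observed/expected division by the mean contact at each bin distance,
  removing the power-law distance decay.

`interaction_summary` compares mean contact frequency between
chromosome-pair classes (intra/inter x MAC/MIC), area-normalized so that
chromosome length does not confound the comparison.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .genome import GenomeLayout

__all__ = [
    "ContactMap",
    "BalancedMatrix",
    "read_contacts",
    "write_contacts",
    "normalize_library",
    "ice_balance",
    "observed_over_expected",
    "expected_by_distance",
    "interaction_summary",
    "coarsen",
]


class ContactParseError(ValueError):
    """A malformed record in a sparse-triplet contact file."""


@dataclass
class ContactMap:
    """Symmetric sparse binned contact counts for a whole genome.

    ``matrix`` is upper-triangular (i <= j) in the genome-wide bin index
    space defined by ``genome`` at ``resolution``.
    """

    genome: GenomeLayout
    resolution: int
    matrix: sp.csr_matrix  # upper triangular, counts >= 0

    def __post_init__(self) -> None:
        n = self.genome.total_bins(self.resolution)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n} genome bins at {self.resolution} bp"
            )

    def total(self) -> float:
        """Genome-wide total: off-diagonal entries twice, diagonal once."""
        diag = self.matrix.diagonal().sum()
        return float(2.0 * self.matrix.sum() - diag)

    def scaled(self, factor: float) -> "ContactMap":
        return ContactMap(self.genome, self.resolution, self.matrix * factor)

    def chrom_dense(self, name: str) -> np.ndarray:
        """Dense symmetric intra-chromosomal matrix for one chromosome."""
        offs = self.genome.bin_offsets(self.resolution)
        ci = self.genome.index_of(name)
        lo, hi = int(offs[ci]), int(offs[ci + 1])
        block = self.matrix[lo:hi, lo:hi].toarray()
        return block + np.triu(block, 1).T

    def inter_block_sum(self, name1: str, name2: str) -> float:
        """Total count between two distinct chromosomes."""
        offs = self.genome.bin_offsets(self.resolution)
        i, j = sorted((self.genome.index_of(name1), self.genome.index_of(name2)))
        if i == j:
            raise ValueError("use chrom_dense for intra-chromosomal totals")
        return float(
            self.matrix[offs[i] : offs[i + 1], offs[j] : offs[j + 1]].sum()
        )


@dataclass
class BalancedMatrix:
    """ICE-balanced dense intra-chromosomal matrix with bias and mask.

    ``balanced = raw / outer(bias, bias)`` on unmasked bins; masked bins have
    zero rows/columns and NaN bias.
    """

    matrix: np.ndarray
    bias: np.ndarray
    mask: np.ndarray  # True where the bin is masked (invalid)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# sparse triplet I/O
# ---------------------------------------------------------------------------

def _opener(path, mode="rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def read_contacts(path, chromsizes_path, resolution: int,
                  mac_threshold: int = 50_000_000) -> ContactMap:
    """Read a sparse-triplet contact file.

    Format: five tab-separated columns ``chrom1 start1 chrom2 start2 count``
    with bin-start coordinates aligned to ``resolution``. Records given on
    (i, j) and (j, i) are summed into one upper-triangular entry.
    """
    genome = GenomeLayout.from_chromsizes_tsv(chromsizes_path, mac_threshold)
    rows, cols, vals = [], [], []
    with _opener(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ContactParseError(f"line {ln}: expected 5 columns, got {len(parts)}")
            c1, s1, c2, s2, cnt = parts
            try:
                i = genome.bin_index(c1, int(s1), resolution)
                j = genome.bin_index(c2, int(s2), resolution)
            except KeyError as e:
                raise ContactParseError(f"line {ln}: {e.args[0]}") from None
            except ValueError as e:
                raise ContactParseError(f"line {ln}: {e}") from None
            v = float(cnt)
            if v < 0:
                raise ContactParseError(f"line {ln}: negative count {cnt}")
            if i > j:
                i, j = j, i
            rows.append(i)
            cols.append(j)
            vals.append(v)
    n = genome.total_bins(resolution)
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    m.sum_duplicates()
    return ContactMap(genome, resolution, m)


def write_contacts(cmap: ContactMap, path) -> None:
    """Write upper-triangular entries as the 5-column sparse-triplet TSV."""
    coo = cmap.matrix.tocoo()
    offs = cmap.genome.bin_offsets(cmap.resolution)
    res = cmap.resolution
    ci = cmap.genome.bin_chrom_of(coo.row, res)
    cj = cmap.genome.bin_chrom_of(coo.col, res)
    with _opener(path, "wt") as fh:
        order = np.lexsort((coo.col, coo.row))
        for k in order:
            i, j, v = coo.row[k], coo.col[k], coo.data[k]
            n1, n2 = cmap.genome.names[ci[k]], cmap.genome.names[cj[k]]
            s1 = (i - offs[ci[k]]) * res
            s2 = (j - offs[cj[k]]) * res
            val = int(v) if float(v).is_integer() else v
            fh.write(f"{n1}\t{s1}\t{n2}\t{s2}\t{val}\n")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_library(cmap: ContactMap, target_total: float = 1e9) -> ContactMap:
    """Scale counts so the genome-wide total equals ``target_total``.

    The total counts off-diagonal entries twice (each read pair has two
    distinct bin ends) and diagonal entries once, matching a scaling of maps
    to a common number of input read pairs.
    """
    total = cmap.total()
    if total <= 0:
        raise ValueError("cannot normalize an empty contact map")
    return cmap.scaled(target_total / total)


def ice_balance(matrix: np.ndarray, max_iter: int = 200, tol: float = 1e-5,
                min_coverage_quantile: float = 0.02) -> BalancedMatrix:
    """Iterative correction (ICE) of one intra-chromosomal matrix.

    Bins whose coverage (row sum) is zero, or below the
    ``min_coverage_quantile`` quantile of the nonzero coverages, are masked
    out. Iterative proportional fitting then equalizes unmasked row sums, to
    a common target equal to the mean unmasked raw coverage, so the balanced
    matrix stays on the raw count scale. Stops when the maximum relative
    deviation of unmasked row sums drops below ``tol``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(m, m.T):
        raise ValueError("expected a symmetric matrix")
    if (m < 0).any():
        raise ValueError("expected non-negative counts")

    coverage = m.sum(axis=1)
    nonzero = coverage[coverage > 0]
    if nonzero.size == 0:
        raise ValueError("matrix too sparse: all bins have zero coverage")
    # "lower" keeps the cut at an attained coverage value so that the strict
    # comparison never masks the minimum bin of a dense small matrix
    cut = np.quantile(nonzero, min_coverage_quantile, method="lower")
    mask = (coverage == 0) | (coverage < cut)
    if mask.all():
        raise ValueError("matrix too sparse: all bins masked")

    work = m.copy()
    work[mask, :] = 0.0
    work[:, mask] = 0.0
    bias = np.ones(m.shape[0])
    unmasked = ~mask
    for _ in range(max_iter):
        s = work.sum(axis=1)
        mean_s = s[unmasked].mean()
        if mean_s == 0:
            raise ValueError("matrix too sparse: unmasked bins have no signal")
        dev = np.abs(s[unmasked] / mean_s - 1.0).max()
        if dev < tol:
            break
        upd = np.where(unmasked, s / mean_s, 1.0)
        bias *= upd
        work /= np.outer(upd, upd)

    # rescale to the raw-coverage target so values stay count-like
    target = coverage[unmasked].mean()
    s = work.sum(axis=1)
    scale = s[unmasked].mean() / target
    work /= scale
    bias *= np.sqrt(scale)
    bias[mask] = np.nan
    return BalancedMatrix(matrix=work, bias=bias, mask=mask)


def expected_by_distance(bal: BalancedMatrix) -> np.ndarray:
    """Mean balanced value at each bin distance d = 0 .. n-1, unmasked pairs."""
    n = bal.n_bins
    unmasked = ~bal.mask
    expected = np.zeros(n)
    # vectorized over diagonals
    for d in range(n):
        diag = np.diagonal(bal.matrix, offset=d)
        valid = unmasked[: n - d] & unmasked[d:]
        cnt = int(valid.sum())
        expected[d] = diag[valid].sum() / cnt if cnt else 0.0
    return expected


def observed_over_expected(bal: BalancedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """O/E matrix and the distance-decay profile it divides by.

    Expected at distance d is the mean balanced value over unmasked bin
    pairs at that distance; entries whose distance class has zero expectation
    are set to 0. Returns ``(oe, expected)``.
    """
    n = bal.n_bins
    expected = expected_by_distance(bal)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp_mat = expected[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp_mat > 0, bal.matrix / exp_mat, 0.0)
    oe[bal.mask, :] = 0.0
    oe[:, bal.mask] = 0.0
    return oe, expected


def coarsen(cmap: ContactMap, factor: int) -> ContactMap:
    """Aggregate a contact map to ``factor`` x coarser resolution.

    Bins are pooled within chromosomes; the last (ragged) bin of each
    chromosome absorbs the remainder.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1:
        return cmap
    res_out = cmap.resolution * factor
    g = cmap.genome
    offs_in = g.bin_offsets(cmap.resolution)
    offs_out = g.bin_offsets(res_out)
    nbins_out = g.bin_counts(res_out)
    # map each fine bin to its coarse genome-wide bin
    mapping = np.empty(g.total_bins(cmap.resolution), dtype=np.int64)
    for ci in range(len(g)):
        local = np.arange(offs_in[ci + 1] - offs_in[ci]) // factor
        np.minimum(local, nbins_out[ci] - 1, out=local)
        mapping[offs_in[ci] : offs_in[ci + 1]] = offs_out[ci] + local
    coo = cmap.matrix.tocoo()
    r = mapping[coo.row]
    c = mapping[coo.col]
    swap = r > c
    r2 = np.where(swap, c, r)
    c2 = np.where(swap, r, c)
    n_out = g.total_bins(res_out)
    m = sp.coo_matrix((coo.data, (r2, c2)), shape=(n_out, n_out)).tocsr()
    m.sum_duplicates()
    return ContactMap(g, res_out, m)


# ---------------------------------------------------------------------------
# MAC/MIC interaction summary
# ---------------------------------------------------------------------------

INTERACTION_CLASSES = (
    "intra_MAC",
    "intra_MIC",
    "inter_MAC_MAC",
    "inter_MIC_MIC",
    "inter_MAC_MIC",
)


def _pair_class(genome: GenomeLayout, n1: str, n2: str) -> str:
    m1, m2 = genome.is_mac(n1), genome.is_mac(n2)
    if n1 == n2:
        return "intra_MAC" if m1 else "intra_MIC"
    if m1 and m2:
        return "inter_MAC_MAC"
    if not m1 and not m2:
        return "inter_MIC_MIC"
    return "inter_MAC_MIC"


def interaction_summary(cmap: ContactMap, mac_threshold: int | None = None) -> dict:
    """Per-class mean contact frequency and Welch t-tests between classes.

    Each chromosome pair contributes one frequency: total count divided by
    the number of bin pairs (intra pairs use the upper-triangle pair count
    including the diagonal), so MAC and MIC classes are comparable despite
    their length difference. Welch two-sample t-tests compare intra vs inter
    frequencies, and the MIC-MIC inter class against each other inter class.
    Classes with fewer than two members report test statistics as None.
    """
    g = cmap.genome
    if mac_threshold is not None and mac_threshold != g.mac_threshold:
        g = GenomeLayout(g.names, g.lengths, mac_threshold)
        cmap = ContactMap(g, cmap.resolution, cmap.matrix)
    if len(g) < 2:
        raise ValueError("need at least 2 chromosomes")
    res = cmap.resolution
    freqs: dict[str, list[float]] = {c: [] for c in INTERACTION_CLASSES}
    for a in range(len(g)):
        for b in range(a, len(g)):
            n1, n2 = g.names[a], g.names[b]
            nb1, nb2 = g.n_bins(n1, res), g.n_bins(n2, res)
            if a == b:
                total = float(cmap.matrix[
                    g.bin_offsets(res)[a]: g.bin_offsets(res)[a + 1],
                    g.bin_offsets(res)[a]: g.bin_offsets(res)[a + 1]].sum())
                area = nb1 * (nb1 + 1) / 2
            else:
                total = cmap.inter_block_sum(n1, n2)
                area = nb1 * nb2
            freqs[_pair_class(g, n1, n2)].append(total / area)

    def welch(x: list[float], y: list[float]):
        if len(x) < 2 or len(y) < 2:
            return None, None
        t, p = stats.ttest_ind(x, y, equal_var=False)
        return float(t), float(p)

    intra = freqs["intra_MAC"] + freqs["intra_MIC"]
    inter = freqs["inter_MAC_MAC"] + freqs["inter_MIC_MIC"] + freqs["inter_MAC_MIC"]
    t_ii, p_ii = welch(intra, inter)
    tests = {"intra_vs_inter": {"t": t_ii, "p": p_ii}}
    for other in ("inter_MAC_MAC", "inter_MAC_MIC"):
        t, p = welch(freqs["inter_MIC_MIC"], freqs[other])
        tests[f"inter_MIC_MIC_vs_{other}"] = {"t": t, "p": p}

    return {
        "class_means": {c: (float(np.mean(v)) if v else 0.0) for c, v in freqs.items()},
        "class_sizes": {c: len(v) for c, v in freqs.items()},
        "per_pair": freqs,
        "tests": tests,
    }
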