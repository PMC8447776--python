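"""A/B compartment calling, orientation and switch analysis.

Compartments are called per chromosome from the observed/expected contact
matrix: the Pearson correlation matrix of O/E rows is eigen-decomposed and
the eigenvector of the largest-magnitude eigenvalue partitions bins by sign.
The sign is arbitrary, so the vector is oriented by its correlation with
gene density — the A (active) compartment is gene-dense — and positive bins
are labelled A, negative B.

Switches between two conditions are per-bin cross-classifications
(A->A, A->B, B->A, B->B); their association with expression change is tested
per category with the Wilcoxon rank-sum test against the pooled stable
(A->A u B->B) group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import BalancedMatrix, observed_over_expected
from .genome import GenomeLayout

__all__ = [
    "CompartmentProfile",
    "SwitchTable",
    "compartment_eigenvector",
    "orient_and_label",
    "call_compartments",
    "gene_density_track",
    "switch_classify",
    "switch_expression_test",
]

DEFAULT_COMPARTMENT_RES = 100_000

MASKED = "."
STABLE_CATEGORIES = ("A->A", "B->B")
SWITCH_CATEGORIES = ("A->A", "A->B", "B->A", "B->B")


@dataclass
class CompartmentProfile:
    """Per-bin eigenvector values, A/B labels and gene density.

    Arrays are per chromosome; masked bins carry eigenvector 0 and label ".".
    ``orientation_resolved[chrom]`` is False when gene density had zero
    variance and the A/B polarity could not be fixed.
    """

    genome: GenomeLayout
    resolution: int
    eigenvector: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    gene_density: dict[str, np.ndarray]
    orientation_resolved: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.eigenvector:
            starts = self.genome.bin_starts(chrom, self.resolution)
            for s, e, lab, gd in zip(starts, self.eigenvector[chrom],
                                     self.labels[chrom], self.gene_density[chrom]):
                rows.append((chrom, int(s), float(e), lab, float(gd)))
        return pd.DataFrame(rows, columns=["chrom", "start", "eigenvector",
                                           "label", "gene_density"])

    def label_at(self, chrom: str, pos: int) -> str:
        b = pos // self.resolution
        arr = self.labels[chrom]
        if b < 0 or b >= len(arr):
            return MASKED
        return arr[b]


@dataclass
class SwitchTable:
    """Per-bin switch categories between two compartment profiles."""

    genome: GenomeLayout
    resolution: int
    categories: dict[str, np.ndarray]  # per-chrom array of "A->B" etc. or "."

    def fractions(self, chrom: str | None = None) -> dict[str, float]:
        """Category fractions over unmasked bins (per chrom or genome-wide)."""
        if chrom is not None:
            arr = self.categories[chrom]
        else:
            arr = np.concatenate(list(self.categories.values()))
        unmasked = arr[arr != MASKED]
        n = len(unmasked)
        if n == 0:
            return {c: float("nan") for c in SWITCH_CATEGORIES}
        return {c: float((unmasked == c).sum()) / n for c in SWITCH_CATEGORIES}

    def opposite_fraction(self, chrom: str | None = None) -> float:
        f = self.fractions(chrom)
        return f["A->B"] + f["B->A"]

    def category_at(self, chrom: str, pos: int) -> str:
        arr = self.categories[chrom]
        b = pos // self.resolution
        if b < 0 or b >= len(arr):
            return MASKED
        return arr[b]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, arr in self.categories.items():
            starts = self.genome.bin_starts(chrom, self.resolution)
            for s, c in zip(starts, arr):
                rows.append((chrom, int(s), int(s) + self.resolution, c))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])


# ---------------------------------------------------------------------------
# eigenvector
# ---------------------------------------------------------------------------

def _pairwise_corr_excluding_diag(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of x, excluding for each pair (i, j)
    the entries at positions i and j (the self/partner diagonal entries)."""
    n = x.shape[0]
    m = n - 2
    if m < 2:
        raise ValueError("too few bins for a correlation matrix")
    S = x.sum(axis=1)
    Q = (x ** 2).sum(axis=1)
    P = x @ x.T
    d = np.diagonal(x)                       # x[i, i]
    Xij = x                                  # x[i, j]
    sum_x = S[:, None] - d[:, None] - Xij            # (i,j): S_i - x_ii - x_ij
    sum_y = S[None, :] - d[None, :] - Xij.T          # S_j - x_jj - x_ji
    sum_xy = P - d[:, None] * Xij.T - Xij * d[None, :]
    sum_xx = Q[:, None] - d[:, None] ** 2 - Xij ** 2
    sum_yy = Q[None, :] - d[None, :] ** 2 - Xij.T ** 2
    cov = sum_xy - sum_x * sum_y / m
    varx = sum_xx - sum_x ** 2 / m
    vary = sum_yy - sum_y ** 2 / m
    off = ~np.eye(n, dtype=bool)
    if (varx[off] <= 1e-12).any() or (vary[off] <= 1e-12).any():
        raise ValueError("degenerate correlation matrix (constant O/E rows)")
    corr = cov / np.sqrt(varx * vary)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def compartment_eigenvector(oe: np.ndarray, mask: np.ndarray,
                            chrom: str = "?") -> np.ndarray:
    """Leading eigenvector of the O/E Pearson correlation matrix.

    The correlation is computed over unmasked bins with the distance-0
    (diagonal) entries excluded from each row pair. Returns the unit-norm
    eigenvector of the largest-magnitude eigenvalue, zero-filled at masked
    bins; its sign is arbitrary until :func:`orient_and_label`.
    """
    unmasked = ~np.asarray(mask, bool)
    if unmasked.sum() < 10:
        raise ValueError(f"chromosome {chrom}: fewer than 10 unmasked bins")
    sub = np.asarray(oe, float)[np.ix_(unmasked, unmasked)]
    try:
        corr = _pairwise_corr_excluding_diag(sub)
    except ValueError as e:
        raise ValueError(f"chromosome {chrom}: {e}") from None
    evals, evecs = np.linalg.eigh(corr)
    lead = int(np.argmax(np.abs(evals)))
    v = evecs[:, lead]
    full = np.zeros(len(mask))
    full[unmasked] = v
    norm = np.linalg.norm(full)
    return full / norm if norm > 0 else full


def gene_density_track(genes: pd.DataFrame, genome: GenomeLayout,
                       resolution: int = DEFAULT_COMPARTMENT_RES) -> dict[str, np.ndarray]:
    """Number of gene TSSs per bin for each chromosome."""
    out = {}
    for chrom in genome.names:
        n = genome.n_bins(chrom, resolution)
        track = np.zeros(n)
        sub = genes[genes["chrom"] == chrom]
        if len(sub):
            bins = np.clip(sub["tss"].to_numpy() // resolution, 0, n - 1)
            np.add.at(track, bins, 1.0)
        out[chrom] = track
    return out


def orient_and_label(eigenvector: np.ndarray, gene_density: np.ndarray,
                     mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, bool]:
    """Orient an eigenvector by gene density and label bins A/B.

    If the Pearson correlation between eigenvector and gene density over
    unmasked bins is negative, the sign is flipped so A (positive) is the
    gene-dense compartment. Returns ``(oriented, labels, resolved)`` where
    ``resolved`` is False when gene density has zero variance (polarity
    cannot be fixed; labels are still emitted).
    """
    ev = np.asarray(eigenvector, float)
    gd = np.asarray(gene_density, float)
    if ev.shape != gd.shape:
        raise ValueError("eigenvector and gene density differ in length")
    if mask is None:
        mask = np.zeros(len(ev), dtype=bool)
    unmasked = ~np.asarray(mask, bool)
    resolved = True
    sub_ev, sub_gd = ev[unmasked], gd[unmasked]
    if sub_gd.std() == 0 or sub_ev.std() == 0:
        resolved = False
    else:
        r = np.corrcoef(sub_ev, sub_gd)[0, 1]
        if r < 0:
            ev = -ev
    labels = np.full(len(ev), MASKED, dtype=object)
    labels[unmasked & (ev > 0)] = "A"
    labels[unmasked & (ev < 0)] = "B"
    return ev, labels, resolved


def call_compartments(balanced: dict[str, BalancedMatrix], genes: pd.DataFrame,
                      genome: GenomeLayout,
                      resolution: int = DEFAULT_COMPARTMENT_RES) -> CompartmentProfile:
    """Call oriented A/B compartments for every chromosome."""
    density = gene_density_track(genes, genome, resolution)
    evs, labs, resolved = {}, {}, {}
    for chrom, bal in balanced.items():
        oe, _ = observed_over_expected(bal)
        ev = compartment_eigenvector(oe, bal.mask, chrom)
        ev, lab, res_ok = orient_and_label(ev, density[chrom], bal.mask)
        evs[chrom], labs[chrom], resolved[chrom] = ev, lab, res_ok
    return CompartmentProfile(genome, resolution, evs, labs,
                              {c: density[c] for c in evs}, resolved)


# ---------------------------------------------------------------------------
# switches
# ---------------------------------------------------------------------------

def switch_classify(profile1: CompartmentProfile,
                    profile2: CompartmentProfile) -> SwitchTable:
    """Cross-classify bins of two profiles into A->A/A->B/B->A/B->B.

    A bin masked in either profile is masked in the result.
    """
    if profile1.resolution != profile2.resolution:
        raise ValueError("profiles have different resolutions")
    if profile1.genome.names != profile2.genome.names:
        raise ValueError("profiles are on different genomes")
    cats = {}
    for chrom in profile1.labels:
        l1 = profile1.labels[chrom]
        l2 = profile2.labels[chrom]
        out = np.full(len(l1), MASKED, dtype=object)
        ok = (l1 != MASKED) & (l2 != MASKED)
        out[ok] = np.char.add(np.char.add(l1[ok].astype(str), "->"),
                              l2[ok].astype(str))
        cats[chrom] = out
    return SwitchTable(profile1.genome, profile1.resolution, cats)


def switch_expression_test(switch: SwitchTable, expr_lfc: pd.Series,
                           genes: pd.DataFrame) -> pd.DataFrame:
    """Per-switch-category expression change vs the stable group.

    Each gene takes the category of the bin containing its TSS. Categories
    A->B and B->A are tested against the pooled stable (A->A u B->B) group
    with the Wilcoxon rank-sum test. Categories with < 2 genes (or an empty
    stable group) report NaN statistics rather than raising.
    """
    cats = []
    for row in genes.itertuples(index=False):
        if row.chrom in switch.categories:
            cats.append(switch.category_at(row.chrom, row.tss))
        else:
            cats.append(MASKED)
    df = pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "category": cats,
    })
    df["lfc"] = expr_lfc.reindex(df["gene_id"]).to_numpy()
    df = df.dropna(subset=["lfc"])
    stable = df.loc[df["category"].isin(STABLE_CATEGORIES), "lfc"].to_numpy()

    rows = []
    for cat in SWITCH_CATEGORIES:
        vals = df.loc[df["category"] == cat, "lfc"].to_numpy()
        n = len(vals)
        med = float(np.median(vals)) if n else float("nan")
        if cat in STABLE_CATEGORIES or n < 2 or len(stable) < 2:
            stat, p = float("nan"), float("nan")
        else:
            stat, p = stats.ranksums(vals, stable)
        rows.append((cat, n, med, float(stat), float(p)))
    rows.append(("stable", len(stable),
                 float(np.median(stable)) if len(stable) else float("nan"),
                 float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["category", "n_genes", "median_lfc",
                                       "statistic", "p_value"])
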