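"""Focal chromatin-loop calling by local-background enrichment.

A loop is a pixel of the balanced intra-chromosomal matrix whose contact
count exceeds what the local background predicts. Following the donut-filter
approach, four neighborhoods around each candidate pixel — the donut
annulus, the lower-left quadrant, the horizontal stripe and the vertical
stripe — each yield a local expectation by rescaling the distance-decay
expectation by the neighborhood's observed/expected ratio. A pixel is a
candidate when its observed count exceeds ``min_fold`` times every local
expectation and its Poisson upper-tail p-value against the most conservative
(largest) expectation survives Benjamini-Hochberg correction per chromosome
and resolution.

Candidates within a Chebyshev radius of 2 bins are single-linkage clustered
into loop peaks (representative = most significant pixel); peaks called at
10 kb take precedence over overlapping 25 kb peaks when resolutions are
merged. Calls are restricted to anchor separations of at most 1 Mb.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import fftconvolve
from statsmodels.stats.multitest import multipletests

from .compartments import MASKED, CompartmentProfile
from .contacts import BalancedMatrix, expected_by_distance
from .genome import GenomeLayout

__all__ = [
    "call_loops",
    "cluster_and_merge",
    "assign_compartment",
    "loop_gene_coupling",
    "span_histogram",
]

MAX_LOOP_DIST = 1_000_000
NEIGHBORHOODS = ("donut", "lower_left", "horizontal", "vertical")


def _kernels(p: int, w: int) -> dict[str, np.ndarray]:
    """Boolean neighborhood footprints over offsets di, dj in [-w, w]."""
    di, dj = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1),
                         indexing="ij")
    cheb = np.maximum(np.abs(di), np.abs(dj))
    donut = (cheb > p) & (di != 0) & (dj != 0)
    horizontal = (di == 0) & (np.abs(dj) > p)
    vertical = (dj == 0) & (np.abs(di) > p)
    lower_left = (di >= 1) & (dj <= -1) & (cheb > p)
    return {"donut": donut.astype(float),
            "lower_left": lower_left.astype(float),
            "horizontal": horizontal.astype(float),
            "vertical": vertical.astype(float)}


def _conv(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    # correlation = convolution with flipped kernel; kernels here are used
    # as footprints centered on the pixel
    out = fftconvolve(x, k[::-1, ::-1], mode="same")
    return np.clip(out, 0.0, None)


def call_loops(bal: BalancedMatrix, resolution: int, chrom: str,
               max_dist: int = MAX_LOOP_DIST, peak_width: int = 1,
               donut_width: int = 5, fdr: float = 0.1,
               min_fold: float = 1.5) -> pd.DataFrame:
    """Candidate loop pixels for one chromosome at one resolution.

    Returns a DataFrame with one row per significant pixel: bin coordinates,
    anchor bp intervals, observed count, the four local expectations,
    p-value and BH q-value. Pixels are restricted to the band
    ``peak_width < j - i <= max_dist / resolution``.
    """
    p, w = peak_width, donut_width
    n = bal.n_bins
    cols = ["chrom", "bin1", "bin2", "start1", "end1", "start2", "end2",
            "resolution", "observed",
            *(f"exp_{nb}" for nb in NEIGHBORHOODS), "p_value", "q_value"]
    if n <= 2 * w + 1:
        warnings.warn(f"{chrom}: matrix smaller than the donut footprint; "
                      "no loops called")
        return pd.DataFrame(columns=cols)

    obs = np.asarray(bal.matrix, float)
    unm = (~bal.mask).astype(float)
    valid = np.outer(unm, unm)
    expected = expected_by_distance(bal)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    emat = expected[d] * valid

    kernels = _kernels(p, w)
    local_exp = {}
    ok_cover = {}
    for name, k in kernels.items():
        num = _conv(obs * valid, k)
        den = _conv(emat, k)
        cover = _conv(valid, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > 0, num / den, np.nan)
        local_exp[name] = ratio * expected[d]
        ok_cover[name] = cover >= 0.5 * k.sum()

    band = (d > p) & (d <= max_dist // resolution)
    band &= valid.astype(bool)
    band &= np.triu(np.ones((n, n), bool), 1)
    for name in kernels:
        band &= ok_cover[name]
        band &= np.isfinite(local_exp[name])

    ii, jj = np.nonzero(band)
    if len(ii) == 0:
        return pd.DataFrame(columns=cols)
    o = obs[ii, jj]
    exps = np.stack([local_exp[name][ii, jj] for name in NEIGHBORHOODS])
    mu = exps.max(axis=0)
    mu = np.maximum(mu, 1e-12)
    # Poisson upper tail: P(X >= obs) with obs on the count scale
    pvals = stats.poisson.sf(np.ceil(o) - 1, mu)
    rej, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    fold_ok = (o > min_fold * exps).all(axis=0)
    keep = rej & fold_ok

    df = pd.DataFrame({
        "chrom": chrom,
        "bin1": ii[keep],
        "bin2": jj[keep],
        "start1": ii[keep] * resolution,
        "end1": (ii[keep] + 1) * resolution,
        "start2": jj[keep] * resolution,
        "end2": (jj[keep] + 1) * resolution,
        "resolution": resolution,
        "observed": o[keep],
        **{f"exp_{name}": exps[k][keep]
           for k, name in enumerate(NEIGHBORHOODS)},
        "p_value": pvals[keep],
        "q_value": qvals[keep],
    })
    return df[cols]


def _cluster_one(df: pd.DataFrame, radius: int = 2) -> pd.DataFrame:
    """Single-linkage clustering of pixels within a Chebyshev radius."""
    if len(df) == 0:
        return df.assign(cluster_size=pd.Series(dtype=int))
    pts = df[["bin1", "bin2"]].to_numpy()
    n = len(pts)
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    order = np.argsort(pts[:, 0])
    for x in range(n):
        a = order[x]
        for y in range(x + 1, n):
            b = order[y]
            if pts[b, 0] - pts[a, 0] > radius:
                break
            if abs(pts[b, 1] - pts[a, 1]) <= radius:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    roots = np.array([find(k) for k in range(n)])
    reps = []
    for r in np.unique(roots):
        members = df.iloc[np.nonzero(roots == r)[0]]
        best = members.sort_values(["q_value", "p_value", "bin1", "bin2"]).iloc[0]
        rep = best.copy()
        rep["cluster_size"] = len(members)
        reps.append(rep)
    return pd.DataFrame(reps).reset_index(drop=True)


def cluster_and_merge(candidates: pd.DataFrame, radius: int = 2) -> pd.DataFrame:
    """Cluster candidate pixels into loop peaks and merge resolutions.

    Clustering is per chromosome and resolution with single linkage at the
    given Chebyshev radius; the cluster representative is the most
    significant pixel. Peaks called at the finest resolution take precedence
    over coarser peaks whose anchors both overlap a finer peak's anchors.
    Adds ``span`` (anchor2 start - anchor1 start, bp).
    """
    if len(candidates) == 0:
        out = candidates.copy()
        out["span"] = pd.Series(dtype=int)
        out["cluster_size"] = pd.Series(dtype=int)
        return out
    peaks = []
    for (_, _), grp in candidates.groupby(["chrom", "resolution"], sort=False):
        peaks.append(_cluster_one(grp.reset_index(drop=True), radius))
    peaks = pd.concat(peaks, ignore_index=True)

    resolutions = sorted(peaks["resolution"].unique())
    kept = [peaks[peaks["resolution"] == resolutions[0]]]
    for res in resolutions[1:]:
        coarse = peaks[peaks["resolution"] == res]
        fine = pd.concat(kept, ignore_index=True)
        keep_rows = []
        for row in coarse.itertuples(index=False):
            f = fine[fine["chrom"] == row.chrom]
            ov = ((f["start1"] < row.end1) & (f["end1"] > row.start1) &
                  (f["start2"] < row.end2) & (f["end2"] > row.start2))
            if not ov.any():
                keep_rows.append(row)
        if keep_rows:
            kept.append(pd.DataFrame(keep_rows, columns=coarse.columns))
    out = pd.concat(kept, ignore_index=True)
    out["span"] = out["start2"] - out["start1"]
    return out.sort_values(["chrom", "start1", "start2"]).reset_index(drop=True)


def peak_loci_count(loops: pd.DataFrame) -> int:
    """Number of distinct peak loci (unique anchor intervals, both sides)."""
    left = loops[["chrom", "start1", "end1"]].rename(
        columns={"start1": "start", "end1": "end"})
    right = loops[["chrom", "start2", "end2"]].rename(
        columns={"start2": "start", "end2": "end"})
    return len(pd.concat([left, right]).drop_duplicates())


def assign_compartment(loops: pd.DataFrame,
                       profile: CompartmentProfile) -> pd.DataFrame:
    """Label each loop A/B/mixed by its anchor midpoints' compartments.

    A loop is A (euchromatic) when both anchor midpoints fall in A bins of
    the 100 kb compartment profile, B when both fall in B bins, otherwise
    mixed; anchors on masked bins give mixed with ``anchor_masked`` True.
    """
    labels = []
    flagged = []
    for row in loops.itertuples(index=False):
        m1 = (row.start1 + row.end1) // 2
        m2 = (row.start2 + row.end2) // 2
        l1 = profile.label_at(row.chrom, m1)
        l2 = profile.label_at(row.chrom, m2)
        if l1 == MASKED or l2 == MASKED:
            labels.append("mixed")
            flagged.append(True)
        elif l1 == l2:
            labels.append(l1)
            flagged.append(False)
        else:
            labels.append("mixed")
            flagged.append(False)
    out = loops.copy()
    out["compartment"] = labels
    out["anchor_masked"] = flagged
    return out


def span_histogram(loops: pd.DataFrame, bin_bp: int = 50_000) -> pd.Series:
    """Loop-span histogram at the stated bin width (counts per span bin)."""
    if len(loops) == 0:
        return pd.Series(dtype=int)
    bins = (loops["span"] // bin_bp) * bin_bp
    return bins.value_counts().sort_index()


def loop_gene_coupling(loops: pd.DataFrame, genes: pd.DataFrame,
                       expression: pd.DataFrame, condition: str,
                       fpkm_high: float = 20.0) -> dict:
    """High-expression fraction of loop-coupled vs uncoupled genes.

    A gene is coupled when its TSS falls inside any loop anchor interval.
    Reports the fraction of coupled and of uncoupled genes whose FPKM
    exceeds ``fpkm_high``, with a two-proportion z-test. With no loops the
    coupled-side statistics are None.
    """
    anchors: dict[str, list[tuple[int, int]]] = {}
    for row in loops.itertuples(index=False):
        anchors.setdefault(row.chrom, []).append((row.start1, row.end1))
        anchors.setdefault(row.chrom, []).append((row.start2, row.end2))
    sorted_anchors = {}
    for chrom, iv in anchors.items():
        arr = np.array(sorted(set(iv)))
        sorted_anchors[chrom] = arr

    expr = expression[expression["condition"] == condition].set_index("gene_id")
    loop_chroms = set(sorted_anchors)
    coupled_flags = []
    fpkms = []
    for row in genes.itertuples(index=False):
        if loop_chroms and row.chrom not in loop_chroms:
            continue
        if row.gene_id not in expr.index:
            continue
        iv = sorted_anchors.get(row.chrom)
        hit = False
        if iv is not None and len(iv):
            idx = np.searchsorted(iv[:, 0], row.tss, side="right") - 1
            # anchors are fixed width; scan back over any that might span tss
            k = idx
            while k >= 0 and iv[k, 0] <= row.tss:
                if row.tss < iv[k, 1]:
                    hit = True
                    break
                if row.tss - iv[k, 0] > MAX_LOOP_DIST:
                    break
                k -= 1
        coupled_flags.append(hit)
        fpkms.append(float(expr.loc[row.gene_id, "fpkm"]))
    coupled_flags = np.array(coupled_flags, bool)
    fpkms = np.array(fpkms)
    high = fpkms > fpkm_high

    n_c = int(coupled_flags.sum())
    n_u = int((~coupled_flags).sum())
    frac_c = float(high[coupled_flags].mean()) if n_c else None
    frac_u = float(high[~coupled_flags].mean()) if n_u else None
    p = None
    if n_c and n_u:
        from statsmodels.stats.proportion import proportions_ztest
        counts = np.array([int(high[coupled_flags].sum()),
                           int(high[~coupled_flags].sum())])
        nobs = np.array([n_c, n_u])
        if 0 < counts.sum() < nobs.sum():
            _, p = proportions_ztest(counts, nobs)
            p = float(p)
        elif counts.sum() in (0, nobs.sum()):
            p = 1.0
    return {
        "n_coupled": n_c,
        "n_uncoupled": n_u,
        "frac_high_coupled": frac_c,
        "frac_high_uncoupled": frac_u,
        "p_two_proportion": p,
        "fpkm_high": fpkm_high,
    }
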