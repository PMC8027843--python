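"""Read-depth aggregation, noisy-region masking, clone clustering.

Input depth is assumed already normalized to copy-number units
(GC/mappability-corrected, denoised); these operations cover the
low-pass screening workflow: collapse fine bins by median, mask
recurrently noisy windows, and cluster clones by genome-wide Euclidean
distance of their binned profiles with Ward (ward.D2) linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .balance import DepthProfile

__all__ = [
    "BinnedDepthMatrix",
    "collapse_bins",
    "mask_noisy_regions",
    "cluster_clones",
    "infer_breakpoints",
    "linkage_to_newick",
]


def collapse_bins(profile: DepthProfile, factor: int) -> DepthProfile:
    """Aggregate consecutive bins ``factor``-fold, taking the median.

    The trailing partial tile of each chromosome uses the bins
    available.  Bin frames tile exactly: each output bin spans from the
    start of its first constituent to the end of its last.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1 or len(profile) == 0:
        return DepthProfile(
            profile.chroms.copy(), profile.starts.copy(),
            profile.ends.copy(), profile.values.copy(),
        )
    chroms, starts, ends, values = [], [], [], []
    df = profile.to_dataframe()
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        tiles = np.arange(len(grp)) // factor
        for _, sub in grp.groupby(tiles):
            chroms.append(chrom)
            starts.append(int(sub["start"].iloc[0]))
            ends.append(int(sub["end"].iloc[-1]))
            values.append(float(sub["value"].median()))
    return DepthProfile(
        np.array(chroms, object), np.array(starts), np.array(ends), np.array(values)
    )


@dataclass
class BinnedDepthMatrix:
    """Clones × bins matrix of normalized depth on a shared bin frame."""

    bins: pd.DataFrame  # columns chrom, start, end
    values: np.ndarray  # shape (n_clones, n_bins)
    clone_names: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.clone_names), len(self.bins)):
            raise ValueError("values shape inconsistent with clones x bins")
        if self.mask is None:
            self.mask = np.zeros(len(self.bins), dtype=bool)

    @classmethod
    def from_profiles(cls, profiles: dict[str, DepthProfile]) -> "BinnedDepthMatrix":
        names = list(profiles)
        first = profiles[names[0]]
        bins = pd.DataFrame(
            {"chrom": first.chroms, "start": first.starts, "end": first.ends}
        )
        rows = []
        for name in names:
            p = profiles[name]
            if len(p) != len(first) or not np.array_equal(p.starts, first.starts):
                raise ValueError(f"clone {name}: bin frame differs")
            rows.append(p.values)
        return cls(bins, np.vstack(rows), names)


def mask_noisy_regions(
    matrix: BinnedDepthMatrix,
    window_bp: int,
    sd_cut: float = 0.3,
    recurrence: float = 0.1,
    lowqual_regions: pd.DataFrame | None = None,
    reference_values: np.ndarray | None = None,
) -> BinnedDepthMatrix:
    """Mask bins in windows with recurrently high relative variance.

    Within each ``window_bp`` window, a clone is flagged when the
    population standard deviation of bin values over the window mean
    exceeds ``sd_cut`` (zero-mean windows are flagged as degenerate).
    Bins in windows flagged in more than ``recurrence`` of the cohort
    are masked, as are bins overlapping ``lowqual_regions`` (a BED-like
    frame).  ``reference_values`` substitutes a separate (e.g.,
    high-pass) cohort for deriving the variance mask.
    """
    bins = matrix.bins
    vals = reference_values if reference_values is not None else matrix.values
    n_clones = vals.shape[0]
    widths = (bins["end"] - bins["start"]).to_numpy()
    bin_w = int(widths[0])
    if window_bp % bin_w != 0:
        raise ValueError("window_bp must be a multiple of the bin width")
    mask = matrix.mask.copy()
    window_id = (
        bins["chrom"].astype(str)
        + ":"
        + (bins["start"].to_numpy() // window_bp).astype(str)
    ).to_numpy()
    for wid in pd.unique(window_id):
        idx = np.nonzero(window_id == wid)[0]
        sub = vals[:, idx]
        means = sub.mean(axis=1)
        flagged = np.zeros(n_clones, dtype=bool)
        nonzero = means != 0
        flagged[~nonzero] = True  # degenerate zero-mean window
        sd = sub[nonzero].std(axis=1, ddof=0)
        flagged[nonzero] = sd / np.abs(means[nonzero]) > sd_cut
        if flagged.mean() > recurrence:
            mask[idx] = True
    if lowqual_regions is not None:
        for _, r in lowqual_regions.iterrows():
            hit = (
                (bins["chrom"] == r["chrom"])
                & (bins["start"] < r["end"])
                & (bins["end"] > r["start"])
            )
            mask[hit.to_numpy()] = True
    return replace(matrix, mask=mask)


def cluster_clones(
    matrix: BinnedDepthMatrix,
    k: int,
    region: list[tuple[str, int, int]] | None = None,
) -> tuple[dict[str, int], np.ndarray]:
    """Ward (ward.D2) hierarchical clustering of clones; cut at k.

    Distances are Euclidean over unmasked bins (optionally restricted to
    ``region`` intervals); linkage is Ward on those distances with the
    squared-update (ward.D2) semantics, which is what
    :func:`scipy.cluster.hierarchy.linkage` computes on raw observation
    rows.  Returns (clone → 1-based cluster label, linkage matrix).
    """
    if k > len(matrix.clone_names):
        raise ValueError(f"k={k} exceeds number of clones {len(matrix.clone_names)}")
    keep = ~matrix.mask
    if region is not None:
        in_region = np.zeros(len(matrix.bins), dtype=bool)
        for chrom, lo, hi in region:
            in_region |= (
                (matrix.bins["chrom"] == chrom)
                & (matrix.bins["start"] < hi)
                & (matrix.bins["end"] > lo)
            ).to_numpy()
        keep &= in_region
    if keep.sum() < 1:
        raise ValueError("no unmasked bins to cluster on")
    X = matrix.values[:, keep]
    Z = sch.linkage(X, method="ward")
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(matrix.clone_names, (int(x) for x in labels))), Z


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with heights."""
    tree = sch.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    # root length 0
    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def infer_breakpoints(
    profile: DepthProfile,
    min_step: float = 0.6,
    window: int = 5,
    guard_bp: int = 0,
) -> dict[str, list[int]]:
    """Copy-number change points from binned depth, per chromosome.

    A candidate sits between adjacent bins where the medians of the
    flanking ``window``-bin runs differ by at least ``min_step`` CN;
    runs of contiguous candidates are reduced to the position of the
    largest step.  Positions within ``guard_bp`` of another breakpoint
    are suppressed (useful to avoid duplicating junction breakends).
    Returned positions are bin-edge coordinates.
    """
    out: dict[str, list[int]] = {}
    df = profile.to_dataframe()
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        v = grp["value"].to_numpy()
        edges = grp["start"].to_numpy()
        n = len(v)
        if n < 2 * window:
            out[chrom] = []
            continue
        steps = np.zeros(n - 1)
        for i in range(window - 1, n - window):
            left = np.median(v[i - window + 1 : i + 1])
            right = np.median(v[i + 1 : i + 1 + window])
            steps[i] = right - left
        cand = np.abs(steps) >= min_step
        positions: list[int] = []
        i = 0
        while i < len(cand):
            if not cand[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(cand) and cand[j + 1]:
                j += 1
            # within a run of candidates, the true boundary shows the
            # largest single-bin jump
            jumps = np.abs(np.diff(v))[i : j + 1]
            best = i + int(np.argmax(jumps))
            positions.append(int(edges[best + 1]))
            i = j + 1
        if guard_bp > 0:
            kept: list[int] = []
            for p in positions:
                if all(abs(p - q) > guard_bp for q in kept):
                    kept.append(p)
            positions = kept
        out[chrom] = positions
    return out
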