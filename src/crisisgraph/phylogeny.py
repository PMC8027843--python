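"""Clone phylogeny from somatic SNVs.

The pipeline: hard-filter called SNV sites (mapping quality, caller
score, total ALT count), call per-clone presence with a two-component
binomial mixture whose prior is the aggregated allele frequency across
clones, build a neighbor-joining tree from the binary presence matrix,
assign each SNV to its closest tree branch by Jaccard distance, and
detect kataegis-like clusters as runs of closely spaced SNVs.

The presence model: at a site with prior π (aggregated ALT fraction),
a clone with ``alt`` of ``depth`` reads has

    P(present | data) = π·B(alt; depth, p_present)
                        / [π·B(alt; depth, p_present) + (1−π)·B(alt; depth, p_absent)]

with ``p_present`` the expected VAF of a clonal heterozygous variant in
a pure, near-diploid clone (default 0.5) and ``p_absent`` the
sequencing error rate (default 0.001).  Zero-depth entries fall back to
the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "CloneSnvMatrix",
    "PresenceMatrix",
    "CloneTree",
    "presence_posterior",
    "neighbor_joining",
    "assign_snvs_to_branches",
    "rainfall_clusters",
]


@dataclass
class CloneSnvMatrix:
    """Per-clone REF/ALT read counts at somatic SNV sites.

    ``sites`` columns: chrom, pos, ref, alt, and optional boolean
    filter columns ``mq_pass`` (MQ=60-equivalent) and ``score_pass``
    (caller confidence, e.g. SomaticEVS>12).  Counts are
    (clones × sites) arrays.
    """

    sites: pd.DataFrame
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    clone_names: list[str]

    def __post_init__(self) -> None:
        n, m = len(self.clone_names), len(self.sites)
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        for a in (self.ref_counts, self.alt_counts):
            if a.shape != (n, m):
                raise ValueError("count matrices must be clones x sites")
            if (a < 0).any():
                raise ValueError("read counts must be >= 0")

    def apply_hard_filters(self, min_alt_total: int = 4) -> "CloneSnvMatrix":
        """Keep sites passing MQ and caller-score flags with total ALT count
        strictly above ``min_alt_total``."""
        keep = self.alt_counts.sum(axis=0) > min_alt_total
        for col in ("mq_pass", "score_pass"):
            if col in self.sites.columns:
                keep &= self.sites[col].to_numpy(bool)
        idx = np.nonzero(keep)[0]
        return CloneSnvMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            self.ref_counts[:, idx],
            self.alt_counts[:, idx],
            self.clone_names,
        )

    @classmethod
    def from_tsv(cls, path: str) -> "CloneSnvMatrix":
        """Read a TSV with columns chrom, pos, ref, alt, [flags,]
        ``<clone>_ref`` / ``<clone>_alt`` count pairs."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        clone_names = sorted(
            {c[:-4] for c in df.columns if c.endswith("_ref")}
        )
        site_cols = [
            c for c in df.columns if not (c.endswith("_ref") or c.endswith("_alt"))
        ]
        ref = np.vstack([df[f"{c}_ref"].to_numpy() for c in clone_names])
        alt = np.vstack([df[f"{c}_alt"].to_numpy() for c in clone_names])
        return cls(df[site_cols].copy(), ref, alt, clone_names)

    def to_tsv(self, path: str) -> None:
        df = self.sites.copy()
        for i, c in enumerate(self.clone_names):
            df[f"{c}_ref"] = self.ref_counts[i]
            df[f"{c}_alt"] = self.alt_counts[i]
        df.to_csv(path, sep="\t", index=False)


@dataclass
class PresenceMatrix:
    """Binary presence calls (clones × sites) with their posteriors."""

    presence: np.ndarray
    posterior: np.ndarray
    prior: np.ndarray
    clone_names: list[str]
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)


def presence_posterior(
    m: CloneSnvMatrix,
    p_present: float = 0.5,
    p_absent: float = 0.001,
    eps: float = 1e-6,
) -> PresenceMatrix:
    """Per-entry posterior probability that a variant is present.

    The per-site prior is the aggregated allele frequency over all
    clones, clamped to [eps, 1−eps]; entries are binarized at 0.5.
    """
    if not 0 < p_absent < p_present <= 1:
        raise ValueError("need 0 < p_absent < p_present <= 1")
    depth = m.ref_counts + m.alt_counts
    alt = m.alt_counts
    total_alt = alt.sum(axis=0).astype(float)
    total_depth = depth.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prior = np.where(total_depth > 0, total_alt / np.maximum(total_depth, 1), 0.5)
    prior = np.clip(prior, eps, 1 - eps)

    like_present = sps.binom.pmf(alt, depth, p_present)
    like_absent = sps.binom.pmf(alt, depth, p_absent)
    num = prior[None, :] * like_present
    den = num + (1 - prior[None, :]) * like_absent
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(den > 0, num / np.maximum(den, 1e-300), prior[None, :])
    post = np.where(depth == 0, prior[None, :], post)
    return PresenceMatrix(post > 0.5, post, prior, m.clone_names, m.sites)


@dataclass
class CloneTree:
    """Unrooted clone tree with SNV-count branch lengths."""

    tree: TreeNode
    clone_names: list[str]

    def branches(self) -> list[tuple[int, frozenset[str]]]:
        """Deterministic (branch id, clade leaf set) pairs, one per edge.

        Each edge of the unrooted tree is identified by the leaf set of
        the subtree below it under the (arbitrary) rooting; the root
        edge is skipped as it duplicates a child bipartition.
        """
        out = []
        bid = 0
        seen: set[frozenset[str]] = set()
        all_leaves = frozenset(self.clone_names)
        for node in self.tree.postorder(include_self=False):
            clade = frozenset(t.name for t in node.tips()) or frozenset([node.name])
            if clade in seen or (all_leaves - clade) in seen:
                continue
            if clade == all_leaves or not clade:
                continue
            seen.add(clade)
            out.append((bid, clade))
            bid += 1
        return out

    def to_newick(self) -> str:
        return str(self.tree).strip()


def neighbor_joining(presence: PresenceMatrix) -> CloneTree:
    """Classical neighbor joining on symmetric-difference SNV counts.

    The pairwise distance between clones is the number of sites where
    exactly one of them carries the variant — the natural additive
    distance for a binary matrix under a no-recurrence model.  Negative
    branch lengths (an NJ artifact) are clamped to 0.
    """
    B = presence.presence.astype(np.int8)
    n = B.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 clones")
    D = np.zeros((n, n))
    for i in range(n):
        diff = (B != B[i]).sum(axis=1)
        D[i] = diff
    dm = DistanceMatrix(D, ids=presence.clone_names)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return CloneTree(tree, list(presence.clone_names))


def assign_snvs_to_branches(
    tree: CloneTree,
    presence: PresenceMatrix,
    max_jaccard: float = 0.1,
) -> pd.DataFrame:
    """Assign each SNV to the closest tree branch by Jaccard distance.

    Each branch's incidence vector is the clone clade below it; both
    orientations of the unrooted edge are considered and the closer one
    used.  An SNV is linked only when its distance is strictly below
    ``max_jaccard``; ties break deterministically on branch id.
    """
    clones = presence.clone_names
    branches = tree.branches()
    inc = []
    for bid, clade in branches:
        vec = np.array([c in clade for c in clones], dtype=bool)
        inc.append((bid, vec))
    B = presence.presence.astype(bool)
    m = B.shape[1]
    best_branch = np.full(m, -1)
    best_dist = np.full(m, np.inf)
    for bid, vec in inc:
        for v in (vec, ~vec):
            inter = (B & v[:, None]).sum(axis=0)
            union = (B | v[:, None]).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.where(union > 0, 1.0 - inter / np.maximum(union, 1), 1.0)
            better = dist < best_dist
            best_dist[better] = dist[better]
            best_branch[better] = bid
    assigned = best_dist < max_jaccard
    nonzero = B.sum(axis=0) > 0
    out = presence.sites.copy() if len(presence.sites) else pd.DataFrame(index=range(m))
    out["branch"] = np.where(assigned & nonzero, best_branch, -1)
    out["jaccard"] = best_dist
    out["assigned"] = assigned & nonzero
    return out


def rainfall_clusters(
    snvs: pd.DataFrame,
    max_gap_bp: int = 2000,
    min_run: int = 2,
) -> pd.DataFrame:
    """Kataegis-like clusters: runs of SNVs with small inter-SNV gaps.

    ``snvs`` needs chrom and pos columns (optionally ref, for base
    composition).  A cluster is a maximal run of ``min_run`` or more
    consecutive SNVs on one chromosome with successive distances
    strictly below ``max_gap_bp``.  Returns one row per cluster with
    span, size, member positions and G/C reference-base count.
    """
    rows = []
    if len(snvs) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "size", "positions", "gc_count"]
        )
    for chrom, grp in snvs.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        refs = grp["ref"].to_numpy() if "ref" in grp.columns else None
        i = 0
        while i < len(pos):
            j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[j] < max_gap_bp:
                j += 1
            if j - i + 1 >= min_run:
                members = pos[i : j + 1]
                gc = (
                    int(np.isin(refs[i : j + 1], ["G", "C"]).sum())
                    if refs is not None
                    else 0
                )
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(members[0]),
                        "end": int(members[-1]) + 1,
                        "size": len(members),
                        "positions": list(int(p) for p in members),
                        "gc_count": gc,
                    }
                )
            i = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "size", "positions", "gc_count"])
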