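"""Reconstruction of rearranged alleles as walks through balanced graphs.

A *walk* is an alternating sequence of oriented segments and edges —
an open path between two end sides (telomeric termini or copy-bearing
loose ends) or a closed cycle.  Enumeration is restricted to *minimal*
walks: no oriented vertex (signed segment) is revisited.  Alleles that
revisit a segment — the hallmark of breakage-fusion-bridge fold-backs —
are reached afterwards by splicing cycles into paths
(:func:`combine_walks`).

Copy numbers are assigned to walks by a joint MILP that requires the
copy-weighted element multiplicities of the chosen walks to sum exactly
to κ in every clone, while minimizing the number of *unique* walks used
across the compendium (clone walks that project to the same prototype
walk count once).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import numpy as np

from .balance import _Model, _status_of
from .graph import (
    LOOSE,
    CopyAssignment,
    GenomeGraph,
    GraphCompendium,
    Side,
)

__all__ = [
    "Walk",
    "WalkSet",
    "WalkCopyAssignment",
    "WalkEnumerationError",
    "enumerate_minimal_walks",
    "decompose_joint",
    "combine_walks",
    "search_merge_recipe",
    "conservation_violations",
]


class WalkEnumerationError(RuntimeError):
    """Raised when enumeration exceeds the walk cap.

    Raise the cap or restrict the region of interest to proceed.
    """


@dataclass(frozen=True)
class Walk:
    """An oriented walk: ``vertices[i]`` is a signed segment id.

    For open walks ``edges`` has one entry fewer than ``vertices`` and
    ``endpoints`` records the two terminal sides, each ``("telomere",
    Side)``, ``("loose", edge_id)`` or ``("boundary", Side)`` for walks
    cut off at a region boundary.  For cycles ``edges`` has equal length
    with the last edge closing back to ``vertices[0]``.
    """

    vertices: tuple[int, ...]
    edges: tuple[int, ...]
    closed: bool
    endpoints: tuple = ()

    def __post_init__(self) -> None:
        want = len(self.vertices) if self.closed else len(self.vertices) - 1
        if len(self.edges) != want:
            raise ValueError("edge count inconsistent with walk shape")

    def reverse_complement(self) -> "Walk":
        rc_vertices = tuple(-v for v in reversed(self.vertices))
        if self.closed:
            rc_edges = tuple(reversed(self.edges[:-1])) + (self.edges[-1],)
            return Walk(rc_vertices, rc_edges, True)
        return Walk(
            rc_vertices,
            tuple(reversed(self.edges)),
            False,
            tuple(reversed(self.endpoints)),
        )

    def _rotations(self) -> Iterable["Walk"]:
        n = len(self.vertices)
        for k in range(n):
            yield Walk(
                self.vertices[k:] + self.vertices[:k],
                self.edges[k:] + self.edges[:k],
                True,
            )

    def canonical(self) -> "Walk":
        """RC- (and for cycles rotation-) invariant representative."""
        if not self.closed:
            rc = self.reverse_complement()
            return min((self, rc), key=lambda w: (w.vertices, w.edges))
        cands = list(self._rotations()) + list(self.reverse_complement()._rotations())
        return min(cands, key=lambda w: (w.vertices, w.edges))

    def key(self) -> tuple:
        """Hashable identity of the canonical walk (prototype identity)."""
        c = self.canonical()
        return (c.closed, c.vertices, c.edges)

    def delta(self) -> Counter:
        """Element multiplicities: ('v', seg) and ('e', edge id) counts.

        Loose edges at open-walk endpoints count once per endpoint.
        """
        d: Counter = Counter()
        for v in self.vertices:
            d[("v", abs(v))] += 1
        for e in self.edges:
            d[("e", e)] += 1
        for kind, ref in self.endpoints:
            if kind == "loose":
                d[("e", ref)] += 1
        return d

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class WalkSet:
    """Deduplicated canonical walks of one clone graph."""

    walks: list[Walk]

    @property
    def paths(self) -> list[Walk]:
        return [w for w in self.walks if not w.closed]

    @property
    def cycles(self) -> list[Walk]:
        return [w for w in self.walks if w.closed]

    def keys(self) -> list[tuple]:
        return [w.key() for w in self.walks]


@dataclass
class WalkCopyAssignment:
    """Integer copy number φ per walk (indexed into a WalkSet)."""

    phi: dict[int, int] = field(default_factory=dict)

    def copies(self, idx: int) -> int:
        return self.phi.get(idx, 0)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _end_descriptor(
    g: GenomeGraph, k: CopyAssignment, side: Side, region_segs: set[int]
):
    """End-side descriptor at ``side``, or None if not an end side."""
    if side in g.termini:
        return ("telomere", side)
    le = g.loose_edge_at(side)
    if le is not None and k.edge_cn.get(le.id, 0) > 0:
        return ("loose", le.id)
    # a side whose continuation leaves the restricted region ends walks too
    for e in g.incident_edges(side):
        if e.kind == LOOSE:
            continue
        if k.edge_cn.get(e.id, 0) <= 0:
            continue
        others = [s for s in e.sides if s != side] or [side]
        if any(o.seg not in region_segs for o in others):
            return ("boundary", side)
    return None


def enumerate_minimal_walks(
    g: GenomeGraph,
    k: CopyAssignment,
    max_walks: int = 10_000,
    region: tuple[str, int, int] | None = None,
) -> WalkSet:
    """All minimal paths and cycles of the nonzero-κ subgraph.

    Paths run between end sides (telomeric termini, copy-bearing loose
    ends, or region boundaries when ``region`` restricts the traversal);
    cycles are closed walks.  No oriented vertex is revisited within a
    walk; walks are returned in canonical orientation, deduplicated.
    """
    active = {s for s in g.segments if k.vertex_cn.get(s, 0) > 0}
    if region is not None:
        chrom, lo, hi = region
        active = {
            s
            for s in active
            if g.segments[s].chrom == chrom
            and g.segments[s].start < hi
            and g.segments[s].end > lo
        }

    def edge_active(e) -> bool:
        return (
            k.edge_cn.get(e.id, 0) > 0
            and e.kind != LOOSE
            and all(s.seg in active for s in e.sides)
        )

    end_at: dict[Side, tuple] = {}
    for s in active:
        for end in ("L", "R"):
            side = Side(s, end)
            d = _end_descriptor(g, k, side, active)
            if d is not None:
                end_at[side] = d

    found: dict[tuple, Walk] = {}
    budget = [0]

    def record(w: Walk) -> None:
        budget[0] += 1
        if budget[0] > max_walks:
            raise WalkEnumerationError(
                f"walk enumeration exceeded max_walks={max_walks}; raise the cap "
                "or restrict the region"
            )
        c = w.canonical()
        found.setdefault((c.closed, c.vertices, c.edges), c)

    # open walks between end sides
    def entry_side(v: int) -> Side:
        return Side(abs(v), "L" if v > 0 else "R")

    def dfs_path(vertices: list[int], edges: list[int], visited: set[int], start_desc):
        cur = vertices[-1]
        exit_side = g.exit_side(cur)
        if exit_side in end_at:
            record(
                Walk(
                    tuple(vertices), tuple(edges), False,
                    (start_desc, end_at[exit_side]),
                )
            )
        for e, nxt in g.successors(cur):
            if not edge_active(e) or nxt in visited:
                continue
            visited.add(nxt)
            dfs_path(vertices + [nxt], edges + [e.id], visited, start_desc)
            visited.remove(nxt)

    for side in sorted(end_at):
        start_desc = end_at[side]
        v0 = g.entry_vertex(side)
        if abs(v0) not in active:
            continue
        dfs_path([v0], [], {v0}, start_desc)

    # cycles: fixed minimal start vertex, both directions (deduped canonically)
    def vkey(v: int) -> tuple[int, int]:
        return (abs(v), 0 if v > 0 else 1)

    def dfs_cycle(start: int, vertices: list[int], edges: list[int], visited: set[int]):
        cur = vertices[-1]
        for e, nxt in g.successors(cur):
            if not edge_active(e):
                continue
            if nxt == start and len(vertices) >= 1:
                record(Walk(tuple(vertices), tuple(edges + [e.id]), True))
                continue
            if nxt in visited or vkey(nxt) <= vkey(start):
                continue
            visited.add(nxt)
            dfs_cycle(start, vertices + [nxt], edges + [e.id], visited)
            visited.remove(nxt)

    for s in sorted(active):
        for start in (s, -s):
            dfs_cycle(start, [start], [], {start})

    walks = sorted(found.values(), key=lambda w: (w.closed, w.vertices, w.edges))
    return WalkSet(walks)


# ---------------------------------------------------------------------------
# joint copy assignment (minimal unique walks)
# ---------------------------------------------------------------------------

@dataclass
class DecomposeResult:
    assignments: dict[str, WalkCopyAssignment]
    objective: int
    status: str
    unmet: dict[str, list] = field(default_factory=dict)


def decompose_joint(
    comp: GraphCompendium,
    sols: Mapping[str, CopyAssignment],
    walksets: Mapping[str, WalkSet],
    region: tuple[str, int, int] | None = None,
    time_limit: float | None = None,
) -> DecomposeResult:
    """Assign φ to walks so copies sum to κ, minimizing unique walks.

    Unique means up to projection onto the prototype graph: clone walks
    with identical projected element sequences count once.  Vertex
    conservation is enforced for every segment (terminal ones included)
    and edge conservation for every edge, loose ends included.  When
    the walks were enumerated under a ``region`` restriction, pass the
    same region so conservation is required only of elements inside it
    (edges crossing the boundary are exempt — walks end there).
    """
    clones = [c for c in comp.clone_names if c in walksets]
    model = _Model()

    # prototype walks = canonical keys shared across clones (p is identity)
    proto_keys = sorted(
        {key for c in clones for key in walksets[c].keys()},
        key=repr,
    )
    caps = {
        c: max(list(sols[c].vertex_cn.values()) + [0], default=0) for c in clones
    }
    zvar = {key: model.add_var(1.0, 0, 1) for key in proto_keys}
    fvar: dict[tuple[str, int], int] = {}
    eps = 1e-6
    for c in clones:
        for i, _ in enumerate(walksets[c].walks):
            fvar[(c, i)] = model.add_var(eps, 0, caps[c])
    bigm = float(sum(caps.values())) or 1.0
    for key in proto_keys:
        coefs = {}
        for c in clones:
            for i, w in enumerate(walksets[c].walks):
                if w.key() == key:
                    coefs[fvar[(c, i)]] = 1.0
        coefs[zvar[key]] = -bigm
        model.add_row(coefs, -math.inf, 0.0)

    unmet: dict[str, list] = {}
    for c in clones:
        g = comp.clones[c]
        k = sols[c]
        if region is None:
            scope = set(g.segments)
        else:
            chrom, lo, hi = region
            scope = {
                s
                for s in g.segments
                if g.segments[s].chrom == chrom
                and g.segments[s].start < hi
                and g.segments[s].end > lo
            }
        deltas = [w.delta() for w in walksets[c].walks]
        targets: dict[tuple, int] = {}
        for sid in scope:
            targets[("v", sid)] = k.vertex_cn.get(sid, 0)
        for eid, e in g.edges.items():
            if all(s.seg in scope for s in e.sides):
                targets[("e", eid)] = k.edge_cn.get(eid, 0)
        for elem, want in targets.items():
            coefs = {
                fvar[(c, i)]: float(d[elem])
                for i, d in enumerate(deltas)
                if d.get(elem, 0)
            }
            if not coefs:
                if want != 0:
                    unmet.setdefault(c, []).append(elem)
                continue
            model.add_row(coefs, float(want), float(want))
    if unmet:
        return DecomposeResult({}, 0, "infeasible", unmet)

    res = model.solve(time_limit)
    if res.x is None:
        return DecomposeResult({}, 0, _status_of(res), {})
    x = np.round(res.x).astype(int)
    assignments = {
        c: WalkCopyAssignment(
            {i: int(x[fvar[(c, i)]]) for i, _ in enumerate(walksets[c].walks)}
        )
        for c in clones
    }
    objective = int(sum(x[zvar[key]] for key in proto_keys))
    # report the recomputed objective: number of unique walks actually used
    used = {
        w.key()
        for c in clones
        for i, w in enumerate(walksets[c].walks)
        if assignments[c].copies(i) > 0
    }
    return DecomposeResult(assignments, len(used), _status_of(res), {})


def conservation_violations(
    g: GenomeGraph,
    k: CopyAssignment,
    walks: Sequence[Walk],
    phi: WalkCopyAssignment,
    region: tuple[str, int, int] | None = None,
) -> list[str]:
    """Elements where Σ_h φ(h)·δ(x,h) differs from κ(x).

    With ``region``, only in-region segments and edges fully inside the
    region are checked (matching a region-restricted decomposition).
    """
    total: Counter = Counter()
    for i, w in enumerate(walks):
        c = phi.copies(i)
        if c:
            for elem, mult in w.delta().items():
                total[elem] += c * mult
    if region is None:
        scope = set(g.segments)
    else:
        chrom, lo, hi = region
        scope = {
            s
            for s in g.segments
            if g.segments[s].chrom == chrom
            and g.segments[s].start < hi
            and g.segments[s].end > lo
        }
    out = []
    for sid in sorted(scope):
        want = k.vertex_cn.get(sid, 0)
        if total.get(("v", sid), 0) != want:
            out.append(f"segment {sid}: walks give {total.get(('v', sid), 0)}, κ={want}")
    for eid, e in sorted(g.edges.items()):
        if not all(s.seg in scope for s in e.sides):
            continue
        want = k.edge_cn.get(eid, 0)
        if total.get(("e", eid), 0) != want:
            out.append(f"edge {eid}: walks give {total.get(('e', eid), 0)}, κ={want}")
    return out


# ---------------------------------------------------------------------------
# manual combination of cycles into paths
# ---------------------------------------------------------------------------

def _rotate_to(cycle: Walk, anchor: int) -> Walk | None:
    for cand in (cycle, cycle.reverse_complement()):
        if anchor in cand.vertices:
            i = cand.vertices.index(anchor)
            return Walk(
                cand.vertices[i:] + cand.vertices[:i],
                cand.edges[i:] + cand.edges[:i],
                True,
            )
    return None


def search_merge_recipe(
    walks: Sequence[Walk],
    phi: WalkCopyAssignment,
    target_vertices: tuple[int, ...],
    target_edges: tuple[int, ...],
    max_merges: int = 5,
    max_frontier: int = 200,
) -> list[tuple] | None:
    """Find a merge sequence whose spliced path equals the target walk.

    A bounded breadth-first search over (cycle, path, anchor,
    occurrence) splice options, used to *verify* that a known allele is
    reachable from a decomposition by cycle splicing — the splice
    choices themselves remain an explicit, user-supplied record
    (``combine_walks``), not an inferred one.  Targets match up to
    reverse complement.  Returns the merge list, or None.
    """
    rc_target = (
        tuple(-v for v in reversed(target_vertices)),
        tuple(reversed(target_edges)),
    )
    targets = {(target_vertices, target_edges), rc_target}
    cycles = [i for i, w in enumerate(walks) if w.closed and phi.copies(i) > 0]
    paths = [i for i, w in enumerate(walks) if not w.closed and phi.copies(i) > 0]

    def done(state) -> int | None:
        for pi in paths:
            w = state[pi]
            if (w.vertices, w.edges) in targets:
                return pi
        return None

    frontier: list[tuple[tuple[Walk, ...], WalkCopyAssignment, list[tuple]]] = [
        (tuple(walks), phi, [])
    ]
    if done(frontier[0][0]) is not None:
        return []
    for _ in range(max_merges):
        new_frontier = []
        for state, book, hist in frontier:
            for ci in cycles:
                anchors = {v for v in walks[ci].vertices} | {
                    -v for v in walks[ci].vertices
                }
                for pi in paths:
                    for anchor in sorted(anchors):
                        n_occ = sum(
                            1 for v in state[pi].vertices if abs(v) == abs(anchor)
                        )
                        for occ in range(n_occ):
                            merge = (ci, pi, anchor, occ)
                            try:
                                res, book2 = combine_walks(list(state), book, [merge])
                            except ValueError:
                                continue
                            hist2 = hist + [merge]
                            if done(tuple(res)) is not None:
                                return hist2
                            new_frontier.append((tuple(res), book2, hist2))
        # dedupe states to keep the frontier small
        seen = set()
        frontier = []
        for state, book, hist in new_frontier:
            key = tuple((w.vertices, w.edges) for w in state)
            if key not in seen:
                seen.add(key)
                frontier.append((state, book, hist))
            if len(frontier) >= max_frontier:
                break
        if not frontier:
            return None
    return None


def combine_walks(
    walks: Sequence[Walk],
    phi: WalkCopyAssignment,
    merges: Sequence[tuple],
) -> tuple[list[Walk], WalkCopyAssignment]:
    """Splice cycles into paths to build linear somatic haplotypes.

    ``merges`` is an ordered list of ``(cycle_index, path_index, anchor,
    occurrence)`` records (occurrence optional, default 0): the cycle is
    entered at the given occurrence of the signed ``anchor`` vertex in
    the path, traversed once, and the path resumed; the path at
    ``path_index`` is replaced by the spliced walk and the cycle's φ is
    decremented by the path's φ.  Returns the final walk list (open
    walks are the haplotypes) and the updated copy bookkeeping.
    """
    work = list(walks)
    book = dict(phi.phi)
    for merge in merges:
        ci, pi, anchor, *rest = merge
        occurrence = rest[0] if rest else 0
        cycle, path = work[ci], work[pi]
        if not cycle.closed or path.closed:
            raise ValueError(f"merge {merge}: need (cycle, path) walk pair")
        hits = [
            i
            for i, v in enumerate(path.vertices)
            if abs(v) == abs(anchor)
        ]
        hits = [i for i in hits if _rotate_to(cycle, path.vertices[i]) is not None]
        if not hits:
            raise ValueError(f"merge {merge}: anchor not shared by cycle and path")
        if occurrence >= len(hits):
            raise ValueError(f"merge {merge}: occurrence {occurrence} out of range")
        i = hits[occurrence]
        rot = _rotate_to(cycle, path.vertices[i])
        assert rot is not None
        consumed = book.get(pi, 0)
        if consumed <= 0:
            raise ValueError(f"merge {merge}: path has no copies to splice into")
        if book.get(ci, 0) < consumed:
            raise ValueError(
                f"merge {merge}: cycle copies {book.get(ci, 0)} < required {consumed}"
            )
        book[ci] = book.get(ci, 0) - consumed
        spliced = Walk(
            path.vertices[: i + 1]
            + rot.vertices[1:]
            + (path.vertices[i],)
            + path.vertices[i + 1 :],
            path.edges[:i] + rot.edges + path.edges[i:],
            False,
            path.endpoints,
        )
        work[pi] = spliced
    return work, WalkCopyAssignment(book)
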