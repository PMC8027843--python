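"""Genome-graph data model.

A genome graph represents a (possibly rearranged) genome as a set of
genomic segments (vertices) connected by edges of three kinds:

* ``reference`` edges join segments that are adjacent on the reference
  chromosome, in reference orientation;
* ``variant`` edges are rearrangement junctions joining two breakend
  sides anywhere in the genome (deletions, duplications, fold-back
  inversions, translocations, ...);
* ``loose`` edges are half-edges attached to a single segment side.
  They absorb copy-number change points that no junction explains and
  are penalized by the balancing objective.

Every segment has two *sides*: ``L`` (the end facing lower reference
coordinates) and ``R`` (facing higher coordinates).  An edge is stored as
an unordered pair of sides; the two traversal directions of an edge are
reverse complements of each other.  Likewise each segment can be
traversed forward (signed vertex ``+s``) or in reverse complement
(``-s``).  The data model stores the reverse-complement quotient — one
record per {v, v̄} and {e, ē} pair — so the symmetry constraints
κ(v)=κ(v̄), κ(e)=κ(ē) hold by construction.

Chromosome ends are *telomeric termini*: distinguished sides that need
no incident edge.  Every non-terminal ("interstitial") segment is
subject to junction balance: each copy must have a left and a right
neighbor, so its copy number equals the sum of incident edge copies on
each side.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "Side",
    "Breakend",
    "Junction",
    "GraphEdge",
    "GenomeGraph",
    "GraphCompendium",
    "CopyAssignment",
    "build_prototype",
    "reverse_complement",
]

REFERENCE = "reference"
VARIANT = "variant"
LOOSE = "loose"

LEFT = "L"
RIGHT = "R"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, pos: float) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True, order=True)
class Side:
    """One end of a segment: ``L`` faces lower coordinates, ``R`` higher."""

    seg: int
    end: str

    def __post_init__(self) -> None:
        if self.end not in (LEFT, RIGHT):
            raise ValueError(f"side end must be L or R, got {self.end!r}")


@dataclass(frozen=True, order=True)
class Breakend:
    """A breakpoint side: position ``pos`` on ``chrom``, facing ``strand``.

    ``strand`` follows BEDPE semantics: ``+`` denotes the segment end
    facing higher coordinates (a segment *ending* at ``pos``), ``-`` the
    end facing lower coordinates (a segment *starting* at ``pos``).
    """

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"breakend strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class Junction:
    """A rearrangement junction joining two breakend sides."""

    bnd1: Breakend
    bnd2: Breakend

    def canonical(self) -> "Junction":
        a, b = sorted([self.bnd1, self.bnd2])
        return Junction(a, b)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Junction):
            return NotImplemented
        return {self.bnd1, self.bnd2} == {other.bnd1, other.bnd2}

    def __hash__(self) -> int:
        return hash(frozenset((self.bnd1, self.bnd2)))


@dataclass(frozen=True)
class GraphEdge:
    """An edge of the genome graph.

    ``side2`` is ``None`` exactly for loose edges.  A fold-back junction
    may join a side to itself (``side1 == side2``); such a self-loop
    contributes *two* copies to that side's balance sum per edge copy.
    """

    id: int
    kind: str
    side1: Side
    side2: Side | None = None

    def __post_init__(self) -> None:
        if self.kind not in (REFERENCE, VARIANT, LOOSE):
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if (self.side2 is None) != (self.kind == LOOSE):
            raise ValueError("side2 must be None iff edge is loose")

    @property
    def sides(self) -> tuple[Side, ...]:
        return (self.side1,) if self.side2 is None else (self.side1, self.side2)

    def multiplicity_at(self, side: Side) -> int:
        """Copies this edge contributes to ``side``'s balance sum, per edge copy."""
        return sum(1 for s in self.sides if s == side)

    def reverse(self) -> "GraphEdge":
        """The reverse-complement traversal view (sides swapped)."""
        if self.side2 is None:
            return self
        return replace(self, side1=self.side2, side2=self.side1)


class GenomeGraph:
    """Segments + edges + telomeric termini.

    Segment ids are positive integers assigned in (chrom, start) order;
    a signed id ``+s`` / ``-s`` denotes the forward / reverse-complement
    oriented vertex of segment ``s``.
    """

    def __init__(
        self,
        segments: Mapping[int, GenomicInterval],
        edges: Iterable[GraphEdge],
        termini: Iterable[Side],
    ) -> None:
        self.segments: dict[int, GenomicInterval] = dict(segments)
        self.edges: dict[int, GraphEdge] = {}
        self.termini: frozenset[Side] = frozenset(termini)
        self._incidence: dict[Side, list[int]] = {}
        for e in edges:
            self._add_edge(e)
        for side in self.termini:
            if side.seg not in self.segments:
                raise ValueError(f"terminus {side} references missing segment")

    def _add_edge(self, e: GraphEdge) -> None:
        if e.id in self.edges:
            raise ValueError(f"duplicate edge id {e.id}")
        for s in e.sides:
            if s.seg not in self.segments:
                raise ValueError(f"edge {e.id} references missing segment {s.seg}")
        self.edges[e.id] = e
        for s in set(e.sides):
            self._incidence.setdefault(s, []).append(e.id)

    # -- queries ---------------------------------------------------------
    def incident_edges(self, side: Side) -> list[GraphEdge]:
        return [self.edges[i] for i in self._incidence.get(side, [])]

    def interstitial_segments(self) -> list[int]:
        """Segments not abutting a telomeric terminus (V_I)."""
        return [
            s
            for s in sorted(self.segments)
            if Side(s, LEFT) not in self.termini and Side(s, RIGHT) not in self.termini
        ]

    def constrained_sides(self) -> list[Side]:
        """All non-telomeric segment sides, in (segment, side) order.

        Junction balance applies at each: every copy of a segment must
        have a neighbor on each side except across a telomere.
        """
        out = []
        for s in sorted(self.segments):
            for end in (LEFT, RIGHT):
                side = Side(s, end)
                if side not in self.termini:
                    out.append(side)
        return out

    def edges_of_kind(self, kind: str) -> list[GraphEdge]:
        return [e for e in self.edges.values() if e.kind == kind]

    def loose_edge_at(self, side: Side) -> GraphEdge | None:
        for e in self.incident_edges(side):
            if e.kind == LOOSE:
                return e
        return None

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in sorted(self.segments):
            seen.setdefault(self.segments[s].chrom, None)
        return list(seen)

    def segments_of_chrom(self, chrom: str) -> list[int]:
        return [s for s in sorted(self.segments) if self.segments[s].chrom == chrom]

    def side_of_breakend(self, bnd: Breakend) -> Side:
        """Resolve a breakend to the segment side it denotes."""
        for s in self.segments_of_chrom(bnd.chrom):
            iv = self.segments[s]
            if bnd.strand == "+" and iv.end == bnd.pos:
                return Side(s, RIGHT)
            if bnd.strand == "-" and iv.start == bnd.pos:
                return Side(s, LEFT)
        raise KeyError(f"breakend {bnd} is not on a segment boundary")

    def segment_at(self, chrom: str, pos: float) -> int:
        for s in self.segments_of_chrom(chrom):
            if self.segments[s].contains(pos):
                return s
        raise KeyError(f"no segment containing {chrom}:{pos}")

    # -- traversal -------------------------------------------------------
    @staticmethod
    def exit_side(vertex: int) -> Side:
        """Side through which an oriented vertex is exited when walking."""
        return Side(abs(vertex), RIGHT if vertex > 0 else LEFT)

    @staticmethod
    def entry_vertex(side: Side) -> int:
        """Oriented vertex obtained by entering a segment through ``side``."""
        return side.seg if side.end == LEFT else -side.seg

    def successors(self, vertex: int) -> list[tuple[GraphEdge, int]]:
        """(edge, next oriented vertex) pairs reachable from ``vertex``.

        Loose edges are not traversable.  A fold-back self-loop on the
        exit side is followed back into the reverse complement of the
        same segment.
        """
        out: list[tuple[GraphEdge, int]] = []
        exit_ = self.exit_side(vertex)
        for e in self.incident_edges(exit_):
            if e.kind == LOOSE:
                continue
            if e.side1 == e.side2:  # fold-back: re-enter through the same side
                out.append((e, -vertex))
            else:
                other = e.side2 if e.side1 == exit_ else e.side1
                out.append((e, self.entry_vertex(other)))
        return out

    # -- structural equality / copying ----------------------------------
    def _key(self):
        return (
            tuple(sorted(self.segments.items())),
            tuple(
                sorted(
                    (e.id, e.kind, tuple(sorted(e.sides)))
                    for e in self.edges.values()
                )
            ),
            tuple(sorted(self.termini)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeGraph):
            return NotImplemented
        return self._key() == other._key()

    def copy(self) -> "GenomeGraph":
        return GenomeGraph(
            dict(self.segments), [copy.copy(e) for e in self.edges.values()], self.termini
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kinds = {k: len(self.edges_of_kind(k)) for k in (REFERENCE, VARIANT, LOOSE)}
        return (
            f"GenomeGraph({len(self.segments)} segments, "
            f"{kinds[REFERENCE]} ref / {kinds[VARIANT]} var / {kinds[LOOSE]} loose edges)"
        )


@dataclass
class CopyAssignment:
    """Nonnegative integer copy number per segment and per edge (κ)."""

    vertex_cn: dict[int, int] = field(default_factory=dict)
    edge_cn: dict[int, int] = field(default_factory=dict)

    def side_sum(self, g: GenomeGraph, side: Side) -> int:
        return sum(
            self.edge_cn.get(e.id, 0) * e.multiplicity_at(side)
            for e in g.incident_edges(side)
        )

    def balance_violations(self, g: GenomeGraph) -> list[str]:
        """Junction-balance violations; empty iff κ is a valid assignment."""
        out = []
        for v, cn in self.vertex_cn.items():
            if cn < 0:
                out.append(f"segment {v}: negative copy number {cn}")
        for e, cn in self.edge_cn.items():
            if cn < 0:
                out.append(f"edge {e}: negative copy number {cn}")
        for side in g.constrained_sides():
            cn = self.vertex_cn.get(side.seg, 0)
            s = self.side_sum(g, side)
            if s != cn:
                out.append(
                    f"segment {side.seg} side {side.end}: "
                    f"κ(v)={cn} but incident edge sum={s}"
                )
        return out

    def total_loose(self, g: GenomeGraph) -> int:
        return sum(self.edge_cn.get(e.id, 0) for e in g.edges_of_kind(LOOSE))

    def nonzero_loose_edges(self, g: GenomeGraph) -> list[int]:
        return [e.id for e in g.edges_of_kind(LOOSE) if self.edge_cn.get(e.id, 0) > 0]


@dataclass
class GraphCompendium:
    """n structurally identical clone graphs plus their prototype G⁰.

    Clone graphs are replicas of the prototype; the projection map ``p``
    from clone elements to prototype elements is the identity on ids.
    """

    prototype: GenomeGraph
    clone_names: list[str]
    clones: dict[str, GenomeGraph] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.clones:
            self.clones = {name: self.prototype.copy() for name in self.clone_names}

    @property
    def n(self) -> int:
        return len(self.clone_names)

    def p_vertex(self, clone: str, v: int) -> int:
        """Project a clone (possibly signed) vertex id to the prototype."""
        if abs(v) not in self.clones[clone].segments:
            raise KeyError(f"vertex {v} not in clone {clone}")
        return v

    def p_edge(self, clone: str, e: int) -> int:
        if e not in self.clones[clone].edges:
            raise KeyError(f"edge {e} not in clone {clone}")
        return e


def reverse_complement(g: GenomeGraph) -> GenomeGraph:
    """The reverse-complement view of a genome graph.

    On the stored quotient representation this swaps each edge's side
    order (e → ē); the result compares equal to the input and applying
    the operation twice restores it elementwise.
    """
    return GenomeGraph(
        dict(g.segments), [e.reverse() for e in g.edges.values()], g.termini
    )


# ---------------------------------------------------------------------------
# prototype construction
# ---------------------------------------------------------------------------

def _merge_junctions(
    junctions: Sequence[Junction], merge_window: int
) -> list[Junction]:
    """Deduplicate junctions across clones.

    Exact-coordinate dedup by default; with ``merge_window`` > 0, a
    junction within ±window of an already-kept junction (both breakends,
    matching chrom/strand) collapses onto it.
    """
    kept: list[Junction] = []
    for j in junctions:
        j = j.canonical()
        match = None
        for k in kept:
            if j == k:
                match = k
                break
            if merge_window > 0:
                pairs = (
                    (j.bnd1, k.bnd1, j.bnd2, k.bnd2),
                    (j.bnd1, k.bnd2, j.bnd2, k.bnd1),
                )
                for a1, b1, a2, b2 in pairs:
                    if (
                        a1.chrom == b1.chrom
                        and a1.strand == b1.strand
                        and abs(a1.pos - b1.pos) <= merge_window
                        and a2.chrom == b2.chrom
                        and a2.strand == b2.strand
                        and abs(a2.pos - b2.pos) <= merge_window
                    ):
                        match = k
                        break
            if match:
                break
        if match is None:
            kept.append(j)
    return kept


def build_prototype(
    segment_sets: Mapping[str, Sequence[GenomicInterval]],
    junction_sets: Mapping[str, Sequence[Junction]],
    merge_window: int = 0,
) -> GraphCompendium:
    """Build the prototype graph G⁰ and its clone replicas.

    The prototype segmentation is the disjoint refinement of every
    clone's breakpoints plus every junction breakend; junctions are
    deduplicated across clones by exact breakend coordinates (or within
    ``merge_window`` bp).  Reference edges join genome-adjacent
    segments, every interstitial side receives a loose edge, and the
    outermost side of each chromosome is a telomeric terminus.
    """
    clone_names = list(segment_sets)
    if set(junction_sets) - set(segment_sets):
        raise ValueError("junction_sets contains clones absent from segment_sets")

    # chromosome extents must agree across clones
    extents: dict[str, tuple[int, int]] = {}
    for clone, ivs in segment_sets.items():
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in ivs:
            per_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, chrom_ivs in per_chrom.items():
            chrom_ivs.sort()
            for a, b in zip(chrom_ivs, chrom_ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"clone {clone}: overlapping intervals {a} and {b}"
                    )
            ext = (chrom_ivs[0].start, chrom_ivs[-1].end)
            if chrom in extents and extents[chrom] != ext:
                raise ValueError(
                    f"inconsistent extents for {chrom}: {extents[chrom]} vs {ext} "
                    f"(clone {clone})"
                )
            extents.setdefault(chrom, ext)

    all_junctions = [j for js in junction_sets.values() for j in js]
    merged = _merge_junctions(all_junctions, merge_window)

    # breakpoint union per chromosome
    breaks: dict[str, set[int]] = {c: {lo, hi} for c, (lo, hi) in extents.items()}
    for ivs in segment_sets.values():
        for iv in ivs:
            breaks[iv.chrom].update((iv.start, iv.end))
    for j in merged:
        for bnd in (j.bnd1, j.bnd2):
            if bnd.chrom not in extents:
                raise ValueError(f"junction breakend {bnd}: unknown chromosome")
            lo, hi = extents[bnd.chrom]
            if not (lo <= bnd.pos <= hi):
                raise ValueError(
                    f"junction breakend {bnd} outside chromosome extent [{lo},{hi}]"
                )
            breaks[bnd.chrom].add(bnd.pos)

    segments: dict[int, GenomicInterval] = {}
    termini: set[Side] = set()
    sid = 0
    chrom_order = sorted(extents)
    for chrom in chrom_order:
        bps = sorted(b for b in breaks[chrom] if extents[chrom][0] <= b <= extents[chrom][1])
        first = sid + 1
        for lo, hi in zip(bps, bps[1:]):
            sid += 1
            segments[sid] = GenomicInterval(chrom, lo, hi)
        termini.add(Side(first, LEFT))
        termini.add(Side(sid, RIGHT))

    g0 = GenomeGraph(segments, [], termini)

    edges: list[GraphEdge] = []
    eid = 0
    # reference edges between genome-adjacent segments
    for chrom in chrom_order:
        segs = g0.segments_of_chrom(chrom)
        for a, b in zip(segs, segs[1:]):
            eid += 1
            edges.append(GraphEdge(eid, REFERENCE, Side(a, RIGHT), Side(b, LEFT)))
    # variant edges from merged junctions
    for j in merged:
        try:
            s1 = g0.side_of_breakend(j.bnd1)
            s2 = g0.side_of_breakend(j.bnd2)
        except KeyError as exc:
            raise ValueError(f"junction {j}: {exc}") from exc
        eid += 1
        edges.append(GraphEdge(eid, VARIANT, s1, s2))
    # a loose edge at every interstitial side
    prototype = GenomeGraph(segments, edges, termini)
    for s in sorted(segments):
        for end in (LEFT, RIGHT):
            side = Side(s, end)
            if side in termini:
                continue
            eid += 1
            edges.append(GraphEdge(eid, LOOSE, side))

    prototype = GenomeGraph(segments, edges, termini)
    return GraphCompendium(prototype, clone_names)
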