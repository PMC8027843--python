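"""Synthetic post-telomere-crisis clone compendia with full ground truth.

The generator plays a telomere crisis forward on a small diploid genome:
one parental haplotype (the L allele of a "12"-like chromosome) loses
its telomere and undergoes breakage-fusion-bridge (BFB) cycles —
modeled as truncate-and-mirror: the walk is cut inside its terminal
span and the retained prefix appended with its own reverse complement
(sister-chromatid fusion), so the region proximal to the fold-back
focus doubles per cycle — optionally resolved by a stabilizing fusion
to an intact acrocentric partner arm.  Other lineages carry arm loss,
tandem duplication, or chromothripsis (shatter, drop, shuffle,
re-ligate).  Clones sit at the leaves of a known lineage tree; SNVs
accrete on branches with no back-mutation.

Emitted per clone: noisy binned depth in CN units (Gaussian noise on
the true total copy number), junction calls with Poisson read support
(subject to dropout, which creates loose ends), SNV allelic counts, and
phased parental het-SNP counts — plus a truth manifest (allele walks,
true κ on any segmentation, junction multiplicities, tree splits,
presence and phase truth) against which every pipeline stage can be
scored.

All event coordinates are multiples of the bin width so truth copy
number is piecewise constant on bins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import (
    Breakend,
    CopyAssignment,
    GenomeGraph,
    GenomicInterval,
    Junction,
    Side,
)
from .balance import DepthProfile
from .phasing import HetSiteTable
from .phylogeny import CloneSnvMatrix
from .walks import Walk

__all__ = [
    "Span",
    "Event",
    "LineageNode",
    "CrisisScenario",
    "SimulatedCohort",
    "rc_walk",
    "apply_fold_back",
    "apply_arm_loss",
    "apply_stabilizing_fusion",
    "apply_arm_fusion",
    "apply_tandem_dup",
    "apply_chromothripsis",
    "walk_junction_counts",
    "spans_to_vertices",
    "default_scenario",
    "archetype_cohort_scenario",
    "simulate",
]


@dataclass(frozen=True)
class Span:
    """Oriented genomic interval inside a haplotype walk.

    ``+`` traverses start → end (ascending coordinates).
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty span {self}")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def width(self) -> int:
        return self.end - self.start

    def rc(self) -> "Span":
        return replace(self, strand="-" if self.strand == "+" else "+")


def rc_walk(walk: Sequence[Span]) -> list[Span]:
    return [s.rc() for s in reversed(walk)]


def _truncate(walk: Sequence[Span], break_pos: int) -> list[Span]:
    term = walk[-1]
    if not (term.start < break_pos < term.end):
        raise ValueError(
            f"break {break_pos} not interior to terminal span {term}"
        )
    if term.strand == "+":
        new = replace(term, end=break_pos)
    else:
        new = replace(term, start=break_pos)
    return list(walk[:-1]) + [new]


def apply_fold_back(walk: Sequence[Span], break_pos: int) -> list[Span]:
    """One BFB cycle: break in the terminal span, fuse to sister.

    The retained prefix is mirrored (appended with its own reverse
    complement), creating a fold-back junction at ``break_pos`` and
    doubling every retained segment's copy on this allele.
    """
    kept = _truncate(walk, break_pos)
    return kept + rc_walk(kept)


def apply_arm_loss(walk: Sequence[Span], break_pos: int) -> list[Span]:
    """Terminal deletion: everything distal to the break is lost.

    The resulting end carries no telomere and no junction — it will
    surface as a loose end in the balanced graph.
    """
    return _truncate(walk, break_pos)


def apply_stabilizing_fusion(
    walk: Sequence[Span], break_pos: int, partner: Sequence[Span]
) -> list[Span]:
    """Resolve the unstable end: break, then capture an intact partner
    arm (translocation junction), acquiring its telomere."""
    return _truncate(walk, break_pos) + list(partner)


def apply_arm_fusion(walk: Sequence[Span], partner: Sequence[Span]) -> list[Span]:
    """End-to-end fusion of the walk terminus to a partner walk."""
    return list(walk) + list(partner)


def _find_containing(walk: Sequence[Span], chrom: str, start: int, end: int) -> int:
    for i, s in enumerate(walk):
        if s.chrom == chrom and s.start <= start and end <= s.end:
            return i
    raise ValueError(f"no walk span contains {chrom}:{start}-{end}")


def _splice(walk, i, plus_repr, strand):
    repl = plus_repr if strand == "+" else rc_walk(plus_repr)
    return list(walk[:i]) + repl + list(walk[i + 1 :])


def apply_tandem_dup(
    walk: Sequence[Span], chrom: str, start: int, end: int
) -> list[Span]:
    """Duplicate [start, end) in place within the span containing it."""
    i = _find_containing(walk, chrom, start, end)
    s = walk[i]
    plus = []
    if s.start < start:
        plus.append(Span(chrom, s.start, start, "+"))
    plus.append(Span(chrom, start, end, "+"))
    plus.append(Span(chrom, start, end, "+"))
    if end < s.end:
        plus.append(Span(chrom, end, s.end, "+"))
    return _splice(walk, i, plus, s.strand)


def apply_chromothripsis(
    walk: Sequence[Span],
    chrom: str,
    start: int,
    end: int,
    n_fragments: int,
    retain_prob: float,
    rng: np.random.Generator,
    snap: int = 10_000,
) -> list[Span]:
    """Shatter [start, end), drop/shuffle/flip fragments, re-ligate.

    Fragment boundaries are drawn uniformly and snapped to ``snap``;
    each fragment is kept with ``retain_prob``, kept fragments are
    permuted and randomly re-oriented.  Zero kept fragments is a clean
    deletion of the region.
    """
    if n_fragments < 2:
        raise ValueError("n_fragments must be >= 2")
    i = _find_containing(walk, chrom, start, end)
    s = walk[i]
    cuts: set[int] = set()
    while len(cuts) < n_fragments - 1:
        p = int(rng.integers(start + snap, end, size=1)[0]) // snap * snap
        if start < p < end:
            cuts.add(p)
    bounds = [start] + sorted(cuts) + [end]
    frags = [(a, b) for a, b in zip(bounds, bounds[1:])]
    kept = [f for f in frags if rng.random() < retain_prob]
    order = rng.permutation(len(kept))
    pieces = []
    for j in order:
        a, b = kept[j]
        pieces.append(Span(chrom, a, b, "+" if rng.random() < 0.5 else "-"))
    plus = []
    if s.start < start:
        plus.append(Span(chrom, s.start, start, "+"))
    plus.extend(pieces)
    if end < s.end:
        plus.append(Span(chrom, end, s.end, "+"))
    if not plus:
        raise ValueError("chromothripsis removed the entire haplotype walk")
    return _splice(walk, i, plus, s.strand)


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------

@dataclass
class Event:
    """One rearrangement operation on a haplotype walk."""

    kind: str  # fold_back | arm_loss | stabilizing_fusion | arm_fusion |
    #            tandem_dup | chromothripsis
    params: dict = field(default_factory=dict)
    hap: str | None = None  # default: scenario.target_hap


@dataclass
class LineageNode:
    """A node of the clone lineage tree; leaves are emitted clones.

    ``events`` and branch SNVs sit on the edge from the parent to this
    node; ``extra_snvs`` are explicitly placed branch SNVs
    (chrom, pos, ref, alt), e.g. a planted kataegis cluster.
    """

    name: str
    children: list["LineageNode"] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    extra_snvs: list[tuple] = field(default_factory=list)

    def leaves(self) -> list["LineageNode"]:
        if not self.children:
            return [self]
        return [l for c in self.children for l in c.leaves()]

    def walk_nodes(self) -> list["LineageNode"]:
        out = [self]
        for c in self.children:
            out.extend(c.walk_nodes())
        return out


@dataclass
class CrisisScenario:
    """Study conditions for one simulated compendium."""

    chrom_lengths: dict[str, int]
    root: LineageNode
    target_hap: str = "12_L"
    bin_width: int = 10_000
    depth_sd: float = 0.15
    dropout: float = 0.0
    forced_dropout: list[Junction] = field(default_factory=list)
    support_per_copy: float = 15.0
    snvs_per_branch: int = 200
    snv_depth: int = 60
    snv_error_rate: float = 1e-3
    presence_error: float = 0.005
    het_spacing: int = 4_000
    het_chroms: tuple[str, ...] = ("12",)
    hap_depth: int = 40
    n_loose_mates: int = 10
    mate_length: int = 150
    seed: int = 0


def _partner_walk(scenario: CrisisScenario, chrom: str, pos: int) -> list[Span]:
    return [Span(chrom, pos, scenario.chrom_lengths[chrom], "+")]


def default_scenario(seed: int = 0) -> CrisisScenario:
    """The 13-clone, 4-clade compendium used throughout.

    A 120-Mbp "12"-like chromosome (p-arm distal to 35 Mbp) and a
    45-Mbp acrocentric "21"-like partner.  Clades: unrearranged (2),
    arm loss of 12p on the L allele (2, providing the phasing loss
    clone), chromothripsis of 12p (1), and a BFB lineage (8) sharing a
    first fold-back at 8.0 Mbp — three clones stabilize immediately,
    five run two further fold-back cycles (8.7, 9.4 Mbp; proximal copy
    2³ = 8 on the allele) before the same stabilizing fusion to the
    partner arm at 20 Mbp.  A 3-SNV kataegis-like cluster is planted
    within 2 kbp of the first fold-back locus on the BFB trunk.
    """
    fuse = Event(
        "stabilizing_fusion",
        {"pos": 20_000_000, "partner_chrom": "21", "partner_pos": 6_000_000},
    )
    # fully binary lineage so the planted topology is NJ-recoverable
    bl_tail = LineageNode(
        "BL2",
        [
            LineageNode("F2"),
            LineageNode(
                "BL3",
                [
                    LineageNode("F3"),
                    LineageNode("BL4", [LineageNode("F4"), LineageNode("F5")]),
                ],
            ),
        ],
    )
    root = LineageNode(
        "root",
        children=[
            LineageNode(
                "P1",
                [
                    LineageNode("U_anc", [LineageNode("U1"), LineageNode("U2")]),
                    LineageNode(
                        "A_anc",
                        [LineageNode("A1"), LineageNode("A2")],
                        events=[Event("arm_loss", {"pos": 35_000_000})],
                    ),
                ],
            ),
            LineageNode(
                "P2",
                [
                    LineageNode(
                        "C1",
                        events=[
                            Event(
                                "chromothripsis",
                                {
                                    "start": 5_000_000,
                                    "end": 20_000_000,
                                    "n_fragments": 12,
                                    "retain_prob": 0.5,
                                },
                            )
                        ],
                    ),
                    LineageNode(
                        "B_anc",
                        [
                            LineageNode(
                                "BE_anc",
                                [
                                    LineageNode("E1"),
                                    LineageNode(
                                        "BE2",
                                        [LineageNode("E2"), LineageNode("E3")],
                                    ),
                                ],
                                events=[fuse],
                            ),
                            LineageNode(
                                "BL_anc",
                                [LineageNode("F1"), bl_tail],
                                events=[
                                    Event("fold_back", {"pos": 8_700_000}),
                                    Event("fold_back", {"pos": 9_400_000}),
                                    fuse,
                                ],
                            ),
                        ],
                        events=[Event("fold_back", {"pos": 8_000_000})],
                        extra_snvs=[
                            ("12", 8_000_200, "C", "T"),
                            ("12", 8_000_900, "G", "A"),
                            ("12", 8_001_600, "C", "A"),
                        ],
                    ),
                ],
            ),
        ],
    )
    return CrisisScenario(
        chrom_lengths={"12": 120_000_000, "21": 45_000_000},
        root=root,
        seed=seed,
    )


def archetype_cohort_scenario(
    n_clones: int = 118, seed: int = 0
) -> CrisisScenario:
    """A low-pass-style cohort spanning six copy-number archetypes.

    Unrearranged, 21q gain, 12p arm loss, early BFB, extended BFB, and
    chromothripsis clades sized to total ``n_clones``; depth only (no
    SNV/SNP emission), for clone clustering.
    """
    sizes = _archetype_sizes(n_clones)
    fuse = Event(
        "stabilizing_fusion",
        {"pos": 20_000_000, "partner_chrom": "21", "partner_pos": 6_000_000},
    )
    clades = {
        "wt": [],
        "gain21": [
            Event("tandem_dup", {"start": 1_000_000, "end": 44_000_000}, hap="21_L")
        ],
        "loss": [Event("arm_loss", {"pos": 35_000_000})],
        "early": [Event("fold_back", {"pos": 8_000_000}), fuse],
        "bfb": [
            Event("fold_back", {"pos": 8_000_000}),
            Event("fold_back", {"pos": 8_700_000}),
            Event("fold_back", {"pos": 9_400_000}),
            fuse,
        ],
        "ct": [
            Event(
                "chromothripsis",
                {"start": 5_000_000, "end": 20_000_000, "n_fragments": 12,
                 "retain_prob": 0.5},
            )
        ],
    }
    children = []
    for (clade, events), size in zip(clades.items(), sizes):
        children.append(
            LineageNode(
                f"{clade}_anc",
                [LineageNode(f"{clade}{i + 1}") for i in range(size)],
                events=events,
            )
        )
    return CrisisScenario(
        chrom_lengths={"12": 120_000_000, "21": 45_000_000},
        root=LineageNode("root", children),
        snvs_per_branch=0,
        het_chroms=(),
        seed=seed,
    )


def _archetype_sizes(n: int) -> list[int]:
    base = np.array([30, 20, 18, 20, 20, 10])
    sizes = np.maximum(1, (base * n / base.sum()).astype(int))
    while sizes.sum() < n:
        sizes[int(np.argmin(sizes))] += 1
    while sizes.sum() > n:
        sizes[int(np.argmax(sizes))] -= 1
    return [int(s) for s in sizes]


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

def _walk_breakends(span_a: Span, span_b: Span) -> tuple[Breakend, Breakend]:
    """Breakend pair of the adjacency between consecutive walk spans."""
    if span_a.strand == "+":
        b1 = Breakend(span_a.chrom, span_a.end, "+")
    else:
        b1 = Breakend(span_a.chrom, span_a.start, "-")
    if span_b.strand == "+":
        b2 = Breakend(span_b.chrom, span_b.start, "-")
    else:
        b2 = Breakend(span_b.chrom, span_b.end, "+")
    return b1, b2


def _is_reference_adjacency(span_a: Span, span_b: Span) -> bool:
    return (
        span_a.chrom == span_b.chrom
        and span_a.strand == span_b.strand
        and (
            (span_a.strand == "+" and span_a.end == span_b.start)
            or (span_a.strand == "-" and span_a.start == span_b.end)
        )
    )


def walk_junction_counts(walks: Iterable[Sequence[Span]]) -> Counter:
    """Variant-junction multiplicities across haplotype walks."""
    out: Counter = Counter()
    for walk in walks:
        for a, b in zip(walk, walk[1:]):
            if _is_reference_adjacency(a, b):
                continue
            b1, b2 = _walk_breakends(a, b)
            out[Junction(b1, b2).canonical()] += 1
    return out


def _walk_end_breakends(
    walk: Sequence[Span], chrom_lengths: Mapping[str, int]
) -> list[Breakend]:
    """Non-telomeric walk termini (future loose ends)."""
    out = []
    first, last = walk[0], walk[-1]
    # entry end of the walk
    if first.strand == "+":
        if first.start != 0:
            out.append(Breakend(first.chrom, first.start, "-"))
    else:
        if first.end != chrom_lengths[first.chrom]:
            out.append(Breakend(first.chrom, first.end, "+"))
    # exit end
    if last.strand == "+":
        if last.end != chrom_lengths[last.chrom]:
            out.append(Breakend(last.chrom, last.end, "+"))
    else:
        if last.start != 0:
            out.append(Breakend(last.chrom, last.start, "-"))
    return out


def merge_reference_adjacent(spans: Sequence[Span]) -> list[Span]:
    """Fuse consecutive spans that continue the reference contiguously.

    A shuffle can by chance re-ligate two fragments in their original
    order and orientation; the junction vanishes and downstream graphs
    see one segment, so the walk should too.
    """
    out: list[Span] = []
    for sp in spans:
        if out and _is_reference_adjacency(out[-1], sp):
            prev = out[-1]
            out[-1] = Span(
                prev.chrom, min(prev.start, sp.start), max(prev.end, sp.end), prev.strand
            )
        else:
            out.append(sp)
    return out


def spans_to_vertices(graph: GenomeGraph, spans: Sequence[Span]) -> list[int]:
    """Project a span walk onto graph segments as signed vertex ids.

    Span boundaries (after fusing reference-adjacent spans) must
    coincide with segment boundaries.
    """
    verts: list[int] = []
    for sp in merge_reference_adjacent(spans):
        segs = [
            s
            for s in graph.segments_of_chrom(sp.chrom)
            if graph.segments[s].start >= sp.start and graph.segments[s].end <= sp.end
        ]
        covered = sum(graph.segments[s].width for s in segs)
        if covered != sp.width:
            raise ValueError(f"span {sp} not tiled by graph segments")
        verts.extend(segs if sp.strand == "+" else [-s for s in reversed(segs)])
    return verts


# ---------------------------------------------------------------------------
# cohort emission
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Everything a simulated compendium emits, plus its ground truth."""

    scenario: CrisisScenario
    seed: int
    clone_names: list[str]
    haplotypes: dict[str, dict[str, list[Span]]]  # clone -> hap -> walk
    depth: dict[str, DepthProfile]
    junctions: list[Junction]
    junction_support: dict[str, dict[Junction, int]]
    true_junction_counts: dict[str, Counter]
    snv_matrix: CloneSnvMatrix
    snv_truth: pd.DataFrame  # chrom pos ref alt branch + presence truth cols
    het_table: HetSiteTable
    het_phase_truth: np.ndarray  # True where alt allele is on L
    loose_mates: dict[str, dict[Breakend, list[str]]]
    branch_clades: dict[str, frozenset[str]]

    # -- truth helpers ---------------------------------------------------
    def clone_walks(self, clone: str) -> list[list[Span]]:
        return list(self.haplotypes[clone].values())

    def clone_segment_intervals(self, clone: str) -> list[GenomicInterval]:
        """The clone's breakpoint-refined segmentation of the genome."""
        breaks: dict[str, set[int]] = {
            c: {0, L} for c, L in self.scenario.chrom_lengths.items()
        }
        for walk in self.clone_walks(clone):
            for sp in walk:
                breaks[sp.chrom].update((sp.start, sp.end))
        out = []
        for chrom in sorted(breaks):
            bps = sorted(breaks[chrom])
            out.extend(
                GenomicInterval(chrom, a, b) for a, b in zip(bps, bps[1:])
            )
        return out

    def truth_vertex_cn(self, clone: str, graph: GenomeGraph) -> dict[int, int]:
        cn = {s: 0 for s in graph.segments}
        for walk in self.clone_walks(clone):
            for v in spans_to_vertices(graph, walk):
                cn[abs(v)] += 1
        return cn

    def truth_assignment(self, clone: str, graph: GenomeGraph) -> CopyAssignment:
        """Planted κ on ``graph``: vertices, edges, and loose ends."""
        vcn = self.truth_vertex_cn(clone, graph)
        ecn = {e: 0 for e in graph.edges}
        for walk in self.clone_walks(clone):
            verts = spans_to_vertices(graph, walk)
            for v, w in zip(verts, verts[1:]):
                exit_side = graph.exit_side(v)
                entry_side = Side(abs(w), "L" if w > 0 else "R")
                edge = None
                for e in graph.incident_edges(exit_side):
                    if e.kind == "loose":
                        continue
                    if {e.side1, e.side2} == {exit_side, entry_side} or (
                        e.side1 == e.side2 == exit_side == entry_side
                    ):
                        edge = e
                        break
                if edge is None:
                    raise ValueError(
                        f"no graph edge for adjacency {v}->{w} in clone {clone}"
                    )
                ecn[edge.id] += 1
            for bnd in _walk_end_breakends(walk, self.scenario.chrom_lengths):
                side = graph.side_of_breakend(bnd)
                le = graph.loose_edge_at(side)
                if le is not None:
                    ecn[le.id] += 1
        return CopyAssignment(vcn, ecn)

    def allele_walk(self, clone: str, graph: GenomeGraph, hap: str) -> Walk:
        """The planted haplotype as a Walk over ``graph`` (open)."""
        spans = self.haplotypes[clone][hap]
        verts = spans_to_vertices(graph, spans)
        truth = self.truth_assignment(clone, graph)  # for edge resolution only
        edges = []
        for v, w in zip(verts, verts[1:]):
            exit_side = graph.exit_side(v)
            entry_side = Side(abs(w), "L" if w > 0 else "R")
            eid = None
            for e in graph.incident_edges(exit_side):
                if e.kind == "loose":
                    continue
                if {e.side1, e.side2} == {exit_side, entry_side} or (
                    e.side1 == e.side2 == exit_side == entry_side
                ):
                    eid = e.id
                    break
            if eid is None:
                raise ValueError(f"unresolved adjacency {v}->{w}")
            edges.append(eid)
        return Walk(tuple(verts), tuple(edges), False)

    def true_splits(self) -> set[frozenset[frozenset[str]]]:
        """Nontrivial bipartitions of the planted tree over clone names."""
        leaves = frozenset(self.clone_names)
        out = set()
        for clade in self.branch_clades.values():
            if 1 < len(clade) < len(leaves) - 1:
                out.add(frozenset({clade, leaves - clade}))
        return out

    def presence_truth(self) -> np.ndarray:
        cols = [f"in_{c}" for c in self.clone_names]
        return self.snv_truth[cols].to_numpy(bool).T

    def truth_total_cn_bins(self, clone: str) -> dict[str, np.ndarray]:
        """True total copy number per depth bin, per chromosome."""
        bw = self.scenario.bin_width
        out = {}
        for chrom, L in self.scenario.chrom_lengths.items():
            n_bins = int(np.ceil(L / bw))
            out[chrom] = _coverage_per_bin(
                self.haplotypes[clone].values(), chrom, n_bins, bw
            )
        return out

    def bfb_focus_proximal_copy(self, clone: str) -> int:
        """Allele-level copy of the region proximal to the fold-back
        focus (just inside the first break) on the target haplotype."""
        chrom = self.scenario.target_hap.split("_")[0]
        hap = [
            sp
            for sp in self.haplotypes[clone][self.scenario.target_hap]
            if sp.chrom == chrom
        ]
        # probe just proximal (higher coordinate) of the first break
        first_break = min(sp.start for sp in hap)
        probe = first_break + 1
        return sum(1 for sp in hap if sp.start <= probe < sp.end)


def _apply_event(
    genome: dict[str, list[Span]],
    ev: Event,
    scenario: CrisisScenario,
    rng: np.random.Generator,
) -> None:
    hap = ev.hap or scenario.target_hap
    walk = genome[hap]
    p = ev.params
    if ev.kind == "fold_back":
        genome[hap] = apply_fold_back(walk, p["pos"])
    elif ev.kind == "arm_loss":
        genome[hap] = apply_arm_loss(walk, p["pos"])
    elif ev.kind == "stabilizing_fusion":
        genome[hap] = apply_stabilizing_fusion(
            walk, p["pos"], _partner_walk(scenario, p["partner_chrom"], p["partner_pos"])
        )
    elif ev.kind == "arm_fusion":
        genome[hap] = apply_arm_fusion(
            walk, _partner_walk(scenario, p["partner_chrom"], p["partner_pos"])
        )
    elif ev.kind == "tandem_dup":
        chrom = p.get("chrom", hap.split("_")[0])
        genome[hap] = apply_tandem_dup(walk, chrom, p["start"], p["end"])
    elif ev.kind == "chromothripsis":
        chrom = p.get("chrom", hap.split("_")[0])
        genome[hap] = apply_chromothripsis(
            walk, chrom, p["start"], p["end"], p["n_fragments"],
            p["retain_prob"], rng, snap=scenario.bin_width,
        )
    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")


def _initial_genome(scenario: CrisisScenario) -> dict[str, list[Span]]:
    genome: dict[str, list[Span]] = {}
    target_chrom = scenario.target_hap.split("_")[0]
    for chrom, L in scenario.chrom_lengths.items():
        for allele in ("L", "R"):
            hap = f"{chrom}_{allele}"
            if hap == scenario.target_hap:
                # ordered from the stable (q-telomere) end; the unstable
                # p-terminus is the walk's terminal end
                genome[hap] = [Span(chrom, 0, L, "-")]
            else:
                genome[hap] = [Span(chrom, 0, L, "+")]
    return genome


def _coverage_per_bin(
    walks: Iterable[Sequence[Span]], chrom: str, n_bins: int, bw: int
) -> np.ndarray:
    cov = np.zeros(n_bins, dtype=np.int64)
    for walk in walks:
        for sp in walk:
            if sp.chrom != chrom:
                continue
            cov[sp.start // bw : sp.end // bw] += 1
    return cov


def simulate(scenario: CrisisScenario, seed: int | None = None) -> SimulatedCohort:
    """Run the scenario and emit the full per-clone dataset + truth."""
    seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    (
        ss_events, ss_depth, ss_support, ss_snv, ss_het, ss_mates,
    ) = ss.spawn(6)
    rng_events = np.random.default_rng(ss_events)
    rng_depth = np.random.default_rng(ss_depth)
    rng_support = np.random.default_rng(ss_support)
    rng_snv = np.random.default_rng(ss_snv)
    rng_het = np.random.default_rng(ss_het)
    rng_mates = np.random.default_rng(ss_mates)

    # --- lineage traversal: genomes + branch SNVs -----------------------
    leaves = scenario.root.leaves()
    clone_names = [l.name for l in leaves]
    genomes: dict[str, dict[str, list[Span]]] = {}
    branch_clades: dict[str, frozenset[str]] = {}
    snv_records: list[dict] = []

    chroms = sorted(scenario.chrom_lengths)
    lengths = np.array([scenario.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    bases = np.array(list("ACGT"))

    def branch_snvs(node: LineageNode) -> list[dict]:
        recs = []
        n = scenario.snvs_per_branch
        if n > 0:
            idx = rng_snv.choice(len(chroms), size=n, p=chrom_p)
            for ci in idx:
                chrom = chroms[ci]
                pos = int(rng_snv.integers(1, scenario.chrom_lengths[chrom]))
                ref = str(rng_snv.choice(bases))
                alt = str(rng_snv.choice([b for b in "ACGT" if b != ref]))
                recs.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                             "branch": node.name})
        for chrom, pos, ref, alt in node.extra_snvs:
            recs.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                         "branch": node.name})
        return recs

    def traverse(node: LineageNode, genome: dict[str, list[Span]]):
        for ev in node.events:
            _apply_event(genome, ev, scenario, rng_events)
        if node is not scenario.root:
            clade = frozenset(l.name for l in node.leaves())
            branch_clades[node.name] = clade
            for rec in branch_snvs(node):
                rec["clade"] = clade
                snv_records.append(rec)
        if not node.children:
            genomes[node.name] = genome
            return
        for child in node.children:
            traverse(child, {h: list(w) for h, w in genome.items()})

    traverse(scenario.root, _initial_genome(scenario))

    # --- depth ----------------------------------------------------------
    bw = scenario.bin_width
    depth: dict[str, DepthProfile] = {}
    bin_frames = {
        c: np.arange(0, scenario.chrom_lengths[c], bw) for c in chroms
    }
    for clone in clone_names:
        ch_l, st_l, en_l, va_l = [], [], [], []
        for chrom in chroms:
            starts = bin_frames[chrom]
            n_bins = len(starts)
            cov = _coverage_per_bin(genomes[clone].values(), chrom, n_bins, bw)
            noise = (
                rng_depth.normal(0.0, scenario.depth_sd, size=n_bins)
                if scenario.depth_sd > 0
                else np.zeros(n_bins)
            )
            vals = np.maximum(cov + noise, 0.0)
            ch_l.extend([chrom] * n_bins)
            st_l.append(starts)
            en_l.append(np.minimum(starts + bw, scenario.chrom_lengths[chrom]))
            va_l.append(vals)
        depth[clone] = DepthProfile(
            np.array(ch_l, object), np.concatenate(st_l),
            np.concatenate(en_l), np.concatenate(va_l),
        )

    # --- junctions + support ---------------------------------------------
    true_counts = {
        c: walk_junction_counts(genomes[c].values()) for c in clone_names
    }
    all_junctions = sorted(
        {j for cnt in true_counts.values() for j in cnt},
        key=lambda j: (j.canonical().bnd1, j.canonical().bnd2),
    )
    forced = {j.canonical() for j in scenario.forced_dropout}
    support: dict[str, dict[Junction, int]] = {}
    for clone in clone_names:
        sup = {}
        for j in all_junctions:
            mult = true_counts[clone].get(j, 0)
            if mult == 0:
                sup[j] = 0
                continue
            if j in forced or rng_support.random() < scenario.dropout:
                sup[j] = 0
            else:
                sup[j] = int(rng_support.poisson(scenario.support_per_copy * mult))
        support[clone] = sup

    # --- SNV counts -------------------------------------------------------
    snv_truth = pd.DataFrame(
        snv_records,
        columns=["chrom", "pos", "ref", "alt", "branch", "clade"],
    )
    if len(snv_truth):
        snv_truth = snv_truth.sort_values(["chrom", "pos"]).reset_index(drop=True)
    n_sites = len(snv_truth)
    n_clones = len(clone_names)
    present = np.zeros((n_clones, n_sites), dtype=bool)
    for j in range(n_sites):
        clade = snv_truth["clade"].iloc[j]
        for i, c in enumerate(clone_names):
            present[i, j] = c in clade
    presence_cols = pd.DataFrame(
        {f"in_{c}": present[i] for i, c in enumerate(clone_names)},
        index=snv_truth.index,
    )
    snv_truth = pd.concat([snv_truth.drop(columns=["clade"]), presence_cols], axis=1)

    flips = rng_snv.random((n_clones, n_sites)) < scenario.presence_error
    emitted = present ^ flips
    depth_mat = rng_snv.poisson(scenario.snv_depth, size=(n_clones, n_sites))
    vaf = np.where(emitted, 0.5, scenario.snv_error_rate)
    alt = rng_snv.binomial(depth_mat, vaf)
    ref = depth_mat - alt
    sites = snv_truth[["chrom", "pos", "ref", "alt"]].copy()
    sites["mq_pass"] = True
    sites["score_pass"] = True
    snv_matrix = CloneSnvMatrix(sites, ref, alt, clone_names)

    # --- parental het SNPs ----------------------------------------------
    het_rows = []
    for chrom in scenario.het_chroms:
        L = scenario.chrom_lengths[chrom]
        for pos in range(scenario.het_spacing // 2, L, scenario.het_spacing):
            het_rows.append((chrom, pos))
    n_het = len(het_rows)
    het_sites = pd.DataFrame(het_rows, columns=["chrom", "pos"])
    if n_het:
        het_sites["ref"] = rng_het.choice(bases, size=n_het)
        het_sites["alt"] = [
            str(rng_het.choice([b for b in "ACGT" if b != r]))
            for r in het_sites["ref"]
        ]
        het_sites["parental_ref"] = rng_het.poisson(scenario.hap_depth, n_het)
        het_sites["parental_alt"] = rng_het.poisson(scenario.hap_depth, n_het)
    else:
        for col in ("ref", "alt", "parental_ref", "parental_alt"):
            het_sites[col] = []
    alt_on_L = rng_het.random(n_het) < 0.5

    het_ref = np.zeros((n_clones, n_het), dtype=np.int64)
    het_alt = np.zeros((n_clones, n_het), dtype=np.int64)
    for i, clone in enumerate(clone_names):
        for chrom in scenario.het_chroms:
            sel = np.nonzero((het_sites["chrom"] == chrom).to_numpy())[0]
            if len(sel) == 0:
                continue
            n_bins = len(bin_frames[chrom])
            cov_L = _coverage_per_bin(
                [w for h, w in genomes[clone].items() if h.endswith("_L")],
                chrom, n_bins, bw,
            )
            cov_R = _coverage_per_bin(
                [w for h, w in genomes[clone].items() if h.endswith("_R")],
                chrom, n_bins, bw,
            )
            pos = het_sites["pos"].to_numpy()[sel]
            bins = pos // bw
            lam_L = scenario.hap_depth * cov_L[bins]
            lam_R = scenario.hap_depth * cov_R[bins]
            l_counts = rng_het.poisson(lam_L)
            r_counts = rng_het.poisson(lam_R)
            a_on_l = alt_on_L[sel]
            het_alt[i, sel] = np.where(a_on_l, l_counts, r_counts)
            het_ref[i, sel] = np.where(a_on_l, r_counts, l_counts)
    het_table = HetSiteTable(het_sites, het_ref, het_alt, clone_names)

    # --- loose-end mates -------------------------------------------------
    loose_mates: dict[str, dict[Breakend, list[str]]] = {}
    for clone in clone_names:
        ends: dict[Breakend, list[str]] = {}
        for walk in genomes[clone].values():
            for bnd in _walk_end_breakends(walk, scenario.chrom_lengths):
                seqs = [
                    "".join(rng_mates.choice(bases, size=scenario.mate_length))
                    for _ in range(scenario.n_loose_mates)
                ]
                ends[bnd] = seqs
        loose_mates[clone] = ends

    return SimulatedCohort(
        scenario=scenario,
        seed=seed,
        clone_names=clone_names,
        haplotypes=genomes,
        depth=depth,
        junctions=all_junctions,
        junction_support=support,
        true_junction_counts=true_counts,
        snv_matrix=snv_matrix,
        snv_truth=snv_truth,
        het_table=het_table,
        het_phase_truth=alt_on_L,
        loose_mates=loose_mates,
        branch_clades=branch_clades,
    )
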