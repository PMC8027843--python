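"""Walk enumeration, copy decomposition, and cycle splicing."""

import itertools

import pytest

from crisisgraph.exhaustive import exhaustive_decompose_objective
from crisisgraph.graph import (
    Breakend,
    CopyAssignment,
    GenomicInterval,
    Junction,
    build_prototype,
    reverse_complement,
)
from crisisgraph.walks import (
    Walk,
    combine_walks,
    conservation_violations,
    decompose_joint,
    enumerate_minimal_walks,
    WalkEnumerationError,
    search_merge_recipe,
)


def deletion_setup():
    j = Junction(Breakend("1", 10_000, "+"), Breakend("1", 20_000, "-"))
    comp = build_prototype({"c": [GenomicInterval("1", 0, 30_000)]}, {"c": [j]})
    g = comp.prototype
    loose = {e.id: 0 for e in g.edges_of_kind("loose")}
    k = CopyAssignment({1: 2, 2: 1, 3: 2}, {1: 1, 2: 1, 3: 1, **loose})
    return comp, g, k


def dup_setup():
    j = Junction(Breakend("1", 20_000, "+"), Breakend("1", 10_000, "-"))
    comp = build_prototype(
        {"c": [GenomicInterval("1", 0, 30_000)]}, {"c": [j]}
    )
    g = comp.prototype
    loose = {e.id: 0 for e in g.edges_of_kind("loose")}
    k = CopyAssignment({1: 1, 2: 2, 3: 1}, {1: 1, 2: 1, 3: 1, **loose})
    return comp, g, k


class TestEnumeration:
    def test_linear_chromosome_single_path(self):
        comp = build_prototype({"c": [GenomicInterval("1", 0, 30_000)]}, {"c": []})
        k = CopyAssignment({s: 1 for s in comp.prototype.segments}, {e: 1 for e in comp.prototype.edges})
        ws = enumerate_minimal_walks(comp.prototype, k)
        assert len(ws.paths) == 1 and len(ws.cycles) == 0
        assert len(ws.paths[0]) == len(comp.prototype.segments)

    def test_deletion_toy_two_paths(self):
        _, g, k = deletion_setup()
        ws = enumerate_minimal_walks(g, k)
        lengths = sorted(len(w) for w in ws.paths)
        assert lengths == [2, 3] and not ws.cycles

    def test_tandem_dup_path_plus_cycle(self):
        _, g, k = dup_setup()
        ws = enumerate_minimal_walks(g, k)
        assert len(ws.paths) == 1 and len(ws.cycles) == 1
        assert len(ws.cycles[0]) == 1  # the duplicated segment alone

    def test_rc_graph_gives_identical_canonical_walks(self):
        _, g, k = deletion_setup()
        a = enumerate_minimal_walks(g, k)
        b = enumerate_minimal_walks(reverse_complement(g), k)
        assert a.keys() == b.keys()

    def test_walk_cap_raises(self, clean_cohort, clean_fit):
        comp, _, sol = clean_fit
        with pytest.raises(WalkEnumerationError, match="max_walks"):
            enumerate_minimal_walks(
                comp.clones["C1"], sol.assignments["C1"], max_walks=3,
                region=("12", 0, 35_000_000),
            )


class TestDecompose:
    def test_single_linear_path(self):
        comp = build_prototype({"c": [GenomicInterval("1", 0, 30_000)]}, {"c": []})
        g = comp.prototype
        k = CopyAssignment({s: 1 for s in g.segments}, {e: 1 for e in g.edges})
        ws = enumerate_minimal_walks(g, k)
        dec = decompose_joint(comp, {"c": k}, {"c": ws})
        assert dec.objective == 1
        assert dec.assignments["c"].phi[0] == 1

    def test_deletion_matches_brute_force(self):
        comp, g, k = deletion_setup()
        ws = enumerate_minimal_walks(g, k)
        dec = decompose_joint(comp, {"c": k}, {"c": ws})
        assert dec.status == "optimal" and dec.objective == 2
        assert conservation_violations(g, k, ws.walks, dec.assignments["c"]) == []
        targets = {("v", s): k.vertex_cn[s] for s in g.segments}
        targets.update({("e", e): k.edge_cn.get(e, 0) for e in g.edges})
        oracle = exhaustive_decompose_objective(
            {"c": ws.keys()}, {"c": [w.delta() for w in ws.walks]}, {"c": targets}, 4
        )
        assert dec.objective == oracle

    def test_shared_allele_counted_once(self):
        j = Junction(Breakend("1", 10_000, "+"), Breakend("1", 20_000, "-"))
        comp = build_prototype(
            {c: [GenomicInterval("1", 0, 30_000)] for c in "ab"}, {c: [j] for c in "ab"}
        )
        loose = {e.id: 0 for e in comp.prototype.edges_of_kind("loose")}
        k = CopyAssignment({1: 2, 2: 1, 3: 2}, {1: 1, 2: 1, 3: 1, **loose})
        sols = {c: k for c in "ab"}
        walksets = {
            c: enumerate_minimal_walks(comp.clones[c], k) for c in "ab"
        }
        joint = decompose_joint(comp, sols, walksets)
        assert joint.objective == 2  # both alleles shared via the prototype
        independent = sum(
            decompose_joint(comp, {c: k}, {c: walksets[c]}).objective for c in "ab"
        )
        assert independent == 4

    @staticmethod
    def _three_segment_graph():
        return build_prototype(
            {"c": [GenomicInterval("1", 0, 10_000), GenomicInterval("1", 10_000, 20_000),
                   GenomicInterval("1", 20_000, 30_000)]},
            {"c": []},
        )

    def test_infeasible_when_kappa_not_expressible(self):
        # κ(B)=2 on a plain linear graph: the only walk covers B once
        comp = self._three_segment_graph()
        g = comp.prototype
        loose = {e.id: 0 for e in g.edges_of_kind("loose")}
        k_enum = CopyAssignment({1: 1, 2: 1, 3: 1}, {1: 1, 2: 1, **loose})
        ws = enumerate_minimal_walks(g, k_enum)
        k_bad = CopyAssignment({1: 1, 2: 2, 3: 1}, {1: 1, 2: 1, **loose})
        dec = decompose_joint(comp, {"c": k_bad}, {"c": ws})
        assert dec.status == "infeasible"

    def test_infeasible_reports_uncovered_elements(self):
        # copy on a loose edge no enumerated walk terminates at
        comp = self._three_segment_graph()
        g = comp.prototype
        loose_ids = [e.id for e in g.edges_of_kind("loose")]
        loose = {e: 0 for e in loose_ids}
        k_enum = CopyAssignment({1: 1, 2: 1, 3: 1}, {1: 1, 2: 1, **loose})
        ws = enumerate_minimal_walks(g, k_enum)
        bad_edges = {1: 1, 2: 1, **loose}
        bad_edges[loose_ids[0]] = 1
        dec = decompose_joint(comp, {"c": CopyAssignment({1: 1, 2: 1, 3: 1}, bad_edges)}, {"c": ws})
        assert dec.status == "infeasible"
        assert ("e", loose_ids[0]) in dec.unmet["c"]


class TestCombine:
    def test_tandem_dup_splice(self):
        comp, g, k = dup_setup()
        ws = enumerate_minimal_walks(g, k)
        dec = decompose_joint(comp, {"c": k}, {"c": ws})
        ci = next(i for i, w in enumerate(ws.walks) if w.closed)
        pi = next(i for i, w in enumerate(ws.walks) if not w.closed)
        haps, book = combine_walks(ws.walks, dec.assignments["c"], [(ci, pi, 2, 0)])
        counts = [abs(v) for v in haps[pi].vertices]
        assert counts.count(2) == 2  # A·B·B·C up to orientation
        assert book.phi[ci] == 0

    def test_no_merges_identity(self):
        _, g, k = deletion_setup()
        ws = enumerate_minimal_walks(g, k)
        phi = decompose_joint(
            build_prototype({"c": [GenomicInterval("1", 0, 30_000)]},
                            {"c": [Junction(Breakend("1", 10_000, "+"), Breakend("1", 20_000, "-"))]}),
            {"c": k}, {"c": ws}
        ).assignments["c"]
        haps, book = combine_walks(ws.walks, phi, [])
        assert [w.vertices for w in haps] == [w.vertices for w in ws.walks]

    def test_anchor_not_shared_rejected(self):
        comp, g, k = dup_setup()
        ws = enumerate_minimal_walks(g, k)
        ci = next(i for i, w in enumerate(ws.walks) if w.closed)
        pi = next(i for i, w in enumerate(ws.walks) if not w.closed)
        phi = decompose_joint(comp, {"c": k}, {"c": ws}).assignments["c"]
        with pytest.raises(ValueError, match="anchor"):
            combine_walks(ws.walks, phi, [(ci, pi, 3, 0)])

    def test_copy_bookkeeping_cannot_go_negative(self):
        comp, g, k = dup_setup()
        ws = enumerate_minimal_walks(g, k)
        ci = next(i for i, w in enumerate(ws.walks) if w.closed)
        pi = next(i for i, w in enumerate(ws.walks) if not w.closed)
        phi = decompose_joint(comp, {"c": k}, {"c": ws}).assignments["c"]
        with pytest.raises(ValueError, match="copies"):
            combine_walks(ws.walks, phi, [(ci, pi, 2, 0), (ci, pi, 2, 0)])


class TestBfbSplice:
    def test_splice_recovers_planted_allele(self, clean_cohort, clean_fit):
        """Fold-back cycles spliced into the backbone path rebuild the
        planted BFB allele's exact element sequence."""
        comp, _, sol = clean_fit
        region = ("12", 0, 35_000_000)
        clone = "F1"
        g = comp.clones[clone]
        ws = enumerate_minimal_walks(g, sol.assignments[clone], region=region)
        dec = decompose_joint(comp, {clone: sol.assignments[clone]}, {clone: ws}, region=region)
        allele = clean_cohort.allele_walk(clone, g, "12_L")
        chrom, lo, hi = region
        scope = {
            s for s in g.segments
            if g.segments[s].chrom == chrom and g.segments[s].start < hi
        }
        keep = [i for i, v in enumerate(allele.vertices) if abs(v) in scope]
        i0, i1 = keep[0], keep[-1]
        target_v = allele.vertices[i0 : i1 + 1]
        target_e = allele.edges[i0:i1]
        recipe = search_merge_recipe(
            ws.walks, dec.assignments[clone], target_v, target_e
        )
        assert recipe is not None and len(recipe) >= 2
        haps, _ = combine_walks(ws.walks, dec.assignments[clone], recipe)
        spliced = {(w.vertices, w.edges) for w in haps if not w.closed}
        rc = (tuple(-v for v in reversed(target_v)), tuple(reversed(target_e)))
        assert (target_v, target_e) in spliced or rc in spliced
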