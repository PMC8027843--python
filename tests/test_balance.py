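"""Junction balancing: residual arithmetic, single/joint fits, bounds."""

import math

import numpy as np
import pytest

from crisisgraph.balance import (
    BalanceConfig,
    DepthProfile,
    EdgeBounds,
    depth_residual,
    derive_edge_bounds,
    fit_joint,
    fit_single,
)
from crisisgraph.exhaustive import (
    exhaustive_joint_objective,
    exhaustive_single_objective,
    random_toy_compendium,
)
from crisisgraph.graph import (
    Breakend,
    CopyAssignment,
    GenomicInterval,
    Junction,
    build_prototype,
    reverse_complement,
)
from conftest import flat_profile


class TestDepthResidual:
    def test_zero_when_means_match(self, deletion_toy):
        comp, _, x = deletion_toy
        k = CopyAssignment({1: 2, 2: 1, 3: 2}, {})
        assert depth_residual(comp.prototype, k, x) == 0.0

    def test_hand_arithmetic(self):
        comp = build_prototype({"c": [GenomicInterval("1", 0, 4_000)]}, {"c": []})
        x = flat_profile([1.5], seg_bins=4)
        k = CopyAssignment({1: 2}, {})
        # 4 bins x (2 - 1.5)^2
        assert depth_residual(comp.prototype, k, x) == pytest.approx(1.0)

    def test_invariant_under_reverse_complement(self, deletion_toy):
        comp, _, x = deletion_toy
        k = CopyAssignment({1: 2, 2: 2, 3: 1}, {})
        g = comp.prototype
        assert depth_residual(g, k, x) == depth_residual(reverse_complement(g), k, x)


class TestFitSingle:
    def test_flat_diploid(self):
        comp = build_prototype(
            {"c": [GenomicInterval("1", 0, 30_000)]}, {"c": []}
        )
        x = flat_profile([2.0, 2.0, 2.0])
        sol = fit_single(comp.prototype, x, cfg=BalanceConfig(cn_cap=4))
        assert sol.solver_status == "optimal"
        assert sol.objective == pytest.approx(0.0, abs=1e-5)
        assert all(v == 2 for v in sol.assignments["sample"].vertex_cn.values())

    def test_supported_deletion(self, deletion_toy):
        comp, _, x = deletion_toy
        sol = fit_single(comp.prototype, x, cfg=BalanceConfig(slack_penalty=500, cn_cap=4))
        k = sol.assignments["sample"]
        assert k.vertex_cn == {1: 2, 2: 1, 3: 2}
        del_edge = comp.prototype.edges_of_kind("variant")[0]
        assert k.edge_cn[del_edge.id] == 1
        assert k.total_loose(comp.prototype) == 0
        assert sol.objective == pytest.approx(0.0, abs=1e-4)

    def test_unsupported_deletion_pays_loose_ends(self):
        """With a long middle segment the loose-end solution beats
        flattening; the optimum takes one loose end per flank."""
        j = Junction(Breakend("1", 10_000, "+"), Breakend("1", 20_000, "-"))
        comp = build_prototype({"c": [GenomicInterval("1", 0, 30_000)]}, {"c": [j]})
        x = flat_profile([2.0, 1.0, 2.0])
        u = EdgeBounds({comp.prototype.edges_of_kind("variant")[0].id: 0.0})
        cfg = BalanceConfig(slack_penalty=2.0, cn_cap=4)
        sol = fit_single(comp.prototype, x, u, cfg)
        k = sol.assignments["sample"]
        assert sol.objective == pytest.approx(4.0, abs=1e-4)  # 2 loose copies x 2
        assert len(k.nonzero_loose_edges(comp.prototype)) == 2
        oracle = exhaustive_single_objective(comp.prototype, x, u, cfg, 4)
        assert sol.objective == pytest.approx(oracle, abs=1e-6)

    def test_solution_satisfies_invariants(self, noisy_cohort, noisy_fit):
        comp, bounds, sol = noisy_fit
        for clone in comp.clone_names:
            k = sol.assignments[clone]
            assert k.balance_violations(comp.clones[clone]) == []
            for eid, cn in k.edge_cn.items():
                assert cn <= min(bounds[clone].get(eid), 12)

    def test_cn_cap_below_depth_rejected(self, deletion_toy):
        comp, _, x = deletion_toy
        with pytest.raises(ValueError, match="cn_cap"):
            fit_single(comp.prototype, x, cfg=BalanceConfig(cn_cap=1))


class TestEdgeBounds:
    def test_support_thresholds(self, deletion_toy):
        comp, j, _ = deletion_toy
        for count, expect in [(0, 0.0), (3, math.inf)]:
            bounds = derive_edge_bounds(comp, {"c": {j: count}}, min_support=1)
            eid = comp.prototype.edges_of_kind("variant")[0].id
            assert bounds["c"].get(eid) == expect

    def test_supported_unknown_junction_rejected(self, deletion_toy):
        comp, _, _ = deletion_toy
        alien = Junction(Breakend("1", 21_000, "+"), Breakend("1", 29_000, "-"))
        with pytest.raises(ValueError, match="absent"):
            derive_edge_bounds(comp, {"c": {alien: 5}})

    def test_reference_and_loose_always_unbounded(self, deletion_toy):
        comp, j, _ = deletion_toy
        bounds = derive_edge_bounds(comp, {"c": {j: 0}})
        for e in comp.prototype.edges.values():
            if e.kind != "variant":
                assert bounds["c"].get(e.id) == math.inf


class TestFitJoint:
    def test_degenerate_single_clone_flat(self):
        comp = build_prototype({"c": [GenomicInterval("1", 0, 30_000)]}, {"c": []})
        sol = fit_joint(comp, {"c": flat_profile([2.0, 2.0, 2.0])}, cfg=BalanceConfig(cn_cap=4))
        assert sol.unique_loose_ends == 0
        assert sol.objective == pytest.approx(0.0, abs=1e-5)

    def test_shared_breakpoint_charged_once(self):
        """Two clones with the same unsupported junction: the joint
        objective pays the flanks once, independent fits pay per clone."""
        j = Junction(Breakend("1", 10_000, "+"), Breakend("1", 20_000, "-"))
        comp = build_prototype(
            {c: [GenomicInterval("1", 0, 30_000)] for c in "ab"},
            {c: [j] for c in "ab"},
        )
        x = flat_profile([2.0, 1.0, 2.0])
        eid = comp.prototype.edges_of_kind("variant")[0].id
        bounds = {c: EdgeBounds({eid: 0.0}) for c in "ab"}
        cfg = BalanceConfig(lambda_=0.1, cn_cap=4)
        sol = fit_joint(comp, {"a": x, "b": x}, bounds, cfg)
        assert sol.unique_loose_ends == 2  # one per flank, shared by both clones
        oracle = exhaustive_joint_objective(comp, {"a": x, "b": x}, bounds, cfg, 4)
        assert sol.objective == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(8):
            comp, profiles, bounds, lam = random_toy_compendium(rng)
            cfg = BalanceConfig(lambda_=lam, cn_cap=4)
            sol = fit_joint(comp, profiles, bounds, cfg)
            oracle = exhaustive_joint_objective(comp, profiles, bounds, cfg, 4)
            assert sol.objective == pytest.approx(oracle, abs=1e-5)

    def test_zero_noise_recovery(self, clean_cohort, clean_fit):
        comp, _, sol = clean_fit
        assert sol.solver_status == "optimal"
        for clone in comp.clone_names:
            truth = clean_cohort.truth_assignment(clone, comp.clones[clone])
            got = sol.assignments[clone]
            assert got.vertex_cn == truth.vertex_cn
            assert got.edge_cn == truth.edge_cn

    def test_missing_profile_rejected(self, deletion_toy):
        comp, _, x = deletion_toy
        comp2 = build_prototype(
            {c: [GenomicInterval("1", 0, 30_000)] for c in "ab"}, {"a": [], "b": []}
        )
        with pytest.raises(ValueError, match="missing depth"):
            fit_joint(comp2, {"a": x})
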