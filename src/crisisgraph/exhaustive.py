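"""Exhaustive reference solvers for small balancing/decomposition instances.

These enumerate every feasible integer assignment directly, without any
MIP machinery, and exist to validate the optimizers on toy problems.
They are exponential in instance size and intended for graphs with a
handful of segments and walks only.

The enumeration exploits the structure of prototype-built graphs: each
segment side carries exactly one reference edge (to its genome
neighbor), at most a few variant edges, and at most one loose edge.
Given vertex and variant-edge copy numbers, the leftover demand at a
side ("need") must be met by its reference edge plus its loose edge;
setting the reference edge to the minimum need of its two sides yields
the inclusion-minimal set of nonzero loose ends and the minimal total
loose copies, so it is optimal for both the ℓ0 and the per-copy slack
objective.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping

import numpy as np

from .balance import BalanceConfig, DepthProfile, EdgeBounds
from .graph import LOOSE, REFERENCE, VARIANT, GenomeGraph, GraphCompendium, Side

__all__ = [
    "enumerate_clone_assignments",
    "exhaustive_single_objective",
    "exhaustive_joint_objective",
    "exhaustive_decompose_objective",
    "random_toy_compendium",
]


def random_toy_compendium(rng: np.random.Generator):
    """A small random compendium for optimizer-vs-enumeration checks.

    3-6 segments on one chromosome, up to 3 variant junctions (possibly
    fold-backs), 1-3 clones with per-clone junction support and depth
    either derived from a random walk-free assignment plus noise or
    fully random.  Returns (compendium, profiles, bounds, lambda).
    """
    from .graph import Breakend, GenomicInterval, Junction, build_prototype
    from .balance import DepthProfile, EdgeBounds

    n_segs = int(rng.integers(3, 6))
    n_clones = int(rng.integers(1, 4))
    bnds_per_seg = int(rng.integers(2, 6))
    seg_len = 1000 * bnds_per_seg
    total = n_segs * seg_len
    cuts = [i * seg_len for i in range(n_segs + 1)]

    # candidate breakend sides at internal boundaries
    sides = []
    for p in cuts[1:-1]:
        sides.append(Breakend("1", p, "+"))
        sides.append(Breakend("1", p, "-"))
    junctions = []
    n_var = int(rng.integers(0, 4))
    for _ in range(n_var):
        a, b = rng.choice(len(sides), size=2, replace=True)
        j = Junction(sides[int(a)], sides[int(b)]).canonical()
        if j not in junctions:
            junctions.append(j)

    clone_names = [f"t{i}" for i in range(n_clones)]
    comp = build_prototype(
        {c: [GenomicInterval("1", 0, total)] for c in clone_names},
        {c: junctions for c in clone_names},
    )
    profiles = {}
    bounds = {}
    for c in clone_names:
        means = rng.uniform(0.0, 3.4, size=n_segs)
        if rng.random() < 0.5:
            means = rng.integers(0, 4, size=n_segs) + rng.normal(0, 0.2, n_segs)
            means = np.clip(means, 0, None)
        vals = np.repeat(means, bnds_per_seg)
        starts = np.arange(0, total, 1000)
        profiles[c] = DepthProfile(
            np.array(["1"] * len(starts), object), starts, starts + 1000, vals
        )
        b = {}
        g = comp.clones[c]
        for e in g.edges_of_kind(VARIANT):
            b[e.id] = math.inf if rng.random() < 0.7 else 0.0
        bounds[c] = EdgeBounds(b)
    lam = float(rng.choice([1.0, 10.0, 100.0]))
    return comp, profiles, bounds, lam


def _clone_tables(
    g: GenomeGraph,
    x: DepthProfile,
    u: EdgeBounds,
    cap: int,
):
    """Enumerate all feasible assignments of one clone.

    Returns (loose_mask, residual, loose_copies) arrays over feasible
    assignments, where loose_mask is an integer bitmask over the graph's
    loose-edge ids (sorted order) marking nonzero loose ends.
    """
    stats = x.vertex_stats(g)
    constrained_sides = set(g.constrained_sides())
    inter = sorted({s.seg for s in constrained_sides})
    free_segs = [s for s in g.segments if s not in inter]
    var_edges = [e for e in g.edges_of_kind(VARIANT)]
    free_var = [e for e in var_edges if u.get(e.id) > 0]
    loose_ids = sorted(e.id for e in g.edges_of_kind(LOOSE))
    loose_bit = {eid: i for i, eid in enumerate(loose_ids)}

    # segments with no constrained side (single-segment chromosomes) are
    # unconstrained: take their best residual directly
    base_resid = 0.0
    for s in free_segs:
        mean, w = stats[s]
        if w > 0:
            base_resid += min(w * (mean - c) ** 2 for c in range(cap + 1))

    nI, nV = len(inter), len(free_var)
    grid_shape = [cap + 1] * (nI + nV)
    N = int(np.prod(grid_shape)) if grid_shape else 1
    combos = np.indices(grid_shape).reshape(nI + nV, N) if grid_shape else np.zeros((0, 1), int)
    KV = combos[:nI]          # vertex CN, rows follow `inter`
    KE = combos[nI:]          # variant edge CN, rows follow `free_var`

    v_index = {s: i for i, s in enumerate(inter)}
    e_index = {e.id: i for i, e in enumerate(free_var)}

    def need(side: Side) -> np.ndarray | None:
        """Demand at a constrained side left to its ref + loose edges."""
        if side not in constrained_sides:
            return None  # telomeric terminus: unconstrained
        n = KV[v_index[side.seg]].astype(np.int64).copy()
        for e in g.incident_edges(side):
            if e.kind == VARIANT and e.id in e_index:
                n -= e.multiplicity_at(side) * KE[e_index[e.id]]
            # variant edges with u=0 contribute nothing
        return n

    feasible = np.ones(N, dtype=bool)
    loose_mask = np.zeros(N, dtype=np.int64)
    loose_total = np.zeros(N, dtype=np.int64)

    for e in g.edges_of_kind(REFERENCE):
        nA, nB = need(e.side1), need(e.side2)
        sides = [(e.side1, nA), (e.side2, nB)]
        constrained = [(s, n) for s, n in sides if n is not None]
        if not constrained:
            continue
        for _, n in constrained:
            feasible &= n >= 0
        # forced value when a side has no loose slack
        forced = None
        for s, n in constrained:
            if g.loose_edge_at(s) is None:
                forced = n if forced is None else np.minimum(forced, n)
        if forced is not None:
            r = forced
            for s, n in constrained:
                if g.loose_edge_at(s) is None:
                    feasible &= n == r
        else:
            r = constrained[0][1]
            for _, n in constrained[1:]:
                r = np.minimum(r, n)
        feasible &= r >= 0
        for s, n in constrained:
            le = g.loose_edge_at(s)
            slack = n - r
            if le is None:
                feasible &= slack == 0
            else:
                feasible &= slack >= 0
                loose_total += np.maximum(slack, 0)
                loose_mask |= np.where(slack > 0, 1 << loose_bit[le.id], 0)

    resid = np.full(N, base_resid)
    for s in inter:
        mean, w = stats[s]
        if w > 0:
            resid += w * (mean - KV[v_index[s]]) ** 2

    return loose_mask[feasible], resid[feasible], loose_total[feasible], loose_ids


def enumerate_clone_assignments(
    g: GenomeGraph, x: DepthProfile, u: EdgeBounds, cap: int
) -> list[tuple[frozenset[int], float, int]]:
    """All feasible (nonzero-loose-edge set, residual, loose copies) triples,
    reduced to the minimal residual per distinct loose-end set."""
    mask, resid, total, loose_ids = _clone_tables(g, x, u, cap)
    best: dict[int, tuple[float, int]] = {}
    for m, r, t in zip(mask, resid, total):
        cur = best.get(int(m))
        if cur is None or (r, t) < cur:
            best[int(m)] = (float(r), int(t))
    out = []
    for m, (r, t) in best.items():
        ids = frozenset(eid for i, eid in enumerate(loose_ids) if m >> i & 1)
        out.append((ids, r, t))
    return out


def exhaustive_single_objective(
    g: GenomeGraph, x: DepthProfile, u: EdgeBounds, cfg: BalanceConfig, cap: int
) -> float:
    """Minimal residual + slack_penalty * loose copies over all assignments."""
    mask, resid, total, _ = _clone_tables(g, x, u, cap)
    if len(resid) == 0:
        return math.inf
    return float(np.min(resid + cfg.slack_penalty * total))


def exhaustive_joint_objective(
    comp: GraphCompendium,
    profiles: Mapping[str, DepthProfile],
    bounds: Mapping[str, EdgeBounds],
    cfg: BalanceConfig,
    cap: int,
) -> float:
    """Minimal λ·|unique nonzero prototype loose ends| + Σ residuals.

    Clone loose edges project to prototype loose edges by identity, so
    the union of per-clone nonzero loose sets is taken directly.
    """
    per_clone = []
    for clone in comp.clone_names:
        cands = enumerate_clone_assignments(
            comp.clones[clone], profiles[clone], bounds[clone], cap
        )
        if not cands:
            return math.inf
        # prune dominated candidates: another with subset loose-set and <= residual
        cands.sort(key=lambda t: t[1])
        kept: list[tuple[frozenset[int], float]] = []
        for ids, r, _ in cands:
            if not any(k_ids <= ids and k_r <= r for k_ids, k_r in kept):
                kept.append((ids, r))
        per_clone.append(kept)
    best = math.inf
    for combo in itertools.product(*per_clone):
        union: frozenset[int] = frozenset()
        resid = 0.0
        for ids, r in combo:
            union |= ids
            resid += r
        best = min(best, cfg.lambda_ * len(union) + resid)
    return best


def exhaustive_decompose_objective(
    clone_walk_keys: Mapping[str, list],
    clone_deltas: Mapping[str, list[dict]],
    clone_targets: Mapping[str, dict],
    max_copy: int,
) -> float:
    """Minimal number of unique prototype walks over all feasible φ.

    ``clone_walk_keys[c][j]`` is the prototype identity of clone c's
    j-th walk; ``clone_deltas[c][j]`` maps graph elements to their
    multiplicity in that walk; ``clone_targets[c]`` maps each element to
    its κ.  Entries of φ are enumerated over 0..max_copy.
    """
    per_clone: list[list[frozenset]] = []
    for clone, deltas in clone_deltas.items():
        target = clone_targets[clone]
        keys = clone_walk_keys[clone]
        feasible: list[frozenset] = []
        for phi in itertools.product(range(max_copy + 1), repeat=len(deltas)):
            ok = True
            for elem, want in target.items():
                got = sum(f * d.get(elem, 0) for f, d in zip(phi, deltas))
                if got != want:
                    ok = False
                    break
            if ok:
                feasible.append(
                    frozenset(k for f, k in zip(phi, keys) if f > 0)
                )
        if not feasible:
            return math.inf
        per_clone.append(feasible)
    best = math.inf
    for combo in itertools.product(*per_clone):
        used: frozenset = frozenset()
        for s in combo:
            used |= s
        best = min(best, float(len(used)))
    return best
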