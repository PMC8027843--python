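"""Junction balancing: integer copy-number inference on genome graphs.

Given binned read depth in copy-number units and a genome graph, infer a
nonnegative integer copy number κ for every segment and edge such that
junction balance holds — each copy of every interstitial segment has a
left and a right neighbor — while fitting the depth and discouraging
*loose ends* (copy-number change points explained by no junction).

Two objectives are supported:

* single-sample (``fit_single``): minimize the depth residual plus a
  per-copy slack penalty on loose-end copies;
* joint (``fit_joint``): across a compendium of n structurally
  identical clone graphs, minimize

      λ · #{prototype loose edges with nonzero total copy}  +  Σᵢ Vᵢ

  where Vᵢ is clone i's depth residual.  The ℓ0 loose-end term counts a
  loose end once however many clones use it, so lineages sharing an
  unexplained breakpoint are charged jointly — the parsimony that makes
  compendium-wide fits more consistent than independent ones.

The residual is the bin-count-weighted squared error between each
segment's mean bin depth and its integer copy number,

    V(G, κ, x, J) = Σ_v w_v (x̄_v − κ(v))²,

with w_v the number of bins mapped to segment v.  The program is solved
as a mixed-integer *linear* program by one-hot encoding κ(v) over
{0..cn_cap}, which expresses the quadratic exactly; the backend is
HiGHS via :func:`scipy.optimize.milp`, solved to proven optimality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, milp

from .graph import (
    LOOSE,
    REFERENCE,
    VARIANT,
    CopyAssignment,
    GenomeGraph,
    GraphCompendium,
    Junction,
    Side,
)

__all__ = [
    "DepthProfile",
    "EdgeBounds",
    "BalanceConfig",
    "BalanceSolution",
    "depth_residual",
    "fit_single",
    "fit_joint",
    "derive_edge_bounds",
]

#: tiny per-copy nudge used only to break ties among equal-objective optima
_TIE_EPS = 1e-7


@dataclass
class DepthProfile:
    """Binned read depth in purity/ploidy-transformed copy-number units."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.values)
        if not (len(self.chroms) == len(self.starts) == len(self.ends) == n):
            raise ValueError("bin arrays must have equal length")
        v = np.asarray(self.values, dtype=float)
        if n and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise ValueError("bin values must be finite and >= 0")
        self.values = v
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DepthProfile":
        return cls(
            df["chrom"].to_numpy(object),
            df["start"].to_numpy(np.int64),
            df["end"].to_numpy(np.int64),
            df["value"].to_numpy(float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends,
             "value": self.values}
        )

    def __len__(self) -> int:
        return len(self.values)

    def bin_to_vertex(self, g: GenomeGraph) -> np.ndarray:
        """Map each bin to the segment containing its midpoint (J).

        Bins outside every segment map to 0.
        """
        out = np.zeros(len(self), dtype=np.int64)
        for chrom in g.chromosomes():
            segs = g.segments_of_chrom(chrom)
            bounds = np.array([g.segments[s].start for s in segs] +
                              [g.segments[segs[-1]].end])
            in_chrom = np.nonzero(self.chroms == chrom)[0]
            mids = (self.starts[in_chrom] + self.ends[in_chrom]) / 2.0
            idx = np.searchsorted(bounds, mids, side="right") - 1
            ok = (idx >= 0) & (idx < len(segs))
            out[in_chrom[ok]] = np.array(segs, dtype=np.int64)[idx[ok]]
        return out

    def vertex_stats(self, g: GenomeGraph) -> dict[int, tuple[float, int]]:
        """Per segment: (mean of mapped bin values x̄_v, bin count w_v)."""
        j = self.bin_to_vertex(g)
        stats: dict[int, tuple[float, int]] = {}
        for sid in g.segments:
            mask = j == sid
            w = int(mask.sum())
            stats[sid] = (float(self.values[mask].mean()) if w else math.nan, w)
        return stats


@dataclass
class EdgeBounds:
    """Upper bound u(e) ∈ {0, ∞} per edge; 0 forbids the edge in a clone."""

    bounds: dict[int, float] = field(default_factory=dict)

    def get(self, edge_id: int) -> float:
        return self.bounds.get(edge_id, math.inf)

    @classmethod
    def all_supported(cls, g: GenomeGraph) -> "EdgeBounds":
        return cls({e: math.inf for e in g.edges})


@dataclass
class BalanceConfig:
    """Hyperparameters of the balancing program.

    ``lambda_`` weighs the joint unique-loose-end count (default 100);
    ``slack_penalty`` is the per-copy loose-end weight in single-sample
    mode (default 500, with 100 a documented alternative for noisier
    material).  ``cn_cap`` bounds every copy number; when None it is
    derived from the data as ceil(max segment mean) + 2.
    """

    lambda_: float = 100.0
    slack_penalty: float = 500.0
    cn_cap: int | None = None
    solver_time_limit: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.slack_penalty < 0:
            raise ValueError("penalties must be >= 0")
        if self.cn_cap is not None and self.cn_cap < 0:
            raise ValueError("cn_cap must be >= 0")


@dataclass
class BalanceSolution:
    assignments: dict[str, CopyAssignment]
    objective: float
    residual_per_clone: dict[str, float]
    unique_loose_ends: int
    solver_status: str
    unmapped_vertices: dict[str, list[int]] = field(default_factory=dict)
    message: str = ""


def depth_residual(
    g: GenomeGraph, k: CopyAssignment, x: DepthProfile
) -> float:
    """Bin-count-weighted squared depth residual Σ_v w_v (x̄_v − κ(v))².

    Segments with no mapped bins contribute 0.
    """
    total = 0.0
    for sid, (mean, w) in x.vertex_stats(g).items():
        if w == 0:
            continue
        total += w * (mean - k.vertex_cn.get(sid, 0)) ** 2
    return total


def derive_edge_bounds(
    comp: GraphCompendium,
    junction_support: Mapping[str, Mapping[Junction, int]],
    min_support: int = 1,
) -> dict[str, EdgeBounds]:
    """Per-clone edge upper bounds from junction read support.

    A variant edge gets u=∞ in a clone iff its junction has at least
    ``min_support`` supporting read pairs there, else 0.  Reference and
    loose edges are always unbounded.
    """
    g0 = comp.prototype
    edge_of_junction = {
        _junction_of_edge(g0, e): e.id for e in g0.edges_of_kind(VARIANT)
    }
    out: dict[str, EdgeBounds] = {}
    for clone in comp.clone_names:
        support = {
            j.canonical(): count
            for j, count in junction_support.get(clone, {}).items()
        }
        for j, count in support.items():
            if count < 0:
                raise ValueError("support counts must be >= 0")
            if count > 0 and j not in edge_of_junction:
                raise ValueError(f"clone {clone}: junction {j} absent from compendium")
        bounds = {
            eid: (math.inf if support.get(j, 0) >= min_support else 0.0)
            for j, eid in edge_of_junction.items()
        }
        out[clone] = EdgeBounds(bounds)
    return out


def _junction_of_edge(g: GenomeGraph, e) -> Junction:
    from .graph import Breakend

    def bnd(side: Side) -> Breakend:
        iv = g.segments[side.seg]
        if side.end == "R":
            return Breakend(iv.chrom, iv.end, "+")
        return Breakend(iv.chrom, iv.start, "-")

    return Junction(bnd(e.side1), bnd(e.side2)).canonical()


# ---------------------------------------------------------------------------
# MILP core
# ---------------------------------------------------------------------------

class _Model:
    """Sparse MILP under construction: min c·x s.t. lb <= A x <= ub."""

    def __init__(self) -> None:
        self.ncol = 0
        self.cost: list[float] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integrality: list[int] = []
        self.rows: list[tuple[dict[int, float], float, float]] = []

    def add_var(self, cost: float, lb: float, ub: float, integer: bool = True) -> int:
        self.cost.append(cost)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integrality.append(1 if integer else 0)
        self.ncol += 1
        return self.ncol - 1

    def add_row(self, coefs: dict[int, float], lb: float, ub: float) -> None:
        self.rows.append((coefs, lb, ub))

    def solve(self, time_limit: float | None):
        A = sp.lil_matrix((len(self.rows), self.ncol))
        row_lb = np.empty(len(self.rows))
        row_ub = np.empty(len(self.rows))
        for i, (coefs, lb, ub) in enumerate(self.rows):
            for j, v in coefs.items():
                A[i, j] = v
            row_lb[i] = lb
            row_ub[i] = ub
        options: dict = {"mip_rel_gap": 0.0}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = milp(
            c=np.array(self.cost),
            constraints=LinearConstraint(A.tocsr(), row_lb, row_ub),
            integrality=np.array(self.integrality),
            bounds=(np.array(self.lb), np.array(self.ub)),
            options=options,
        )
        return res


def _status_of(res) -> str:
    return {0: "optimal", 1: "timeout", 2: "infeasible", 3: "infeasible"}.get(
        res.status, "infeasible" if not res.success else "feasible"
    )


def _build_and_solve(
    comp: GraphCompendium,
    profiles: Mapping[str, DepthProfile],
    bounds: Mapping[str, EdgeBounds],
    cfg: BalanceConfig,
    mode: str,
) -> BalanceSolution:
    g0 = comp.prototype
    clones = comp.clone_names
    stats = {c: profiles[c].vertex_stats(comp.clones[c]) for c in clones}

    cap = cfg.cn_cap
    if cap is None:
        max_mean = max(
            (m for st in stats.values() for m, w in st.values() if w > 0),
            default=0.0,
        )
        cap = int(math.ceil(max_mean)) + 2
    for st in stats.values():
        for m, w in st.values():
            if w > 0 and round(m) > cap:
                raise ValueError(
                    f"cn_cap={cap} below max observed rounded depth {round(m)}"
                )

    model = _Model()
    # per clone: one-hot vertex CN and integer edge CN
    yvar: dict[tuple[str, int, int], int] = {}
    evar: dict[tuple[str, int], int] = {}
    for clone in clones:
        g = comp.clones[clone]
        st = stats[clone]
        for sid in sorted(g.segments):
            mean, w = st[sid]
            for c in range(cap + 1):
                cost = w * (mean - c) ** 2 if w > 0 else 0.0
                cost += _TIE_EPS * c
                yvar[(clone, sid, c)] = model.add_var(cost, 0, 1)
            model.add_row(
                {yvar[(clone, sid, c)]: 1.0 for c in range(cap + 1)}, 1.0, 1.0
            )
        ub = bounds[clone]
        for eid in sorted(g.edges):
            e = g.edges[eid]
            hi = min(float(cap), ub.get(eid))
            cost = _TIE_EPS
            if mode == "single" and e.kind == LOOSE:
                cost += cfg.slack_penalty
            evar[(clone, eid)] = model.add_var(cost, 0, hi)
        # junction balance at every non-telomeric segment side
        for side in g.constrained_sides():
            coefs: dict[int, float] = {}
            for e in g.incident_edges(side):
                coefs[evar[(clone, e.id)]] = float(e.multiplicity_at(side))
            for c in range(1, cap + 1):
                coefs[yvar[(clone, side.seg, c)]] = -float(c)
            model.add_row(coefs, 0.0, 0.0)

    # joint ℓ0 over unique prototype loose ends
    zvar: dict[int, int] = {}
    if mode == "joint":
        bigm = float(cap * len(clones))
        for e in g0.edges_of_kind(LOOSE):
            zvar[e.id] = model.add_var(cfg.lambda_, 0, 1)
            coefs = {evar[(clone, e.id)]: 1.0 for clone in clones}
            coefs[zvar[e.id]] = -bigm
            model.add_row(coefs, -math.inf, 0.0)

    res = model.solve(cfg.solver_time_limit)
    status = _status_of(res)
    if res.x is None:
        zeroed = [
            f"clone {c}: variant edges with u=0: "
            + ",".join(str(e.id) for e in comp.clones[c].edges_of_kind(VARIANT)
                       if bounds[c].get(e.id) == 0)
            for c in clones
        ]
        return BalanceSolution(
            {}, math.nan, {}, 0, status,
            message="no feasible integer assignment; " + "; ".join(zeroed),
        )

    x = np.round(res.x).astype(int)
    assignments: dict[str, CopyAssignment] = {}
    residuals: dict[str, float] = {}
    unmapped: dict[str, list[int]] = {}
    for clone in clones:
        g = comp.clones[clone]
        vcn = {
            sid: int(
                np.argmax([res.x[yvar[(clone, sid, c)]] for c in range(cap + 1)])
            )
            for sid in g.segments
        }
        ecn = {eid: int(x[evar[(clone, eid)]]) for eid in g.edges}
        k = CopyAssignment(vcn, ecn)
        assignments[clone] = k
        residuals[clone] = depth_residual(g, k, profiles[clone])
        unmapped[clone] = [s for s, (m, w) in stats[clone].items() if w == 0]

    # unique prototype loose edges with nonzero total copy across clones
    unique_loose = sum(
        1
        for e in g0.edges_of_kind(LOOSE)
        if sum(assignments[c].edge_cn.get(e.id, 0) for c in clones) > 0
    )
    total_resid = sum(residuals.values())
    if mode == "joint":
        objective = cfg.lambda_ * unique_loose + total_resid
    else:
        clone = clones[0]
        objective = total_resid + cfg.slack_penalty * assignments[clone].total_loose(
            comp.clones[clone]
        )
    return BalanceSolution(
        assignments, objective, residuals, unique_loose, status, unmapped
    )


def fit_single(
    g: GenomeGraph,
    x: DepthProfile,
    u: EdgeBounds | None = None,
    cfg: BalanceConfig | None = None,
) -> BalanceSolution:
    """Single-sample junction balancing with per-copy loose-end slack."""
    cfg = cfg or BalanceConfig()
    u = u or EdgeBounds.all_supported(g)
    comp = GraphCompendium(g, ["sample"], clones={"sample": g})
    return _build_and_solve(comp, {"sample": x}, {"sample": u}, cfg, "single")


def fit_joint(
    comp: GraphCompendium,
    profiles: Mapping[str, DepthProfile],
    bounds: Mapping[str, EdgeBounds] | None = None,
    cfg: BalanceConfig | None = None,
) -> BalanceSolution:
    """Joint junction balancing across a clone compendium (ℓ0 loose ends)."""
    cfg = cfg or BalanceConfig()
    if bounds is None:
        bounds = {
            c: EdgeBounds.all_supported(comp.clones[c]) for c in comp.clone_names
        }
    missing = [c for c in comp.clone_names if c not in profiles]
    if missing:
        raise ValueError(f"missing depth profiles for clones: {missing}")
    return _build_and_solve(comp, profiles, bounds, cfg, "joint")
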