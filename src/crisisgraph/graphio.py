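"""(De)serialization of genome graphs and the standard flat formats.

Graphs round-trip through a JSON document (segments, edges, termini, and
optionally a copy assignment).  BED/bedGraph/BEDPE I/O uses those
formats' native conventions: 0-based half-open intervals; BEDPE strand
``+`` denotes the segment end facing higher coordinates.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .graph import (
    LOOSE,
    Breakend,
    CopyAssignment,
    GenomeGraph,
    GenomicInterval,
    GraphEdge,
    Junction,
    Side,
)

__all__ = [
    "graph_to_dict",
    "graph_from_dict",
    "write_graph",
    "read_graph",
    "read_bedgraph",
    "write_bedgraph",
    "read_bedpe",
    "write_bedpe",
    "write_segment_bed",
]

_SCHEMA = "crisisgraph-genome-graph/1"


class GraphParseError(ValueError):
    """Raised when a graph document is malformed; names the offending field."""


def graph_to_dict(
    g: GenomeGraph, assignment: CopyAssignment | None = None
) -> dict:
    doc = {
        "schema": _SCHEMA,
        "segments": [
            {"id": sid, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for sid, iv in sorted(g.segments.items())
        ],
        "termini": [[s.seg, s.end] for s in sorted(g.termini)],
        "edges": [
            {
                "id": e.id,
                "kind": e.kind,
                "side1": [e.side1.seg, e.side1.end],
                **({} if e.side2 is None else {"side2": [e.side2.seg, e.side2.end]}),
            }
            for e in sorted(g.edges.values(), key=lambda e: e.id)
        ],
    }
    if assignment is not None:
        doc["vertex_cn"] = {str(k): int(v) for k, v in sorted(assignment.vertex_cn.items())}
        doc["edge_cn"] = {str(k): int(v) for k, v in sorted(assignment.edge_cn.items())}
    return doc


def graph_from_dict(doc: Mapping) -> tuple[GenomeGraph, CopyAssignment | None]:
    try:
        segments = {
            int(s["id"]): GenomicInterval(s["chrom"], int(s["start"]), int(s["end"]))
            for s in doc["segments"]
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise GraphParseError(f"bad segment record: {exc}") from exc
    edges = []
    for rec in doc.get("edges", []):
        try:
            side1 = Side(int(rec["side1"][0]), rec["side1"][1])
            side2 = (
                Side(int(rec["side2"][0]), rec["side2"][1]) if "side2" in rec else None
            )
            edges.append(GraphEdge(int(rec["id"]), rec["kind"], side1, side2))
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            raise GraphParseError(f"bad edge record {rec!r}: {exc}") from exc
    termini = []
    for t in doc.get("termini", []):
        try:
            termini.append(Side(int(t[0]), t[1]))
        except (TypeError, ValueError, IndexError) as exc:
            raise GraphParseError(f"bad terminus record {t!r}: {exc}") from exc
    try:
        g = GenomeGraph(segments, edges, termini)
    except ValueError as exc:
        raise GraphParseError(str(exc)) from exc
    assignment = None
    if "vertex_cn" in doc or "edge_cn" in doc:
        assignment = CopyAssignment(
            vertex_cn={int(k): int(v) for k, v in doc.get("vertex_cn", {}).items()},
            edge_cn={int(k): int(v) for k, v in doc.get("edge_cn", {}).items()},
        )
        for v in assignment.vertex_cn:
            if v not in g.segments:
                raise GraphParseError(f"vertex_cn references missing segment {v}")
        for e in assignment.edge_cn:
            if e not in g.edges:
                raise GraphParseError(f"edge_cn references missing edge {e}")
    return g, assignment


def write_graph(
    g: GenomeGraph, path: str, assignment: CopyAssignment | None = None
) -> None:
    with open(path, "w") as fh:
        json.dump(graph_to_dict(g, assignment), fh, indent=1)
        fh.write("\n")


def read_graph(path: str) -> tuple[GenomeGraph, CopyAssignment | None]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GraphParseError(f"{path}: not valid JSON (line {exc.lineno})") from exc
    return graph_from_dict(doc)


# ---------------------------------------------------------------------------
# flat formats
# ---------------------------------------------------------------------------

def read_bedgraph(path: str) -> pd.DataFrame:
    """Read a bedGraph into a (chrom, start, end, value) frame."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def _breakend_interval(bnd: Breakend) -> tuple[int, int]:
    # the 1-bp BED interval containing the breakpoint base
    return (bnd.pos - 1, bnd.pos) if bnd.strand == "+" else (bnd.pos, bnd.pos + 1)


def write_bedpe(
    junctions: Sequence[Junction],
    path: str,
    support: pd.DataFrame | None = None,
    names: Sequence[str] | None = None,
) -> None:
    """Write junctions as BEDPE; optional per-clone support columns.

    ``support`` is a frame with one row per junction and one column per
    clone (read-pair support counts); its columns are appended after
    strand2 and named in a ``#``-prefixed header line.
    """
    rows = []
    for i, j in enumerate(junctions):
        b1, b2 = j.bnd1, j.bnd2
        s1, e1 = _breakend_interval(b1)
        s2, e2 = _breakend_interval(b2)
        name = names[i] if names is not None else f"junction_{i + 1}"
        row = [b1.chrom, s1, e1, b2.chrom, s2, e2, name, ".", b1.strand, b2.strand]
        if support is not None:
            row.extend(int(x) for x in support.iloc[i])
        rows.append(row)
    cols = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "name", "score", "strand1", "strand2",
    ]
    if support is not None:
        cols.extend(support.columns)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, cols)) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_bedpe(path: str) -> tuple[list[Junction], pd.DataFrame]:
    """Read BEDPE junctions; returns (junctions, extras).

    ``extras`` holds the name column and any columns past strand2
    (e.g., per-clone support counts), one row per junction.
    """
    with open(path) as fh:
        first = fh.readline()
    header = None
    if first.startswith("#"):
        header = first.lstrip("#").rstrip("\n").split("\t")
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    base = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "name", "score", "strand1", "strand2",
    ]
    ncol = df.shape[1]
    if ncol < 10:
        raise ValueError(f"{path}: BEDPE needs >= 10 columns, got {ncol}")
    if header is not None and len(header) == ncol:
        df.columns = header
    else:
        extra = [f"extra_{i}" for i in range(ncol - 10)]
        df.columns = base + extra
    junctions = []
    for _, r in df.iterrows():
        pos1 = int(r["end1"]) if r["strand1"] == "+" else int(r["start1"])
        pos2 = int(r["end2"]) if r["strand2"] == "+" else int(r["start2"])
        junctions.append(
            Junction(
                Breakend(str(r["chrom1"]), pos1, r["strand1"]),
                Breakend(str(r["chrom2"]), pos2, r["strand2"]),
            )
        )
    extras = df.drop(columns=[c for c in base if c != "name"])
    return junctions, extras


def write_segment_bed(
    g: GenomeGraph, assignment: CopyAssignment, path: str
) -> None:
    """Per-segment copy number as BED with a numeric CN column."""
    with open(path, "w") as fh:
        for sid in sorted(g.segments):
            iv = g.segments[sid]
            cn = assignment.vertex_cn.get(sid, 0)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tsegment_{sid}\t{cn}\n")
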