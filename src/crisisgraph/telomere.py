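"""Telomere-motif screening of loose-end mate sequences.

Loose ends are copy-number change points without a mappable junction.
One candidate explanation is neo-telomere formation — telomerase adding
fresh telomere repeats at a break.  If that happened, the mates of
high-mapping-quality reads anchored at the loose end should be packed
with telomere repeats.  This module counts occurrences of a 12-bp
telomere repeat motif (all distinct cyclic rotations of
``TTAGGGTTAGGG``, plus reverse complements) in such mate sequences and
classifies each loose end.

Note the 12-mer has period 6, so there are 6 distinct rotations per
strand (12 with reverse complements); the motif set is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LooseEndEvidence",
    "telomere_motif_set",
    "count_telomere_motif",
    "classify_loose_end",
    "screen_loose_ends",
]

NEO_TELOMERE = "neo-telomere candidate"
UNRESOLVED = "repetitive/unresolved"

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def telomere_motif_set(
    motif: str = "TTAGGGTTAGGG", both_strands: bool = True
) -> frozenset[str]:
    """All distinct cyclic rotations of ``motif`` (± reverse complements)."""
    rot = {motif[i:] + motif[:i] for i in range(len(motif))}
    if both_strands:
        rot |= {_revcomp(m) for m in rot}
    return frozenset(rot)


def count_telomere_motif(
    seq: str, motifs: frozenset[str] | None = None
) -> int:
    """Occurrences (overlapping) of any motif in ``seq``; N never matches."""
    if motifs is None:
        motifs = telomere_motif_set()
    if not motifs:
        return 0
    k = len(next(iter(motifs)))
    seq = seq.upper()
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] in motifs)


@dataclass
class LooseEndEvidence:
    """Mate sequences gathered for one loose end."""

    loose_end_id: int
    mate_sequences: list[str] = field(default_factory=list)
    motif_counts: list[int] = field(default_factory=list)
    classification: str = UNRESOLVED

    def count(self, motifs: frozenset[str] | None = None) -> "LooseEndEvidence":
        self.motif_counts = [
            count_telomere_motif(s, motifs) for s in self.mate_sequences
        ]
        return self


def classify_loose_end(
    ev: LooseEndEvidence,
    min_count: int = 1,
    min_reads: int = 3,
    motifs: frozenset[str] | None = None,
) -> str:
    """Nominate or reject neo-telomere formation at a loose end.

    Candidate iff at least ``min_reads`` mate sequences each contain at
    least ``min_count`` motif hits; empty evidence is unresolved.
    """
    if not ev.motif_counts:
        ev.count(motifs)
    hits = sum(1 for c in ev.motif_counts if c >= min_count)
    ev.classification = NEO_TELOMERE if hits >= min_reads else UNRESOLVED
    return ev.classification


def screen_loose_ends(
    evidence: list[LooseEndEvidence],
    min_count: int = 1,
    min_reads: int = 3,
    motifs: frozenset[str] | None = None,
):
    """Classify a batch of loose ends; returns a summary table (pandas)."""
    import pandas as pd

    rows = []
    for ev in evidence:
        cls = classify_loose_end(ev, min_count, min_reads, motifs)
        rows.append(
            {
                "loose_end": ev.loose_end_id,
                "n_mates": len(ev.mate_sequences),
                "mates_with_motif": sum(1 for c in ev.motif_counts if c >= min_count),
                "total_motif_hits": sum(ev.motif_counts),
                "classification": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "loose_end", "n_mates", "mates_with_motif",
            "total_motif_hits", "classification",
        ],
    )
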