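"""Parental SNP phasing and allele-specific copy number.

Heterozygous parental sites (VAF strictly inside an interval, default
(0.3, 0.7)) are phased into the L ("lost") and R ("retained")
haplotypes using a clone with single-allele loss of the region of
interest: at each site, the allele with a zero read count in the loss
clone is the lost one.  Dividing per-clone allelic counts by the
genome-wide mean heterozygous allele count (valid for 100% pure,
near-diploid clones) gives absolute allelic copy number, revealing
which parental allele carries rearrangement-driven gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HetSiteTable",
    "call_het_sites",
    "phase_by_loss_clone",
    "allelic_copy_number",
]


@dataclass
class HetSiteTable:
    """Candidate/phased heterozygous sites with per-clone allelic counts.

    ``sites`` columns: chrom, pos, ref, alt, parental_ref, parental_alt,
    and once phased: ``phase`` ∈ {"ref_L", "alt_L", "unphased"} —
    which allele belongs to the lost haplotype.  ``ref_counts`` /
    ``alt_counts`` are (clones × sites) arrays.
    """

    sites: pd.DataFrame
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    clone_names: list[str]

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        shape = (len(self.clone_names), len(self.sites))
        if self.ref_counts.shape != shape or self.alt_counts.shape != shape:
            raise ValueError("count matrices must be clones x sites")

    def subset(self, keep: np.ndarray) -> "HetSiteTable":
        idx = np.nonzero(keep)[0]
        return HetSiteTable(
            self.sites.iloc[idx].reset_index(drop=True),
            self.ref_counts[:, idx],
            self.alt_counts[:, idx],
            self.clone_names,
        )

    def in_region(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        return (
            (self.sites["chrom"] == chrom)
            & (self.sites["pos"] >= lo)
            & (self.sites["pos"] < hi)
        ).to_numpy()


def call_het_sites(
    table: HetSiteTable,
    vaf_lo: float = 0.3,
    vaf_hi: float = 0.7,
    min_depth: int = 10,
) -> HetSiteTable:
    """Retain sites heterozygous in the parental line.

    Parental VAF must lie strictly inside (vaf_lo, vaf_hi) at depth of
    at least ``min_depth``; zero-depth sites are dropped.
    """
    ref = table.sites["parental_ref"].to_numpy(float)
    alt = table.sites["parental_alt"].to_numpy(float)
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    keep = (depth >= min_depth) & (vaf > vaf_lo) & (vaf < vaf_hi)
    return table.subset(keep)


def phase_by_loss_clone(
    table: HetSiteTable,
    loss_clone: str,
    region: tuple[str, int, int],
) -> HetSiteTable:
    """Phase region sites by the zero-count allele of the loss clone.

    The allele (ref or alt) with 0 reads in ``loss_clone`` is assigned
    to the L (lost) haplotype, the other to R (retained).  Sites where
    neither or both alleles are zero remain unphased and are flagged.
    Idempotent: re-phasing with the same loss clone changes nothing.
    """
    out = HetSiteTable(
        table.sites.copy(), table.ref_counts, table.alt_counts, table.clone_names
    )
    ci = out.clone_names.index(loss_clone)
    mask = out.in_region(*region)
    phase = np.array(["outside"] * len(out.sites), dtype=object)
    ref = out.ref_counts[ci]
    alt = out.alt_counts[ci]
    phase[mask & (ref == 0) & (alt > 0)] = "ref_L"
    phase[mask & (alt == 0) & (ref > 0)] = "alt_L"
    ambiguous = mask & ~np.isin(phase, ["ref_L", "alt_L"])
    phase[ambiguous] = "unphased"
    out.sites["phase"] = phase
    return out


def allelic_copy_number(
    table: HetSiteTable,
    region: tuple[str, int, int],
) -> pd.DataFrame:
    """Absolute allelic copy number (L_cn, R_cn) per phased site & clone.

    The per-clone normalizer is the genome-wide mean heterozygous
    allele count over sites *outside* the region of interest (avoiding
    circularity with the event region); L/R counts in the region are
    divided by it.  Returns a long frame: clone, chrom, pos, L_cn, R_cn.
    """
    if "phase" not in table.sites.columns:
        raise ValueError("table must be phased first (phase_by_loss_clone)")
    mask = table.in_region(*region)
    phased = mask & np.isin(table.sites["phase"].to_numpy(), ["ref_L", "alt_L"])
    outside = ~mask
    if outside.sum() == 0:
        raise ValueError("no sites outside the region to derive the normalizer")
    rows = []
    ref_L = table.sites["phase"].to_numpy() == "ref_L"
    for ci, clone in enumerate(table.clone_names):
        # mean per-allele count over outside-region het sites
        norm = float(
            (table.ref_counts[ci, outside] + table.alt_counts[ci, outside]).mean()
        ) / 2.0
        if norm <= 0:
            raise ValueError(f"clone {clone}: zero normalizer")
        L = np.where(ref_L, table.ref_counts[ci], table.alt_counts[ci])
        R = np.where(ref_L, table.alt_counts[ci], table.ref_counts[ci])
        sub = table.sites.loc[phased, ["chrom", "pos"]].copy()
        sub["clone"] = clone
        sub["L_cn"] = L[phased] / norm
        sub["R_cn"] = R[phased] / norm
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)[["clone", "chrom", "pos", "L_cn", "R_cn"]]
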