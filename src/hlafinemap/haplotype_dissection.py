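"""Extended vs recombinant dissection of focal-allele haplotypes.

Each phased haplotype carrying a focal HLA allele is aligned to a reference
extended haplotype over the HLA-B -> HLA-DQB1 span; haplotypes matching the
reference (up to a small mismatch tolerance) are "extended", the rest are
"recombinant" with a breakpoint localized to the interval between the last
matching SNP (scanning from the DQB1 side) and the first divergent SNP on
the Class I side.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .synthetic_cohorts import RegionMap

__all__ = [
    "DissectionError",
    "ReferenceExtended",
    "HaplotypeClass",
    "classify_against_reference",
    "dissect_focal_allele",
    "share_extended",
]


class DissectionError(ValueError):
    pass


@dataclass
class ReferenceExtended:
    """A reference extended haplotype: anchor alleles + SNP pattern."""

    name: str
    anchor_alleles: dict[str, str]  # gene -> allele label
    snp_pattern: np.ndarray

    def __post_init__(self) -> None:
        self.snp_pattern = np.asarray(self.snp_pattern, dtype=np.int8)


@dataclass
class HaplotypeClass:
    label: str  # "extended" | "recombinant" | "other"
    breakpoint: tuple[int, int] | None = None  # half-open bp interval

    def __post_init__(self) -> None:
        if (self.label == "recombinant") != (self.breakpoint is not None):
            raise DissectionError("breakpoint present iff label is recombinant")


def _span_indices(region: RegionMap) -> np.ndarray:
    """Panel SNP indices within the HLA-B..HLA-DQB1 anchor span."""
    anchors = region.anchors
    pos = region.snp_positions
    return np.flatnonzero((pos >= anchors["HLA-B"]) & (pos <= anchors["HLA-DQB1"]))


def classify_against_reference(
    haplotype: np.ndarray,
    focal_allele_carried: bool,
    reference: ReferenceExtended,
    region: RegionMap,
    mismatch_tolerance: int = 1,
) -> HaplotypeClass:
    """Classify one haplotype as extended / recombinant / other.

    ``focal_allele_carried`` states whether the haplotype carries the
    reference's focal allele (imputed or truth); non-carriers are "other".
    The comparison span runs from the HLA-B anchor to the HLA-DQB1 anchor.
    """
    if not focal_allele_carried:
        return HaplotypeClass("other")
    hap = np.asarray(haplotype)
    span = _span_indices(region)
    mism = hap[span] != reference.snp_pattern[span]
    if int(mism.sum()) <= mismatch_tolerance:
        return HaplotypeClass("extended")
    # scanning from the DQB1 (centromeric) side, find where divergence starts
    pos = region.snp_positions
    mm_idx = span[mism]
    matching = span[~mism]
    last_div = mm_idx.max()  # first divergent SNP on the Class I side
    right_matches = matching[matching > last_div]
    if right_matches.size:
        left_bp = int(pos[last_div])
        right_bp = int(pos[right_matches.min()])
    else:
        # diverges all the way to DQB1: breakpoint beyond the last span SNP
        left_bp = int(pos[last_div])
        right_bp = int(region.anchors["HLA-DQB1"])
    return HaplotypeClass("recombinant", (left_bp, right_bp))


def share_extended(n_subset: int, n_total: int) -> float:
    """Percentage ``100*n_subset/n_total`` rounded half-away-from-zero, 1 dp."""
    if n_total <= 0:
        raise DissectionError("n_total must be positive")
    if not 0 <= n_subset <= n_total:
        raise DissectionError("need 0 <= n_subset <= n_total")
    pct = Decimal(100 * n_subset) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def dissect_focal_allele(
    cohorts: dict[str, dict],
    focal_allele: str,
    focal_gene: str,
    reference: ReferenceExtended,
    region: RegionMap,
    mismatch_tolerance: int = 1,
) -> pd.DataFrame:
    """Tabulate extended/recombinant strata of a focal allele per cohort.

    ``cohorts`` maps cohort name to a dict with keys ``haplotypes`` (2n, m),
    ``calls`` (per-haplotype allele labels at the focal gene) and
    ``phenotype`` (per-individual bool).  Returns one row per cohort and
    stratum with case/control haplotype counts and frequencies, plus pooled
    totals usable for association and power analysis.
    """
    rows = []
    total_ext = total_rec = 0
    for name, data in cohorts.items():
        H = np.asarray(data["haplotypes"])
        calls = np.asarray(data["calls"], dtype=object)
        pheno = np.asarray(data["phenotype"], dtype=bool)
        hap_case = np.repeat(pheno, 2)
        carrier = calls == focal_allele
        labels = np.full(H.shape[0], "other", dtype=object)
        for h in np.flatnonzero(carrier):
            labels[h] = classify_against_reference(
                H[h], True, reference, region, mismatch_tolerance
            ).label
        n_case_chrom = int(hap_case.sum())
        n_ctrl_chrom = int((~hap_case).sum())
        for stratum in ("extended", "recombinant"):
            sel = labels == stratum
            ca = int(np.sum(sel & hap_case))
            co = int(np.sum(sel & ~hap_case))
            rows.append(
                {
                    "cohort": name,
                    "focal_allele": focal_allele,
                    "stratum": stratum,
                    "n_case_hap": ca,
                    "n_ctrl_hap": co,
                    "n_case_chrom": n_case_chrom,
                    "n_ctrl_chrom": n_ctrl_chrom,
                    "freq_case": ca / n_case_chrom if n_case_chrom else np.nan,
                    "freq_ctrl": co / n_ctrl_chrom if n_ctrl_chrom else np.nan,
                }
            )
            if stratum == "extended":
                total_ext += ca + co
            else:
                total_rec += ca + co
    df = pd.DataFrame(rows)
    total = total_ext + total_rec
    df.attrs["n_total"] = total
    df.attrs["n_extended"] = total_ext
    df.attrs["n_recombinant"] = total_rec
    df.attrs["pct_extended"] = share_extended(total_ext, total) if total else np.nan
    df.attrs["pct_recombinant"] = (
        share_extended(total_rec, total) if total else np.nan
    )
    return df
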