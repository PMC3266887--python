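"""Segment-based imputation of classical HLA alleles from phased SNP panels.

The workflow mirrors a tagging-SNP + haplotype-alignment strategy:

1. :func:`select_tag_snps` — pick one maximally informative (haploid r^2)
   SNP per common HLA allele plus a backbone of common, mutually
   independent SNPs spread across the region (denser over Class I).
2. :func:`learn_allele_segments` — on a phased, HLA-typed training set,
   find for each allele the longest run of consecutive panel SNPs around
   its tag whose carrier-consensus pattern occurs on no non-carrier
   haplotype ("allele-defining segment").
3. :func:`impute_hla_alleles` — call an allele on any haplotype matching
   its defining segment; conflicting or absent matches yield no-calls.
4. :func:`evaluate_imputation` — per-allele sensitivity / specificity /
   PPV on training and held-out validation haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohorts import GENES, RegionMap

__all__ = [
    "ImputationError",
    "TagSnpPanel",
    "AlleleDefiningSegment",
    "HlaCallSet",
    "select_tag_snps",
    "learn_allele_segments",
    "impute_hla_alleles",
    "evaluate_imputation",
    "allele_gene",
    "align_truth_labels",
    "haploid_r2",
]


class ImputationError(ValueError):
    pass


def allele_gene(allele: str) -> str:
    """Gene of an HLA allele label, e.g. ``DRB1*0301`` -> ``HLA-DRB1``."""
    return f"HLA-{allele.split('*')[0]}"


def haploid_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared correlation between two binary haploid vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return 0.0
    c = ((x - x.mean()) * (y - y.mean())).mean()
    return float(c * c / (vx * vy))


@dataclass
class TagSnpPanel:
    """Tagging + backbone SNP panel over a region's SNP loci."""

    tag_snps: dict[str, str]  # allele -> locus_id
    backbone_snps: list[str]
    region: RegionMap
    max_backbone_r2: float = 0.0
    maf: dict[str, float] = field(default_factory=dict)

    @property
    def tag_loci(self) -> list[str]:
        seen: list[str] = []
        for locus in self.tag_snps.values():
            if locus not in seen:
                seen.append(locus)
        return seen

    @property
    def panel_loci(self) -> list[str]:
        return sorted(
            set(self.tag_loci) | set(self.backbone_snps),
            key=self.region.snp_index_at,
        )

    @property
    def n_panel(self) -> int:
        return len(self.panel_loci)

    def tag_index(self, allele: str) -> int:
        return self.region.snp_index_at(self.tag_snps[allele])


@dataclass
class AlleleDefiningSegment:
    """Consecutive-SNP pattern uniquely identifying one HLA allele."""

    allele: str
    interval: tuple[int, int]  # half-open panel SNP index interval
    pattern: np.ndarray
    tag_index: int
    carrier_coverage: float = 1.0

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=np.int8)
        i, j = self.interval
        if not i <= self.tag_index < j:
            raise ImputationError(
                f"{self.allele}: segment [{i},{j}) does not contain tag {self.tag_index}"
            )
        if self.pattern.size != j - i:
            raise ImputationError(f"{self.allele}: pattern length mismatch")

    @property
    def gene(self) -> str:
        return allele_gene(self.allele)

    def matches(self, haplotypes: np.ndarray) -> np.ndarray:
        i, j = self.interval
        return np.all(haplotypes[:, i:j] == self.pattern[None, :], axis=1)


@dataclass
class HlaCallSet:
    """Per-haplotype, per-gene imputed allele calls (None = no-call)."""

    calls: dict[str, np.ndarray]  # gene -> (2n,) object array
    conflicts: dict[str, np.ndarray]  # gene -> (2n,) bool

    def dosage(self, allele: str) -> np.ndarray:
        """Per-individual copy count of ``allele`` over called chromosomes."""
        carrier = self.calls[allele_gene(allele)] == allele
        return (carrier[0::2].astype(int) + carrier[1::2]).astype(np.int64)

    def no_call_chromosomes(self, gene: str) -> np.ndarray:
        return np.array([c is None for c in self.calls[gene]])


# ---------------------------------------------------------------------------


def _common_alleles(
    labels: dict[str, np.ndarray], min_carriers: int
) -> list[tuple[str, int]]:
    """Alleles with enough carrier haplotypes, most common first."""
    out = []
    for gene in GENES:
        if gene not in labels:
            continue
        vals, counts = np.unique(
            [a for a in labels[gene] if a is not None and "*" in str(a)],
            return_counts=True,
        )
        for allele, count in zip(vals, counts):
            if count >= min_carriers:
                out.append((str(allele), int(count)))
    return sorted(out, key=lambda ac: (-ac[1], ac[0]))


def select_tag_snps(
    haplotypes: np.ndarray,
    labels: dict[str, np.ndarray],
    region: RegionMap,
    n_tags: int = 11,
    n_backbone: int = 38,
    r2_threshold: float = 0.5,
    maf_min: float = 0.05,
    min_carriers: int = 10,
    class1_boundary: int = 32_000_000,
    class1_weight: float = 1.5,
    control_mask: np.ndarray | None = None,
) -> TagSnpPanel:
    """Select the tagging + backbone SNP panel from phased training data.

    Each common HLA allele is tagged by the SNP with the highest haploid
    r^2 against its carrier indicator; alleles are processed from most to
    least common and, once ``n_tags`` distinct tag SNPs have accumulated,
    later alleles are tagged by the best SNP within the existing tag set.
    The backbone fills ``n_backbone`` further slots, greedily matching a
    density target (``class1_weight``-fold denser over Class I) subject to
    pairwise r^2 < ``r2_threshold`` and control MAF >= ``maf_min``.
    """
    H = np.asarray(haplotypes)
    ctrl = H if control_mask is None else H[control_mask]
    m = region.n_snps
    positions = region.snp_positions
    snp_ids = region.snp_ids

    maf = ctrl.mean(axis=0)
    maf = np.minimum(maf, 1 - maf)

    tag_map: dict[str, str] = {}
    tag_idx: list[int] = []
    for allele, _count in _common_alleles(labels, min_carriers):
        indicator = (labels[allele_gene(allele)] == allele).astype(float)
        r2 = np.array([haploid_r2(indicator, H[:, j]) for j in range(m)])
        if len(tag_idx) >= n_tags:
            cand = tag_idx
        else:
            cand = list(range(m))
        best = max(cand, key=lambda j: (r2[j], -j))
        tag_map[allele] = snp_ids[best]
        if best not in tag_idx:
            tag_idx.append(best)
    if len(tag_idx) < min(n_tags, len(tag_map)):
        raise ImputationError(
            f"only {len(tag_idx)} distinct tag SNPs found for {len(tag_map)} alleles"
        )

    # backbone: ideal positions from a piecewise density, greedy nearest fill
    remaining = [j for j in range(m) if j not in tag_idx]
    eligible = [j for j in remaining if maf[j] >= maf_min]
    lo, hi = positions.min(), positions.max()
    grid = np.linspace(lo, hi, 2000)
    dens = np.where(grid < class1_boundary, class1_weight, 1.0)
    cdf = np.cumsum(dens)
    cdf = cdf / cdf[-1]
    targets = np.interp(
        (np.arange(n_backbone) + 0.5) / n_backbone, cdf, grid
    )

    chosen: list[int] = []
    pool = set(eligible)
    violations: list[str] = []
    for t in targets:
        order = sorted(pool, key=lambda j: (abs(positions[j] - t), j))
        pick = None
        for j in order:
            if all(
                haploid_r2(ctrl[:, j], ctrl[:, k]) < r2_threshold for k in chosen
            ):
                pick = j
                break
        if pick is None:
            continue
        chosen.append(pick)
        pool.discard(pick)
    if len(chosen) < n_backbone:
        low_maf = [snp_ids[j] for j in remaining if maf[j] < maf_min]
        violations.append(f"{n_backbone - len(chosen)} backbone slots unfilled")
        if low_maf:
            violations.append(f"MAF < {maf_min}: {low_maf}")
        violations.append(f"pairwise r2 >= {r2_threshold} among remainder")
        raise ImputationError("backbone selection failed: " + "; ".join(violations))

    max_r2 = 0.0
    for a_i, j in enumerate(chosen):
        for k in chosen[a_i + 1:]:
            max_r2 = max(max_r2, haploid_r2(ctrl[:, j], ctrl[:, k]))

    return TagSnpPanel(
        tag_snps=tag_map,
        backbone_snps=[snp_ids[j] for j in sorted(chosen)],
        region=region,
        max_backbone_r2=max_r2,
        maf={snp_ids[j]: float(maf[j]) for j in range(m)},
    )


def learn_allele_segments(
    haplotypes: np.ndarray,
    labels: dict[str, np.ndarray],
    panel: TagSnpPanel,
    consensus: float = 0.95,
    min_carriers: int = 10,
    min_pattern_count: int = 2,
) -> tuple[list[AlleleDefiningSegment], list[str], list[str]]:
    """Learn allele-defining segments on phased, HLA-typed haplotypes.

    For every tagged allele, scan all windows of consecutive panel SNPs
    containing the tag; a window is valid when the per-position carrier
    majority pattern matches at least ``consensus`` of carriers and occurs
    on zero non-carrier haplotypes.  The largest valid window wins, ties
    broken toward the window most centered on the tag SNP.

    Training individuals contribute only when both of their reconstructed
    haplotypes occur at least ``min_pattern_count`` times in the pool:
    singleton haplotypes are dominated by phase-switch chimeras whose
    attached typing labels are unreliable (the manual-alignment analogue
    discounts such isolated discordant haplotypes).

    Returns ``(segments, untaggable, skipped)`` where ``untaggable`` lists
    alleles with no uniquely identifying window and ``skipped`` alleles
    with fewer than ``min_carriers`` training carriers.
    """
    H = np.asarray(haplotypes)
    if min_pattern_count > 1 and H.shape[0]:
        _uniq, inv, counts = np.unique(
            H, axis=0, return_inverse=True, return_counts=True
        )
        keep_hap = counts[inv] >= min_pattern_count
        # drop both chromosomes of an individual with any singleton
        keep_ind = keep_hap[0::2] & keep_hap[1::2]
        keep = np.repeat(keep_ind, 2)
        H = H[keep]
        labels = {g: v[keep] for g, v in labels.items()}
    m = H.shape[1]
    segments: list[AlleleDefiningSegment] = []
    untaggable: list[str] = []
    skipped: list[str] = []
    for allele in sorted(panel.tag_snps):
        gene = allele_gene(allele)
        carrier = labels[gene] == allele
        n_car = int(carrier.sum())
        if n_car < min_carriers:
            skipped.append(allele)
            continue
        t = panel.tag_index(allele)
        consensus_pat = (H[carrier].mean(axis=0) > 0.5).astype(np.int8)
        car_match = H[carrier] == consensus_pat[None, :]
        non_match = H[~carrier] == consensus_pat[None, :]
        car_run = np.c_[np.zeros((car_match.shape[0], 1), int), np.cumsum(car_match, axis=1)]
        non_run = np.c_[np.zeros((non_match.shape[0], 1), int), np.cumsum(non_match, axis=1)]

        best = None  # (length, -centering, -i, interval)
        for i in range(t + 1):
            for j in range(t + 1, m + 1):
                width = j - i
                cov = float(np.mean(car_run[:, j] - car_run[:, i] == width))
                if cov < consensus:
                    continue
                n_non = int(np.sum(non_run[:, j] - non_run[:, i] == width))
                if n_non > 0:
                    continue
                centering = abs((i + j - 1) / 2 - t)
                key = (width, -centering, -i)
                if best is None or key > best[0]:
                    best = (key, (i, j), cov)
        if best is None:
            untaggable.append(allele)
            continue
        (i, j) = best[1]
        segments.append(
            AlleleDefiningSegment(
                allele=allele,
                interval=(i, j),
                pattern=consensus_pat[i:j],
                tag_index=t,
                carrier_coverage=best[2],
            )
        )
    return segments, untaggable, skipped


def impute_hla_alleles(
    haplotypes: np.ndarray, segments: list[AlleleDefiningSegment]
) -> HlaCallSet:
    """Call HLA alleles on haplotypes by defining-segment alignment.

    A haplotype is called for allele A iff it matches A's segment pattern;
    zero matches for a gene gives a no-call, several matches a conflicted
    no-call.
    """
    H = np.asarray(haplotypes)
    n_hap = H.shape[0]
    calls = {g: np.full(n_hap, None, dtype=object) for g in GENES}
    n_matches = {g: np.zeros(n_hap, dtype=int) for g in GENES}
    for seg in segments:
        hit = seg.matches(H)
        gene = seg.gene
        calls[gene][hit & (n_matches[gene] == 0)] = seg.allele
        n_matches[gene] += hit
    conflicts = {}
    for gene in GENES:
        conflict = n_matches[gene] > 1
        calls[gene][conflict] = None
        conflicts[gene] = conflict
    return HlaCallSet(calls=calls, conflicts=conflicts)


def evaluate_imputation(
    calls: HlaCallSet,
    truth: dict[str, np.ndarray],
    splits: dict[str, np.ndarray],
    alleles: list[str] | None = None,
) -> pd.DataFrame:
    """Per-allele confusion counts and metrics on haplotype subsets.

    ``splits`` maps a set label (e.g. ``training`` / ``validation``) to a
    boolean mask over haplotypes; ``truth`` maps gene to per-haplotype true
    allele labels.  Haplotypes with no true label at a gene (unlabelled
    lineages) count as non-carriers of every allele of that gene.
    """
    rows = []
    for set_label, mask in splits.items():
        if not np.any(mask):
            raise ImputationError(f"evaluation set '{set_label}' is empty")
        for gene in GENES:
            if gene not in truth:
                continue
            t = truth[gene][mask]
            c = calls.calls[gene][mask]
            universe = alleles
            if universe is None:
                universe = sorted(
                    {a for a in t if a is not None} | {a for a in c if a is not None}
                )
            for allele in universe:
                if allele_gene(allele) != gene:
                    continue
                tp = int(np.sum((t == allele) & (c == allele)))
                fn = int(np.sum((t == allele) & (c != allele)))
                fp = int(np.sum((t != allele) & (c == allele)))
                tn = int(np.sum((t != allele) & (c != allele)))
                rows.append(
                    {
                        "set": set_label,
                        "gene": gene,
                        "allele": allele,
                        "TP": tp,
                        "FP": fp,
                        "FN": fn,
                        "TN": tn,
                        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                        "specificity": tn / (tn + fp) if tn + fp else np.nan,
                        "ppv": tp / (tp + fp) if tp + fp else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def align_truth_labels(phased_haplotypes: np.ndarray, cohort) -> dict[str, np.ndarray]:
    """Attach truth HLA labels to phased haplotypes by within-individual
    alignment (emulates assigning lab typing to reconstructed haplotypes).

    For each individual the phased pair is matched to the truth pair in the
    orientation minimizing total Hamming distance.
    """
    P = np.asarray(phased_haplotypes)
    T = cohort.haplotypes
    n = P.shape[0] // 2
    flip = np.zeros(n, dtype=bool)
    for i in range(n):
        straight = np.sum(P[2 * i] != T[2 * i]) + np.sum(P[2 * i + 1] != T[2 * i + 1])
        crossed = np.sum(P[2 * i] != T[2 * i + 1]) + np.sum(P[2 * i + 1] != T[2 * i])
        flip[i] = crossed < straight
    labels: dict[str, np.ndarray] = {}
    for gene in GENES:
        t = cohort.truth_hla(gene)
        out = t.copy()
        idx = np.flatnonzero(flip)
        out[2 * idx] = t[2 * idx + 1]
        out[2 * idx + 1] = t[2 * idx]
        labels[gene] = out
    return labels
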