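"""Synthetic MHC-like case-control cohort generator.

Generates diploid SNP genotypes over a chromosome-6-like region (Build-36
style coordinates, 25-35 Mb) from a pool of ancestral haplotype templates,
each carrying classical HLA allele labels at three anchor genes
(HLA-B, HLA-DRB1, HLA-DQB1) and, optionally, a causal variant with a
per-copy multiplicative genotype relative risk (GRR).

Key modelling choices:

* Penetrance is per-haplotype multiplicative: an individual's disease
  probability is ``f0 * grr(h1) * grr(h2)`` where ``grr(h)`` multiplies the
  GRRs of every causal variant physically carried by haplotype ``h``.  Risk
  travels with the mosaic segment that contains the causal position, so a
  recombinant haplotype that lost the causal segment carries no risk.
* With probability ``recomb_prob`` a sampled haplotype is a two-template
  mosaic with a single breakpoint drawn uniformly (in bp) between the
  HLA-B and HLA-DRB1 anchors (the interval where the modelled historical
  recombination events occur).
* Haplotypes not drawn from a template ("background") are per-SNP
  independent draws at the template-frequency-weighted allele frequencies
  and carry no risk and no HLA labels.
* ``f0`` is calibrated analytically so the population prevalence equals
  the requested value exactly under the sampling model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GENES",
    "Locus",
    "RegionMap",
    "HaplotypeTemplate",
    "CohortSpec",
    "SimulatedCohort",
    "ScenarioError",
    "build_default_scenario",
    "simulate_cohort",
    "sample_population",
    "apply_missingness_and_typing",
    "mean_relative_risk",
    "causal_dosages",
]

GENES = ("HLA-B", "HLA-DRB1", "HLA-DQB1")

MISSING = np.int8(-1)

#: internal batch size for rejection sampling; fixed so runs are reproducible
_BATCH = 20_000


class ScenarioError(ValueError):
    """Raised for invalid scenario configurations."""


@dataclass(frozen=True)
class Locus:
    locus_id: str
    position: int
    kind: str = "snp"  # "snp" | "hla_anchor"
    gene: str | None = None


@dataclass
class RegionMap:
    """Ordered loci of the simulated region (SNPs + three HLA anchors)."""

    loci: list[Locus]

    def __post_init__(self) -> None:
        pos = [l.position for l in self.loci]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ScenarioError("locus positions must be strictly increasing")
        anchors = [l for l in self.loci if l.kind == "hla_anchor"]
        if tuple(l.gene for l in anchors) != GENES:
            raise ScenarioError(
                f"region must contain exactly the anchors {GENES} in genomic order"
            )
        if any(l.kind not in ("snp", "hla_anchor") for l in self.loci):
            raise ScenarioError("locus kind must be 'snp' or 'hla_anchor'")

    @property
    def snp_loci(self) -> list[Locus]:
        return [l for l in self.loci if l.kind == "snp"]

    @property
    def snp_ids(self) -> list[str]:
        return [l.locus_id for l in self.snp_loci]

    @property
    def snp_positions(self) -> np.ndarray:
        return np.array([l.position for l in self.snp_loci], dtype=np.int64)

    @property
    def n_snps(self) -> int:
        return len(self.snp_loci)

    @property
    def anchors(self) -> dict[str, int]:
        return {l.gene: l.position for l in self.loci if l.kind == "hla_anchor"}

    def snp_index_at(self, locus_id: str) -> int:
        for i, l in enumerate(self.snp_loci):
            if l.locus_id == locus_id:
                return i
        raise KeyError(locus_id)


@dataclass
class HaplotypeTemplate:
    """An ancestral haplotype: SNP pattern, HLA labels, frequencies, risk."""

    name: str
    snp_pattern: np.ndarray
    hla_alleles: dict[str, str]
    cohort_freqs: dict[str, float]
    grr: float = 1.0
    causal_position: int | None = None

    def __post_init__(self) -> None:
        self.snp_pattern = np.asarray(self.snp_pattern, dtype=np.int8)
        if self.grr <= 0:
            raise ScenarioError(f"template {self.name}: grr must be > 0")
        if self.grr != 1.0 and self.causal_position is None:
            raise ScenarioError(
                f"template {self.name}: grr != 1 requires a causal_position"
            )
        if not set(np.unique(self.snp_pattern)) <= {0, 1}:
            raise ScenarioError(f"template {self.name}: pattern must be 0/1")


@dataclass
class CohortSpec:
    name: str
    n_cases: int
    n_controls: int
    templates: list[HaplotypeTemplate]
    recomb_prob: float = 0.02
    prevalence: float = 0.002
    missing_rate: float = 0.0
    typed_fraction: float = 1.0
    validation_size: int = 79
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ScenarioError("n_cases and n_controls must be positive")
        if not 0.0 <= self.recomb_prob <= 1.0:
            raise ScenarioError("recomb_prob must be in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ScenarioError("prevalence must be in (0, 1)")
        for rate in (self.missing_rate, self.typed_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ScenarioError("rates must be in [0, 1]")
        total = sum(t.cohort_freqs.get(self.name, 0.0) for t in self.templates)
        if total > 1.0 + 1e-9:
            raise ScenarioError(
                f"cohort {self.name}: template frequencies sum to {total:.4f} > 1"
            )

    @property
    def n_individuals(self) -> int:
        return self.n_cases + self.n_controls

    def template_freqs(self) -> np.ndarray:
        return np.array(
            [t.cohort_freqs.get(self.name, 0.0) for t in self.templates], dtype=float
        )


@dataclass
class SimulatedCohort:
    """Genotypes, phenotypes and full truth annotation for one cohort.

    Haplotype ``2*i`` and ``2*i + 1`` belong to individual ``i``.  A mosaic
    haplotype records its two source templates and the breakpoint ``b``:
    loci with ``position < b`` come from the left source, the rest from the
    right.  Background haplotypes have source ``-1``.
    """

    spec: CohortSpec
    region: RegionMap
    genotypes: np.ndarray  # (n, m) int8, -1 = missing
    phenotype: np.ndarray  # (n,) bool, True = case
    haplotypes: np.ndarray  # (2n, m) int8 truth
    hap_source: np.ndarray  # (2n, 2) template index, -1 = background
    hap_breakpoint: np.ndarray  # (2n,) bp, -1 if not mosaic
    typed_mask: np.ndarray = field(default=None)  # (n,) bool
    validation_mask: np.ndarray = field(default=None)  # (n,) bool

    def __post_init__(self) -> None:
        n = self.genotypes.shape[0]
        if self.typed_mask is None:
            self.typed_mask = np.ones(n, dtype=bool)
        if self.validation_mask is None:
            self.validation_mask = np.zeros(n, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def truth_hla(self, gene: str) -> np.ndarray:
        """Per-haplotype allele label at ``gene`` (None for background)."""
        anchor = self.region.anchors[gene]
        out = np.empty(self.haplotypes.shape[0], dtype=object)
        templates = self.spec.templates
        for h in range(out.size):
            left, right = self.hap_source[h]
            bp = self.hap_breakpoint[h]
            src = left if (bp < 0 or anchor < bp) else right
            out[h] = None if src < 0 else templates[src].hla_alleles.get(gene)
        return out

    def truth_hla_table(self) -> "object":
        """Long-format truth table: sample, haplotype, gene, allele."""
        import pandas as pd

        rows = []
        for gene in GENES:
            labels = self.truth_hla(gene)
            for h, allele in enumerate(labels):
                rows.append(
                    {
                        "sample": f"{self.spec.name}_{h // 2:05d}",
                        "haplotype": h % 2 + 1,
                        "gene": gene,
                        "allele": allele if allele is not None else "NA",
                    }
                )
        return pd.DataFrame(rows)

    def hap_grr(self) -> np.ndarray:
        """Per-haplotype multiplicative relative risk (truth)."""
        return _hap_grr(self.spec.templates, self.hap_source, self.hap_breakpoint)


# ---------------------------------------------------------------------------
# risk model helpers


def _causal_grr_arrays(templates: list[HaplotypeTemplate]):
    grr = np.array([t.grr for t in templates] + [1.0])
    causal = np.array(
        [t.causal_position if t.causal_position is not None else -1 for t in templates]
        + [-1],
        dtype=np.int64,
    )
    return grr, causal


def _hap_grr(templates, hap_source, hap_breakpoint) -> np.ndarray:
    grr, causal = _causal_grr_arrays(templates)
    left = hap_source[:, 0].copy()
    right = hap_source[:, 1].copy()
    bp = hap_breakpoint
    gl = np.where((causal[left] >= 0) & ((bp < 0) | (causal[left] < bp)), grr[left], 1.0)
    gr = np.where((bp >= 0) & (causal[right] >= 0) & (causal[right] >= bp), grr[right], 1.0)
    return gl * gr


def mean_relative_risk(spec: CohortSpec, region: RegionMap) -> float:
    """Exact E[grr(h)] for one randomly sampled haplotype under ``spec``.

    The mosaic expectation is integrated in closed form over the uniform
    breakpoint distribution: the product of the left/right conditional
    means is piecewise constant between causal positions.
    """
    freqs = spec.template_freqs()
    f_bg = 1.0 - freqs.sum()
    grrs = np.array([t.grr for t in spec.templates])
    causal = np.array(
        [t.causal_position if t.causal_position is not None else -1 for t in spec.templates],
        dtype=np.int64,
    )
    base = float(freqs @ grrs + f_bg)

    anchors = region.anchors
    lo, hi = anchors["HLA-B"], anchors["HLA-DRB1"]
    cuts = sorted({lo, hi} | {int(c) for c in causal if lo < c < hi})
    e_mosaic = 0.0
    for x0, x1 in zip(cuts, cuts[1:]):
        # breakpoint bp uniform over integers in (x0, x1]
        u = float(np.sum(freqs * np.where((causal >= 0) & (causal <= x0), grrs, 1.0)) + f_bg)
        v = float(np.sum(freqs * np.where((causal >= 0) & (causal >= x1), grrs, 1.0)) + f_bg)
        e_mosaic += (x1 - x0) / (hi - lo) * u * v
    rho = spec.recomb_prob
    return (1.0 - rho) * base + rho * e_mosaic


def _baseline_penetrance(spec: CohortSpec, region: RegionMap) -> float:
    mu = mean_relative_risk(spec, region)
    f0 = spec.prevalence / (mu * mu)
    # largest achievable per-haplotype grr: single template or mosaic pair
    grrs = [t.grr for t in spec.templates]
    causal = [t.causal_position for t in spec.templates]
    gmax = max([1.0] + grrs)
    for i, ci in enumerate(causal):
        for j, cj in enumerate(causal):
            if ci is not None and cj is not None and ci < cj:
                gmax = max(gmax, grrs[i] * grrs[j])
    if f0 * gmax * gmax > 1.0:
        raise ScenarioError(
            f"cohort {spec.name}: prevalence {spec.prevalence} unreachable — "
            f"baseline penetrance {f0:.3g} times max grr^2 {gmax**2:.3g} exceeds 1"
        )
    return f0


# ---------------------------------------------------------------------------
# haplotype sampling


def _draw_haplotypes(rng: np.random.Generator, spec: CohortSpec, region: RegionMap, k: int):
    """Draw ``k`` haplotypes; returns (haps, source, breakpoint, grr)."""
    freqs = spec.template_freqs()
    f_bg = max(0.0, 1.0 - freqs.sum())
    probs = np.append(freqs, f_bg)
    probs = probs / probs.sum()
    n_t = len(spec.templates)
    patterns = np.vstack(
        [t.snp_pattern for t in spec.templates] + [np.zeros(region.n_snps, dtype=np.int8)]
    )
    bg_freq = freqs @ patterns[:-1].astype(float)
    if freqs.sum() > 0:
        bg_freq = bg_freq / freqs.sum()
    positions = region.snp_positions
    anchors = region.anchors
    lo, hi = anchors["HLA-B"], anchors["HLA-DRB1"]

    idx_l = rng.choice(n_t + 1, size=k, p=probs)
    idx_r = rng.choice(n_t + 1, size=k, p=probs)
    mosaic = rng.random(k) < spec.recomb_prob
    bp = rng.integers(lo + 1, hi + 1, size=k)
    bg_draw = (rng.random((k, region.n_snps)) < bg_freq).astype(np.int8)

    idx_r = np.where(mosaic, idx_r, idx_l)
    bp = np.where(mosaic, bp, -1)

    left = patterns[idx_l].copy()
    right = patterns[idx_r].copy()
    left[idx_l == n_t] = bg_draw[idx_l == n_t]
    right[idx_r == n_t] = bg_draw[idx_r == n_t]
    take_left = (bp[:, None] < 0) | (positions[None, :] < bp[:, None])
    haps = np.where(take_left, left, right).astype(np.int8)

    source = np.stack(
        [np.where(idx_l == n_t, -1, idx_l), np.where(idx_r == n_t, -1, idx_r)], axis=1
    ).astype(np.int64)
    grr = _hap_grr(spec.templates, source, bp)
    return haps, source, bp, grr


def _assemble(spec, region, h1, h2, s1, s2, b1, b2, phenotype, typed=None, valid=None):
    n = h1.shape[0]
    haps = np.empty((2 * n, region.n_snps), dtype=np.int8)
    haps[0::2] = h1
    haps[1::2] = h2
    source = np.empty((2 * n, 2), dtype=np.int64)
    source[0::2] = s1
    source[1::2] = s2
    bp = np.empty(2 * n, dtype=np.int64)
    bp[0::2] = b1
    bp[1::2] = b2
    genotypes = (h1 + h2).astype(np.int8)
    return SimulatedCohort(
        spec=spec,
        region=region,
        genotypes=genotypes,
        phenotype=phenotype.astype(bool),
        haplotypes=haps,
        hap_source=source,
        hap_breakpoint=bp,
        typed_mask=typed,
        validation_mask=valid,
    )


def simulate_cohort(spec: CohortSpec, region: RegionMap) -> SimulatedCohort:
    """Rejection-sample a case-control cohort under the planted risk model.

    Individuals are drawn from the haplotype pool until ``n_cases`` cases and
    ``n_controls`` controls are ascertained; disease status is Bernoulli with
    probability ``f0 * grr(h1) * grr(h2)``.
    """
    rng = np.random.default_rng(spec.seed)
    f0 = _baseline_penetrance(spec, region)
    want_ca, want_co = spec.n_cases, spec.n_controls
    got = {True: [], False: []}
    while len(got[True]) < want_ca or len(got[False]) < want_co:
        h, s, b, g = _draw_haplotypes(rng, spec, region, 2 * _BATCH)
        h1, h2 = h[:_BATCH], h[_BATCH:]
        s1, s2 = s[:_BATCH], s[_BATCH:]
        b1, b2 = b[:_BATCH], b[_BATCH:]
        pen = f0 * g[:_BATCH] * g[_BATCH:]
        is_case = rng.random(_BATCH) < pen
        for flag, want in ((True, want_ca), (False, want_co)):
            need = want - len(got[flag])
            if need > 0:
                take = np.flatnonzero(is_case == flag)[:need]
                for i in take:
                    got[flag].append((h1[i], h2[i], s1[i], s2[i], b1[i], b2[i]))
    rows = got[True] + got[False]
    phenotype = np.r_[np.ones(want_ca, bool), np.zeros(want_co, bool)]
    h1 = np.stack([r[0] for r in rows])
    h2 = np.stack([r[1] for r in rows])
    s1 = np.stack([r[2] for r in rows])
    s2 = np.stack([r[3] for r in rows])
    b1 = np.array([r[4] for r in rows])
    b2 = np.array([r[5] for r in rows])
    return _assemble(spec, region, h1, h2, s1, s2, b1, b2, phenotype)


def sample_population(spec: CohortSpec, region: RegionMap, n: int, seed: int | None = None) -> SimulatedCohort:
    """Draw ``n`` unascertained individuals; case status follows penetrance."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    f0 = _baseline_penetrance(spec, region)
    h, s, b, g = _draw_haplotypes(rng, spec, region, 2 * n)
    pen = f0 * g[:n] * g[n:]
    phenotype = rng.random(n) < pen
    return _assemble(
        spec, region, h[:n], h[n:], s[:n], s[n:], b[:n], b[n:], phenotype
    )


def apply_missingness_and_typing(cohort: SimulatedCohort, spec: CohortSpec) -> SimulatedCohort:
    """Mask genotypes at ``missing_rate`` and mark the HLA-typed subset.

    The typed subset is split into a training part and a held-out validation
    part of ``spec.validation_size`` individuals.
    """
    rng = np.random.default_rng([spec.seed, 0xA11E1E])
    n = cohort.n_individuals
    genotypes = cohort.genotypes.copy()
    if spec.missing_rate > 0:
        mask = rng.random(genotypes.shape) < spec.missing_rate
        genotypes[mask] = MISSING
    n_typed = int(round(spec.typed_fraction * n))
    typed_idx = rng.permutation(n)[:n_typed]
    typed = np.zeros(n, dtype=bool)
    typed[typed_idx] = True
    if n_typed < spec.validation_size:
        raise ScenarioError(
            f"typed subset ({n_typed}) smaller than validation size "
            f"({spec.validation_size})"
        )
    valid = np.zeros(n, dtype=bool)
    valid[rng.choice(typed_idx, size=spec.validation_size, replace=False)] = True
    return dataclasses.replace(
        cohort, genotypes=genotypes, typed_mask=typed, validation_mask=valid
    )


def causal_dosages(cohort: SimulatedCohort) -> dict[int, np.ndarray]:
    """Per-individual copy counts of each planted causal variant (truth).

    Keys are causal bp positions; a haplotype carries the variant at position
    ``c`` planted on template ``t`` iff the mosaic segment sourced from a
    template with that causal position contains ``c``.
    """
    templates = cohort.spec.templates
    positions = sorted(
        {t.causal_position for t in templates if t.causal_position is not None and t.grr != 1.0}
    )
    grr, causal = _causal_grr_arrays(templates)
    left = cohort.hap_source[:, 0]
    right = cohort.hap_source[:, 1]
    bp = cohort.hap_breakpoint
    out: dict[int, np.ndarray] = {}
    for c in positions:
        lcar = (causal[left] == c) & (grr[left] != 1.0) & ((bp < 0) | (c < bp))
        rcar = (bp >= 0) & (causal[right] == c) & (grr[right] != 1.0) & (c >= bp)
        carrier = (lcar | rcar).astype(np.int64)
        out[int(c)] = carrier[0::2] + carrier[1::2]
    return out


# ---------------------------------------------------------------------------
# default scenario (three European-style cohorts, 49-SNP panel)

_COHORTS = (
    ("sweden_iceland", 430, 1090),
    ("spain", 256, 322),
    ("finland", 86, 564),
)

# anchor gene coordinates (Build-36 style)
_POS_B = 31_430_000
_POS_DRB1 = 32_654_000
_POS_DQB1 = 32_735_000

# planted causal positions
_CAUSAL_DR3 = 32_300_000  # Class III / Class II border
_CAUSAL_DR7 = 32_710_000  # DQA1-DQB1 interval
_CAUSAL_DR1 = 32_150_000  # Class III, telomeric to Class II
_CAUSAL_DR15 = 32_690_000  # DRB1-DQB1 block

# template table: name, (B, DRB1, DQB1), per-cohort control freqs, grr, causal
_TEMPLATE_DEFS = [
    ("ext_DR3", ("B*0801", "DRB1*0301", "DQB1*0201"), (0.097, 0.026, 0.083), 3.33, _CAUSAL_DR3),
    ("rec_DR3", ("B*1801", "DRB1*0301", "DQB1*0201"), (0.039, 0.093, 0.030), 1.0, None),
    ("ext_DR7", ("B*1302", "DRB1*0701", "DQB1*0202"), (0.008, 0.009, 0.023), 2.23, _CAUSAL_DR7),
    ("rec_DR7_DQ2", ("B*4402", "DRB1*0701", "DQB1*0202"), (0.049, 0.132, 0.038), 2.23, _CAUSAL_DR7),
    ("rec_DR7_nonDQ2", ("B*5701", "DRB1*0701", "DQB1*0303"), (0.033, 0.033, 0.008), 1.0, None),
    ("ext_DR1_0102", ("B*1402", "DRB1*0102", "DQB1*0501"), (0.002, 0.030, 0.002), 4.59, _CAUSAL_DR1),
    ("rec_DR1_0102", ("B*3501", "DRB1*0102", "DQB1*0501"), (0.001, 0.016, 0.003), 4.59, _CAUSAL_DR1),
    ("ext_DR15", ("B*0702", "DRB1*1501", "DQB1*0602"), (0.077, 0.034, 0.067), 0.14, _CAUSAL_DR15),
    ("rec_DR15", ("B*4001", "DRB1*1501", "DQB1*0602"), (0.073, 0.073, 0.063), 0.14, _CAUSAL_DR15),
    ("DR1_0101", ("B*2705", "DRB1*0101", "DQB1*0501"), (0.121, 0.107, 0.211), 1.0, None),
    ("DR4", ("B*4402", "DRB1*0401", "DQB1*0302"), (0.150, 0.100, 0.120), 1.0, None),
    ("DR13", ("B*4403", "DRB1*1301", "DQB1*0603"), (0.120, 0.100, 0.100), 1.0, None),
    ("DR11", ("B*3502", "DRB1*1101", "DQB1*0301"), (0.080, 0.120, 0.080), 1.0, None),
    ("DR8", ("B*5101", "DRB1*0801", "DQB1*0402"), (0.070, 0.060, 0.090), 1.0, None),
    ("DR9", ("B*1501", "DRB1*0901", "DQB1*0303"), (0.050, 0.040, 0.050), 1.0, None),
    # breaks the otherwise perfect DRB1*1501 / DQB1*0602 carrier-set identity
    ("DR16", ("B*3801", "DRB1*1602", "DQB1*0602"), (0.020, 0.020, 0.020), 1.0, None),
]

# recombinant templates share the DQB1-proximal part of their extended
# partner's pattern: (template, partner, share_from_bp, share_to_bp)
_SHARING = [
    ("rec_DR3", "ext_DR3", 32_400_000, None),
    ("rec_DR7_DQ2", "ext_DR7", 32_500_000, None),
    ("rec_DR7_nonDQ2", "ext_DR7", 32_500_000, 32_700_000),
    ("rec_DR1_0102", "ext_DR1_0102", 31_900_000, None),
    ("rec_DR15", "ext_DR15", 32_400_000, None),
]

# HLA-tagging SNPs: position -> tagged allele plus templates OR'ed in to keep
# the SNP common (a tag for a rare allele is shared with a neutral lineage;
# the flanking segment, not the tag alone, identifies the allele).
_TAG_DEFS = [
    (31_398_000, "B*0801", ()),
    (31_407_000, "B*1302", ("DR13",)),
    (31_417_000, "B*1402", ("DR11",)),
    (31_441_000, "B*0702", ()),
    (32_600_000, "DRB1*0301", ()),
    (32_620_000, "DRB1*0701", ()),
    (32_640_000, "DRB1*0102", ("DR4",)),
    (32_660_000, "DRB1*0101", ()),
    (32_670_000, "DRB1*1501", ()),
    (32_720_000, "DQB1*0501", ()),
    (32_740_000, "DQB1*0602", ()),
]

_PATTERN_SEED = 240_112


def _backbone_positions() -> list[int]:
    class1 = [31_200_000 + 44_000 * i for i in range(18)]  # denser Class I
    class3 = [32_050_000 + 56_000 * i for i in range(8)]
    class2 = [32_513_000 + 20_000 * i for i in range(12)]
    pos = class1 + class3 + class2
    assert len(pos) == 38
    return pos


def _carries(alleles: tuple[str, str, str], allele: str) -> bool:
    return allele in alleles


def _weighted_r2(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    px = float(w @ x)
    py = float(w @ y)
    pxy = float(w @ (x * y))
    var = px * (1 - px) * py * (1 - py)
    if var <= 0:
        return 0.0
    return (pxy - px * py) ** 2 / var


def build_default_scenario(
    seed: int = 1,
    missing_rate: float = 0.01,
    typed_fraction: float = 0.5,
    recomb_prob: float = 0.01,
    prevalence: float = 0.002,
) -> tuple[RegionMap, list[CohortSpec]]:
    """Default three-cohort scenario with the four planted haplotype effects.

    Control-population template frequencies follow the published per-cohort
    haplotype frequency table; per-copy risks 3.33 (extended DR3 lineage),
    2.23 (DQB1*02-bearing DR7 lineages), 4.59 (DRB1*0102 lineages) and 0.14
    (DR15 lineages) are attached to fixed causal positions so that risk
    travels with the corresponding haplotype segment.

    Frequencies for the recombinant non-B*0801 DR3 lineage and the minor
    recombinant lineages are invented (not published); see config comments
    emitted by :mod:`hlafinemap.pipeline_io`.
    """
    names = [c[0] for c in _COHORTS]
    # control-frequency weights (pooled across cohorts) used for pattern QC
    ctrl_n = np.array([c[2] for c in _COHORTS], dtype=float)
    freq_mat = np.array([d[2] for d in _TEMPLATE_DEFS])  # (T, 3)
    pooled = freq_mat @ (ctrl_n / ctrl_n.sum())
    w = pooled / pooled.sum()

    tag_positions = [t[0] for t in _TAG_DEFS]
    backbone = _backbone_positions()
    all_defs: list[tuple[int, str, np.ndarray | None]] = []
    for i, (pos, allele, extra) in enumerate(_TAG_DEFS):
        col = np.array(
            [
                1 if (_carries(d[1], allele) or d[0] in extra) else 0
                for d in _TEMPLATE_DEFS
            ],
            dtype=np.int8,
        )
        all_defs.append((pos, f"tag{i + 1:02d}_{allele.replace('*', '')}", col))

    # backbone columns: random per-template alleles, rejected until common
    # (pooled MAF >= 0.07) and in low pairwise LD (r^2 < 0.4) post-sharing;
    # screened against tag columns too so that any 38-SNP backbone subset of
    # the final panel satisfies the pairwise-r^2 constraint
    rng = np.random.default_rng(_PATTERN_SEED)
    t_index = {d[0]: i for i, d in enumerate(_TEMPLATE_DEFS)}
    share = [
        (t_index[t], t_index[p], lo, hi if hi is not None else 10**9)
        for t, p, lo, hi in _SHARING
    ]
    accepted: list[np.ndarray] = [col for _, _, col in all_defs]
    for j, pos in enumerate(backbone):
        for _attempt in range(1000):
            col = (rng.random(len(_TEMPLATE_DEFS)) < 0.5).astype(np.int8)
            for ti, pi, lo, hi in share:
                if lo <= pos < hi:
                    col[ti] = col[pi]
            maf = float(w @ col)
            if not 0.07 <= maf <= 0.93:
                continue
            if any(_weighted_r2(col, prev, w) >= 0.40 for prev in accepted):
                continue
            accepted.append(col)
            break
        else:  # pragma: no cover - generation is deterministic and verified
            raise ScenarioError(f"could not generate backbone column at {pos}")
        all_defs.append((pos, f"bb{j + 1:02d}", col))

    all_defs.sort(key=lambda d: d[0])
    snp_positions = [d[0] for d in all_defs]
    columns = np.stack([d[2] for d in all_defs], axis=1)  # (T, 49)

    loci = [Locus(d[1], d[0], "snp") for d in all_defs]
    loci += [
        Locus("HLA-B", _POS_B, "hla_anchor", "HLA-B"),
        Locus("HLA-DRB1", _POS_DRB1, "hla_anchor", "HLA-DRB1"),
        Locus("HLA-DQB1", _POS_DQB1, "hla_anchor", "HLA-DQB1"),
    ]
    loci.sort(key=lambda l: l.position)
    region = RegionMap(loci)

    templates = []
    for i, (name, (b, dr, dq), freqs, grr, causal) in enumerate(_TEMPLATE_DEFS):
        templates.append(
            HaplotypeTemplate(
                name=name,
                snp_pattern=columns[i],
                hla_alleles={"HLA-B": b, "HLA-DRB1": dr, "HLA-DQB1": dq},
                cohort_freqs=dict(zip(names, np.asarray(freqs, dtype=float))),
                grr=grr,
                causal_position=causal,
            )
        )

    specs = [
        CohortSpec(
            name=name,
            n_cases=n_ca,
            n_controls=n_co,
            templates=templates,
            recomb_prob=recomb_prob,
            prevalence=prevalence,
            missing_rate=missing_rate,
            typed_fraction=typed_fraction,
            seed=seed + k,
        )
        for k, (name, n_ca, n_co) in enumerate(_COHORTS)
    ]
    assert region.n_snps == 49
    assert len(tag_positions) == 11 and len(snp_positions) == 49
    return region, specs
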