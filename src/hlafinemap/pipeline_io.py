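"""File formats, configuration and the end-to-end pipeline orchestrator.

All genomic coordinates are emitted 1-based only where the format demands
it (VCF); internally everything is 0-based half-open over panel SNP
indices with bp positions carried alongside.  The missing-genotype
sentinel is ``-1`` internally and ``NA`` / ``./.`` on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association_stats import (
    GENOME_WIDE_P,
    allele_association,
    AlleleCounts2x2,
    AssociationError,
    cmh_combined,
    logistic_scan,
    meta_weighted_z,
    stepwise_conditional,
)
from .haplotype_dissection import (
    ReferenceExtended,
    classify_against_reference,
    dissect_focal_allele,
)
from .hla_imputation import (
    align_truth_labels,
    allele_gene,
    evaluate_imputation,
    impute_hla_alleles,
    learn_allele_segments,
    select_tag_snps,
)
from .phasing import partition_ligation_phase
from .power_analysis import DEFAULT_ALPHAS, power_table
from .synthetic_cohorts import (
    GENES,
    CohortSpec,
    HaplotypeTemplate,
    Locus,
    RegionMap,
    SimulatedCohort,
    apply_missingness_and_typing,
    build_default_scenario,
    simulate_cohort,
)

__all__ = [
    "PipelineIOError",
    "PipelineConfig",
    "RunReport",
    "write_vcf",
    "write_tabular",
    "read_genotypes",
    "write_phased_tsv",
    "write_truth_tables",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "simulate_to_dir",
    "load_simulated_dir",
    "run_pipeline",
]

MISSING = -1


class PipelineIOError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotype round-trip formats


def write_vcf(
    path: str | Path,
    genotypes: np.ndarray,
    region: RegionMap,
    samples: list[str],
    phased_haplotypes: np.ndarray | None = None,
) -> None:
    """Write a minimal GT-only VCF (v4.2, chromosome 6, 1-based positions)."""
    G = np.asarray(genotypes)
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=6,length=171115067>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for j, locus in enumerate(region.snp_loci):
        fields = ["6", str(locus.position), locus.locus_id, "A", "G", ".", "PASS", ".", "GT"]
        if phased_haplotypes is None:
            for i in range(G.shape[0]):
                g = G[i, j]
                fields.append("./." if g == MISSING else ("0/0", "0/1", "1/1")[g])
        else:
            H = phased_haplotypes
            for i in range(G.shape[0]):
                fields.append(f"{H[2 * i, j]}|{H[2 * i + 1, j]}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_tabular(
    path: str | Path, genotypes: np.ndarray, region: RegionMap, samples: list[str]
) -> None:
    """Write genotypes as TSV: rows = samples, columns = loci, codes 0/1/2/NA."""
    G = np.asarray(genotypes)
    df = pd.DataFrame(G, columns=region.snp_ids)
    df = df.astype(object).where(G != MISSING, "NA")
    df.insert(0, "sample", samples)
    df.to_csv(path, sep="\t", index=False)


def _read_vcf(path: Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, positions, rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise PipelineIOError(
                f"multi-allelic site at {var.CHROM}:{var.POS} ({var.ID})"
            )
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        gt = var.genotype.array()[:, :2]
        row = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        rows.append(row.astype(np.int8))
    matrix = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), np.int8)
    return samples, matrix, ids, positions


def _read_tabular(path: Path):
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise PipelineIOError(f"malformed tabular genotype file {path}: {exc}")
    if "sample" not in df.columns:
        raise PipelineIOError(f"{path}: missing 'sample' column")
    samples = df["sample"].tolist()
    loci = [c for c in df.columns if c != "sample"]
    matrix = np.empty((len(samples), len(loci)), dtype=np.int8)
    for j, c in enumerate(loci):
        for i, v in enumerate(df[c]):
            if v == "NA":
                matrix[i, j] = MISSING
            elif v in ("0", "1", "2"):
                matrix[i, j] = int(v)
            else:
                raise PipelineIOError(
                    f"{path} line {i + 2}: invalid genotype code {v!r} at {c}"
                )
    return samples, matrix, loci, None


def read_genotypes(path: str | Path, fmt: str | None = None):
    """Read a genotype matrix from VCF or the tabular dialect.

    Returns ``(samples, matrix, locus_ids, positions)``; ``positions`` is
    None for the tabular dialect (which does not carry coordinates).
    """
    path = Path(path)
    if not path.exists():
        raise PipelineIOError(f"genotype file not found: {path}")
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "tabular"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tabular":
        return _read_tabular(path)
    raise PipelineIOError(f"unknown genotype format {fmt!r}")


def write_phased_tsv(path: str | Path, haplotypes: np.ndarray, samples: list[str],
                     certainty: np.ndarray | None = None) -> None:
    rows = []
    for i, s in enumerate(samples):
        for k in (0, 1):
            rows.append(
                {
                    "sample": s,
                    "haplotype": k + 1,
                    "pattern": "".join(map(str, haplotypes[2 * i + k])),
                    "certainty": "" if certainty is None else f"{certainty[i]:.6f}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_tables(outdir: Path, cohort: SimulatedCohort, samples: list[str]) -> None:
    """Persist truth haplotypes/HLA/masks so a cohort can be reloaded exactly."""
    hap_rows = []
    for i, s in enumerate(samples):
        for k in (0, 1):
            h = 2 * i + k
            hap_rows.append(
                {
                    "sample": s,
                    "haplotype": k + 1,
                    "pattern": "".join(map(str, cohort.haplotypes[h])),
                    "source_left": cohort.hap_source[h, 0],
                    "source_right": cohort.hap_source[h, 1],
                    "breakpoint": cohort.hap_breakpoint[h],
                }
            )
    pd.DataFrame(hap_rows).to_csv(outdir / "truth_haplotypes.tsv", sep="\t", index=False)
    typing = []
    for gene in GENES:
        labels = cohort.truth_hla(gene)
        for i, s in enumerate(samples):
            if not cohort.typed_mask[i]:
                continue
            for k in (0, 1):
                allele = labels[2 * i + k]
                typing.append(
                    {
                        "sample": s,
                        "haplotype": k + 1,
                        "gene": gene,
                        "allele": allele if allele else "NA",
                        "resolution": 4,
                    }
                )
    pd.DataFrame(typing).to_csv(outdir / "hla_typing.tsv", sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "sample": samples,
            "phenotype": np.where(cohort.phenotype, "case", "control"),
            "typed": cohort.typed_mask.astype(int),
            "validation": cohort.validation_mask.astype(int),
        }
    )
    meta.to_csv(outdir / "samples.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# scenario (de)serialization


def scenario_to_yaml(region: RegionMap, specs: list[CohortSpec]) -> str:
    doc = {
        "region": {
            "loci": [
                {
                    "id": l.locus_id,
                    "position": int(l.position),
                    "kind": l.kind,
                    **({"gene": l.gene} if l.gene else {}),
                }
                for l in region.loci
            ]
        },
        "templates": [
            {
                "name": t.name,
                "pattern": "".join(map(str, t.snp_pattern)),
                "hla_alleles": dict(t.hla_alleles),
                "cohort_freqs": {k: float(v) for k, v in t.cohort_freqs.items()},
                "grr": float(t.grr),
                **(
                    {"causal_position": int(t.causal_position)}
                    if t.causal_position is not None
                    else {}
                ),
            }
            for t in specs[0].templates
        ],
        "cohorts": [
            {
                "name": s.name,
                "n_cases": s.n_cases,
                "n_controls": s.n_controls,
                "recomb_prob": s.recomb_prob,
                "prevalence": s.prevalence,
                "missing_rate": s.missing_rate,
                "typed_fraction": s.typed_fraction,
                "validation_size": s.validation_size,
                "seed": s.seed,
            }
            for s in specs
        ],
    }
    header = (
        "# Synthetic MHC scenario. Control-population frequencies of the\n"
        "# extended/recombinant risk lineages follow the published per-cohort\n"
        "# haplotype table; frequencies of minor recombinant lineages are\n"
        "# invented defaults (no published values exist for them).\n"
    )
    return header + yaml.safe_dump(doc, sort_keys=False)


def scenario_from_yaml(text: str) -> tuple[RegionMap, list[CohortSpec]]:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise PipelineIOError(f"invalid scenario YAML: {exc}")
    for key in ("region", "templates", "cohorts"):
        if key not in doc:
            raise PipelineIOError(f"scenario missing section {key!r}")
    loci = [
        Locus(d["id"], int(d["position"]), d.get("kind", "snp"), d.get("gene"))
        for d in doc["region"]["loci"]
    ]
    region = RegionMap(loci)
    templates = [
        HaplotypeTemplate(
            name=t["name"],
            snp_pattern=np.array([int(c) for c in t["pattern"]], dtype=np.int8),
            hla_alleles=dict(t["hla_alleles"]),
            cohort_freqs=dict(t["cohort_freqs"]),
            grr=float(t.get("grr", 1.0)),
            causal_position=t.get("causal_position"),
        )
        for t in doc["templates"]
    ]
    specs = [
        CohortSpec(templates=templates, **c) for c in doc["cohorts"]
    ]
    return region, specs


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    scenario: str = "default"  # "default" or a scenario YAML path
    input_dir: str | None = None  # pre-simulated cohort directory
    outdir: str = "out"
    seed: int = 1
    genotype_format: str = "tabular"  # "tabular" | "vcf"
    window_size: int = 8
    top_patterns: int = 30
    consensus: float = 0.95
    min_carriers: int = 10
    mismatch_tolerance: int = 1
    r2_threshold: float = 0.5
    maf_min: float = 0.05
    n_tags: int = 11
    n_backbone: int = 38
    significance: float = GENOME_WIDE_P
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    run_scan: bool = True
    run_power: bool = True

    def validate(self) -> None:
        checks = [
            (0 < self.consensus <= 1, "consensus in (0, 1]"),
            (0 <= self.mismatch_tolerance <= 10, "mismatch_tolerance in [0, 10]"),
            (0 < self.r2_threshold <= 1, "r2_threshold in (0, 1]"),
            (0 <= self.maf_min < 0.5, "maf_min in [0, 0.5)"),
            (0 < self.significance < 1, "significance in (0, 1)"),
            (2 <= self.window_size <= 12, "window_size in [2, 12]"),
            (self.genotype_format in ("tabular", "vcf"), "genotype_format"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise PipelineIOError("invalid config: " + "; ".join(bad))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineIOError(f"config file not found: {path}")
        doc = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineIOError(f"unknown config keys: {sorted(unknown)}")
        if "alphas" in doc:
            doc["alphas"] = tuple(doc["alphas"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# simulate / load cohort directories


def _sample_names(spec: CohortSpec) -> list[str]:
    return [f"{spec.name}_{i:05d}" for i in range(spec.n_individuals)]


def simulate_to_dir(
    region: RegionMap, specs: list[CohortSpec], outdir: str | Path, fmt: str = "tabular"
) -> dict[str, SimulatedCohort]:
    """Simulate every cohort and persist genotypes + truth as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "scenario.yaml").write_text(scenario_to_yaml(region, specs))
    cohorts = {}
    for spec in specs:
        cdir = outdir / spec.name
        cdir.mkdir(exist_ok=True)
        cohort = apply_missingness_and_typing(simulate_cohort(spec, region), spec)
        samples = _sample_names(spec)
        if fmt == "vcf":
            write_vcf(cdir / "genotypes.vcf", cohort.genotypes, region, samples)
        else:
            write_tabular(cdir / "genotypes.tsv", cohort.genotypes, region, samples)
        write_truth_tables(cdir, cohort, samples)
        cohorts[spec.name] = cohort
    return cohorts


def load_simulated_dir(indir: str | Path) -> tuple[RegionMap, list[CohortSpec], dict[str, SimulatedCohort]]:
    """Reload a directory written by :func:`simulate_to_dir` bit-exactly."""
    indir = Path(indir)
    region, specs = scenario_from_yaml((indir / "scenario.yaml").read_text())
    cohorts = {}
    for spec in specs:
        cdir = indir / spec.name
        vcf = cdir / "genotypes.vcf"
        path = vcf if vcf.exists() else cdir / "genotypes.tsv"
        _samples, genotypes, _ids, _pos = read_genotypes(path)
        truth = pd.read_csv(cdir / "truth_haplotypes.tsv", sep="\t", dtype={"pattern": str})
        n = spec.n_individuals
        haps = np.stack(
            [np.frombuffer(p.encode(), np.uint8) - ord("0") for p in truth["pattern"]]
        ).astype(np.int8)
        source = truth[["source_left", "source_right"]].to_numpy(np.int64)
        bp = truth["breakpoint"].to_numpy(np.int64)
        meta = pd.read_csv(cdir / "samples.tsv", sep="\t")
        cohorts[spec.name] = SimulatedCohort(
            spec=spec,
            region=region,
            genotypes=genotypes,
            phenotype=(meta["phenotype"] == "case").to_numpy(),
            haplotypes=haps,
            hap_source=source,
            hap_breakpoint=bp,
            typed_mask=meta["typed"].to_numpy(bool),
            validation_mask=meta["validation"].to_numpy(bool),
        )
        assert cohorts[spec.name].n_individuals == n
    return region, specs, cohorts


# ---------------------------------------------------------------------------
# orchestrator

#: focal alleles dissected against their extended reference lineage
_DISSECTIONS = [
    ("DRB1*0301", "HLA-DRB1", "ext_DR3"),
    ("DRB1*0701", "HLA-DRB1", "ext_DR7"),
    ("DRB1*0102", "HLA-DRB1", "ext_DR1_0102"),
    ("DRB1*1501", "HLA-DRB1", "ext_DR15"),
]


@dataclass
class RunReport:
    config: PipelineConfig
    hla_association: pd.DataFrame = None
    dissections: dict[str, pd.DataFrame] = field(default_factory=dict)
    haplotype_association: pd.DataFrame = None
    imputation_performance: pd.DataFrame = None
    scan: dict | None = None
    scan_inputs: dict | None = None  # in-memory only (marker dosages)
    power: pd.DataFrame = None
    lambda_gc: dict[str, float | None] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.hla_association is not None:
            self.hla_association.to_csv(outdir / "hla_association.tsv", sep="\t", index=False)
        if self.haplotype_association is not None:
            self.haplotype_association.to_csv(
                outdir / "haplotype_association.tsv", sep="\t", index=False
            )
        for allele, df in self.dissections.items():
            safe = allele.replace("*", "")
            df.to_csv(outdir / f"dissection_{safe}.tsv", sep="\t", index=False)
        if self.imputation_performance is not None:
            self.imputation_performance.to_csv(
                outdir / "imputation_performance.tsv", sep="\t", index=False
            )
        if self.power is not None:
            self.power.to_csv(outdir / "power_table.tsv", sep="\t", index=False)
        if self.scan is not None:
            with open(outdir / "conditional_scan.json", "w") as fh:
                json.dump(
                    {
                        "selected": self.scan["selected"],
                        "selected_p": self.scan["selected_p"],
                        "scans": self.scan["scans"],
                    },
                    fh,
                    indent=2,
                )
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        (outdir / "run.log").write_text("\n".join(self.log) + "\n")


def _stage(report: RunReport, t0: float, msg: str) -> None:
    report.log.append(f"[{time.time() - t0:8.2f}s] {msg}")


def manhattan_plot(
    positions: np.ndarray,
    p_values: np.ndarray,
    path: str | Path,
    threshold: float = GENOME_WIDE_P,
) -> None:
    """Optional -log10(p) vs bp plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(np.asarray(positions) / 1e6, -np.log10(np.asarray(p_values)), s=12)
    ax.axhline(-np.log10(threshold), color="red", lw=0.8)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("-log10 combined p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Simulate (or load) -> phase -> impute HLA -> dissect -> associate ->
    conditional scan -> power.  Deterministic given the config seed."""
    config.validate()
    report = RunReport(config=config)
    t0 = time.time()

    if config.input_dir:
        region, specs, cohorts = load_simulated_dir(config.input_dir)
        _stage(report, t0, f"loaded {len(cohorts)} cohorts from {config.input_dir}")
    else:
        if config.scenario == "default":
            region, specs = build_default_scenario(seed=config.seed)
        else:
            region, specs = scenario_from_yaml(Path(config.scenario).read_text())
        cohorts = {
            s.name: apply_missingness_and_typing(simulate_cohort(s, region), s)
            for s in specs
        }
        _stage(report, t0, f"simulated {len(cohorts)} cohorts")

    # --- phase
    phased = {}
    for name, cohort in cohorts.items():
        phased[name] = partition_ligation_phase(
            cohort.genotypes,
            window_size=config.window_size,
            top_patterns=config.top_patterns,
        )
        _stage(report, t0, f"phased {name} ({cohort.n_individuals} individuals)")

    # --- training labels from typed subset; select panel; learn segments
    hap_blocks, label_blocks = [], {g: [] for g in GENES}
    train_mask_blocks, valid_mask_blocks, ctrl_blocks = [], [], []
    for name, cohort in cohorts.items():
        labels = align_truth_labels(phased[name].haplotypes, cohort)
        hap_blocks.append(phased[name].haplotypes)
        for g in GENES:
            label_blocks[g].append(labels[g])
        train = np.repeat(cohort.typed_mask & ~cohort.validation_mask, 2)
        valid = np.repeat(cohort.typed_mask & cohort.validation_mask, 2)
        train_mask_blocks.append(train)
        valid_mask_blocks.append(valid)
        ctrl_blocks.append(np.repeat(~cohort.phenotype, 2))
    all_haps = np.vstack(hap_blocks)
    all_labels = {g: np.concatenate(label_blocks[g]) for g in GENES}
    train_mask = np.concatenate(train_mask_blocks)
    valid_mask = np.concatenate(valid_mask_blocks)
    ctrl_mask = np.concatenate(ctrl_blocks)

    train_labels = {g: np.where(train_mask, all_labels[g], None) for g in GENES}
    panel = select_tag_snps(
        all_haps[train_mask],
        {g: all_labels[g][train_mask] for g in GENES},
        region,
        n_tags=config.n_tags,
        n_backbone=config.n_backbone,
        r2_threshold=config.r2_threshold,
        maf_min=config.maf_min,
        min_carriers=config.min_carriers,
        control_mask=ctrl_mask[train_mask],
    )
    segments, untaggable, skipped = learn_allele_segments(
        all_haps[train_mask],
        {g: all_labels[g][train_mask] for g in GENES},
        panel,
        consensus=config.consensus,
        min_carriers=config.min_carriers,
    )
    _stage(
        report,
        t0,
        f"panel {panel.n_panel} SNPs; {len(segments)} segments learned, "
        f"{len(untaggable)} untaggable, {len(skipped)} skipped",
    )

    # --- impute HLA everywhere; evaluate on training/validation
    calls_all = impute_hla_alleles(all_haps, segments)
    report.imputation_performance = evaluate_imputation(
        calls_all,
        all_labels,
        {"training": train_mask, "validation": valid_mask},
        alleles=[s.allele for s in segments],
    )
    offsets = np.cumsum([0] + [h.shape[0] for h in hap_blocks])
    calls = {}
    for k, name in enumerate(cohorts):
        sel = slice(offsets[k], offsets[k + 1])
        calls[name] = {
            g: calls_all.calls[g][sel] for g in GENES
        }
    _stage(report, t0, "imputed HLA alleles")

    # --- per-allele association: per-cohort tests + CMH + meta
    seg_alleles = sorted({s.allele for s in segments})
    rows = []
    for allele in seg_alleles:
        gene = allele_gene(allele)
        tables, ps, signs, ns = [], [], [], []
        row = {"allele": allele}
        for name, cohort in cohorts.items():
            called = calls[name][gene]
            ok = np.array([c is not None for c in called])
            case = np.repeat(cohort.phenotype, 2)
            hit = called == allele
            tab = AlleleCounts2x2(
                int(np.sum(hit & case & ok)),
                int(np.sum(~hit & case & ok)),
                int(np.sum(hit & ~case & ok)),
                int(np.sum(~hit & ~case & ok)),
            )
            res = allele_association(tab)
            tables.append(tab)
            row[f"{name}_freq_case"] = res.freq_case
            row[f"{name}_freq_ctrl"] = res.freq_ctrl
            row[f"{name}_p"] = res.p
            row[f"{name}_or"] = res.odds_ratio
            if 0 < res.p <= 1:
                ps.append(max(res.p, 1e-300))
                signs.append(1 if (res.freq_case >= res.freq_ctrl) else -1)
                ns.append(cohort.n_individuals)
        strat = cmh_combined(tables)
        meta = meta_weighted_z(ps, signs, ns) if ps else None
        row["or_cmh"] = strat.odds_ratio
        row["or_cmh_l95"] = strat.ci95[0] if strat.ci95 else None
        row["or_cmh_u95"] = strat.ci95[1] if strat.ci95 else None
        row["p_combined"] = meta.p_combined if meta else None
        rows.append(row)
    report.hla_association = pd.DataFrame(rows)
    _stage(report, t0, "allele association tables")

    # --- dissection of focal alleles against extended references
    template_by_name = {t.name: t for t in specs[0].templates}
    hap_rows = []
    for focal, gene, ref_name in _DISSECTIONS:
        if ref_name not in template_by_name:
            continue
        ref_t = template_by_name[ref_name]
        reference = ReferenceExtended(
            ref_name, dict(ref_t.hla_alleles), ref_t.snp_pattern
        )
        data = {
            name: {
                "haplotypes": phased[name].haplotypes,
                "calls": calls[name][gene],
                "phenotype": cohorts[name].phenotype,
            }
            for name in cohorts
        }
        df = dissect_focal_allele(
            data, focal, gene, reference, region, config.mismatch_tolerance
        )
        report.dissections[focal] = df
        for stratum in ("extended", "recombinant"):
            sub = df[df.stratum == stratum]
            tabs = [
                AlleleCounts2x2(
                    int(r.n_case_hap),
                    int(r.n_case_chrom - r.n_case_hap),
                    int(r.n_ctrl_hap),
                    int(r.n_ctrl_chrom - r.n_ctrl_hap),
                )
                for r in sub.itertuples()
            ]
            strat = cmh_combined(tabs)
            ps, signs, ns = [], [], []
            for tab, (name, cohort) in zip(tabs, cohorts.items()):
                res = allele_association(tab)
                if 0 < res.p <= 1:
                    ps.append(max(res.p, 1e-300))
                    signs.append(1 if res.freq_case >= res.freq_ctrl else -1)
                    ns.append(cohort.n_individuals)
            meta = meta_weighted_z(ps, signs, ns) if ps else None
            hap_rows.append(
                {
                    "focal_allele": focal,
                    "stratum": stratum,
                    "n_hap": int(sub.n_case_hap.sum() + sub.n_ctrl_hap.sum()),
                    "pct": df.attrs[f"pct_{stratum}"],
                    "or_cmh": strat.odds_ratio,
                    "p_combined": meta.p_combined if meta else None,
                }
            )
    report.haplotype_association = pd.DataFrame(hap_rows)
    _stage(report, t0, "haplotype dissection + association")

    # --- stepwise conditional scan over SNPs + imputed alleles + lineages
    if config.run_scan:
        marker_names: list[str] = list(region.snp_ids)
        marker_names += [f"allele:{a}" for a in seg_alleles]
        lineage_names = [
            f"lineage:{ref}" for _f, _g, ref in _DISSECTIONS if ref in template_by_name
        ]
        marker_names += lineage_names
        scan_data = {}
        for k, (name, cohort) in enumerate(cohorts.items()):
            H = phased[name].haplotypes
            n = cohort.n_individuals
            snp_dos = (H[0::2] + H[1::2]).astype(float)
            cols = [snp_dos]
            for a in seg_alleles:
                carrier = calls[name][allele_gene(a)] == a
                cols.append((carrier[0::2] + carrier[1::2]).astype(float)[:, None])
            for _f, gene, ref_name in _DISSECTIONS:
                if ref_name not in template_by_name:
                    continue
                ref_t = template_by_name[ref_name]
                reference = ReferenceExtended(
                    ref_name, dict(ref_t.hla_alleles), ref_t.snp_pattern
                )
                carrier = calls[name][gene] == _f
                ext = np.zeros(2 * n, dtype=float)
                for h in np.flatnonzero(carrier):
                    cls = classify_against_reference(
                        H[h], True, reference, region, config.mismatch_tolerance
                    )
                    ext[h] = 1.0 if cls.label == "extended" else 0.0
                cols.append((ext[0::2] + ext[1::2])[:, None])
            scan_data[name] = {
                "dosages": np.hstack(cols),
                "phenotype": cohort.phenotype.astype(float),
            }
        selectable = [
            nm for nm in marker_names if nm.startswith(("allele:", "lineage:"))
        ]
        report.scan = stepwise_conditional(
            scan_data,
            marker_names,
            threshold=config.significance,
            selectable=selectable,
        )
        report.scan_inputs = {"marker_names": marker_names, "data": scan_data}
        # per-cohort lambda from the unconditioned scan (needs enough markers)
        for name in cohorts:
            try:
                res = logistic_scan(
                    scan_data[name]["dosages"],
                    scan_data[name]["phenotype"],
                    marker_names=marker_names,
                    compute_lambda=True,
                )
                report.lambda_gc[name] = res.lambda_gc
            except AssociationError:
                report.lambda_gc[name] = None
        _stage(
            report,
            t0,
            f"conditional scan selected {report.scan['selected']}",
        )

    # --- power table (recombinant rows at the extended lineage's GRR)
    if config.run_power:
        n_cases = sum(c.spec.n_cases for c in cohorts.values())
        n_controls = sum(c.spec.n_controls for c in cohorts.values())
        prevalence = specs[0].prevalence
        prows = []
        for focal, _gene, _ref in _DISSECTIONS:
            if focal not in report.dissections:
                continue
            df = report.dissections[focal]
            ext = df[df.stratum == "extended"]
            rec = df[df.stratum == "recombinant"]
            wts = ext.n_ctrl_chrom.to_numpy(float)
            ext_fc = float(np.average(ext.freq_case, weights=ext.n_case_chrom))
            ext_fk = float(np.average(ext.freq_ctrl, weights=wts))
            rec_fk = float(np.average(rec.freq_ctrl, weights=rec.n_ctrl_chrom))
            prows.append(
                {
                    "name": f"recombinant {focal}",
                    "ext_freq_case": ext_fc,
                    "ext_freq_ctrl": ext_fk,
                    "rec_freq_ctrl": rec_fk,
                }
            )
        report.power = power_table(
            prows, n_cases, n_controls, prevalence=prevalence, alphas=config.alphas
        )
        _stage(report, t0, "power table")

    report.provenance = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "untaggable_alleles": untaggable,
        "skipped_alleles": skipped,
    }
    report.write(config.outdir)
    return report
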