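import numpy as np
import pytest

from hlafinemap.association_stats import AlleleCounts2x2, allele_association
from hlafinemap.synthetic_cohorts import (
    GENES,
    CohortSpec,
    HaplotypeTemplate,
    Locus,
    RegionMap,
    ScenarioError,
    apply_missingness_and_typing,
    build_default_scenario,
    causal_dosages,
    mean_relative_risk,
    sample_population,
    simulate_cohort,
)


class TestRegionMap:
    def test_default_region_has_49_snps_and_ordered_anchors(self, default_scenario):
        region, _ = default_scenario
        assert region.n_snps == 49
        anchors = region.anchors
        assert list(anchors) == list(GENES)
        assert anchors["HLA-B"] < anchors["HLA-DRB1"] < anchors["HLA-DQB1"]
        assert np.all(np.diff(region.snp_positions) > 0)

    def test_positions_must_increase(self):
        loci = [Locus("a", 100), Locus("b", 100)]
        with pytest.raises(ScenarioError):
            RegionMap(loci)

    def test_anchors_required(self):
        with pytest.raises(ScenarioError):
            RegionMap([Locus("a", 100), Locus("b", 200)])


class TestScenario:
    def test_template_frequencies_sum_below_one(self, default_scenario):
        _, specs = default_scenario
        for spec in specs:
            assert spec.template_freqs().sum() <= 1.0 + 1e-9

    def test_table_control_frequencies_planted(self, default_scenario):
        # extended B*0801 lineage at 0.097 in the Swedish/Icelandic controls
        _, specs = default_scenario
        by_name = {t.name: t for t in specs[0].templates}
        assert by_name["ext_DR3"].cohort_freqs["sweden_iceland"] == pytest.approx(0.097)
        assert by_name["ext_DR3"].cohort_freqs["spain"] == pytest.approx(0.026)
        assert by_name["ext_DR3"].grr == pytest.approx(3.33)
        assert by_name["ext_DR1_0102"].grr == pytest.approx(4.59)
        assert by_name["ext_DR15"].grr == pytest.approx(0.14)
        # DQB1*02-on-DR7 risk shared by extended and recombinant lineages
        assert by_name["ext_DR7"].grr == by_name["rec_DR7_DQ2"].grr == pytest.approx(2.23)

    def test_dr15_causal_between_drb1_and_dqb1(self, default_scenario):
        region, specs = default_scenario
        by_name = {t.name: t for t in specs[0].templates}
        anchors = region.anchors
        pos = by_name["ext_DR15"].causal_position
        assert anchors["HLA-DRB1"] < pos < anchors["HLA-DQB1"]

    def test_grr_without_causal_position_rejected(self, default_scenario):
        region, _ = default_scenario
        with pytest.raises(ScenarioError):
            HaplotypeTemplate(
                "bad", np.zeros(region.n_snps, np.int8), {}, {"x": 0.1}, grr=2.0
            )

    def test_oversummed_frequencies_rejected(self, default_scenario):
        region, specs = default_scenario
        t = specs[0].templates[0]
        clone = HaplotypeTemplate(
            "clone", t.snp_pattern, dict(t.hla_alleles), {"sweden_iceland": 0.9}, 1.0
        )
        with pytest.raises(ScenarioError):
            CohortSpec("sweden_iceland", 10, 10, specs[0].templates + [clone])


def _toy_templates(region, freq_risk=0.10, grr=3.33, causal=32_300_000):
    _, specs = build_default_scenario(seed=1)
    risk_pat = specs[0].templates[0].snp_pattern
    neut_pat = specs[0].templates[10].snp_pattern
    return [
        HaplotypeTemplate(
            "risk",
            risk_pat,
            {"HLA-B": "B*0801", "HLA-DRB1": "DRB1*0301", "HLA-DQB1": "DQB1*0201"},
            {"toy": freq_risk},
            grr,
            causal,
        ),
        HaplotypeTemplate(
            "neut",
            neut_pat,
            {"HLA-B": "B*4402", "HLA-DRB1": "DRB1*0401", "HLA-DQB1": "DQB1*0302"},
            {"toy": 1.0 - freq_risk - 0.05},
        ),
    ]


class TestSimulation:
    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_genotype_equals_haplotype_sum(self, default_scenario, seed):
        region, specs = default_scenario
        pop = sample_population(specs[1], region, 300, seed=seed)
        assert np.array_equal(
            pop.genotypes, pop.haplotypes[0::2] + pop.haplotypes[1::2]
        )

    def test_determinism_bit_identical(self, default_scenario):
        region, specs = default_scenario
        a = simulate_cohort(specs[2], region)
        b = simulate_cohort(specs[2], region)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.hap_breakpoint, b.hap_breakpoint)
        assert np.array_equal(a.phenotype, b.phenotype)

    def test_degenerate_pool_case_yield_matches_prevalence(self, default_scenario):
        region, _ = default_scenario
        tpl = _toy_templates(region)[1]
        tpl = HaplotypeTemplate("only", tpl.snp_pattern, dict(tpl.hla_alleles), {"toy": 1.0})
        spec = CohortSpec("toy", 5, 5, [tpl], recomb_prob=0.0, seed=3)
        pop = sample_population(spec, region, 50_000, seed=3)
        # every individual homozygous for the single pattern
        assert np.all(pop.genotypes == 2 * tpl.snp_pattern[None, :])
        n_cases = int(pop.phenotype.sum())
        # Poisson(100) band
        assert 60 <= n_cases <= 140

    def test_unreachable_prevalence_fails(self, default_scenario):
        region, _ = default_scenario
        tpls = _toy_templates(region, freq_risk=0.5, grr=40.0)
        spec = CohortSpec("toy", 5, 5, tpls, prevalence=0.5, seed=0)
        with pytest.raises(ScenarioError, match="unreachable"):
            simulate_cohort(spec, region)

    def test_control_frequency_recovery_at_5000(self, default_scenario):
        # control DRB1*0301 haplotype frequency within 3 binomial SE of 0.136
        region, specs = default_scenario
        pop = sample_population(specs[0], region, 5000, seed=11)
        ctrl = np.repeat(~pop.phenotype, 2)
        f = float(np.mean(pop.truth_hla("HLA-DRB1")[ctrl] == "DRB1*0301"))
        se = np.sqrt(0.136 * 0.864 / ctrl.sum())
        assert abs(f - 0.136) < 3 * se

    def test_mosaic_breakpoints_between_b_and_drb1(self, default_scenario):
        region, _ = default_scenario
        tpls = _toy_templates(region)
        spec = CohortSpec("toy", 5, 5, tpls, recomb_prob=1.0, seed=5)
        pop = sample_population(spec, region, 200, seed=5)
        bps = pop.hap_breakpoint[pop.hap_breakpoint >= 0]
        assert bps.size > 0
        anchors = region.anchors
        assert np.all((bps > anchors["HLA-B"]) & (bps <= anchors["HLA-DRB1"]))

    def test_mosaic_haplotype_is_template_cross(self, default_scenario):
        region, _ = default_scenario
        tpls = _toy_templates(region)
        spec = CohortSpec("toy", 5, 5, tpls, recomb_prob=1.0, seed=5)
        pop = sample_population(spec, region, 100, seed=5)
        pos = region.snp_positions
        patterns = {i: t.snp_pattern for i, t in enumerate(tpls)}
        for h in range(40):
            left, right = pop.hap_source[h]
            bp = pop.hap_breakpoint[h]
            if bp < 0 or left < 0 or right < 0:
                continue
            expect = np.where(pos < bp, patterns[left], patterns[right])
            assert np.array_equal(pop.haplotypes[h], expect)

    def test_risk_travels_with_causal_segment(self, default_scenario):
        # a mosaic that lost the causal position carries grr 1
        region, _ = default_scenario
        tpls = _toy_templates(region)
        spec = CohortSpec("toy", 5, 5, tpls, recomb_prob=1.0, seed=9)
        pop = sample_population(spec, region, 500, seed=9)
        grr = pop.hap_grr()
        causal = tpls[0].causal_position
        for h in range(1000):
            left, right = pop.hap_source[h]
            bp = pop.hap_breakpoint[h]
            carries = (left == 0 and bp >= 0 and causal < bp) or (
                right == 0 and bp >= 0 and causal >= bp
            ) or (bp < 0 and left == 0)
            assert grr[h] == pytest.approx(3.33 if carries else 1.0)

    def test_planted_or_coverage_over_20_replicates(self, default_scenario):
        # 95% CI of the allele OR covers the planted grr in >= 18/20 runs
        region, _ = default_scenario
        covered = 0
        for rep in range(20):
            tpls = _toy_templates(region)
            spec = CohortSpec("toy", 500, 1000, tpls, recomb_prob=0.0, seed=1000 + rep)
            coh = simulate_cohort(spec, region)
            d = causal_dosages(coh)[32_300_000]
            case = coh.phenotype
            a = int(d[case].sum())
            c = int(d[~case].sum())
            res = allele_association(
                AlleleCounts2x2(a, 1000 - a, c, 2000 - c)
            )
            lo, hi = res.ci95
            covered += lo <= 3.33 <= hi
        assert covered >= 18


class TestMeanRelativeRisk:
    def test_no_recombination_matches_weighted_mean(self, default_scenario):
        region, _ = default_scenario
        tpls = _toy_templates(region, freq_risk=0.2, grr=2.0)
        spec = CohortSpec("toy", 5, 5, tpls, recomb_prob=0.0, seed=0)
        expect = 0.2 * 2.0 + 0.75 * 1.0 + 0.05 * 1.0
        assert mean_relative_risk(spec, region) == pytest.approx(expect)

    def test_monte_carlo_agreement(self, default_scenario):
        region, _ = default_scenario
        tpls = _toy_templates(region, freq_risk=0.2, grr=2.0)
        spec = CohortSpec("toy", 5, 5, tpls, recomb_prob=0.5, seed=0)
        mu = mean_relative_risk(spec, region)
        pop = sample_population(spec, region, 40_000, seed=123)
        mc = float(pop.hap_grr().mean())
        assert mu == pytest.approx(mc, abs=0.01)


class TestMissingnessAndTyping:
    def test_identity_when_rates_trivial(self, default_scenario):
        region, specs = default_scenario
        import dataclasses

        spec = dataclasses.replace(
            specs[2], missing_rate=0.0, typed_fraction=1.0, validation_size=10
        )
        coh = simulate_cohort(spec, region)
        out = apply_missingness_and_typing(coh, spec)
        assert np.array_equal(out.genotypes, coh.genotypes)
        assert out.typed_mask.all()

    def test_missing_rate_within_binomial_ci(self, default_scenario):
        region, specs = default_scenario
        coh = simulate_cohort(specs[0], region)
        out = apply_missingness_and_typing(coh, specs[0])
        n = coh.genotypes.size
        observed = float((out.genotypes == -1).mean())
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(observed - 0.01) < 4 * se

    def test_validation_subset_is_79_under_defaults(self, default_scenario):
        region, specs = default_scenario
        coh = simulate_cohort(specs[0], region)
        out = apply_missingness_and_typing(coh, specs[0])
        assert int(out.validation_mask.sum()) == 79
        assert np.all(out.typed_mask[out.validation_mask])

    def test_typed_subset_smaller_than_validation_fails(self, default_scenario):
        region, specs = default_scenario
        import dataclasses

        spec = dataclasses.replace(specs[2], typed_fraction=0.05)
        coh = simulate_cohort(spec, region)
        with pytest.raises(ScenarioError, match="validation"):
            apply_missingness_and_typing(coh, spec)


class TestCausalDosages:
    def test_four_planted_positions(self, default_scenario):
        region, specs = default_scenario
        coh = simulate_cohort(specs[1], region)
        dosages = causal_dosages(coh)
        assert sorted(dosages) == [32_150_000, 32_300_000, 32_690_000, 32_710_000]
        for d in dosages.values():
            assert d.shape == (coh.n_individuals,)
            assert set(np.unique(d)) <= {0, 1, 2}
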