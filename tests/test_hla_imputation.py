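import numpy as np
import pytest

from hlafinemap.hla_imputation import (
    AlleleDefiningSegment,
    ImputationError,
    allele_gene,
    evaluate_imputation,
    haploid_r2,
    impute_hla_alleles,
    learn_allele_segments,
    select_tag_snps,
    TagSnpPanel,
)
from hlafinemap.synthetic_cohorts import GENES, Locus, RegionMap


def _toy_region(m, spacing=10_000, start=31_000_000):
    loci = [Locus(f"s{j}", start + spacing * j, "snp") for j in range(m)]
    loci += [
        Locus("HLA-B", 31_430_001, "hla_anchor", "HLA-B"),
        Locus("HLA-DRB1", 32_654_000, "hla_anchor", "HLA-DRB1"),
        Locus("HLA-DQB1", 32_735_000, "hla_anchor", "HLA-DQB1"),
    ]
    loci.sort(key=lambda l: l.position)
    return RegionMap(loci)


def _labels(carriers, n, allele="B*0801"):
    lab = {g: np.full(n, None, dtype=object) for g in GENES}
    arr = np.array(["other"] * n, dtype=object)
    arr[carriers] = allele
    lab[allele_gene(allele)] = arr
    return lab


class TestAlleleGene:
    @pytest.mark.parametrize(
        "allele,gene",
        [("B*0801", "HLA-B"), ("DRB1*0301", "HLA-DRB1"), ("DQB1*02", "HLA-DQB1")],
    )
    def test_mapping(self, allele, gene):
        assert allele_gene(allele) == gene


class TestSelectTagSnps:
    def test_perfect_ld_snp_selected_as_tag(self, rng):
        n, m = 200, 12
        H = rng.integers(0, 2, size=(n, m))
        carrier = H[:, 4] == 1  # column 4 is a perfect tag
        region = _toy_region(m)
        panel = select_tag_snps(
            H, _labels(carrier, n), region, n_tags=1, n_backbone=4,
            r2_threshold=0.95, maf_min=0.05, min_carriers=5,
        )
        assert panel.tag_snps["B*0801"] == "s4"

    def test_greedy_tag_equals_exhaustive_max_r2(self, rng):
        # 20-SNP toy panel: the chosen tag maximizes r^2 over all SNPs
        n, m = 300, 20
        H = rng.integers(0, 2, size=(n, m))
        carrier = (H[:, 7] == 1) & (H[:, 3] == 1)
        region = _toy_region(m)
        panel = select_tag_snps(
            H, _labels(carrier, n), region, n_tags=1, n_backbone=5,
            r2_threshold=0.95, min_carriers=5,
        )
        indicator = carrier.astype(float)
        r2 = [haploid_r2(indicator, H[:, j]) for j in range(m)]
        assert panel.tag_snps["B*0801"] == f"s{int(np.argmax(r2))}"

    def test_default_scenario_panel_is_11_plus_38(self, pipeline_report):
        prov = pipeline_report.provenance
        assert prov is not None  # panel size asserted via the pipeline log
        assert any("panel 49 SNPs" in line for line in pipeline_report.log)

    def test_too_few_eligible_snps_fails_with_constraints(self, rng):
        n, m = 100, 6
        H = rng.integers(0, 2, size=(n, m))
        carrier = H[:, 0] == 1
        region = _toy_region(m)
        with pytest.raises(ImputationError, match="backbone"):
            select_tag_snps(
                H, _labels(carrier, n), region, n_tags=1, n_backbone=10,
                min_carriers=5,
            )

    def test_backbone_maf_constraint(self, rng):
        n, m = 400, 10
        H = rng.integers(0, 2, size=(n, m))
        H[:, 5] = 0
        H[:4, 5] = 1  # MAF 0.01 < 0.05: never eligible for the backbone
        carrier = H[:, 0] == 1
        region = _toy_region(m)
        panel = select_tag_snps(
            H, _labels(carrier, n), region, n_tags=1, n_backbone=8,
            r2_threshold=0.99, min_carriers=5,
        )
        assert "s5" not in panel.backbone_snps


def _oracle_segment_scan(H, carrier, tag, consensus=0.95):
    """Independent exhaustive window scan oracle."""
    m = H.shape[1]
    cons = (H[carrier].mean(axis=0) > 0.5).astype(int)
    best = None
    for i in range(tag + 1):
        for j in range(tag + 1, m + 1):
            pat = cons[i:j]
            car_hits = [np.array_equal(h[i:j], pat) for h in H[carrier]]
            non_hits = [np.array_equal(h[i:j], pat) for h in H[~carrier]]
            if np.mean(car_hits) < consensus or any(non_hits):
                continue
            key = (j - i, -abs((i + j - 1) / 2 - tag), -i)
            if best is None or key > best[0]:
                best = (key, (i, j))
    return None if best is None else best[1]


class TestLearnAlleleSegments:
    def _panel(self, region, tag_idx, allele="B*0801"):
        snp = region.snp_ids[tag_idx]
        return TagSnpPanel({allele: snp}, [], region)

    def test_unique_single_snp_tag(self):
        region = _toy_region(5)
        H = np.zeros((40, 5), dtype=np.int8)
        H[:12, 2] = 1  # tag allele present only on carriers
        carrier = np.zeros(40, dtype=bool)
        carrier[:12] = True
        segs, untag, skip = learn_allele_segments(
            H, _labels(carrier, 40), self._panel(region, 2), min_pattern_count=1
        )
        assert untag == [] and skip == []
        # carriers share everything, so the maximal unique window is emitted;
        # it must contain the tag and match the oracle
        oracle = _oracle_segment_scan(H, carrier, 2)
        assert segs[0].interval == oracle

    def test_constructed_shared_core_interval(self, rng):
        # carriers uniquely share positions 3..7 -> interval [3, 8)
        m, n = 10, 60
        H = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        carrier = np.zeros(n, dtype=bool)
        carrier[:15] = True
        core = np.array([1, 0, 1, 1, 0])
        H[:15, 3:8] = core
        # make sure no non-carrier matches the core, but all match outside
        for i in np.flatnonzero(~carrier):
            if np.array_equal(H[i, 3:8], core):
                H[i, 5] = 1 - core[2]
        # carriers must NOT share unique flanks: copy flanks from non-carriers
        H[:15, :3] = H[15:30, :3]
        H[:15, 8:] = H[15:30, 8:]
        segs, untag, _ = learn_allele_segments(
            H, _labels(carrier, n), self._panel(_toy_region(m), 5),
            min_pattern_count=1,
        )
        oracle = _oracle_segment_scan(H, carrier, 5)
        assert oracle == (3, 8)
        assert segs and segs[0].interval == (3, 8)
        assert np.array_equal(segs[0].pattern, core)

    def test_untaggable_when_every_window_shared(self, rng):
        # every carrier window also occurs among non-carriers
        m, n = 8, 60
        H = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        carrier = np.zeros(n, dtype=bool)
        carrier[:12] = True
        H[:12] = H[12:24]  # carriers duplicate non-carrier haplotypes
        segs, untag, _ = learn_allele_segments(
            H, _labels(carrier, n), self._panel(_toy_region(m), 4),
            min_pattern_count=1,
        )
        assert _oracle_segment_scan(H, carrier, 4) is None
        assert untag == ["B*0801"] and not segs

    def test_rare_allele_skipped(self, rng):
        m, n = 6, 40
        H = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        carrier = np.zeros(n, dtype=bool)
        carrier[:4] = True
        segs, untag, skip = learn_allele_segments(
            H, _labels(carrier, n), self._panel(_toy_region(m), 2),
            min_carriers=10, min_pattern_count=1,
        )
        assert skip == ["B*0801"] and not segs

    def test_segment_interval_contains_tag(self):
        with pytest.raises(ImputationError):
            AlleleDefiningSegment("B*0801", (2, 4), [0, 1], tag_index=5)

    def test_emitted_patterns_absent_from_noncarriers(self, rng):
        # segment uniqueness asserted exhaustively on the training pool
        m, n = 12, 100
        base = rng.integers(0, 2, size=(5, m)).astype(np.int8)
        idx = rng.integers(0, 5, size=n)
        H = base[idx]
        carrier = idx == 0
        segs, _, _ = learn_allele_segments(
            H, _labels(carrier, n), self._panel(_toy_region(m), 6),
            min_pattern_count=1,
        )
        for seg in segs:
            assert not seg.matches(H[~carrier]).any()


class TestImputeAndEvaluate:
    def _segments(self):
        return [
            AlleleDefiningSegment("B*0801", (0, 2), [1, 1], tag_index=0),
            AlleleDefiningSegment("B*0702", (0, 2), [0, 1], tag_index=1),
            AlleleDefiningSegment("DRB1*0301", (3, 5), [1, 0], tag_index=3),
        ]

    def test_matching_haplotype_called(self):
        H = np.array([[1, 1, 0, 1, 0], [0, 1, 0, 0, 0]], dtype=np.int8)
        calls = impute_hla_alleles(H, self._segments())
        assert calls.calls["HLA-B"][0] == "B*0801"
        assert calls.calls["HLA-B"][1] == "B*0702"
        assert calls.calls["HLA-DRB1"][0] == "DRB1*0301"
        assert calls.calls["HLA-DRB1"][1] is None  # matches no segment

    def test_two_genes_called_independently(self):
        H = np.array([[1, 1, 1, 1, 0]], dtype=np.int8)
        calls = impute_hla_alleles(H, self._segments())
        assert calls.calls["HLA-B"][0] == "B*0801"
        assert calls.calls["HLA-DRB1"][0] == "DRB1*0301"

    def test_conflicting_matches_yield_flagged_no_call(self):
        segs = self._segments() + [
            AlleleDefiningSegment("B*1402", (1, 2), [1], tag_index=1)
        ]
        H = np.array([[1, 1, 0, 0, 0]], dtype=np.int8)
        calls = impute_hla_alleles(H, segs)
        assert calls.calls["HLA-B"][0] is None
        assert calls.conflicts["HLA-B"][0]

    def test_perfect_calls_metrics_one(self):
        H = np.array([[1, 1, 0, 0, 0], [0, 1, 0, 0, 0]] * 10, dtype=np.int8)
        calls = impute_hla_alleles(H, self._segments())
        truth = {g: calls.calls[g].copy() for g in GENES}
        perf = evaluate_imputation(
            calls, truth, {"training": np.ones(20, dtype=bool)}
        )
        sub = perf[perf.allele.isin(["B*0801", "B*0702"])]
        assert (sub.sensitivity == 1.0).all()
        assert (sub.specificity == 1.0).all()
        assert (sub.ppv == 1.0).all()

    def test_constructed_confusion_counts(self):
        # 10 carriers: 9 called, 1 no-call; 90 non-carriers: no false calls
        n = 100
        truth = {g: np.full(n, None, dtype=object) for g in GENES}
        truth["HLA-B"][:] = "other"
        truth["HLA-B"][:10] = "B*0801"
        calls_arr = np.full(n, None, dtype=object)
        calls_arr[:9] = "B*0801"
        from hlafinemap.hla_imputation import HlaCallSet

        calls = HlaCallSet(
            calls={
                "HLA-B": calls_arr,
                "HLA-DRB1": np.full(n, None, dtype=object),
                "HLA-DQB1": np.full(n, None, dtype=object),
            },
            conflicts={g: np.zeros(n, dtype=bool) for g in GENES},
        )
        perf = evaluate_imputation(
            calls, truth, {"training": np.ones(n, dtype=bool)}, alleles=["B*0801"]
        )
        row = perf.iloc[0]
        assert (row.TP, row.FP, row.FN, row.TN) == (9, 0, 1, 90)
        assert row.sensitivity == pytest.approx(0.9)
        assert row.ppv == pytest.approx(1.0)
        assert row.specificity == pytest.approx(1.0)

    def test_random_calls_ppv_matches_prevalence(self, rng):
        # calls assigned uniformly among k alleles -> PPV ~= carrier prevalence
        n, k = 30_000, 3
        alleles = [f"B*{i:02d}01" for i in range(k)]
        truth = {g: np.full(n, None, dtype=object) for g in GENES}
        truth["HLA-B"] = np.array(rng.choice(alleles, size=n), dtype=object)
        from hlafinemap.hla_imputation import HlaCallSet

        calls = HlaCallSet(
            calls={
                "HLA-B": np.array(rng.choice(alleles, size=n), dtype=object),
                "HLA-DRB1": np.full(n, None, dtype=object),
                "HLA-DQB1": np.full(n, None, dtype=object),
            },
            conflicts={g: np.zeros(n, dtype=bool) for g in GENES},
        )
        perf = evaluate_imputation(
            calls, truth, {"training": np.ones(n, dtype=bool)}, alleles=alleles
        )
        for _, row in perf.iterrows():
            prevalence = np.mean(truth["HLA-B"] == row.allele)
            assert row.ppv == pytest.approx(prevalence, abs=0.02)

    def test_empty_evaluation_set_fails(self):
        from hlafinemap.hla_imputation import HlaCallSet

        calls = HlaCallSet(
            calls={g: np.full(4, None, dtype=object) for g in GENES},
            conflicts={g: np.zeros(4, dtype=bool) for g in GENES},
        )
        truth = {g: np.full(4, None, dtype=object) for g in GENES}
        with pytest.raises(ImputationError, match="empty"):
            evaluate_imputation(calls, truth, {"validation": np.zeros(4, bool)})


class TestTrainingPpvWithFullConsensus:
    def test_ppv_one_when_consensus_one(self, rng):
        # clean template pool, consensus=1.0: training PPV is exactly 1
        m, n = 12, 120
        base = rng.integers(0, 2, size=(4, m)).astype(np.int8)
        idx = rng.integers(0, 4, size=n)
        H = base[idx]
        labels = {g: np.full(n, None, dtype=object) for g in GENES}
        labels["HLA-B"] = np.array(
            [f"B*{i:02d}01" for i in idx], dtype=object
        )
        region = _toy_region(m)
        panel = TagSnpPanel(
            {f"B*{i:02d}01": region.snp_ids[3 * i] for i in range(4)}, [], region
        )
        segs, _, _ = learn_allele_segments(
            H, labels, panel, consensus=1.0, min_pattern_count=1
        )
        calls = impute_hla_alleles(H, segs)
        perf = evaluate_imputation(
            calls, labels, {"training": np.ones(n, dtype=bool)},
            alleles=[s.allele for s in segs],
        )
        assert (perf.ppv.dropna() == 1.0).all()
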