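"""CCF estimation, clonality, early/late timing and enrichment."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from nmibcgen.cohort_io import CNSegment, MutationRecord
from nmibcgen.timing import (
    classify_timing,
    early_enrichment_test,
    estimate_ccf,
    estimate_multiplicity,
    time_cohort,
    time_mutation,
    timing_table,
)


class TestMultiplicity:
    @pytest.mark.parametrize("vaf,purity,cnt,major,c_expected,m_expected", [
        (0.75, 1.0, 4, 3, 3.0, 3),
        (0.25, 0.5, 2, 1, 1.0, 1),
        (0.9, 1.0, 3, 2, 2.7, 2),     # clipped to major
    ])
    def test_formula_and_clip(self, vaf, purity, cnt, major, c_expected,
                              m_expected):
        c, m = estimate_multiplicity(vaf, purity, cnt, major)
        assert c == pytest.approx(c_expected)
        assert m == m_expected

    def test_homozygous_deletion_untimeable(self):
        with pytest.raises(ValueError, match="untimeable"):
            estimate_multiplicity(0.3, 0.5, 0, 0)


class TestCcf:
    def test_algebra_recovers_clonal(self):
        m = MutationRecord("S1", "chr1", 10, "C", "T", "G", "missense", 25, 75)
        ccf, raw, lo, hi = estimate_ccf(m, purity=0.5, cn_total=2,
                                        multiplicity=1)
        assert raw == pytest.approx(1.0)

    def test_subclonal_ci_matches_independent_clopper_pearson(self):
        # vaf=25/200 at purity 1, CNt=2, m=1 -> CCF=0.25; the CI is the
        # exact binomial interval scaled by 2, computed independently
        m = MutationRecord("S1", "chr1", 10, "C", "T", "G", "missense",
                           25, 175)
        ccf, raw, lo, hi = estimate_ccf(m, 1.0, 2, 1)
        exp_lo, exp_hi = proportion_confint(25, 200, alpha=0.05,
                                            method="beta")
        assert raw == pytest.approx(0.25)
        assert lo == pytest.approx(exp_lo * 2, abs=1e-9)
        assert hi == pytest.approx(exp_hi * 2, abs=1e-9)
        assert hi < 1.0  # subclonal: CI excludes 1

    def test_clonal_when_half_vaf_pure_diploid(self):
        m = MutationRecord("S1", "chr1", 10, "C", "T", "G", "missense",
                           100, 100)
        ccf, raw, lo, hi = estimate_ccf(m, 1.0, 2, 1)
        assert ccf == pytest.approx(1.0)
        assert hi >= 1.0


class TestClassifyTiming:
    @pytest.mark.parametrize("clonality,major,m,expected", [
        ("clonal", 3, 3, "early"),
        ("clonal", 2, 1, "late"),
        ("subclonal", 2, 2, "late"),
        ("subclonal", 1, 1, "late"),
        ("clonal", 1, 1, "early"),        # un-gained default
    ])
    def test_rules(self, clonality, major, m, expected):
        assert classify_timing(clonality, major, m) == expected

    def test_strict_mode_marks_ungained_clonal_untimeable(self):
        assert classify_timing("clonal", 1, 1, strict_timing=True) == "untimeable"

    def test_no_covering_segment_untimeable(self):
        m = MutationRecord("S1", "chr1", 10, "C", "T", "G", "missense", 9, 1)
        call = time_mutation(m, 0.5, None)
        assert call.timing == "untimeable"


class TestConservation:
    def test_timing_categories_partition_all_mutations(self, sim):
        calls = time_cohort(sim.cohort)
        n_snv = sum(1 for m in sim.cohort.mutations if m.is_snv)
        table = timing_table(calls)
        assert len(table) == n_snv
        assert table.timing.isin(["early", "late", "untimeable"]).all()


class TestEarlyEnrichment:
    def _calls(self, gene_timings, background):
        """Build minimal timing calls from (gene, timing) specs."""
        calls = []
        for i, (gene, timing) in enumerate(gene_timings + background):
            m = MutationRecord("S1", "chr1", i + 1, "C", "T", gene,
                               "missense", 9, 1)
            calls.append(time_mutation(
                m, 1.0, CNSegment("S1", "chr1", i + 1, i + 1, 1, 1)))
        # overwrite timing labels directly for a controlled fixture
        from dataclasses import replace
        labeled = []
        for call, (gene, timing) in zip(
                calls, gene_timings + background):
            labeled.append(replace(call, gene=gene, timing=timing,
                                   clonality="clonal"))
        return labeled

    def test_all_early_gene_is_enriched(self):
        gene = [("HOT", "early")] * 5
        background = [(f"B{i}", "early" if i % 2 else "late")
                      for i in range(200)]
        calls = self._calls(gene, background)
        result = early_enrichment_test(calls, n_perm=1000, seed=0,
                                       min_mutations=3)
        assert result.set_index("gene").loc["HOT", "p"] <= 0.1

    def test_background_matched_gene_not_enriched(self):
        ps = []
        for seed in range(5):
            gene = [("NULLG", "early" if i % 2 else "late") for i in range(6)]
            background = [(f"B{i}", "early" if i % 2 else "late")
                          for i in range(200)]
            calls = self._calls(gene, background)
            result = early_enrichment_test(calls, n_perm=500, seed=seed,
                                           min_mutations=3)
            ps.append(result.set_index("gene").loc["NULLG", "p"])
        assert max(ps) > 0.3

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            early_enrichment_test([], n_perm=0)


class TestRecoveryOnTruth:
    def test_clonality_ccf_and_timing_recovery(self, sim):
        calls = time_cohort(sim.cohort)
        table = timing_table(calls).set_index(["sample", "chrom", "pos"])
        truth = sim.truth.mutations.set_index(["sample", "chrom", "pos"])
        joined = table.join(truth, rsuffix="_true")
        timed = joined[joined.clonality != "untimeable"]
        accuracy = (timed.clonality == timed.clonality_true).mean()
        rmse = np.sqrt(((timed.ccf - timed.ccf_true) ** 2).mean())
        assert accuracy >= 0.9
        assert rmse <= 0.12
        clonal = joined[joined.clonality_true == "clonal"]
        assert 0.9 <= clonal.ccf_raw.mean() <= 1.1
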