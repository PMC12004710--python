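"""dN/dS opportunities, estimation, timing odds ratios, pathway pooling."""

import numpy as np
import pandas as pd
import pytest

from nmibcgen._constants import CODON_TABLE
from nmibcgen.cohort_io import MutationRecord
from nmibcgen.selection import (
    RateModel,
    dnds_for_scope,
    dnds_from_counts,
    estimate_dnds,
    mutation_opportunities,
    pathway_dnds,
    simulate_class_counts,
    timing_odds_ratio,
)


def _enumerate_codon_changes(codon):
    """Independent oracle: classify all 9 single-base changes of a codon."""
    out = {"missense": 0, "nonsense": 0, "synonymous": 0}
    for i, ref in enumerate(codon):
        for alt in "ACGT":
            if alt == ref:
                continue
            alt_codon = codon[:i] + alt + codon[i + 1:]
            a, b = CODON_TABLE[codon], CODON_TABLE[alt_codon]
            if a == b:
                out["synonymous"] += 1
            elif b == "*":
                out["nonsense"] += 1
            else:
                out["missense"] += 1
    return out


class TestOpportunities:
    def test_atg_all_nine_changes_nonsynonymous(self):
        opp = mutation_opportunities({"G": "ATG"})
        oracle = _enumerate_codon_changes("ATG")
        assert oracle["synonymous"] == 0
        assert opp.loc["G", "synonymous"] == 0
        assert (opp.loc["G", "missense"] + opp.loc["G", "nonsense"]) == 9

    def test_uniform_rates_match_enumeration_over_random_cds(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            cds = "".join(rng.choice(list("ACGT"), size=30))
            opp = mutation_opportunities({"G": cds})
            oracle = {"missense": 0, "nonsense": 0, "synonymous": 0}
            for c in range(0, 30, 3):
                for cls, n in _enumerate_codon_changes(cds[c:c + 3]).items():
                    oracle[cls] += n
            for cls, n in oracle.items():
                assert opp.loc["G", cls] == n

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            mutation_opportunities({"G": "ATGA"})
        with pytest.raises(ValueError, match="empty"):
            mutation_opportunities({"G": ""})


class TestEstimate:
    def test_saturation_identity(self):
        # observing every possible substitution exactly once -> dN/dS = 1
        rng = np.random.default_rng(1)
        cds = "".join(rng.choice(list("ACGT"), size=60))
        opp = mutation_opportunities({"G": cds})
        counts = pd.DataFrame({
            "missense": [opp.loc["G", "missense"]],
            "nonsense": [opp.loc["G", "nonsense"]],
            "synonymous": [opp.loc["G", "synonymous"]],
            "splice": [0]}, index=["G"])
        est = dnds_from_counts(counts, opp)["point-combined"]
        assert est.dnds == pytest.approx(1.0)

    def test_simple_algebra(self):
        est = estimate_dnds(20, 200.0, 10, 100.0)
        assert est.dnds == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_zero_synonymous_flagged_unstable(self):
        est = estimate_dnds(5, 100.0, 0, 100.0)
        assert est.unstable and est.dnds == float("inf")

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n_c, n_s = int(rng.integers(1, 100)), int(rng.integers(1, 100))
            est = estimate_dnds(n_c, 150.0, n_s, 80.0)
            assert est.ci_low <= est.dnds <= est.ci_high


class TestTimingOddsRatio:
    def _est(self, value):
        return estimate_dnds(int(value * 10), 10.0, 10, 10.0)

    def test_early_favored_above_two(self):
        result = timing_odds_ratio("G", self._est(4.0), self._est(1.0))
        assert result.odds_ratio == pytest.approx(4.0)
        assert result.phase == "early-favored"

    def test_late_favored_below_half(self):
        result = timing_odds_ratio("G", self._est(1.0), self._est(4.0))
        assert result.odds_ratio == pytest.approx(0.25)
        assert result.phase == "late-favored"

    def test_equal_strata_none(self):
        result = timing_odds_ratio("G", self._est(2.0), self._est(2.0))
        assert result.phase == "none"

    def test_unstable_late_not_evaluable(self):
        late = estimate_dnds(5, 10.0, 0, 10.0)
        result = timing_odds_ratio("G", self._est(1.0), late)
        assert not result.evaluable


class TestPathways:
    def _mutations(self, spec):
        out = []
        for i, (gene, consequence) in enumerate(spec):
            out.append(MutationRecord("S1", "chr1", i + 1, "C", "T", gene,
                                      consequence, 9, 1))
        return out

    def test_single_gene_pathway_equals_gene_estimate(self):
        rng = np.random.default_rng(3)
        cds = "".join(rng.choice(list("ACGT"), size=300))
        opp = mutation_opportunities({"TP53": cds})
        muts = self._mutations([("TP53", "missense")] * 8
                               + [("TP53", "synonymous")] * 4)
        path = pathway_dnds(muts, opp, {"solo": ["TP53"]})
        gene = dnds_for_scope(muts, opp, {"TP53"})["point-combined"]
        assert path.iloc[0].dnds == pytest.approx(gene.dnds)

    def test_disjoint_pathways_conserve_counts(self):
        rng = np.random.default_rng(4)
        cds = {g: "".join(rng.choice(list("ACGT"), size=60))
               for g in ("A", "B", "C", "D")}
        opp = mutation_opportunities(cds)
        muts = self._mutations(
            [("A", "missense")] * 3 + [("B", "synonymous")] * 2
            + [("C", "nonsense")] * 2 + [("D", "missense")] * 4
            + [("A", "synonymous")] * 3)
        pathways = {"p1": ["A", "B"], "p2": ["C", "D"]}
        table = pathway_dnds(muts, opp, pathways)
        assert table.n_class.sum() == 9   # all nonsynonymous SNVs
        assert table.n_syn.sum() == 5

    def test_empty_pathway_skipped(self):
        opp = mutation_opportunities({"A": "ATGATG"})
        table = pathway_dnds([], opp, {"ghost": ["ZZZ"]})
        assert len(table) == 0


class TestNeutralCalibration:
    def test_neutral_simulation_dnds_near_one(self):
        rng = np.random.default_rng(5)
        cds = {f"G{i}": "".join(rng.choice(list("ACGT"), size=300))
               for i in range(30)}
        opp = mutation_opportunities(cds)
        counts = simulate_class_counts(opp, 5000, rng)
        est = dnds_from_counts(counts, opp)["point-combined"]
        assert 0.9 <= est.dnds <= 1.1

    def test_planted_selection_raises_gene_dnds(self):
        rng = np.random.default_rng(6)
        cds = {f"G{i}": "".join(rng.choice(list("ACGT"), size=300))
               for i in range(20)}
        opp = mutation_opportunities(cds)
        counts = simulate_class_counts(opp, 8000, rng,
                                       selection={"G0": 3.0, "G1": 3.0})
        for gene in ("G0", "G1"):
            est = dnds_from_counts(counts, opp, {gene}, scope=gene)[
                "point-combined"]
            assert est.dnds > 1.5
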