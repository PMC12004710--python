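"""Driver-classification rule engine."""

import numpy as np
import pytest

from nmibcgen.cohort_io import (GeneAnnotation, MutationRecord, SampleProfile,
                                assemble_cohort)
from nmibcgen.drivers import (
    RULE_NONE,
    RULE_ONCOKB,
    RULE_RECURRENT,
    RULE_TSG,
    DeleteriousnessCall,
    build_driver_catalog,
    classify_driver,
    is_deleterious,
    variant_id,
)


def _mutation(consequence="missense", gene="TP53", pos=100):
    return MutationRecord("S1", "chr1", pos, "C", "T", gene, consequence,
                          10, 90, "ACA")


class TestIsDeleterious:
    def test_stop_gain_needs_no_predictors(self):
        call = DeleteriousnessCall()  # all missing
        assert is_deleterious(_mutation("nonsense"), call) is True

    def test_two_of_three_suffice(self):
        call = DeleteriousnessCall("deleterious", "deleterious", "tolerated")
        assert is_deleterious(_mutation(), call) is True

    def test_one_of_three_insufficient(self):
        call = DeleteriousnessCall("deleterious", "tolerated", "tolerated")
        assert is_deleterious(_mutation(), call) is False

    def test_all_missing_indeterminate_warns_false(self):
        with pytest.warns(UserWarning, match="missing"):
            assert is_deleterious(_mutation(), DeleteriousnessCall()) is False

    def test_frameshift_stop_gain_equivalent_and_its_toggle(self):
        call = DeleteriousnessCall()
        assert is_deleterious(_mutation("indel"), call,
                              frameshift_as_stopgain=True) is True
        with pytest.warns(UserWarning):
            assert is_deleterious(_mutation("indel"), call,
                                  frameshift_as_stopgain=False) is False


class TestClassifyDriver:
    def test_deleterious_tsg_fires_tsg_rule(self):
        annotation = GeneAnnotation("TP53", "TSG")
        call = classify_driver(_mutation("nonsense"), True, annotation)
        assert call.is_driver and call.rule_fired == RULE_TSG

    def test_oncogene_with_three_cosmic_matches(self):
        m = _mutation(gene="FGFR3")
        annotation = GeneAnnotation(
            "FGFR3", "oncogene", cosmic_match_counts={variant_id(m): 3})
        call = classify_driver(m, False, annotation)
        assert call.is_driver and call.rule_fired == RULE_RECURRENT

    def test_two_cosmic_matches_not_in_oncokb_is_negative(self):
        m = _mutation(gene="FGFR3")
        annotation = GeneAnnotation(
            "FGFR3", "oncogene", cosmic_match_counts={variant_id(m): 2})
        assert classify_driver(m, False, annotation).rule_fired == RULE_NONE

    def test_oncokb_membership_qualifies(self):
        m = _mutation(gene="HRAS")
        annotation = GeneAnnotation(
            "HRAS", "oncogene", oncogenic_variants=frozenset({variant_id(m)}))
        assert classify_driver(m, False, annotation).rule_fired == RULE_ONCOKB

    def test_both_role_precedence_tsg_first(self):
        m = _mutation(gene="X")
        annotation = GeneAnnotation(
            "X", "both", oncogenic_variants=frozenset({variant_id(m)}))
        assert classify_driver(m, True, annotation).rule_fired == RULE_TSG

    def test_unannotated_gene_never_driver(self):
        assert classify_driver(_mutation(), True, None).is_driver is False

    def test_monotone_in_deleteriousness(self):
        # flipping deleterious False -> True never un-drivers a variant
        rng = np.random.default_rng(3)
        roles = ["TSG", "oncogene", "both", "none"]
        for i in range(300):
            m = _mutation(gene=f"G{i}")
            onc = frozenset({variant_id(m)}) if rng.random() < 0.3 else frozenset()
            counts = {variant_id(m): int(rng.integers(0, 5))}
            annotation = GeneAnnotation(f"G{i}", roles[rng.integers(4)],
                                        onc, counts)
            before = classify_driver(m, False, annotation).is_driver
            after = classify_driver(m, True, annotation).is_driver
            assert after >= before


class TestBruteForceEquivalence:
    def test_rule_engine_matches_clause_reevaluation(self):
        # independent re-statement of the three clauses on random variants
        rng = np.random.default_rng(5)
        verdict_pool = ["deleterious", "tolerated", "missing"]
        for i in range(1000):
            consequence = ["missense", "nonsense"][rng.integers(2)]
            m = _mutation(consequence, gene=f"G{i % 37}", pos=int(rng.integers(1, 1e6)))
            verdicts = DeleteriousnessCall(*(verdict_pool[j] for j in rng.integers(3, size=3)))
            role = ["TSG", "oncogene", "both", "none"][rng.integers(4)]
            vid = variant_id(m)
            onc = frozenset({vid}) if rng.random() < 0.3 else frozenset()
            counts = {vid: int(rng.integers(0, 5))}
            annotation = GeneAnnotation(m.gene, role, onc, counts)

            deleterious = is_deleterious(m, verdicts) if (
                consequence == "nonsense" or not verdicts.all_missing
            ) else False
            # brute-force truth table
            clause_del = (consequence == "nonsense"
                          or verdicts.n_deleterious >= 2)
            clause_tsg = clause_del and role in ("TSG", "both")
            clause_onc = role in ("oncogene", "both") and (
                vid in onc or counts.get(vid, 0) >= 3)
            expected = clause_tsg or clause_onc
            got = classify_driver(m, deleterious, annotation).is_driver
            assert got == expected


class TestCatalog:
    def test_hand_built_fixture_catalog_size(self):
        profiles = {"S1": SampleProfile("S1", 0.5, 2.0)}
        annotations = {
            "TP53": GeneAnnotation("TP53", "TSG"),
            "FGFR3": GeneAnnotation("FGFR3", "oncogene"),
        }
        muts = [
            MutationRecord("S1", "chr1", 1, "C", "T", "TP53", "nonsense", 9, 1),   # driver
            MutationRecord("S1", "chr1", 2, "C", "T", "TP53", "missense", 9, 1),   # no verdicts
            MutationRecord("S1", "chr1", 3, "C", "T", "FGFR3", "missense", 9, 1),  # oncokb below
            MutationRecord("S1", "chr1", 4, "C", "T", "OTHER", "nonsense", 9, 1),  # unannotated
            MutationRecord("S1", "chr1", 5, "C", "T", "TP53", "synonymous", 9, 1),
        ]
        fgfr3 = muts[2]
        annotations["FGFR3"] = GeneAnnotation(
            "FGFR3", "oncogene",
            oncogenic_variants=frozenset({variant_id(fgfr3)}))
        cohort = assemble_cohort(muts, [], profiles, annotations=annotations)
        catalog, per_sample, calls = build_driver_catalog(cohort)
        assert len(catalog) == 2
        assert per_sample["S1"] == {"TP53", "FGFR3"}

    def test_empty_cohort_and_determinism(self):
        profiles = {"S1": SampleProfile("S1", 0.5, 2.0)}
        cohort = assemble_cohort([], [], profiles)
        assert build_driver_catalog(cohort)[0] == set()

    def test_same_input_same_catalog(self, sim):
        a = build_driver_catalog(sim.cohort, sim.verdicts)[0]
        b = build_driver_catalog(sim.cohort, sim.verdicts)[0]
        assert a == b and len(a) > 0
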