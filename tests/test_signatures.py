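"""Spectra, EM exposures, de novo NMF extraction and APOBEC enrichment."""

import numpy as np
import pandas as pd
import pytest

from nmibcgen._constants import CHANNELS_96
from nmibcgen.cohort_io import MutationRecord
from nmibcgen.resources import bundled_catalog
from nmibcgen.signatures import (
    apobec_enrichment,
    build_spectrum,
    cohort_spectra,
    extract_denovo_nmf,
    fit_exposures_em,
    presence_matrix,
)


def _snv(ref, alt, context3, pos=100):
    return MutationRecord("S1", "chr1", pos, ref, alt, "G", "missense",
                          10, 90, context3)


class TestSpectrum:
    def test_pyrimidine_channel(self):
        s = build_spectrum([_snv("C", "T", "ACA")])
        assert s["A[C>T]A"] == 1 and s.sum() == 1

    def test_purine_reverse_complemented(self):
        # G>A at TGT on + strand is A[C>T]A on the pyrimidine strand
        s = build_spectrum([_snv("G", "A", "TGT")])
        assert s["A[C>T]A"] == 1 and s.sum() == 1

    def test_empty_is_zero_vector(self):
        s = build_spectrum([])
        assert s.sum() == 0 and len(s) == 96

    def test_non_snv_and_mismatch_skipped(self):
        indel = MutationRecord("S1", "chr1", 5, "CT", "C", "G", "indel", 9, 1)
        bad_ctx = _snv("C", "T", "AGA")  # context center != ref
        s = build_spectrum([indel, bad_ctx, _snv("C", "G", "TCA")])
        assert s.sum() == 1

    def test_early_late_strata_sum_to_all(self, sim):
        from nmibcgen.timing import time_cohort
        calls = time_cohort(sim.cohort)
        by_key = {c.mutation_key: c.timing for c in calls}
        full = cohort_spectra(sim.cohort, sim.genome)
        early = cohort_spectra(sim.cohort, sim.genome, by_key, "early")
        late = cohort_spectra(sim.cohort, sim.genome, by_key, "late")
        untimed = cohort_spectra(sim.cohort, sim.genome, by_key, "untimeable")
        assert np.allclose(early + late + untimed, full)


class TestExposuresEM:
    def _disjoint_catalog(self):
        cat = pd.DataFrame(0.0, index=list(CHANNELS_96), columns=["s1", "s2"])
        cat.iloc[:48, 0] = 1 / 48
        cat.iloc[48:, 1] = 1 / 48
        return cat

    def test_pure_signature_fully_attributed(self):
        cat = self._disjoint_catalog()
        spectrum = pd.Series(0.0, index=list(CHANNELS_96), name="S1")
        spectrum.iloc[:48] = 100 / 48
        exposures = fit_exposures_em(spectrum, cat)
        assert exposures.counts["s1"] == pytest.approx(100, abs=1e-6)
        assert exposures.counts["s2"] == pytest.approx(0, abs=1e-6)

    def test_disjoint_mixture_exact(self):
        cat = self._disjoint_catalog()
        spectrum = pd.Series(0.0, index=list(CHANNELS_96), name="S1")
        spectrum.iloc[:48] = 60 / 48
        spectrum.iloc[48:] = 40 / 48
        exposures = fit_exposures_em(spectrum, cat)
        assert exposures.counts["s1"] == pytest.approx(60, abs=0.5)
        assert exposures.counts["s2"] == pytest.approx(40, abs=0.5)

    def test_presence_needs_ten_mutations(self):
        # count 9 at 30% fraction fails the >= 10 mutation leg
        cat = self._disjoint_catalog()
        spectrum = pd.Series(0.0, index=list(CHANNELS_96), name="S1")
        spectrum.iloc[:48] = 21 / 48
        spectrum.iloc[48:] = 9 / 48
        exposures = fit_exposures_em(spectrum, cat)
        assert exposures.fractions["s2"] == pytest.approx(0.3, abs=0.01)
        assert not exposures.present["s2"]
        assert exposures.present["s1"]

    def test_loglik_monotone_and_counts_conserved(self, sim):
        catalog = bundled_catalog()
        spectra = cohort_spectra(sim.cohort, sim.genome)
        for sample in list(spectra.columns)[:8]:
            exposures = fit_exposures_em(spectra[sample], catalog)
            ll = exposures.ll_trace
            assert (np.diff(ll) >= -1e-6).all()
            assert exposures.counts.sum() == pytest.approx(
                spectra[sample].sum(), abs=0.5)

    def test_zero_spectrum_nothing_present(self):
        catalog = bundled_catalog()
        spectrum = pd.Series(0.0, index=list(CHANNELS_96), name="S0")
        exposures = fit_exposures_em(spectrum, catalog)
        assert not exposures.present.any()


class TestDenovoNmf:
    def _two_signature_cohort(self, n=12, per_sample=400, seed=0):
        rng = np.random.default_rng(seed)
        cat = pd.DataFrame(0.0, index=list(CHANNELS_96), columns=["s1", "s2"])
        cat.iloc[:48, 0] = 1 / 48
        cat.iloc[48:, 1] = 1 / 48
        cols = {}
        for i in range(n):
            w = 0.9 if i % 2 else 0.1
            p = w * cat["s1"] + (1 - w) * cat["s2"]
            cols[f"S{i}"] = rng.multinomial(per_sample, p.to_numpy())
        return pd.DataFrame(cols, index=list(CHANNELS_96)), cat

    def test_two_signature_cohort_recovered(self):
        spectra, cat = self._two_signature_cohort()
        result = extract_denovo_nmf(spectra, cat, restarts=5, seed=1)
        assert result.k == 2
        assert (result.catalog_match.cosine >= 0.95).all()
        assert set(result.catalog_match.catalog_signature) == {"s1", "s2"}

    def test_determinism(self):
        spectra, cat = self._two_signature_cohort()
        a = extract_denovo_nmf(spectra, cat, restarts=3, seed=7)
        b = extract_denovo_nmf(spectra, cat, restarts=3, seed=7)
        assert np.allclose(a.signatures, b.signatures)

    def test_all_zero_rejected(self):
        spectra = pd.DataFrame(0.0, index=list(CHANNELS_96),
                               columns=[f"S{i}" for i in range(12)])
        with pytest.raises(ValueError, match="zero"):
            extract_denovo_nmf(spectra, bundled_catalog())

    def test_too_few_samples_rejected(self):
        spectra = pd.DataFrame(1.0, index=list(CHANNELS_96),
                               columns=["S1", "S2"])
        with pytest.raises(ValueError, match="10 samples"):
            extract_denovo_nmf(spectra, bundled_catalog())


class _Window:
    """Synthetic reference exposing a fixed window around any position."""

    def __init__(self, window_seq):
        self.window_seq = window_seq

    def fetch(self, chrom, start, end):
        if end - start == 2:          # trinucleotide query
            mid = len(self.window_seq) // 2
            return self.window_seq[mid - 1:mid + 2]
        return self.window_seq


class TestApobec:
    def test_constructed_enrichment_of_four(self):
        # all mutations C>T in tCw; window with 8 C sites of which 2 in tCw
        window = "TCA" + "GCG" * 6 + "TCT" + "ACGTA" * 4
        counts = _Window(window)
        t, c = (window.count("TCA") + window.count("TCT")
                + window.count("TGA") + window.count("AGA"),
                window.count("C") + window.count("G"))
        muts = [_snv("C", "T", "TCA", pos=50 + i) for i in range(10)]
        result = apobec_enrichment(muts, counts, "S1")
        assert result.enrichment == pytest.approx((10 / 10) / (t / c))

    def test_no_cytosine_mutations_undefined(self):
        result = apobec_enrichment([_snv("T", "A", "ATA")], None, "S1")
        assert np.isnan(result.enrichment) and result.group == "none"

    def test_matched_fractions_give_unit_enrichment_zero_load(self):
        # mutation tCw fraction == window tCw fraction -> E = 1, load 0
        window = "TCATGCG"  # 1 tCw (TCA) among C,C,G -> recompute below
        ref = _Window("TCA" + "CCGG" * 5)
        win = ref.fetch("chr1", 1, 41)
        t = sum(win.count(x) for x in ("TCA", "TCT", "TGA", "AGA"))
        c = win.count("C") + win.count("G")
        frac = t / c
        n_tcw = 2
        n_tot = round(n_tcw / frac)
        muts = ([_snv("C", "T", "TCA", pos=i + 1) for i in range(n_tcw)]
                + [_snv("C", "G", "GCC", pos=100 + i)
                   for i in range(n_tot - n_tcw)])
        result = apobec_enrichment(muts, ref, "S1")
        assert result.enrichment == pytest.approx(1.0, abs=0.05)
        assert result.load <= result.mut_tcw * 0.05
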