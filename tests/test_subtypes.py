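"""Brunet NMF, consensus rank selection and subtype characterization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nmibcgen._nmf import kl_divergence, nmf_kl
from nmibcgen.subtypes import (
    assign_labels,
    build_subtyping_matrix,
    characterize_subtypes,
    name_subtypes,
    nmf_brunet,
    select_rank,
)


def four_block_matrix(seed=0, n_per=10, d_per=8, p_in=0.85, p_out=0.08):
    rng = np.random.default_rng(seed)
    rows = []
    for block in range(4):
        for _ in range(n_per):
            row = rng.random(4 * d_per) < p_out
            row[block * d_per:(block + 1) * d_per] = rng.random(d_per) < p_in
            rows.append(row.astype(int))
    return pd.DataFrame(rows, index=[f"S{i}" for i in range(4 * n_per)],
                        columns=[f"e{j}" for j in range(4 * d_per)])


class TestBuildMatrix:
    def test_union_with_column_count(self):
        freq = pd.DataFrame(np.eye(5, dtype=int),
                            columns=[f"f{i}" for i in range(5)])
        cna = pd.DataFrame(np.ones((5, 3), dtype=int),
                           columns=["c1", "c2", "c3"])
        assert build_subtyping_matrix(freq, cna).shape[1] == 8

    def test_duplicate_column_deduplicated_with_warning(self):
        freq = pd.DataFrame({"a": [1, 0, 1], "b": [0, 1, 1]})
        dup = pd.DataFrame({"a": [1, 0, 1]})
        with pytest.warns(UserWarning, match="deduplicated"):
            matrix = build_subtyping_matrix(freq, dup)
        assert list(matrix.columns) == ["a", "b"]

    def test_constant_matrix_rejected(self):
        freq = pd.DataFrame({"a": [1, 1, 1], "b": [0, 0, 0]})
        with pytest.raises(ValueError, match="constant"):
            build_subtyping_matrix(freq)


class TestNmfBrunet:
    def test_rank_one_outer_product_exact(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(0.5, 2.0, size=12)
        v = rng.uniform(0.5, 2.0, size=8)
        matrix = pd.DataFrame(np.outer(u, v))
        W, H, trace = nmf_brunet(matrix, k=1, restarts=3, seed=1)
        assert trace[-1] < 1e-6

    def test_objective_non_increasing(self):
        matrix = four_block_matrix(seed=2)
        _, _, trace = nmf_brunet(matrix, k=4, restarts=1, seed=2)
        assert (np.diff(trace) <= 1e-9).all()

    def test_block_matrix_clusters_by_block(self):
        matrix = four_block_matrix(seed=3)
        _, H, _ = nmf_brunet(matrix, k=4, restarts=10, seed=3)
        labels = assign_labels(H)
        truth = np.repeat(np.arange(4), 10)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_same_seed_identical_factors(self):
        matrix = four_block_matrix(seed=4)
        W1, H1, _ = nmf_brunet(matrix, k=3, restarts=5, seed=9)
        W2, H2, _ = nmf_brunet(matrix, k=3, restarts=5, seed=9)
        assert np.allclose(W1, W2) and np.allclose(H1, H2)

    def test_negative_entries_rejected(self):
        matrix = pd.DataFrame([[1.0, -0.5], [0.2, 0.3]])
        with pytest.raises(ValueError, match="non-negative"):
            nmf_brunet(matrix, k=1)


class TestSelectRank:
    def test_four_block_cohort_selects_four(self):
        matrix = four_block_matrix(seed=5)
        k, diags = select_rank(matrix, (2, 3, 4, 5, 6), restarts=20, seed=5)
        assert k == 4

    def test_consensus_and_cophenetic_bounds(self):
        matrix = four_block_matrix(seed=6)
        _, diags = select_rank(matrix, (2, 3, 4), restarts=10, seed=6)
        for d in diags:
            consensus = d.consensus.to_numpy()
            assert consensus.min() >= 0 and consensus.max() <= 1
            assert np.allclose(np.diag(consensus), 1.0)
            assert np.allclose(consensus, consensus.T)
            assert 0.0 <= d.cophenetic <= 1.0

    def test_structureless_matrix_warns_flat(self):
        rng = np.random.default_rng(7)
        matrix = pd.DataFrame((rng.random((30, 20)) < 0.3).astype(int))
        with pytest.warns(UserWarning, match="flat"):
            select_rank(matrix, (2, 3, 4), restarts=10, seed=7)

    def test_single_value_range_warns_and_returns_it(self):
        matrix = four_block_matrix(seed=8)
        with pytest.warns(UserWarning, match="single-rank"):
            k, _ = select_rank(matrix, (3,), restarts=5, seed=8)
        assert k == 3

    def test_out_of_band_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[2, 8\]"):
            select_rank(four_block_matrix(), (1, 2), restarts=2, seed=0)


class TestCharacterize:
    def test_enrichment_and_naming(self, sim):
        # use truth archetypes as labels: enrichment must find the
        # hallmarks the generator planted
        from nmibcgen.dependency import assemble_event_matrix
        from nmibcgen.drivers import build_driver_catalog
        from nmibcgen.instability import profile_cohort
        from nmibcgen.resources import bundled_catalog
        from nmibcgen.signatures import (cohort_spectra, fit_exposures_em,
                                         presence_matrix)
        cohort = sim.cohort
        instab = profile_cohort(cohort, sim.genome.arms)
        spectra = cohort_spectra(cohort, sim.genome)
        catalog = bundled_catalog()
        presence = presence_matrix(
            [fit_exposures_em(spectra[s], catalog) for s in spectra.columns])
        _, drivers, _ = build_driver_catalog(cohort, sim.verdicts)
        matrix = assemble_event_matrix(drivers, None, presence, instab,
                                       samples=cohort.sample_ids)
        truth = sim.truth.samples.set_index("sample")
        labels = truth.loc[matrix.index, "archetype"].map(
            {"AA-like": 1, "FGFR3/HRAS": 2, "FGFR3&chr9Del": 3, "GI": 4})
        table = characterize_subtypes(labels, matrix, tmb=instab["tmb"])
        aa_sbs22 = table[(table.subtype == 1) & (table.event == "sig:SBS22")]
        gi_wgd = table[(table.subtype == 4) & (table.event == "flag:wgd")]
        assert aa_sbs22.iloc[0].p < 0.05 and aa_sbs22.iloc[0].odds_ratio > 1
        assert gi_wgd.iloc[0].p < 0.05 and gi_wgd.iloc[0].odds_ratio > 1

    def test_constant_feature_reported_na(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        matrix = pd.DataFrame({"mut:X": [1, 1, 1, 1], "mut:Y": [1, 1, 0, 0]},
                              index=list("abcd"))
        table = characterize_subtypes(labels, matrix)
        x_rows = table[table.event == "mut:X"]
        assert x_rows.odds_ratio.isna().all()
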