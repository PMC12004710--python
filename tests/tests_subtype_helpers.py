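"""Shared builders for subtype tests: block matrices and the full
cohort event matrix assembled from all upstream stages."""

import numpy as np
import pandas as pd

from nmibcgen.dependency import assemble_event_matrix
from nmibcgen.drivers import build_driver_catalog
from nmibcgen.instability import profile_cohort
from nmibcgen.resources import bundled_catalog
from nmibcgen.signatures import (apobec_cohort, cohort_spectra,
                                 fit_exposures_em, presence_matrix)


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


def build_event_matrix(sim):
    """Drivers + CNA events + signature presence + instability flags."""
    from nmibcgen.cna import cohort_events
    cohort = sim.cohort
    instab = profile_cohort(cohort, sim.genome.arms)
    apobec = apobec_cohort(cohort, sim.genome)
    instab_full = instab.join(apobec[["group"]])
    catalog = bundled_catalog()
    spectra = cohort_spectra(cohort, sim.genome)
    presence = presence_matrix(
        [fit_exposures_em(spectra[s], catalog) for s in spectra.columns])
    _, drivers, _ = build_driver_catalog(cohort, sim.verdicts)
    events = cohort_events(cohort, sim.genome.arms)
    matrix = assemble_event_matrix(drivers, events, presence, instab_full,
                                   samples=cohort.sample_ids)
    return matrix, instab
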