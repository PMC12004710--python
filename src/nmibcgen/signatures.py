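"""Mutational-signature analysis: 96-channel spectra, EM exposure
fitting against a known catalog, de novo KL-NMF extraction, the
presence rule (>= 10 mutations and >= 5% of a sample's total), and
APOBEC tCw enrichment.

Spectra use the 96 canonical pyrimidine-centred trinucleotide channels
(COSMIC ordering; see ``nmibcgen._constants.CHANNELS_96``).  Exposure
fitting treats a sample's spectrum as a mixture of catalog signatures
and maximizes the multinomial likelihood by EM; de novo extraction
factorizes the cohort's 96 x samples count matrix with Brunet KL-NMF
and maps each component to the catalog by maximal cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from nmibcgen._constants import CHANNEL_INDEX, COMPLEMENT, channel_of
from nmibcgen._nmf import best_of_restarts, cosine_similarity
from nmibcgen.cohort_io import MutationRecord

logger = logging.getLogger(__name__)

PRESENCE_MIN_COUNT = 10
PRESENCE_MIN_FRACTION = 0.05


# ---------------------------------------------------------------------------
# spectra

def build_spectrum(mutations, reference=None, sample_id: str = "",
                   stratum: str = "all") -> pd.Series:
    """96-channel mutation spectrum.

    Contexts come from each record's ``context3`` field, or from
    ``reference.fetch(chrom, pos-1, pos+1)`` when absent.  Non-SNVs are
    skipped (count logged); purine-reference SNVs are reverse-
    complemented into pyrimidine channels.  Context/reference
    mismatches skip the mutation with a log message."""
    counts = np.zeros(96, dtype=float)
    n_skipped = 0
    for m in mutations:
        if not m.is_snv:
            n_skipped += 1
            continue
        context = m.context3
        if not context and reference is not None:
            context = reference.fetch(m.chrom, m.pos - 1, m.pos + 1)
        try:
            channel = channel_of(m.ref, m.alt, context)
        except ValueError:
            n_skipped += 1
            logger.info("context mismatch for %s:%d %s>%s (%r)",
                        m.chrom, m.pos, m.ref, m.alt, context)
            continue
        counts[CHANNEL_INDEX[channel]] += 1
    if n_skipped:
        logger.info("spectrum %s/%s: skipped %d non-SNV or mismatched records",
                    sample_id, stratum, n_skipped)
    spectrum = pd.Series(counts, index=list(CHANNEL_INDEX), name=sample_id)
    spectrum.attrs["stratum"] = stratum
    return spectrum


def cohort_spectra(cohort, reference=None, timing_by_key: dict | None = None,
                   stratum: str = "all") -> pd.DataFrame:
    """96 x samples spectrum matrix, optionally restricted to one timing
    stratum ('early'/'late') via a mutation-key -> timing map."""
    columns = {}
    for sample_id in cohort.sample_ids:
        muts = cohort.mutations_of(sample_id)
        if timing_by_key is not None and stratum != "all":
            muts = [m for m in muts if timing_by_key.get(m.key) == stratum]
        columns[sample_id] = build_spectrum(muts, reference, sample_id, stratum)
    return pd.DataFrame(columns)


# ---------------------------------------------------------------------------
# EM exposure fitting

@dataclass
class ExposureSet:
    """Per-signature mutation counts, fractions and presence flags."""

    sample_id: str
    counts: pd.Series
    fractions: pd.Series
    present: pd.Series
    log_likelihood: float = float("nan")
    ll_trace: np.ndarray = field(default_factory=lambda: np.array([]))


def fit_exposures_em(spectrum: pd.Series, catalog: pd.DataFrame,
                     max_iter: int = 10_000, tol: float = 1e-8) -> ExposureSet:
    """Maximum-likelihood signature exposures for one sample by EM.

    The spectrum is modelled as a multinomial mixture of the catalog
    columns; iteration stops when the relative log-likelihood change
    drops below ``tol``.  The presence rule is applied to counts rounded
    half-up: present iff count >= 10 and fraction >= 0.05."""
    x = spectrum.to_numpy(dtype=float)
    P = catalog.to_numpy(dtype=float)          # 96 x K
    K = P.shape[1]
    total = x.sum()
    names = list(catalog.columns)
    if total == 0:
        zero = pd.Series(0.0, index=names)
        return ExposureSet(spectrum.name or "", zero, zero.copy(),
                           pd.Series(False, index=names), 0.0)
    e = np.full(K, 1.0 / K)
    ll_trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        mix = P @ e                            # 96
        ll = float(np.sum(x * np.log(np.maximum(mix, 1e-300))))
        ll_trace.append(ll)
        if prev_ll != -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
        resp = P * e[None, :] / np.maximum(mix, 1e-300)[:, None]   # 96 x K
        e = (x[:, None] * resp).sum(axis=0) / total
    counts = pd.Series(e * total, index=names)
    fractions = pd.Series(e, index=names)
    rounded = np.floor(counts + 0.5)           # half-up
    present = (rounded >= PRESENCE_MIN_COUNT) & (fractions >= PRESENCE_MIN_FRACTION)
    return ExposureSet(spectrum.name or "", counts, fractions, present,
                       ll_trace[-1], np.array(ll_trace))


def exposures_table(exposures: list) -> pd.DataFrame:
    rows = []
    for e in exposures:
        for sig in e.counts.index:
            rows.append({"sample": e.sample_id, "signature": sig,
                         "count": e.counts[sig], "fraction": e.fractions[sig],
                         "present": bool(e.present[sig])})
    return pd.DataFrame(rows)


def presence_matrix(exposures: list) -> pd.DataFrame:
    """samples x signatures boolean presence matrix."""
    return pd.DataFrame({e.sample_id: e.present for e in exposures}).T


# ---------------------------------------------------------------------------
# de novo extraction (KL-NMF stand-in with catalog matching)

@dataclass
class DenovoResult:
    k: int
    signatures: pd.DataFrame           # 96 x k, columns normalized to sum 1
    exposures: pd.DataFrame            # k x samples
    catalog_match: pd.DataFrame        # component, best catalog signature, cosine
    diagnostics: pd.DataFrame          # per-k error and stability


def _stability(results) -> float:
    """Mean one-to-one matched cosine of each restart's components
    against the best restart's components (Hungarian matching, so noise
    components cannot all shadow one stable component)."""
    from scipy.optimize import linear_sum_assignment
    best_W = min(results, key=lambda r: r[2])[0]
    best_cols = best_W / np.maximum(best_W.sum(axis=0), 1e-12)
    scores = []
    for W, _, _ in results:
        cols = W / np.maximum(W.sum(axis=0), 1e-12)
        k = cols.shape[1]
        cos = np.array([[cosine_similarity(cols[:, j], best_cols[:, i])
                         for i in range(k)] for j in range(k)])
        rows, cols_idx = linear_sum_assignment(-cos)
        scores.extend(cos[rows, cols_idx])
    return float(np.mean(scores))


def extract_denovo_nmf(spectra: pd.DataFrame, catalog: pd.DataFrame,
                       k_range=(1, 2, 3, 4, 5), restarts: int = 10,
                       seed: int = 0) -> DenovoResult:
    """De novo signatures by KL-NMF over the cohort spectrum matrix.

    The rank minimizes AIC = 2*KL + 2*df with df = k*(95 + n_samples):
    for multinomial count data every extra component reduces KL roughly
    linearly by absorbing sampling noise, so a raw reconstruction-error
    elbow (and restart stability, which only measures optimizer
    variance) cannot stop at the true rank; the parameter-count penalty
    can.  Each component is matched to the catalog by maximal cosine
    similarity; restart stability is reported as a diagnostic."""
    if spectra.shape[1] < 10:
        raise ValueError("de novo extraction needs >= 10 samples")
    k_range = sorted(k_range)
    if k_range[-1] > spectra.shape[1]:
        raise ValueError("k exceeds the number of samples")
    V = spectra.to_numpy(dtype=float)
    if V.sum() == 0:
        raise ValueError("all-zero spectra")
    n_channels, n_samples = V.shape
    per_k = {}
    diag_rows = []
    for k in k_range:
        W, H, trace, results = best_of_restarts(V, k, restarts, seed + k)
        stability = _stability(results) if len(results) > 1 else 1.0
        aic = 2.0 * trace[-1] + 2.0 * k * (n_channels - 1 + n_samples)
        per_k[k] = (W, H, trace[-1], stability, aic)
        diag_rows.append({"k": k, "kl": trace[-1], "stability": stability,
                          "aic": aic})
    diagnostics = pd.DataFrame(diag_rows)
    chosen = min(k_range, key=lambda k: per_k[k][4])
    W, H = per_k[chosen][0], per_k[chosen][1]
    col_sums = np.maximum(W.sum(axis=0), 1e-12)
    signatures = pd.DataFrame(W / col_sums, index=spectra.index,
                              columns=[f"denovo{i + 1}" for i in range(chosen)])
    exposures = pd.DataFrame(H * col_sums[:, None],
                             index=signatures.columns, columns=spectra.columns)
    match_rows = []
    for comp in signatures.columns:
        cosines = {sig: cosine_similarity(signatures[comp].to_numpy(),
                                          catalog[sig].to_numpy())
                   for sig in catalog.columns}
        best_sig = max(cosines, key=cosines.get)
        match_rows.append({"component": comp, "catalog_signature": best_sig,
                           "cosine": cosines[best_sig]})
    return DenovoResult(chosen, signatures, exposures,
                        pd.DataFrame(match_rows), diagnostics)


# ---------------------------------------------------------------------------
# APOBEC tCw enrichment

@dataclass
class ApobecResult:
    sample_id: str
    enrichment: float                  # NaN when undefined
    mut_tcw: int
    mut_c: int
    ctx_tcw: int
    ctx_c: int
    p: float = float("nan")
    q: float = float("nan")
    load: float = 0.0
    group: str = "none"


def _is_cytosine_mutation(m: MutationRecord) -> tuple | None:
    """(pyrimidine-strand ref, alt) for C>T / C>G mutations, else None."""
    if not m.is_snv:
        return None
    ref, alt = m.ref.upper(), m.alt.upper()
    if ref == "C" and alt in "TG":
        return ref, alt
    if ref == "G" and alt in "AC":
        return COMPLEMENT[ref], COMPLEMENT[alt]
    return None


def _count_context(window: str) -> tuple:
    """(tCw occurrences, cytosine count) over both strands of a window."""
    window = window.upper()
    ctx_c = window.count("C") + window.count("G")
    tcw = sum(window.count(motif) for motif in ("TCA", "TCT", "TGA", "AGA"))
    return tcw, ctx_c


def apobec_enrichment(mutations, reference, sample_id: str = "",
                      window: int = 20) -> ApobecResult:
    """APOBEC fold enrichment for one sample.

    E = (mut_tCw / mut_C) / (ctx_tCw / ctx_C), with context counted in
    the +-``window`` nt around each mutated cytosine (both strands).
    The one-sided Fisher p on the 2x2 table is filled in; BH adjustment
    and grouping happen cohort-wide in :func:`apobec_cohort`."""
    mut_tcw = mut_c = ctx_tcw = ctx_c = 0
    for m in mutations:
        pyr = _is_cytosine_mutation(m)
        if pyr is None:
            continue
        mut_c += 1
        context = m.context3
        if not context and reference is not None:
            context = reference.fetch(m.chrom, m.pos - 1, m.pos + 1)
        if context:
            if m.ref.upper() == "G":
                from nmibcgen._constants import revcomp
                context = revcomp(context)
            if len(context) == 3 and context[0] == "T" and context[2] in "AT":
                mut_tcw += 1
        if reference is not None:
            win = reference.fetch(m.chrom, m.pos - window, m.pos + window)
            t, c = _count_context(win)
            ctx_tcw += t
            ctx_c += c
    if mut_c == 0 or ctx_tcw == 0 or ctx_c == 0:
        return ApobecResult(sample_id, float("nan"), mut_tcw, mut_c,
                            ctx_tcw, ctx_c)
    mut_frac = mut_tcw / mut_c
    ctx_frac = ctx_tcw / ctx_c
    enrichment = mut_frac / ctx_frac
    table = [[mut_tcw, mut_c - mut_tcw], [ctx_tcw, ctx_c - ctx_tcw]]
    p = stats.fisher_exact(table, alternative="greater")[1]
    load = mut_tcw * max(0.0, (enrichment - 1.0) / enrichment)
    return ApobecResult(sample_id, enrichment, mut_tcw, mut_c, ctx_tcw,
                        ctx_c, p=p, load=load)


def apobec_cohort(cohort, reference, window: int = 20,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-sample APOBEC enrichment with BH adjustment across samples and
    none/low/high grouping (split at the median load of significant
    samples)."""
    from nmibcgen.clinical import bh_adjust
    results = [apobec_enrichment(cohort.mutations_of(s), reference, s, window)
               for s in cohort.sample_ids]
    testable = [r for r in results if np.isfinite(r.enrichment)]
    if testable:
        qs = bh_adjust(np.array([r.p for r in testable]))
        for r, q in zip(testable, qs):
            r.q = float(q)
    significant = [r for r in results if np.isfinite(r.q) and r.q < alpha]
    if significant:
        median_load = float(np.median([r.load for r in significant]))
        for r in significant:
            r.group = "high" if r.load > median_load else "low"
    table = pd.DataFrame([{
        "sample": r.sample_id, "enrichment": r.enrichment,
        "mut_tcw": r.mut_tcw, "mut_c": r.mut_c, "ctx_tcw": r.ctx_tcw,
        "ctx_c": r.ctx_c, "p": r.p, "q": r.q, "load": r.load,
        "group": r.group,
    } for r in results]).set_index("sample")
    for sample_id, row in table.iterrows():
        cohort.profiles[sample_id].apobec_group = row.group
    return table


__all__ = [
    "build_spectrum", "cohort_spectra", "ExposureSet", "fit_exposures_em",
    "exposures_table", "presence_matrix", "DenovoResult",
    "extract_denovo_nmf", "ApobecResult", "apobec_enrichment",
    "apobec_cohort", "PRESENCE_MIN_COUNT", "PRESENCE_MIN_FRACTION",
]
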