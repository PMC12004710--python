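"""Cancer cell fraction estimation and temporal dissection of mutations.

For a mutation with variant allele fraction ``f`` in a tumor of purity
``rho`` on a segment of total copy number ``CNt``, the continuous
mutation copy number is

    c = f * (rho * CNt + 2 (1 - rho)) / rho

with integer multiplicity ``m = round(c)`` clipped to ``[1, major]``,
and the cancer cell fraction is ``CCF = c / m``.  A mutation is clonal
when the 95% CI of its CCF (a Clopper-Pearson binomial interval on the
VAF propagated through the linear map) overlaps 1, subclonal otherwise.
Clonal mutations on segments with major allele copy number >= 2 are
"early" if ``c > 1`` (the mutation predates the gain) and "late"
otherwise; subclonal mutations are always "late".  Clonal mutations on
un-gained segments default to "early" (set ``strict_timing=True`` to
mark them untimeable instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nmibcgen.cohort_io import Cohort, MutationRecord, SegmentIndex, locate_segment

logger = logging.getLogger(__name__)

LOW_DEPTH = 8  # below this the binomial CI is too wide to be informative


@dataclass(frozen=True)
class TimingCall:
    """Per-mutation multiplicity, CCF with CI, clonality and timing."""

    mutation_key: tuple
    gene: str
    multiplicity: int
    mutation_copy_number: float
    ccf: float                  # capped at 1
    ccf_raw: float
    ccf_lo: float
    ccf_hi: float
    clonality: str              # clonal | subclonal | untimeable
    timing: str                 # early | late | untimeable
    low_depth: bool = False


def estimate_multiplicity(vaf: float, purity: float, cn_total: int,
                          major: int) -> tuple:
    """Continuous mutation copy number and its clipped integer multiplicity.

    Returns (c, m); raises for a homozygous deletion (CNt = 0)."""
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if cn_total < 1:
        raise ValueError("CNt = 0: mutation untimeable on a homozygous deletion")
    c = vaf * (purity * cn_total + 2.0 * (1.0 - purity)) / purity
    m = int(np.clip(round(c), 1, max(major, 1)))
    return c, m


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple:
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def estimate_ccf(mutation: MutationRecord, purity: float, cn_total: int,
                 multiplicity: int, level: float = 0.95) -> tuple:
    """CCF point estimate (raw and capped at 1) with a binomial CI.

    The Clopper-Pearson interval on the VAF is propagated through the
    linear map CCF = f * (rho*CNt + 2(1-rho)) / (m*rho)."""
    scale = (purity * cn_total + 2.0 * (1.0 - purity)) / (multiplicity * purity)
    raw = mutation.vaf * scale
    lo, hi = _clopper_pearson(mutation.t_alt, mutation.depth, level)
    return min(raw, 1.0), raw, lo * scale, hi * scale


def classify_timing(clonality: str, major: int, multiplicity: int,
                    strict_timing: bool = False) -> str:
    """Early/late assignment given clonality and local copy state.

    On gained segments (major >= 2) a clonal mutation is early when its
    integer mutation copy number exceeds 1 and late otherwise.  The
    rounded multiplicity is used rather than the raw continuous value:
    a late clonal mutation sits at continuous copy number exactly 1, so
    rounding places the decision boundary at 1.5, midway between the
    single-copy and multi-copy clusters."""
    if clonality == "untimeable":
        return "untimeable"
    if clonality == "subclonal":
        return "late"
    if major >= 2:
        return "early" if multiplicity > 1 else "late"
    return "untimeable" if strict_timing else "early"


def time_mutation(mutation: MutationRecord, purity: float, segment,
                  strict_timing: bool = False) -> TimingCall:
    """Full timing call for one mutation; ``segment`` may be None."""
    key, gene = mutation.key, mutation.gene
    if segment is None or segment.cn_total == 0:
        return TimingCall(key, gene, 0, float("nan"), float("nan"),
                          float("nan"), float("nan"), float("nan"),
                          "untimeable", "untimeable")
    c, m = estimate_multiplicity(mutation.vaf, purity, segment.cn_total,
                                 segment.major)
    ccf, raw, lo, hi = estimate_ccf(mutation, purity, segment.cn_total, m)
    clonality = "clonal" if hi >= 1.0 else "subclonal"
    timing = classify_timing(clonality, segment.major, m, strict_timing)
    return TimingCall(key, gene, m, c, ccf, raw, lo, hi, clonality, timing,
                      low_depth=mutation.depth < LOW_DEPTH)


def time_cohort(cohort: Cohort, strict_timing: bool = False,
                snv_only: bool = True) -> list:
    """Timing calls for every (SNV) mutation in the cohort."""
    index = SegmentIndex(cohort.segments)
    calls = []
    for m in cohort.mutations:
        if snv_only and not m.is_snv:
            continue
        purity = cohort.profiles[m.sample_id].purity
        segment = locate_segment(m, index)
        calls.append(time_mutation(m, purity, segment, strict_timing))
    n_untimed = sum(c.timing == "untimeable" for c in calls)
    logger.info("timed %d mutations (%d untimeable)", len(calls), n_untimed)
    return calls


def timing_table(calls: list) -> pd.DataFrame:
    rows = [{
        "sample": c.mutation_key[0], "chrom": c.mutation_key[1],
        "pos": c.mutation_key[2], "ref": c.mutation_key[3],
        "alt": c.mutation_key[4], "gene": c.gene,
        "multiplicity": c.multiplicity, "mut_cn": c.mutation_copy_number,
        "ccf": c.ccf, "ccf_raw": c.ccf_raw, "ccf_lo": c.ccf_lo,
        "ccf_hi": c.ccf_hi, "clonality": c.clonality, "timing": c.timing,
    } for c in calls]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-gene early enrichment by permutation

def early_enrichment_test(calls: list, n_perm: int = 1000, seed: int = 0,
                          min_mutations: int = 3) -> pd.DataFrame:
    """Permutation test of per-gene early-mutation enrichment.

    For each gene with >= ``min_mutations`` timed mutations, the observed
    early ratio is compared with ratios of ``n_perm`` random draws of the
    same size from all other timed mutations; the one-sided p-value is
    (1 + #{perm >= obs}) / (n_perm + 1), BH-adjusted across tested genes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    timed = [(c.gene, c.timing) for c in calls if c.timing != "untimeable"]
    genes = sorted({g for g, _ in timed if g})
    early_flags = np.array([t == "early" for _, t in timed])
    gene_arr = np.array([g for g, _ in timed])
    rows = []
    for gene in genes:
        mask = gene_arr == gene
        n_gene = int(mask.sum())
        if n_gene < min_mutations:
            logger.info("gene %s skipped: only %d timed mutations", gene, n_gene)
            continue
        observed = early_flags[mask].mean()
        background = early_flags[~mask]
        if len(background) < n_gene:
            continue
        draws = rng.random((n_perm, len(background))).argsort(axis=1)[:, :n_gene]
        perm_ratios = background[draws].mean(axis=1)
        p = (1.0 + np.sum(perm_ratios >= observed)) / (n_perm + 1.0)
        rows.append({"gene": gene, "n_mutations": n_gene,
                     "early_ratio": observed, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        from nmibcgen.clinical import bh_adjust
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


__all__ = [
    "TimingCall", "estimate_multiplicity", "estimate_ccf", "classify_timing",
    "time_mutation", "time_cohort", "timing_table", "early_enrichment_test",
]
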