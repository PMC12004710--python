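"""Genome-instability metrics: whole-genome doubling, wGII/CIN, TMB and
the hypermutation cutoff.

wGD is called only when two methods agree: (1) the major allele has
copy number >= 2 over >= 50% of the covered genome; (2) the
length-weighted modal major allele at chromosome-arm level is >= 2 on
>= 50% of arm length AND ploidy > 2.5 (an arm-profile surrogate for the
published aberration-probability model).  wGII is the length-weighted
fraction of the genome whose total copy number differs from the rounded
sample ploidy; CIN means wGII > 0.2.  Hypermutation is cut at the
largest TMB gap between successive samples within the top quartile of
the descending TMB ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nmibcgen._constants import NONSYNONYMOUS
from nmibcgen.cohort_io import Cohort

CIN_WGII_THRESHOLD = 0.2
WGD_GENOME_FRACTION = 0.5
WGD_PLOIDY_GATE = 2.5


@dataclass
class InstabilityProfile:
    sample_id: str
    wgd_method1: bool
    wgd_method2: bool
    wgii: float
    tmb: float
    hypermutated: bool | None = None

    @property
    def wgd(self) -> bool:
        return self.wgd_method1 and self.wgd_method2

    @property
    def cin(self) -> bool:
        return self.wgii > CIN_WGII_THRESHOLD


def wgd_fraction_method(segments) -> bool:
    """Major allele >= 2 across >= 50% of the covered genome."""
    if not segments:
        raise ValueError("empty segment set")
    lengths = np.array([s.length for s in segments], dtype=float)
    doubled = np.array([s.major >= 2 for s in segments], dtype=float)
    return float((lengths * doubled).sum() / lengths.sum()) >= WGD_GENOME_FRACTION


def _modal_major_per_arm(segments, arms: pd.DataFrame) -> pd.DataFrame:
    """Length-weighted modal (major, minor) per chromosome arm."""
    rows = []
    for arm in arms.itertuples(index=False):
        weights: dict = {}
        covered = 0
        for s in segments:
            if s.chrom != arm.chrom:
                continue
            overlap = min(s.end, arm.end) - max(s.start, arm.start) + 1
            if overlap <= 0:
                continue
            covered += overlap
            key = (s.major, s.minor)
            weights[key] = weights.get(key, 0) + overlap
        if covered == 0:
            warnings.warn(f"arm {arm.arm} not covered by segments; skipped",
                          stacklevel=3)
            continue
        (major, minor), _ = max(weights.items(), key=lambda kv: (kv[1], kv[0]))
        rows.append({"arm": arm.arm, "length": arm.end - arm.start + 1,
                     "major": major, "minor": minor})
    return pd.DataFrame(rows)


def wgd_arm_method(segments, arms: pd.DataFrame, ploidy: float) -> bool:
    """Arm-level modal major >= 2 over >= 50% of arm length, gated on
    ploidy > 2.5."""
    if ploidy <= WGD_PLOIDY_GATE:
        return False
    modal = _modal_major_per_arm(segments, arms)
    if modal.empty:
        return False
    frac = (modal.length * (modal.major >= 2)).sum() / modal.length.sum()
    return float(frac) >= WGD_GENOME_FRACTION


def compute_wgii(segments, ploidy: float) -> float:
    """Length-weighted fraction of the genome at total CN != round(ploidy)."""
    if ploidy <= 0:
        raise ValueError("ploidy must be > 0")
    if not segments:
        return 0.0
    reference_cn = int(round(ploidy))
    lengths = np.array([s.length for s in segments], dtype=float)
    aberrant = np.array([s.cn_total != reference_cn for s in segments],
                        dtype=float)
    return float((lengths * aberrant).sum() / lengths.sum())


def compute_tmb(cohort: Cohort, sample_id: str) -> float:
    """Nonsynonymous mutations per megabase of exome."""
    n = sum(1 for m in cohort.mutations
            if m.sample_id == sample_id and m.consequence in NONSYNONYMOUS)
    return n / cohort.profiles[sample_id].exome_size_mb


def define_hypermutation(tmb: pd.Series) -> tuple:
    """Gap rule: rank samples by TMB descending, compute successive
    differences, and cut at the largest gap within the top quartile.

    Returns (threshold, flags); with a zero maximal gap nothing is
    flagged and the threshold is None."""
    if len(tmb) < 5:
        raise ValueError("hypermutation cutoff needs >= 5 samples")
    ordered = tmb.sort_values(ascending=False)
    values = ordered.to_numpy()
    gaps = values[:-1] - values[1:]
    top_q = max(1, int(np.ceil(len(values) / 4)))
    window = gaps[:top_q]
    best = int(np.argmax(window))
    if window[best] <= 0:
        return None, pd.Series(False, index=tmb.index)
    threshold = values[best]  # TMB of the last hypermutated sample
    flags = tmb >= threshold
    return float(threshold), flags


def profile_cohort(cohort: Cohort, arms: pd.DataFrame) -> pd.DataFrame:
    """Full instability table (one row per sample) with cohort-level
    hypermutation flags; also backfills the SampleProfile flags."""
    rows = []
    for sample_id in cohort.sample_ids:
        segments = cohort.segments_of(sample_id)
        ploidy = cohort.profiles[sample_id].ploidy
        m1 = wgd_fraction_method(segments) if segments else False
        m2 = wgd_arm_method(segments, arms, ploidy) if segments else False
        wgii = compute_wgii(segments, ploidy)
        prof = InstabilityProfile(
            sample_id=sample_id, wgd_method1=m1, wgd_method2=m2,
            wgii=wgii, tmb=compute_tmb(cohort, sample_id))
        rows.append(prof)
    tmb = pd.Series({p.sample_id: p.tmb for p in rows})
    _, flags = define_hypermutation(tmb)
    table = pd.DataFrame([{
        "sample": p.sample_id, "wgd_method1": p.wgd_method1,
        "wgd_method2": p.wgd_method2, "wgd": p.wgd, "wgii": p.wgii,
        "cin": p.cin, "tmb": p.tmb,
        "hypermutated": bool(flags[p.sample_id]),
    } for p in rows]).set_index("sample")
    for sample_id, row in table.iterrows():
        profile = cohort.profiles[sample_id]
        profile.wgd = bool(row.wgd)
        profile.cin = bool(row.cin)
        profile.hypermutated = bool(row.hypermutated)
    return table


__all__ = [
    "InstabilityProfile", "wgd_fraction_method", "wgd_arm_method",
    "compute_wgii", "compute_tmb", "define_hypermutation", "profile_cohort",
    "CIN_WGII_THRESHOLD",
]
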