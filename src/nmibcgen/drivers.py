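"""Rule engine classifying nonsynonymous variants as driver mutations.

A variant is a driver if either
  * it is deleterious (stop-gain, or called deleterious by >= 2 of the
    three predictors SIFT / PolyPhen / MutationTaster) and its gene is a
    tumor suppressor, or
  * its gene is an oncogene and the exact variant has >= 3 COSMIC exact
    matches or is a known-oncogenic variant (OncoKB-style list).

Predictor verdicts are ingested precomputed; running the predictors is
out of scope.  Frameshift indels in tumor suppressors are treated as
stop-gain-equivalent (disable with ``frameshift_as_stopgain=False``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from nmibcgen.cohort_io import Cohort, GeneAnnotation, MutationRecord

RULE_NONE = "none"
RULE_TSG = "TSG-deleterious"
RULE_ONCOKB = "oncokb-oncogenic"
RULE_RECURRENT = "oncogene-recurrent"


@dataclass(frozen=True)
class DeleteriousnessCall:
    """Verdicts from the three predictors; each in
    {"deleterious", "tolerated", "missing"}."""

    sift: str = "missing"
    polyphen: str = "missing"
    mutationtaster: str = "missing"

    def __post_init__(self) -> None:
        for v in (self.sift, self.polyphen, self.mutationtaster):
            if v not in {"deleterious", "tolerated", "missing"}:
                raise ValueError(f"unknown verdict {v!r}")

    @property
    def n_deleterious(self) -> int:
        return sum(v == "deleterious"
                   for v in (self.sift, self.polyphen, self.mutationtaster))

    @property
    def all_missing(self) -> bool:
        return all(v == "missing"
                   for v in (self.sift, self.polyphen, self.mutationtaster))


@dataclass(frozen=True)
class DriverCall:
    variant_key: tuple
    is_driver: bool
    rule_fired: str

    def __post_init__(self) -> None:
        if self.is_driver != (self.rule_fired != RULE_NONE):
            raise ValueError("is_driver must match rule_fired")


def variant_id(mutation: MutationRecord) -> str:
    """Position-level variant identity used for COSMIC/OncoKB matching."""
    return f"{mutation.gene}:{mutation.chrom}:{mutation.pos}:{mutation.ref}>{mutation.alt}"


def is_deleterious(mutation: MutationRecord, calls: DeleteriousnessCall,
                   frameshift_as_stopgain: bool = True) -> bool:
    """Stop-gain, or >= 2 of 3 predictors deleterious.

    When all three predictor slots are missing for a non-stop-gain
    variant the call is indeterminate and returns False with a warning."""
    if mutation.consequence == "nonsense":
        return True
    if frameshift_as_stopgain and mutation.consequence == "indel":
        return True
    if calls.all_missing:
        warnings.warn(
            f"all predictor verdicts missing for {variant_id(mutation)}; "
            "treated as non-deleterious", stacklevel=2)
        return False
    return calls.n_deleterious >= 2


def classify_driver(mutation: MutationRecord, deleterious: bool,
                    annotation: GeneAnnotation | None) -> DriverCall:
    """Apply both rule paths; report by fixed precedence
    TSG-deleterious > oncokb-oncogenic > oncogene-recurrent."""
    key = mutation.key
    if annotation is None:
        return DriverCall(key, False, RULE_NONE)
    vid = variant_id(mutation)
    if deleterious and annotation.role in {"TSG", "both"}:
        return DriverCall(key, True, RULE_TSG)
    if annotation.role in {"oncogene", "both"}:
        if vid in annotation.oncogenic_variants:
            return DriverCall(key, True, RULE_ONCOKB)
        if annotation.cosmic_match_counts.get(vid, 0) >= 3:
            return DriverCall(key, True, RULE_RECURRENT)
    return DriverCall(key, False, RULE_NONE)


def verdicts_from_table(verdicts: pd.DataFrame) -> dict:
    """Index a verdict table (sample, chrom, pos, ref, alt, sift,
    polyphen, mutationtaster) by variant key."""
    out = {}
    for row in verdicts.itertuples(index=False):
        out[(row.sample, row.chrom, int(row.pos), row.ref, row.alt)] = (
            DeleteriousnessCall(row.sift, row.polyphen, row.mutationtaster))
    return out


def build_driver_catalog(cohort: Cohort, verdicts: dict | pd.DataFrame | None = None,
                         frameshift_as_stopgain: bool = True):
    """Classify every nonsynonymous variant in the cohort.

    Returns (catalog, per_sample, calls): the set of driver (gene,
    variant-id) pairs, per-sample sets of mutated driver genes, and the
    full list of DriverCall records."""
    if isinstance(verdicts, pd.DataFrame):
        verdicts = verdicts_from_table(verdicts)
    verdicts = verdicts or {}
    catalog = set()
    per_sample: dict = {s: set() for s in cohort.sample_ids}
    calls = []
    nonsyn = {"missense", "nonsense", "splice", "indel"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # indeterminate passengers are routine
        for m in cohort.mutations:
            if m.consequence not in nonsyn:
                continue
            annotation = cohort.annotations.get(m.gene)
            call_input = verdicts.get(m.key, DeleteriousnessCall())
            deleterious = is_deleterious(m, call_input, frameshift_as_stopgain)
            call = classify_driver(m, deleterious, annotation)
            calls.append(call)
            if call.is_driver:
                catalog.add((m.gene, variant_id(m)))
                per_sample[m.sample_id].add(m.gene)
    return catalog, per_sample, calls


def driver_catalog_table(catalog: set) -> pd.DataFrame:
    rows = sorted(catalog)
    return pd.DataFrame(rows, columns=["gene", "variant"])


__all__ = [
    "DeleteriousnessCall", "DriverCall", "variant_id", "is_deleterious",
    "classify_driver", "verdicts_from_table", "build_driver_catalog",
    "driver_catalog_table",
    "RULE_NONE", "RULE_TSG", "RULE_ONCOKB", "RULE_RECURRENT",
]
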