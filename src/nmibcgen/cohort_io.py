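"""Data model and validated TSV readers/writers for cohort tables.

All tables are tab-separated UTF-8 with a header row.  Coordinates are
1-based, fully closed intervals for both mutations and copy-number
segments (the ASCAT convention).  The writers emit exactly the dialect
the readers accept, so write-then-read round-trips are identity.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from nmibcgen._constants import CONSEQUENCES

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or a field fails validation."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant with read counts and optional 3-mer context.

    ``consequence`` is one of missense, nonsense, splice, synonymous,
    indel, other.  ``context3`` is the +strand trinucleotide around the
    variant ("" when unknown).  VAF is ``t_alt / (t_alt + t_ref)``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    t_alt: int
    t_ref: int
    context3: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SchemaError(f"pos must be >= 1, got {self.pos}")
        if self.t_alt < 0 or self.t_ref < 0:
            raise SchemaError("read counts must be non-negative")
        if self.t_alt + self.t_ref < 1:
            raise SchemaError("t_alt + t_ref must be >= 1")
        if self.ref == self.alt:
            raise SchemaError(f"ref == alt ({self.ref})")
        if self.consequence not in CONSEQUENCES:
            raise SchemaError(f"unknown consequence {self.consequence!r}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def vaf(self) -> float:
        return self.t_alt / (self.t_alt + self.t_ref)

    @property
    def depth(self) -> int:
        return self.t_alt + self.t_ref

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number interval; major >= minor >= 0."""

    sample_id: str
    chrom: str
    start: int
    end: int
    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SchemaError(f"start > end ({self.start} > {self.end})")
        if self.minor < 0 or self.major < self.minor:
            raise SchemaError(
                f"require major >= minor >= 0, got {self.major}+{self.minor}"
            )

    @property
    def cn_total(self) -> int:
        return self.major + self.minor

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleProfile:
    """Per-sample purity/ploidy plus instability flags set downstream."""

    sample_id: str
    purity: float
    ploidy: float
    exome_size_mb: float = 30.0
    wgd: bool | None = None
    cin: bool | None = None
    hypermutated: bool | None = None
    apobec_group: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise SchemaError(f"purity must be in (0, 1], got {self.purity}")
        if not self.ploidy > 0:
            raise SchemaError(f"ploidy must be > 0, got {self.ploidy}")
        if not self.exome_size_mb > 0:
            raise SchemaError("exome_size_mb must be > 0")


@dataclass(frozen=True)
class ClinicalRecord:
    """Stage/grade/therapy and recurrence-free survival outcome."""

    sample_id: str
    stage: str
    grade: str
    therapy: str
    rfs_months: float
    event: int

    def __post_init__(self) -> None:
        if self.stage not in {"Ta", "T1", "Tis"}:
            raise SchemaError(f"unknown stage {self.stage!r}")
        if self.grade not in {"HG", "LG", "PUNLMP"}:
            raise SchemaError(f"unknown grade {self.grade!r}")
        if self.therapy not in {"chemo", "BCG", "none"}:
            raise SchemaError(f"unknown therapy {self.therapy!r}")
        if self.rfs_months < 0:
            raise SchemaError("rfs_months must be >= 0")
        if self.event not in (0, 1):
            raise SchemaError("event must be 0 or 1")
        if self.event == 1 and self.rfs_months <= 0:
            raise SchemaError("event=1 requires rfs_months > 0")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene role (TSG / oncogene / both) with known-oncogenic variants."""

    gene: str
    role: str
    oncogenic_variants: frozenset = frozenset()
    cosmic_match_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in {"TSG", "oncogene", "both", "none"}:
            raise SchemaError(f"unknown role {self.role!r}")
        if any(v < 0 for v in self.cosmic_match_counts.values()):
            raise SchemaError("cosmic match counts must be >= 0")


@dataclass
class Cohort:
    """Validated container tying all per-sample tables together."""

    mutations: list
    segments: list
    profiles: dict
    clinical: dict
    annotations: dict

    @property
    def sample_ids(self) -> list:
        return sorted(self.profiles)

    @property
    def n_samples(self) -> int:
        return len(self.profiles)

    def mutations_of(self, sample_id: str) -> list:
        return [m for m in self.mutations if m.sample_id == sample_id]

    def segments_of(self, sample_id: str) -> list:
        return [s for s in self.segments if s.sample_id == sample_id]


# ---------------------------------------------------------------------------
# readers / writers

_MUTATION_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "gene",
    "consequence", "t_alt", "t_ref", "context3",
]
_SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major", "minor"]
_PROFILE_COLUMNS = ["sample", "purity", "ploidy", "exome_size_mb"]
_CLINICAL_COLUMNS = ["sample", "stage", "grade", "therapy", "rfs_months", "event"]
_ANNOTATION_COLUMNS = ["gene", "role", "oncogenic_variants", "cosmic_match_counts"]


def _read_tsv(path, required: Sequence[str],
              optional: Sequence[str] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extras = [c for c in df.columns if c not in required and c not in optional]
    if extras:
        warnings.warn(f"{path}: ignoring unknown columns {extras}", stacklevel=3)
    return df


def _int(value: str, row: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise SchemaError(f"row {row}: non-numeric {column}={value!r}") from None


def _float(value: str, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(f"row {row}: non-numeric {column}={value!r}") from None


def read_mutations(path) -> list:
    """Read a MAF-like mutation TSV; every row validated or rejected with
    a row-indexed message.  Unknown consequence strings map to "other"
    with a warning.  Row numbers are 1-based over data rows."""
    df = _read_tsv(path, _MUTATION_COLUMNS[:-1], optional=["context3"])
    has_ctx = "context3" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        consequence = row.consequence
        if consequence not in CONSEQUENCES:
            warnings.warn(
                f"row {i}: unknown consequence {consequence!r} mapped to 'other'",
                stacklevel=2,
            )
            consequence = "other"
        try:
            records.append(
                MutationRecord(
                    sample_id=row.sample,
                    chrom=row.chrom,
                    pos=_int(row.pos, i, "pos"),
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene,
                    consequence=consequence,
                    t_alt=_int(row.t_alt, i, "t_alt"),
                    t_ref=_int(row.t_ref, i, "t_ref"),
                    context3=row.context3 if has_ctx else "",
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from None
    return records


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    rows = [
        (m.sample_id, m.chrom, m.pos, m.ref, m.alt, m.gene,
         m.consequence, m.t_alt, m.t_ref, m.context3)
        for m in records
    ]
    pd.DataFrame(rows, columns=_MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list:
    """Read an ASCAT-style segment TSV; enforces per-sample per-chromosome
    sorting and non-overlap."""
    df = _read_tsv(path, _SEGMENT_COLUMNS)
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            segments.append(
                CNSegment(
                    sample_id=row.sample,
                    chrom=row.chrom,
                    start=_int(row.start, i, "start"),
                    end=_int(row.end, i, "end"),
                    major=_int(row.major, i, "major"),
                    minor=_int(row.minor, i, "minor"),
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from None
    validate_segments(segments)
    return segments


def validate_segments(segments: Sequence[CNSegment]) -> None:
    """Raise if any two segments of the same sample/chromosome overlap."""
    by_key: dict = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sample, chrom), group in by_key.items():
        group.sort(key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise SchemaError(
                    f"overlapping segments for {sample}/{chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def write_segments(segments: Iterable[CNSegment], path) -> None:
    rows = [
        (s.sample_id, s.chrom, s.start, s.end, s.major, s.minor) for s in segments
    ]
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> dict:
    df = _read_tsv(path, _PROFILE_COLUMNS)
    profiles = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            profiles[row.sample] = SampleProfile(
                sample_id=row.sample,
                purity=_float(row.purity, i, "purity"),
                ploidy=_float(row.ploidy, i, "ploidy"),
                exome_size_mb=_float(row.exome_size_mb, i, "exome_size_mb"),
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from None
    return profiles


def write_profiles(profiles: Mapping[str, SampleProfile], path) -> None:
    rows = [
        (p.sample_id, p.purity, p.ploidy, p.exome_size_mb)
        for p in profiles.values()
    ]
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> dict:
    df = _read_tsv(path, _CLINICAL_COLUMNS)
    clinical = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            clinical[row.sample] = ClinicalRecord(
                sample_id=row.sample,
                stage=row.stage,
                grade=row.grade,
                therapy=row.therapy,
                rfs_months=_float(row.rfs_months, i, "rfs_months"),
                event=_int(row.event, i, "event"),
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from None
    return clinical


def write_clinical(clinical: Mapping[str, ClinicalRecord], path) -> None:
    rows = [
        (c.sample_id, c.stage, c.grade, c.therapy, c.rfs_months, c.event)
        for c in clinical.values()
    ]
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict:
    """Gene-annotation TSV: role, semicolon-separated oncogenic variants,
    and "variant:count" semicolon-separated COSMIC exact-match counts."""
    df = _read_tsv(path, _ANNOTATION_COLUMNS)
    annotations = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        variants = frozenset(v for v in row.oncogenic_variants.split(";") if v)
        counts = {}
        for item in row.cosmic_match_counts.split(";"):
            if not item:
                continue
            variant, _, count = item.rpartition(":")
            counts[variant] = _int(count, i, "cosmic_match_counts")
        try:
            annotations[row.gene] = GeneAnnotation(
                gene=row.gene,
                role=row.role,
                oncogenic_variants=variants,
                cosmic_match_counts=counts,
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from None
    return annotations


def write_annotations(annotations: Mapping[str, GeneAnnotation], path) -> None:
    rows = []
    for a in annotations.values():
        variants = ";".join(sorted(a.oncogenic_variants))
        counts = ";".join(
            f"{v}:{c}" for v, c in sorted(a.cosmic_match_counts.items())
        )
        rows.append((a.gene, a.role, variants, counts))
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segment lookup and cohort assembly

class SegmentIndex:
    """Sorted per-sample/per-chromosome index for point-in-segment lookup."""

    def __init__(self, segments: Sequence[CNSegment]):
        validate_segments(list(segments))
        self._by_key: dict = {}
        for seg in segments:
            self._by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
        self._starts = {}
        for key, group in self._by_key.items():
            group.sort(key=lambda s: s.start)
            self._starts[key] = [s.start for s in group]

    def locate(self, sample_id: str, chrom: str, pos: int) -> CNSegment | None:
        key = (sample_id, chrom)
        if key not in self._by_key:
            return None
        idx = bisect_right(self._starts[key], pos) - 1
        if idx < 0:
            return None
        seg = self._by_key[key][idx]
        return seg if seg.start <= pos <= seg.end else None


def locate_segment(mutation: MutationRecord, index: SegmentIndex) -> CNSegment | None:
    """The unique segment containing the mutation position, or None.

    Boundaries are inclusive on both ends; absence is a legal outcome
    (the mutation is later recorded as untimeable)."""
    return index.locate(mutation.sample_id, mutation.chrom, mutation.pos)


def assemble_cohort(mutations, segments, profiles, clinical=None,
                    annotations=None) -> Cohort:
    """Cross-validate sample identity across tables and build a Cohort.

    Samples with zero mutations are allowed (their TMB is later 0);
    mutation or segment samples absent from the profile table are an
    error."""
    known = set(profiles)
    orphans = sorted({m.sample_id for m in mutations} - known)
    if orphans:
        raise SchemaError(f"mutation samples missing from profiles: {orphans}")
    orphans = sorted({s.sample_id for s in segments} - known)
    if orphans:
        raise SchemaError(f"segment samples missing from profiles: {orphans}")
    validate_segments(list(segments))
    cohort = Cohort(
        mutations=list(mutations),
        segments=list(segments),
        profiles=dict(profiles),
        clinical=dict(clinical or {}),
        annotations=dict(annotations or {}),
    )
    for sample_id in cohort.sample_ids:
        logger.info(
            "sample %s: %d mutations, %d segments",
            sample_id,
            sum(1 for m in mutations if m.sample_id == sample_id),
            sum(1 for s in segments if s.sample_id == sample_id),
        )
    return cohort


__all__ = [
    "SchemaError", "MutationRecord", "CNSegment", "SampleProfile",
    "ClinicalRecord", "GeneAnnotation", "Cohort", "SegmentIndex",
    "read_mutations", "write_mutations", "read_segments", "write_segments",
    "read_profiles", "write_profiles", "read_clinical", "write_clinical",
    "read_annotations", "write_annotations", "validate_segments",
    "locate_segment", "assemble_cohort",
]
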