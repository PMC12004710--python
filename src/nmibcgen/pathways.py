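"""Integrative pathway-alteration analysis.

A gene counts as altered in a sample when it carries a driver mutation
or a copy-number alteration of sufficient amplitude: deep deletion
(total CN 0 within an event) or amplification (log2 ratio >= 1, about
twice the sample ploidy).  A pathway is altered when any member gene
is; alteration fractions are reported cohort-wide and per subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

AMPLIFICATION_LOG_RATIO = 1.0

logger = logging.getLogger(__name__)


def map_cna_to_genes(events, segments_by_sample: dict,
                     gene_coords: pd.DataFrame) -> dict:
    """Per-sample gene-level amp / deep-del calls from significant events.

    Deep deletion: the gene lies inside a deletion event and its local
    total copy number is 0.  Amplification: the gene lies inside an
    amplification event with log2 ratio >= 1.  Genes outside all events
    get no call."""
    calls: dict = {}
    genes = list(gene_coords.itertuples(index=False))
    for e in events:
        for g in genes:
            if g.chrom != e.chrom or g.end < e.start or g.start > e.end:
                continue
            sample_calls = calls.setdefault(e.sample_id, {})
            if e.is_deletion:
                cn = _local_cn(segments_by_sample.get(e.sample_id, []),
                               g.chrom, g.start, g.end)
                if cn == 0:
                    sample_calls[g.gene] = "deep-del"
            elif e.log_ratio >= AMPLIFICATION_LOG_RATIO:
                sample_calls.setdefault(g.gene, "amp")
    return calls


def _local_cn(segments, chrom: str, start: int, end: int) -> int | None:
    for s in segments:
        if s.chrom == chrom and s.start <= start and end <= s.end:
            return s.cn_total
    return None


@dataclass
class PathwayAlteration:
    pathway: str
    genes: list
    altered_samples: set
    fraction: float


def pathway_alteration_fraction(driver_genes_by_sample: dict,
                                cna_gene_calls: dict,
                                pathways: dict,
                                samples: list) -> list:
    """Altered fraction per pathway over ``samples``.

    A sample is altered for a pathway when >= 1 member gene has a driver
    mutation or a qualifying CNA; unknown genes in pathway definitions
    are ignored with a log message."""
    known_genes = set()
    for gs in driver_genes_by_sample.values():
        known_genes |= set(gs)
    for calls in cna_gene_calls.values():
        known_genes |= set(calls)
    out = []
    for name, genes in pathways.items():
        member_set = set(genes)
        unknown = member_set - known_genes
        if unknown:
            logger.info("pathway %s: %d genes never altered in cohort",
                        name, len(unknown))
        altered = set()
        for sample in samples:
            muts = driver_genes_by_sample.get(sample, set())
            cnas = set(cna_gene_calls.get(sample, {}))
            if member_set & (set(muts) | cnas):
                altered.add(sample)
        out.append(PathwayAlteration(
            pathway=name, genes=list(genes), altered_samples=altered,
            fraction=len(altered) / len(samples) if samples else 0.0))
    return out


def alteration_table(alterations: list, labels: pd.Series | None = None) -> pd.DataFrame:
    """Cohort-wide (and optionally per-subtype) altered fractions."""
    rows = []
    for alt in alterations:
        row = {"pathway": alt.pathway, "fraction": alt.fraction}
        if labels is not None:
            for subtype in sorted(labels.unique()):
                members = set(labels.index[labels == subtype])
                row[f"fraction_{subtype}"] = (
                    len(alt.altered_samples & members) / len(members)
                    if members else 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("pathway")


__all__ = [
    "map_cna_to_genes", "PathwayAlteration", "pathway_alteration_fraction",
    "alteration_table", "AMPLIFICATION_LOG_RATIO",
]
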