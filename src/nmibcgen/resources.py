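"""Bundled fixture tables: signature catalog, pathway sets, marker panels,
and the published two-cohort mutation-count comparison table.

The signature catalog shipped here is a *synthetic* stand-in: four
stylized 96-channel probability vectors with the qualitative shapes of
APOBEC C>T (SBS2), clock-like flat (SBS5), APOBEC C>G (SBS13) and
aristolochic-acid T>A (SBS22).  Real COSMIC v3.3 catalogs in the same
TSV layout (channel index column + one column per signature) are read
by the same function.
"""

from __future__ import annotations

from importlib import resources as _importlib_resources
from pathlib import Path

import pandas as pd

from nmibcgen._constants import CHANNELS_96

_DATA = _importlib_resources.files("nmibcgen") / "data"


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def read_signature_catalog(path) -> pd.DataFrame:
    """Read a 96-row signature catalog TSV; columns renormalized to sum 1."""
    cat = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS_96) - set(cat.index)
    if missing:
        raise ValueError(f"catalog missing {len(missing)} channels, e.g. {sorted(missing)[:3]}")
    cat = cat.loc[list(CHANNELS_96)].astype(float)
    if (cat.to_numpy() < 0).any():
        raise ValueError("catalog entries must be non-negative")
    totals = cat.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("catalog columns must have positive mass")
    return cat / totals


def bundled_catalog() -> pd.DataFrame:
    """The bundled synthetic SBS2/5/13/22-like catalog (96 x 4)."""
    return read_signature_catalog(_data_path("signature_catalog_synthetic.tsv"))


def read_pathways(path=None) -> dict:
    """Pathway definitions: name -> ordered list of member genes.

    Default is the bundled 16-set fixture (10 canonical oncogenic
    signaling pathways plus 6 urothelial-cancer pathway sets)."""
    path = _data_path("pathways.tsv") if path is None else path
    df = pd.read_csv(path, sep="\t")
    return {row.pathway: row.genes.split(";") for row in df.itertuples(index=False)}


def read_panels(path=None) -> dict:
    """Canonical bladder-cancer marker panels: name -> gene list."""
    path = _data_path("expression_panels.tsv") if path is None else path
    if not Path(path).exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    return {row.panel: row.genes.split(";") for row in df.itertuples(index=False)}


def table1_counts(path=None) -> pd.DataFrame:
    """Published per-gene mutant counts, combined European vs Chinese Ta-stage
    cohorts (n=127 vs n=58), as a DataFrame indexed by gene."""
    path = _data_path("table1_counts.tsv") if path is None else path
    df = pd.read_csv(path, sep="\t", index_col="gene")
    bad = df.index[(df.mutant_european > df.total_european)
                   | (df.mutant_chinese > df.total_chinese)]
    if len(bad):
        raise ValueError(f"mutant count exceeds total for {list(bad)}")
    return df


__all__ = [
    "read_signature_catalog", "bundled_catalog", "read_pathways",
    "read_panels", "table1_counts",
]
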