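"""End-to-end pipeline: load a cohort directory, run every analysis
stage in dependency order, write TSV/JSON outputs and a run manifest.

Stage order: io -> drivers / timing / instability / signatures ->
selection / CNA -> dependency -> subtyping -> expression / clinical /
pathways.  Every random stage takes its seed from the config; identical
config + seed re-runs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nmibcgen import __version__
from nmibcgen.cohort_io import (
    assemble_cohort, read_annotations, read_clinical, read_mutations,
    read_profiles, read_segments,
)
from nmibcgen.resources import bundled_catalog, read_panels, read_pathways

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "cohort_dir", "out_dir", "seed", "n_permutations", "stages",
    "cna_threshold", "broad_cutoff", "wgii_threshold", "min_event_frequency",
    "presence_min_count", "presence_min_fraction", "significance_q",
    "nmf_restarts", "nmf_k_range", "strict_timing",
}

_ALL_STAGES = ("drivers", "timing", "instability", "signatures", "selection",
               "cna", "dependency", "subtypes", "expression", "clinical",
               "pathways")


@dataclass
class PipelineConfig:
    """Run configuration; thresholds default to the published values."""

    cohort_dir: str
    out_dir: str
    seed: int
    n_permutations: int = 1000
    stages: tuple = _ALL_STAGES
    cna_threshold: float = 0.25
    broad_cutoff: float = 0.75
    wgii_threshold: float = 0.2
    min_event_frequency: float = 0.10
    presence_min_count: int = 10
    presence_min_fraction: float = 0.05
    significance_q: float = 0.1
    nmf_restarts: int = 20
    nmf_k_range: tuple = (2, 3, 4, 5, 6)
    strict_timing: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cohort_dir", "out_dir", "seed"):
            if key not in raw:
                raise ValueError(f"config missing required key {key!r}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "nmf_k_range" in raw:
            raw["nmf_k_range"] = tuple(raw["nmf_k_range"])
        return cls(**raw)

    def validate_inputs(self) -> None:
        base = Path(self.cohort_dir)
        required = ["mutations.tsv", "profiles.tsv"]
        if "timing" in self.stages or "instability" in self.stages:
            required.append("segments.tsv")
        missing = [f for f in required if not (base / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"cohort dir {base} missing required inputs: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _FastaReference:
    """Minimal 1-based inclusive fetch over a small FASTA file."""

    def __init__(self, path):
        self.sequences = {}
        name, parts = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name:
                        self.sequences[name] = "".join(parts)
                    name, parts = line[1:].split()[0], []
                else:
                    parts.append(line)
        if name:
            self.sequences[name] = "".join(parts)

    def fetch(self, chrom, start, end):
        seq = self.sequences.get(chrom, "")
        return seq[max(start - 1, 0):min(end, len(seq))]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dict."""
    config.validate_inputs()
    base = Path(config.cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "thresholds": {
            "cna_threshold": config.cna_threshold,
            "broad_cutoff": config.broad_cutoff,
            "wgii_threshold": config.wgii_threshold,
            "min_event_frequency": config.min_event_frequency,
            "presence_rule": [config.presence_min_count,
                              config.presence_min_fraction],
            "significance_q": config.significance_q,
        },
        "inputs": {}, "stages": [],
    }
    for f in sorted(base.glob("*.tsv")):
        manifest["inputs"][f.name] = _sha256(f)

    mutations = read_mutations(base / "mutations.tsv")
    segments = (read_segments(base / "segments.tsv")
                if (base / "segments.tsv").exists() else [])
    profiles = read_profiles(base / "profiles.tsv")
    clinical = (read_clinical(base / "clinical.tsv")
                if (base / "clinical.tsv").exists() else {})
    annotations = (read_annotations(base / "annotations.tsv")
                   if (base / "annotations.tsv").exists() else {})
    cohort = assemble_cohort(mutations, segments, profiles, clinical,
                             annotations)
    arms = (pd.read_csv(base / "arms.tsv", sep="\t")
            if (base / "arms.tsv").exists() else None)
    reference = (_FastaReference(base / "reference.fa")
                 if (base / "reference.fa").exists() else None)
    verdicts = (pd.read_csv(base / "verdicts.tsv", sep="\t",
                            dtype={"sample": str, "chrom": str})
                if (base / "verdicts.tsv").exists() else None)
    expression = (pd.read_csv(base / "expression.tsv", sep="\t", index_col=0)
                  if (base / "expression.tsv").exists() else None)

    state: dict = {"cohort": cohort, "arms": arms, "reference": reference}

    def stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.time()
        try:
            fn()
        except Exception:
            manifest["stages"].append({"name": name, "status": "failed"})
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
            logger.exception("stage %s failed; partial outputs preserved", name)
            raise
        # wall-clock goes to the log, not the manifest, so identical
        # runs produce byte-identical manifests
        manifest["stages"].append({"name": name, "status": "ok"})
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    def run_drivers():
        from nmibcgen.drivers import build_driver_catalog, driver_catalog_table
        catalog, per_sample, _ = build_driver_catalog(cohort, verdicts)
        state["driver_catalog"] = catalog
        state["driver_genes_by_sample"] = per_sample
        driver_catalog_table(catalog).to_csv(out / "driver_catalog.tsv",
                                             sep="\t", index=False)

    def run_timing():
        from nmibcgen.timing import (early_enrichment_test, time_cohort,
                                     timing_table)
        calls = time_cohort(cohort, strict_timing=config.strict_timing)
        state["timing_calls"] = calls
        table = timing_table(calls)
        table.to_csv(out / "timing.tsv", sep="\t", index=False)
        enrich = early_enrichment_test(calls, n_perm=config.n_permutations,
                                       seed=config.seed)
        enrich.to_csv(out / "early_enrichment.tsv", sep="\t", index=False)

    def run_instability():
        from nmibcgen.instability import profile_cohort
        table = profile_cohort(cohort, arms)
        state["instability"] = table
        table.to_csv(out / "instability.tsv", sep="\t")

    def run_signatures():
        from nmibcgen.signatures import (apobec_cohort, cohort_spectra,
                                         exposures_table, fit_exposures_em,
                                         presence_matrix)
        catalog = bundled_catalog()
        spectra = cohort_spectra(cohort, reference)
        spectra.to_csv(out / "spectra.tsv", sep="\t")
        exposures = [fit_exposures_em(spectra[s], catalog)
                     for s in spectra.columns]
        exposures_table(exposures).to_csv(out / "exposures.tsv", sep="\t",
                                          index=False)
        state["signature_presence"] = presence_matrix(exposures)
        if reference is not None:
            apobec = apobec_cohort(cohort, reference)
            apobec.to_csv(out / "apobec.tsv", sep="\t")
            state["apobec"] = apobec
        if "timing_calls" in state:
            timing_by_key = {c.mutation_key: c.timing
                             for c in state["timing_calls"]}
            for stratum in ("early", "late"):
                strat = cohort_spectra(cohort, reference, timing_by_key,
                                       stratum)
                strat.to_csv(out / f"spectra_{stratum}.tsv", sep="\t")

    def run_selection():
        from nmibcgen.selection import (gene_level_dnds,
                                        mutation_opportunities, pathway_dnds)
        genes_path = base / "genes.tsv"
        if not genes_path.exists() or reference is None:
            logger.info("selection skipped: no gene models / reference")
            return
        genes = pd.read_csv(genes_path, sep="\t")
        cds = {g.gene: reference.fetch(g.chrom, g.start, g.end)
               for g in genes.itertuples(index=False)}
        opp = mutation_opportunities(cds)
        state["opportunities"] = opp
        gene_level_dnds(cohort.mutations, opp).to_csv(
            out / "dnds_genes.tsv", sep="\t", index=False)
        pathway_dnds(cohort.mutations, opp, read_pathways()).to_csv(
            out / "dnds_pathways.tsv", sep="\t", index=False)
        if "timing_calls" in state:
            timing_by_key = {c.mutation_key: c.timing
                             for c in state["timing_calls"]}
            for stratum in ("early", "late"):
                muts = [m for m in cohort.mutations
                        if timing_by_key.get(m.key) == stratum]
                gene_level_dnds(muts, opp, stratum=stratum).to_csv(
                    out / f"dnds_genes_{stratum}.tsv", sep="\t", index=False)

    def run_cna():
        from nmibcgen.cna import (chr9_codeletion_flag, cohort_events,
                                  event_table, events_by_sample,
                                  recurrence_significance)
        events = cohort_events(cohort, arms, threshold=config.cna_threshold)
        state["cna_events"] = events
        event_table(events).to_csv(out / "cna_events.tsv", sep="\t",
                                   index=False)
        if events:
            for direction in ("del", "amp"):
                if any(e.kind.endswith(direction) for e in events):
                    sig = recurrence_significance(
                        events, arms, n_perm=config.n_permutations,
                        seed=config.seed, direction=direction)
                    sig.to_csv(out / f"cna_recurrence_{direction}.tsv",
                               sep="\t", index=False)
        flags = chr9_codeletion_flag(events_by_sample(events))
        state["chr9_codeletion"] = flags

    def run_dependency():
        from nmibcgen.dependency import assemble_event_matrix, test_pairs
        instab = state.get("instability")
        if state.get("apobec") is not None and instab is not None:
            instab = instab.join(state["apobec"][["group"]])
        matrix = assemble_event_matrix(
            state.get("driver_genes_by_sample"), state.get("cna_events"),
            state.get("signature_presence"), instab,
            samples=cohort.sample_ids,
            min_frequency=config.min_event_frequency)
        state["event_matrix"] = matrix
        matrix.to_csv(out / "event_matrix.tsv", sep="\t")
        pairs = test_pairs(matrix, n_perm=config.n_permutations,
                           seed=config.seed)
        pairs.to_csv(out / "dependency_pairs.tsv", sep="\t", index=False)

    def run_subtypes():
        from nmibcgen.subtypes import (characterize_subtypes, fit_subtypes,
                                       name_subtypes)
        matrix = state.get("event_matrix")
        if matrix is None or matrix.shape[1] < 2:
            logger.info("subtypes skipped: no event matrix")
            return
        k_max = min(max(config.nmf_k_range), matrix.shape[0] - 1, 8)
        k_range = tuple(k for k in config.nmf_k_range if 2 <= k <= k_max)
        model = fit_subtypes(matrix, k_range=k_range,
                             restarts=config.nmf_restarts, seed=config.seed)
        tmb = state["instability"]["tmb"] if "instability" in state else None
        model.enrichment = characterize_subtypes(model.labels, matrix, tmb)
        names = name_subtypes(model.enrichment)
        labels = model.labels.map(names)
        state["subtype_labels"] = labels
        labels.rename("subtype").to_csv(out / "subtypes.tsv", sep="\t")
        model.basis.to_csv(out / "nmf_basis.tsv", sep="\t")
        model.coefficients.to_csv(out / "nmf_coefficients.tsv", sep="\t")
        model.enrichment.to_csv(out / "subtype_enrichment.tsv", sep="\t",
                                index=False)
        diag = {"k": model.k,
                "cophenetic": {d.k: d.cophenetic for d in model.diagnostics}}
        with open(out / "subtype_diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=2, sort_keys=True)

    def run_expression():
        from nmibcgen.expression import (panel_scores, rank_subtype_genes,
                                         score_subtypes)
        if expression is None:
            logger.info("expression skipped: no counts matrix")
            return
        labels = state.get("subtype_labels")
        if labels is None:
            return
        labels = labels[labels.index.intersection(expression.columns)]
        gene_sets = rank_subtype_genes(expression[labels.index], labels)
        scores = score_subtypes(expression, gene_sets)
        scores.to_csv(out / "subtype_scores.tsv", sep="\t")
        panel, comparisons = panel_scores(expression, read_panels(), labels)
        panel.to_csv(out / "panel_scores.tsv", sep="\t")
        if comparisons is not None:
            comparisons.to_csv(out / "panel_comparisons.tsv", sep="\t",
                               index=False)

    def run_clinical():
        from nmibcgen.clinical import (cox_regression, hazard_ratio_table)
        if not cohort.clinical:
            return
        rows = []
        for sample_id, rec in cohort.clinical.items():
            instab = state.get("instability")
            rows.append({
                "sample": sample_id, "rfs_months": rec.rfs_months,
                "event": rec.event,
                "cin": (float(instab.loc[sample_id, "cin"])
                        if instab is not None else 0.0),
                "wgii": (float(instab.loc[sample_id, "wgii"])
                         if instab is not None else 0.0),
            })
        df = pd.DataFrame(rows).set_index("sample")
        if df.event.sum() > 0:
            model = cox_regression(df, covariates=["cin"])
            hazard_ratio_table(model).to_csv(out / "cox_cin.tsv", sep="\t")

    def run_pathways():
        from nmibcgen.cna import events_by_sample
        from nmibcgen.pathways import (alteration_table, map_cna_to_genes,
                                       pathway_alteration_fraction)
        genes_path = base / "genes.tsv"
        if not genes_path.exists():
            return
        gene_coords = pd.read_csv(genes_path, sep="\t")
        segments_by_sample = {s: cohort.segments_of(s)
                              for s in cohort.sample_ids}
        cna_calls = map_cna_to_genes(state.get("cna_events", []),
                                     segments_by_sample, gene_coords)
        alterations = pathway_alteration_fraction(
            state.get("driver_genes_by_sample", {}), cna_calls,
            read_pathways(), cohort.sample_ids)
        alteration_table(alterations, state.get("subtype_labels")).to_csv(
            out / "pathway_alterations.tsv", sep="\t")

    stage("drivers", run_drivers)
    stage("timing", run_timing)
    stage("instability", run_instability)
    stage("signatures", run_signatures)
    stage("selection", run_selection)
    stage("cna", run_cna)
    stage("dependency", run_dependency)
    stage("subtypes", run_subtypes)
    stage("expression", run_expression)
    stage("clinical", run_clinical)
    stage("pathways", run_pathways)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


__all__ = ["PipelineConfig", "run_pipeline"]
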