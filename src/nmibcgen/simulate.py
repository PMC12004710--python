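"""Synthetic NMIBC cohort generator with full ground truth.

Emulates the statistical structure the downstream analyses assume:

* a toy reference genome (10 chromosomes, p/q arms, ~60 coding genes);
* four sample archetypes mirroring the genomic subtypes of NMIBC —
  AA-like (hypermutated, SBS22-dominated), FGFR3/HRAS (flat copy
  number), FGFR3 & chr9Del (9p+9q loss), and genome-instability
  (whole-genome doubled, many CNAs);
* read counts drawn binomially around the expected variant allele
  fraction  VAF = m * rho * CCF / (rho * CNt + 2 (1 - rho))  with
  negative-binomial sequencing depth;
* trinucleotide contexts sampled from per-archetype signature mixtures
  against the toy reference;
* negative-binomial expression counts with archetype-linked marker
  panels, and exponential recurrence times with configured log-hazards.

Every emitted mutation and sample has exactly one ground-truth row, so
recovery of CCF, clonality, timing, signatures, wGD and subtype labels
can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nmibcgen._constants import CHANNELS_96, CODON_TABLE
from nmibcgen.cohort_io import (
    CNSegment,
    ClinicalRecord,
    Cohort,
    GeneAnnotation,
    MutationRecord,
    SampleProfile,
    assemble_cohort,
    write_annotations,
    write_clinical,
    write_mutations,
    write_profiles,
    write_segments,
)
from nmibcgen.resources import bundled_catalog

# ---------------------------------------------------------------------------
# toy reference genome

_GENE_NAMES = [
    # published-comparison and significantly mutated genes first
    "ARID1A", "CREBBP", "EP300", "FGFR3", "KDM6A", "KMT2D", "PIK3CA",
    "RBM10", "STAG2", "TP53", "BAP1", "CDKN1A", "HRAS", "ZFP36L1", "LATS1",
    # pathway members
    "CDKN2A", "TSC1", "ERCC2", "STAG1", "ATM", "BRCA1", "BRCA2", "RAD21",
    "RAD50", "CHEK1", "SMC1A", "SMC3", "NFE2L2", "KEAP1", "CUL3", "TXNIP",
    "SF3B1", "U2AF1", "CDK12", "KMT2C", "ASXL1", "ASXL2", "SETD2",
    "ARID1B", "ARID2", "BRIP1", "KRAS", "NRAS", "ERBB2", "ERBB3", "EGFR",
    "BRAF", "NF1", "PTEN", "AKT1", "TSC2", "MTOR", "RB1", "CCND1", "E2F3",
    "MDM2", "NOTCH1", "FBXW7", "MYC", "FAT1", "APC", "CTNNB1", "SMAD4",
]

# forced placements so arm-level events hit the expected genes
_FORCED_CHROM = {"CDKN2A": ("chr9", "p"), "TSC1": ("chr9", "q"),
                 "FGFR3": ("chr4", "p"), "HRAS": ("chr1", "p"),
                 "TP53": ("chr7", "p")}

_GENE_CDS_LEN = 1200  # 400 codons, divisible by 3
_N_CHROMS = 10
_ARM_SPLIT = 0.4  # p arm covers the first 40% of each chromosome


class ToyGenome:
    """Deterministic toy reference with arms, genes and context indexes."""

    def __init__(self, sequences: dict, arms: pd.DataFrame, genes: pd.DataFrame):
        self.sequences = sequences
        self.arms = arms
        self.genes = genes
        self._gene_by_name = {g.gene: g for g in genes.itertuples(index=False)}
        self._context_positions: dict | None = None

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive subsequence, clipped to the chromosome."""
        seq = self.sequences[chrom]
        return seq[max(start - 1, 0):min(end, len(seq))]

    def cds_of(self, gene: str) -> str:
        g = self._gene_by_name[gene]
        return self.fetch(g.chrom, g.start, g.end)

    def gene_at(self, chrom: str, pos: int) -> str | None:
        for g in self.genes.itertuples(index=False):
            if g.chrom == chrom and g.start <= pos <= g.end:
                return g.gene
        return None

    def context_index(self) -> dict:
        """Map +strand pyrimidine-centred trinucleotides inside gene CDS
        to arrays of (chrom, pos) candidate mutation sites."""
        if self._context_positions is None:
            index: dict = {}
            for g in self.genes.itertuples(index=False):
                seq = self.sequences[g.chrom]
                for pos in range(g.start, g.end + 1):
                    base = seq[pos - 1]
                    if base not in "CT":
                        continue
                    tri = seq[pos - 2:pos + 1]
                    if len(tri) == 3:
                        index.setdefault(tri, []).append((g.chrom, pos))
            self._context_positions = {k: np.array(v, dtype=object)
                                       for k, v in index.items()}
        return self._context_positions

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


def simulate_reference(length: int = 2_000_000, seed: int = 0) -> ToyGenome:
    """Generate a deterministic toy genome of total ``length`` bases.

    Ten chromosomes of equal size, each split into a p arm (first 40%)
    and a q arm; ~60 non-overlapping 1.2 kb coding genes placed across
    the chromosomes (CDKN2A on 9p, TSC1 on 9q, FGFR3 on 4p, HRAS on 1p,
    TP53 on 7p).  Base composition gives GC ~= 0.4."""
    if length < 10_000:
        raise ValueError("reference length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    chrom_len = length // _N_CHROMS
    sequences = {}
    arm_rows = []
    for i in range(_N_CHROMS):
        chrom = f"chr{i + 1}"
        bases = rng.choice(list("ACGT"), size=chrom_len, p=[0.3, 0.2, 0.2, 0.3])
        sequences[chrom] = "".join(bases)
        split = int(chrom_len * _ARM_SPLIT)
        arm_rows.append((chrom, 1, split, f"{i + 1}p"))
        arm_rows.append((chrom, split + 1, chrom_len, f"{i + 1}q"))
    # leftover bases (length % 10) are dropped: arms partition each chromosome
    arms = pd.DataFrame(arm_rows, columns=["chrom", "start", "end", "arm"])

    # place genes evenly; forced genes go to specific arms
    gene_rows = []
    per_chrom_cursor = {f"chr{i + 1}": 2_000 for i in range(_N_CHROMS)}
    free = [g for g in _GENE_NAMES if g not in _FORCED_CHROM]
    for gene, (chrom, arm) in _FORCED_CHROM.items():
        offset = 5_000 if arm == "p" else int(chrom_len * _ARM_SPLIT) + 5_000
        start = offset + 2_000 * list(_FORCED_CHROM).index(gene)
        gene_rows.append((gene, chrom, start, start + _GENE_CDS_LEN - 1))
    for i, gene in enumerate(free):
        chrom = f"chr{(i % _N_CHROMS) + 1}"
        start = per_chrom_cursor[chrom] + 20_000
        per_chrom_cursor[chrom] = start + _GENE_CDS_LEN
        gene_rows.append((gene, chrom, start, start + _GENE_CDS_LEN - 1))
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])
    # sanity: no overlaps within a chromosome
    for chrom, grp in genes.groupby("chrom"):
        grp = grp.sort_values("start")
        if (grp.start.values[1:] <= grp.end.values[:-1]).any():
            raise AssertionError("gene placement produced overlaps")
    return ToyGenome(sequences, arms, genes)


def classify_substitution(genome: ToyGenome, gene: str, pos: int,
                          ref: str, alt: str) -> str:
    """Consequence of a single-base change inside a gene CDS (+ strand)."""
    g = genome._gene_by_name[gene]
    offset = pos - g.start
    codon_idx, within = divmod(offset, 3)
    codon = genome.cds_of(gene)[3 * codon_idx:3 * codon_idx + 3]
    if codon[within] != ref:
        raise ValueError("reference mismatch in consequence classification")
    alt_codon = codon[:within] + alt + codon[within + 1:]
    aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[alt_codon]
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ArchetypeSpec:
    """Parameters of one genomic-subtype archetype."""

    name: str
    n_samples: int = 10
    burden_per_mb: float = 3.0          # somatic SNVs per Mb (all classes)
    signature_weights: dict = field(default_factory=dict)
    cn_profile: str = "flat"            # flat | chr9del | wgd
    hotspot_oncogenes: dict = field(default_factory=dict)   # gene -> prob
    hotspot_tsgs: dict = field(default_factory=dict)        # gene -> prob
    subclone_fraction: float = 0.25
    log_hr: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.signature_weights.values())
        if self.signature_weights and not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"signature weights must sum to 1, got {total}")
        if any(w < 0 for w in self.signature_weights.values()):
            raise ValueError("signature weights must be non-negative")
        if self.cn_profile not in {"flat", "chr9del", "wgd"}:
            raise ValueError(f"unknown cn_profile {self.cn_profile!r}")


def default_archetypes(n_per: int = 10) -> tuple:
    """The four study archetypes; AA-like burden is >= 5x FGFR3/HRAS."""
    return (
        ArchetypeSpec(
            name="FGFR3/HRAS", n_samples=n_per, burden_per_mb=2.0,
            signature_weights={"SBS5": 0.75, "SBS2": 0.15, "SBS13": 0.10},
            cn_profile="flat",
            hotspot_oncogenes={"FGFR3": 0.75, "HRAS": 0.5, "PIK3CA": 0.3},
            hotspot_tsgs={"KDM6A": 0.3},
            log_hr=0.0,
        ),
        ArchetypeSpec(
            name="FGFR3&chr9Del", n_samples=n_per, burden_per_mb=3.0,
            signature_weights={"SBS5": 0.45, "SBS2": 0.33, "SBS13": 0.22},
            cn_profile="chr9del",
            hotspot_oncogenes={"FGFR3": 0.9, "PIK3CA": 0.3},
            hotspot_tsgs={"KDM6A": 0.3, "STAG2": 0.3},
            log_hr=0.1,
        ),
        ArchetypeSpec(
            name="GI", n_samples=n_per, burden_per_mb=5.0,
            signature_weights={"SBS5": 0.4, "SBS2": 0.35, "SBS13": 0.25},
            cn_profile="wgd",
            hotspot_oncogenes={"ERBB2": 0.3},
            hotspot_tsgs={"TP53": 0.8, "RB1": 0.3},
            log_hr=0.5,
        ),
        ArchetypeSpec(
            name="AA-like", n_samples=n_per, burden_per_mb=16.0,
            signature_weights={"SBS22": 0.7, "SBS5": 0.15, "SBS2": 0.1,
                               "SBS13": 0.05},
            cn_profile="flat",
            hotspot_oncogenes={"FGFR3": 0.3},
            hotspot_tsgs={"KMT2D": 0.7, "KDM6A": 0.6, "CREBBP": 0.5,
                          "TP53": 0.4},
            log_hr=0.6,
        ),
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.  ``seed`` is mandatory."""

    seed: int
    archetypes: tuple = ()
    genome_length: int = 2_000_000
    depth_mean: float = 150.0
    depth_dispersion: float = 10.0      # NB size parameter (WES overdispersion)
    purity_range: tuple = (0.3, 0.9)
    exome_size_mb: float = 30.0
    subclone_ccf_range: tuple = (0.15, 0.6)
    early_fraction: float = 0.55        # clonal mutations predating a gain
    baseline_hazard: float = math.log(2) / 24.0   # per month; median RFS 24 mo
    log_hr_cin: float = math.log(2)
    followup_range: tuple = (4.0, 73.0)
    n_filler_genes: int = 240
    expression_dispersion: float = 0.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.archetypes:
            self.archetypes = default_archetypes()


@dataclass
class TruthTables:
    """Ground truth: one row per emitted mutation and per sample."""

    mutations: pd.DataFrame
    samples: pd.DataFrame


@dataclass
class SimulatedCohort:
    cohort: Cohort
    truth: TruthTables
    expression: pd.DataFrame            # genes x samples raw counts
    verdicts: pd.DataFrame              # per-variant predictor verdicts
    genome: ToyGenome
    config: SimulationConfig


# ---------------------------------------------------------------------------
# copy-number archetypes

def _segments_for(archetype: ArchetypeSpec, genome: ToyGenome, sample_id: str,
                  rng: np.random.Generator) -> list:
    segs = []
    arms = genome.arms
    if archetype.cn_profile == "flat":
        for chrom, length in genome.chrom_lengths.items():
            segs.append(CNSegment(sample_id, chrom, 1, length, 1, 1))
    elif archetype.cn_profile == "chr9del":
        # arm-level 9p+9q loss with a nested homozygous 9p21.3-like
        # deletion spanning CDKN2A, the hallmark focal event
        cdkn2a = genome._gene_by_name["CDKN2A"]
        for chrom, length in genome.chrom_lengths.items():
            if chrom == "chr9":
                lo = max(cdkn2a.start - 1000, 1)
                hi = min(cdkn2a.end + 1000, length)
                segs.append(CNSegment(sample_id, chrom, 1, lo - 1, 1, 0))
                segs.append(CNSegment(sample_id, chrom, lo, hi, 0, 0))
                segs.append(CNSegment(sample_id, chrom, hi + 1, length, 1, 0))
            else:
                segs.append(CNSegment(sample_id, chrom, 1, length, 1, 1))
    else:
        # wgd: tetraploid baseline with arm-level aberrations concentrated
        # at recurrent hotspot arms (losses incl. chr9, gains on 8q-like
        # arms), plus a low random background rate
        loss_hotspots = {"9p": 0.6, "9q": 0.6, "3p": 0.8, "8p": 0.7}
        gain_hotspots = {"8q": 0.8, "10q": 0.7, "1q": 0.6}
        states = {}
        for arm in arms.itertuples(index=False):
            major, minor = 2, 2
            if rng.random() < loss_hotspots.get(arm.arm, 0.0):
                major, minor = 2, 1
            elif rng.random() < gain_hotspots.get(arm.arm, 0.0):
                major, minor = 4, 2
            elif rng.random() < 0.12:
                major, minor = (3, 2) if rng.random() < 0.5 else (2, 1)
            states[arm.arm] = (major, minor)
        # the archetype is CIN-positive by definition: aberrate further
        # random arms until >= 25% of the genome deviates from tetraploid
        arm_lengths = {a.arm: a.end - a.start + 1
                       for a in arms.itertuples(index=False)}
        total = sum(arm_lengths.values())

        def aberrant_fraction():
            return sum(arm_lengths[a] for a, s in states.items()
                       if sum(s) != 4) / total

        normal_arms = [a for a, s in states.items() if sum(s) == 4]
        while aberrant_fraction() < 0.25 and normal_arms:
            arm = normal_arms.pop(int(rng.integers(len(normal_arms))))
            states[arm] = (2, 1) if rng.random() < 0.5 else (3, 2)
        for arm in arms.itertuples(index=False):
            major, minor = states[arm.arm]
            segs.append(CNSegment(sample_id, arm.chrom, arm.start, arm.end,
                                  major, minor))
    return segs


def _ploidy(segments: list) -> float:
    lengths = np.array([s.length for s in segments], dtype=float)
    cn = np.array([s.cn_total for s in segments], dtype=float)
    return float((lengths * cn).sum() / lengths.sum())


# ---------------------------------------------------------------------------
# per-sample simulation

def expected_vaf(m: int, purity: float, ccf: float, cn_total: int) -> float:
    """VAF implied by multiplicity, purity, CCF and local total copy number."""
    return m * purity * ccf / (purity * cn_total + 2.0 * (1.0 - purity))


def _draw_depths(rng, n, mean, dispersion):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def simulate_sample(archetype: ArchetypeSpec, config: SimulationConfig,
                    genome: ToyGenome, catalog: pd.DataFrame,
                    sample_id: str, rng: np.random.Generator):
    """Simulate one sample: mutations, segments, profile and truth rows."""
    purity = rng.uniform(*config.purity_range)
    segments = _segments_for(archetype, genome, sample_id, rng)
    ploidy = _ploidy(segments)
    seg_lookup = {s.chrom: sorted([t for t in segments if t.chrom == s.chrom],
                                  key=lambda t: t.start) for s in segments}

    def segment_at(chrom, pos):
        for s in seg_lookup.get(chrom, []):
            if s.start <= pos <= s.end:
                return s
        return None

    sig_names = list(archetype.signature_weights)
    weights = np.array([archetype.signature_weights[s] for s in sig_names])
    ctx_index = genome.context_index()
    subclone_ccf = rng.uniform(*config.subclone_ccf_range)

    n_mut = rng.poisson(archetype.burden_per_mb * config.exome_size_mb)
    mutations, truth_rows = [], []
    seen = set()

    def emit(chrom, pos, ref, alt, context3, gene, consequence, clonal,
             ccf, m, signature, forced_driver=False):
        seg = segment_at(chrom, pos)
        cn_total = seg.cn_total if seg else 2
        if cn_total == 0:
            return False
        vaf = expected_vaf(m, purity, ccf, cn_total)
        depth = int(_draw_depths(rng, 1, config.depth_mean,
                                 config.depth_dispersion)[0])
        if depth == 0:
            return False
        t_alt = int(rng.binomial(depth, min(vaf, 1.0)))
        if t_alt == 0:
            return False
        key = (chrom, pos)
        if key in seen:
            return False
        seen.add(key)
        mutations.append(MutationRecord(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=gene or "", consequence=consequence, t_alt=t_alt,
            t_ref=depth - t_alt, context3=context3,
        ))
        major = seg.major if seg else 1
        if not clonal:
            timing = "late"
        elif major >= 2:
            timing = "early" if m > 1 else "late"
        else:
            timing = "early"
        truth_rows.append({
            "sample": sample_id, "chrom": chrom, "pos": pos, "ref": ref,
            "alt": alt, "gene": gene or "", "ccf": ccf,
            "clonality": "clonal" if clonal else "subclonal",
            "multiplicity": m, "signature": signature, "timing": timing,
            "driver": forced_driver,
        })
        return True

    # passenger mutations from the signature mixture
    for _ in range(n_mut):
        signature = sig_names[rng.choice(len(sig_names), p=weights)]
        channel = CHANNELS_96[rng.choice(96, p=catalog[signature].to_numpy())]
        context = channel[0] + channel[2] + channel[6]
        alt = channel[4]
        sites = ctx_index.get(context)
        if sites is None or not len(sites):
            continue
        chrom, pos = sites[rng.integers(len(sites))]
        ref = context[1]
        gene = genome.gene_at(chrom, pos)
        consequence = (classify_substitution(genome, gene, pos, ref, alt)
                       if gene else "other")
        clonal = rng.random() >= archetype.subclone_fraction
        ccf = 1.0 if clonal else subclone_ccf
        seg = segment_at(chrom, pos)
        major = seg.major if seg else 1
        if clonal and major >= 2 and rng.random() < config.early_fraction:
            m = major
        else:
            m = 1
        emit(chrom, pos, ref, alt, context, gene, consequence, clonal,
             ccf, m, signature)

    # archetype hotspot drivers (clonal, multiplicity 1)
    driver_variants = []
    forced = []
    for gene, prob in archetype.hotspot_oncogenes.items():
        if rng.random() < prob:
            forced.append((gene, "missense"))
    for gene, prob in archetype.hotspot_tsgs.items():
        if rng.random() < prob:
            forced.append((gene, "nonsense"))
    if archetype.name.startswith("FGFR3") and not any(
            g in {"FGFR3", "HRAS"} for g, _ in forced):
        forced.append(("FGFR3", "missense"))
    for gene, kind in forced:
        chrom, pos, ref, alt, context = _hotspot_site(genome, gene, kind)
        if emit(chrom, pos, ref, alt, context, gene, kind, clonal=True,
                ccf=1.0, m=1, signature="driver", forced_driver=True):
            driver_variants.append((gene, chrom, pos, ref, alt, kind))

    profile = SampleProfile(sample_id=sample_id, purity=round(purity, 4),
                            ploidy=round(ploidy, 4),
                            exome_size_mb=config.exome_size_mb)
    truth_sample = {
        "sample": sample_id, "archetype": archetype.name,
        "purity": purity, "ploidy": ploidy,
        "wgd": archetype.cn_profile == "wgd",
        "subclone_ccf": subclone_ccf,
        "log_hr": archetype.log_hr,
    }
    for sig in catalog.columns:
        truth_sample[f"w_{sig}"] = archetype.signature_weights.get(sig, 0.0)
    return mutations, segments, profile, truth_rows, truth_sample, driver_variants


def _hotspot_site(genome: ToyGenome, gene: str, kind: str):
    """A deterministic codon site in ``gene`` yielding the requested
    consequence (first match scanning the CDS)."""
    g = genome._gene_by_name[gene]
    seq = genome.sequences[g.chrom]
    for pos in range(g.start + 3, g.end - 2):
        ref = seq[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            csq = classify_substitution(genome, gene, pos, ref, alt)
            if csq == kind:
                return g.chrom, pos, ref, alt, seq[pos - 2:pos + 1]
    raise RuntimeError(f"no {kind} site found in {gene}")


# ---------------------------------------------------------------------------
# cohort-level simulation

def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort, its ground truth, expression and clinical data."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_reference(config.genome_length,
                                seed=int(rng.integers(2**31)))
    catalog = bundled_catalog()

    all_mut, all_seg = [], []
    profiles, truth_mut, truth_samples = {}, [], []
    driver_rows = []
    sample_archetype = {}
    idx = 0
    for archetype in config.archetypes:
        for _ in range(archetype.n_samples):
            idx += 1
            sample_id = f"S{idx:03d}"
            (muts, segs, profile, t_rows, t_sample,
             drivers) = simulate_sample(archetype, config, genome, catalog,
                                        sample_id, rng)
            all_mut.extend(muts)
            all_seg.extend(segs)
            profiles[sample_id] = profile
            truth_mut.extend(t_rows)
            truth_samples.append(t_sample)
            sample_archetype[sample_id] = archetype.name
            for gene, chrom, pos, ref, alt, kind in drivers:
                driver_rows.append((sample_id, gene, chrom, pos, ref, alt, kind))

    annotations = _build_annotations(driver_rows)
    verdicts = _build_verdicts(all_mut, driver_rows, rng)
    clinical = _simulate_clinical(truth_samples, sample_archetype, config, rng)
    expression = _simulate_expression(sample_archetype, config, rng)

    cohort = assemble_cohort(all_mut, all_seg, profiles, clinical, annotations)
    truth = TruthTables(
        mutations=pd.DataFrame(truth_mut),
        samples=pd.DataFrame(truth_samples),
    )
    return SimulatedCohort(cohort=cohort, truth=truth, expression=expression,
                           verdicts=verdicts, genome=genome, config=config)


def _build_annotations(driver_rows) -> dict:
    """Gene annotations: hotspot oncogene variants become known-oncogenic;
    TSG hotspot genes are annotated as tumor suppressors."""
    tsg_genes = {"TP53", "RB1", "KDM6A", "KMT2D", "CREBBP", "STAG2", "CDKN2A",
                 "ARID1A", "EP300", "RBM10", "BAP1", "LATS1", "PTEN", "TSC1"}
    onco_genes = {"FGFR3", "HRAS", "PIK3CA", "ERBB2", "KRAS", "NRAS", "BRAF",
                  "MYC", "CCND1", "E2F3", "MDM2", "AKT1"}
    onco_variants: dict = {g: set() for g in onco_genes}
    for _, gene, chrom, pos, ref, alt, kind in driver_rows:
        if gene in onco_genes:
            onco_variants[gene].add(f"{gene}:{chrom}:{pos}:{ref}>{alt}")
    annotations = {}
    for gene in sorted(tsg_genes | onco_genes):
        if gene in tsg_genes and gene in onco_genes:
            role = "both"
        elif gene in tsg_genes:
            role = "TSG"
        else:
            role = "oncogene"
        annotations[gene] = GeneAnnotation(
            gene=gene, role=role,
            oncogenic_variants=frozenset(onco_variants.get(gene, ())),
            cosmic_match_counts={},
        )
    return annotations


def _build_verdicts(mutations, driver_rows, rng) -> pd.DataFrame:
    """Per-variant SIFT/PolyPhen/MutationTaster-style verdict table.

    Hotspot driver variants in TSGs get concordant deleterious verdicts;
    passenger missense variants get mostly tolerated calls with occasional
    discordance."""
    driver_keys = {(s, c, p) for s, _, c, p, *_ in driver_rows}
    rows = []
    for m in mutations:
        if m.consequence not in {"missense", "nonsense"}:
            continue
        if (m.sample_id, m.chrom, m.pos) in driver_keys:
            verdict = ["deleterious"] * 3
        else:
            verdict = ["deleterious" if rng.random() < 0.15 else "tolerated"
                       for _ in range(3)]
        rows.append((m.sample_id, m.chrom, m.pos, m.ref, m.alt, *verdict))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                       "sift", "polyphen", "mutationtaster"])


def _simulate_clinical(truth_samples, sample_archetype, config, rng) -> dict:
    """Exponential recurrence model with CIN and archetype log-hazards."""
    clinical = {}
    stage_probs = {"FGFR3/HRAS": [0.85, 0.13, 0.02],
                   "FGFR3&chr9Del": [0.8, 0.18, 0.02],
                   "GI": [0.5, 0.48, 0.02],
                   "AA-like": [0.5, 0.48, 0.02]}
    for t in truth_samples:
        sample_id = t["sample"]
        archetype = sample_archetype[sample_id]
        cin_true = t["wgd"]  # wGD archetype is the CIN-positive class
        hazard = config.baseline_hazard * math.exp(
            config.log_hr_cin * cin_true + t["log_hr"])
        event_time = rng.exponential(1.0 / hazard)
        censor_time = rng.uniform(*config.followup_range)
        event = int(event_time <= censor_time)
        rfs = min(event_time, censor_time)
        probs = stage_probs.get(archetype, [0.7, 0.28, 0.02])
        stage = rng.choice(["Ta", "T1", "Tis"], p=probs)
        grade = rng.choice(["HG", "LG", "PUNLMP"],
                           p=[0.6, 0.3, 0.1] if archetype in ("GI", "AA-like")
                           else [0.3, 0.5, 0.2])
        therapy = rng.choice(["chemo", "BCG", "none"], p=[0.7, 0.17, 0.13])
        clinical[sample_id] = ClinicalRecord(
            sample_id=sample_id, stage=str(stage), grade=str(grade),
            therapy=str(therapy), rfs_months=round(max(rfs, 0.1), 2),
            event=event)
    return clinical


def _expression_gene_panel(config) -> list:
    from nmibcgen.resources import read_panels
    panel_genes = sorted({g for genes in read_panels().values() for g in genes})
    filler = [f"G{i:04d}" for i in range(1, config.n_filler_genes + 1)]
    extra = ["APOBEC3B", "APOBEC3A"]
    return sorted(set(panel_genes) | set(_GENE_NAMES) | set(filler) | set(extra))


def _archetype_lfc(config) -> dict:
    """Planted log2 fold changes per archetype (vs the rest)."""
    from nmibcgen.resources import read_panels
    panels = read_panels()
    lfc: dict = {"AA-like": {}, "GI": {}, "FGFR3/HRAS": {}, "FGFR3&chr9Del": {}}
    high_in_aa_gi = ["p53", "stroma", "inflammation", "claudin_low"]
    for panel in high_in_aa_gi:
        for g in panels[panel]:
            lfc["AA-like"][g] = 1.5
            lfc["GI"][g] = 1.5
    for panel in ["immune_checkpoint", "interferon", "bcg_response"]:
        for g in panels[panel]:
            lfc["AA-like"][g] = 1.5
            lfc["GI"][g] = 1.0
    # APOBEC3B gradient across FGFR3/HRAS -> chr9Del -> GI
    lfc["FGFR3/HRAS"]["APOBEC3B"] = -1.0
    lfc["GI"]["APOBEC3B"] = 1.5
    lfc["FGFR3&chr9Del"]["APOBEC3B"] = 0.5
    # archetype-private filler markers (20 each) for DE-recovery tests
    for i, name in enumerate(lfc):
        for j in range(20):
            lfc[name][f"G{(i * 20 + j + 1):04d}"] = 2.0
    return lfc


def planted_up_genes(archetype: str, config: SimulationConfig | None = None) -> list:
    """Genes planted as upregulated (lfc > 0) in the given archetype."""
    cfg = config or SimulationConfig(seed=0)
    return sorted(g for g, v in _archetype_lfc(cfg).get(archetype, {}).items()
                  if v > 0)


def _simulate_expression(sample_archetype, config, rng) -> pd.DataFrame:
    genes = _expression_gene_panel(config)
    lfc_map = _archetype_lfc(config)
    from nmibcgen.resources import read_panels
    panels = read_panels()
    base = pd.Series(np.exp(rng.normal(4.0, 1.0, size=len(genes))), index=genes)
    # luminal markers expressed above basal markers cohort-wide
    for g in panels["luminal"]:
        base[g] = base[g] * 4.0
    samples = sorted(sample_archetype)
    disp = config.expression_dispersion
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        archetype = sample_archetype[sample]
        lfc = lfc_map.get(archetype, {})
        libsize = rng.uniform(0.7, 1.3)
        mean = base.to_numpy() * libsize
        fold = np.array([2.0 ** lfc.get(g, 0.0) for g in genes])
        mu = np.maximum(mean * fold, 1e-3)
        n_param = 1.0 / disp
        p = n_param / (n_param + mu)
        counts[:, j] = rng.negative_binomial(n_param, p)
    return pd.DataFrame(counts, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# emission to disk (the exact formats cohort_io reads)

def write_simulated_cohort(sim: SimulatedCohort, outdir) -> dict:
    """Write every table of a simulated cohort; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("mutations", "mutations.tsv"), ("segments", "segments.tsv"),
        ("profiles", "profiles.tsv"), ("clinical", "clinical.tsv"),
        ("annotations", "annotations.tsv"), ("verdicts", "verdicts.tsv"),
        ("expression", "expression.tsv"), ("truth_mutations", "truth_mutations.tsv"),
        ("truth_samples", "truth_samples.tsv"), ("reference", "reference.fa"),
        ("arms", "arms.tsv"), ("genes", "genes.tsv"),
    ]}
    write_mutations(sim.cohort.mutations, paths["mutations"])
    write_segments(sim.cohort.segments, paths["segments"])
    write_profiles(sim.cohort.profiles, paths["profiles"])
    write_clinical(sim.cohort.clinical, paths["clinical"])
    write_annotations(sim.cohort.annotations, paths["annotations"])
    sim.verdicts.to_csv(paths["verdicts"], sep="\t", index=False)
    sim.expression.to_csv(paths["expression"], sep="\t")
    sim.truth.mutations.to_csv(paths["truth_mutations"], sep="\t", index=False)
    sim.truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    sim.genome.write_fasta(paths["reference"])
    sim.genome.arms.to_csv(paths["arms"], sep="\t", index=False)
    sim.genome.genes.to_csv(paths["genes"], sep="\t", index=False)
    return paths


__all__ = [
    "ToyGenome", "simulate_reference", "classify_substitution",
    "ArchetypeSpec", "SimulationConfig", "TruthTables", "SimulatedCohort",
    "default_archetypes", "expected_vaf", "simulate_sample",
    "simulate_cohort", "write_simulated_cohort", "planted_up_genes",
]
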