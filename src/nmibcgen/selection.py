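"""Gene, gene-set and pathway dN/dS estimation with early/late timing
odds ratios.

The expected nonsynonymous/synonymous site counts ("opportunities") are
computed by enumerating every possible single-base change in each
coding sequence and weighting it under a trinucleotide-free rate model:
six pyrimidine-centred base-substitution rates, each split by a CpG
flag (12 parameters), estimated from synonymous sites or uniform.
dN/dS for a class is the rate ratio

    omega = (n_class / L_class) / (n_syn / L_syn)

with an exact conditional-binomial CI (conditioning on the total count,
the class count is binomial with success probability
L_class*omega / (L_class*omega + L_syn)).  The point-combined estimate
pools missense, nonsense and splice substitutions.  Timing odds ratio
OR = omega_early / omega_late; OR > 2 is early-favored, OR < 0.5
late-favored, otherwise none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nmibcgen._constants import CODON_TABLE, COMPLEMENT

POINT_CLASSES = ("missense", "nonsense", "splice")


# ---------------------------------------------------------------------------
# rate model

@dataclass(frozen=True)
class RateModel:
    """Relative substitution rates keyed by (pyrimidine sub-type, is_cpg)."""

    rates: dict

    @classmethod
    def uniform(cls) -> "RateModel":
        subs = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
        return cls({(s, flag): 1.0 for s in subs for flag in (False, True)})

    @classmethod
    def estimate_from_synonymous(cls, cds_sequences: dict,
                                 mutations) -> "RateModel":
        """Rates proportional to synonymous counts / synonymous opportunity
        in each of the 12 categories (pseudocount 0.5)."""
        opp = _category_opportunities(cds_sequences)
        counts = {key: 0.0 for key in opp}
        gene_set = set(cds_sequences)
        for m in mutations:
            if m.consequence != "synonymous" or m.gene not in gene_set:
                continue
            key = _rate_key(m.ref, m.alt, m.context3[2] if len(m.context3) == 3 else "N")
            if key in counts:
                counts[key] += 1
        rates = {key: (counts[key] + 0.5) / (opp[key] + 1.0) for key in opp}
        mean = np.mean(list(rates.values()))
        return cls({k: v / mean for k, v in rates.items()})

    def weight(self, ref: str, alt: str, next_base: str) -> float:
        return self.rates.get(_rate_key(ref, alt, next_base), 1.0)


def _rate_key(ref: str, alt: str, next_base: str) -> tuple:
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        # CpG status of a purine-strand site is carried by the preceding
        # base on that strand; callers pass the +strand next base, which
        # complements to the pyrimidine-strand context
        next_base = COMPLEMENT.get(next_base, "N")
    is_cpg = ref == "C" and next_base == "G"
    return (f"{ref}>{alt}", is_cpg)


def _category_opportunities(cds_sequences: dict) -> dict:
    subs = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
    opp = {(s, flag): 0.0 for s in subs for flag in (False, True)}
    for seq in cds_sequences.values():
        for i, ref in enumerate(seq):
            nxt = seq[i + 1] if i + 1 < len(seq) else "N"
            for alt in "ACGT":
                if alt == ref:
                    continue
                opp[_rate_key(ref, alt, nxt)] += 1
    return opp


# ---------------------------------------------------------------------------
# opportunities

def mutation_opportunities(cds_sequences: dict,
                           rate_model: RateModel | None = None) -> pd.DataFrame:
    """Rate-weighted expected site counts per gene and consequence class.

    Enumerates all 3L possible substitutions of each in-frame CDS and
    classifies them against the codon table.  Splice opportunities are 0
    for plain CDS models (no intron boundaries)."""
    rate_model = rate_model or RateModel.uniform()
    rows = []
    for gene, seq in cds_sequences.items():
        seq = seq.upper()
        if len(seq) == 0:
            raise ValueError(f"{gene}: empty coding sequence")
        if len(seq) % 3:
            raise ValueError(f"{gene}: CDS length {len(seq)} not divisible by 3")
        L = {"missense": 0.0, "nonsense": 0.0, "synonymous": 0.0, "splice": 0.0}
        for i, ref in enumerate(seq):
            codon_idx, within = divmod(i, 3)
            codon = seq[3 * codon_idx:3 * codon_idx + 3]
            nxt = seq[i + 1] if i + 1 < len(seq) else "N"
            for alt in "ACGT":
                if alt == ref:
                    continue
                alt_codon = codon[:within] + alt + codon[within + 1:]
                aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[alt_codon]
                if aa_ref == aa_alt:
                    cls = "synonymous"
                elif aa_alt == "*":
                    cls = "nonsense"
                else:
                    cls = "missense"
                L[cls] += rate_model.weight(ref, alt, nxt)
        rows.append({"gene": gene, **L})
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# estimation

@dataclass
class DndsEstimate:
    scope: str
    stratum: str
    mutation_class: str
    dnds: float
    ci_low: float
    ci_high: float
    n_class: int
    n_syn: int
    p: float
    unstable: bool = False
    q: float = float("nan")


def estimate_dnds(n_class: int, L_class: float, n_syn: int, L_syn: float,
                  scope: str = "", stratum: str = "all",
                  mutation_class: str = "point-combined",
                  level: float = 0.95) -> DndsEstimate:
    """Rate-ratio dN/dS with an exact conditional binomial CI.

    With zero synonymous mutations the estimate is flagged unstable and
    the upper bound is infinite."""
    if L_class <= 0 or L_syn <= 0:
        raise ValueError("opportunities must be positive")
    N = n_class + n_syn
    unstable = n_syn == 0
    if N == 0:
        return DndsEstimate(scope, stratum, mutation_class, float("nan"),
                            float("nan"), float("nan"), 0, 0, 1.0, True)
    omega = ((n_class / L_class) / (n_syn / L_syn)) if n_syn else float("inf")
    alpha = 1.0 - level
    p_lo = stats.beta.ppf(alpha / 2, n_class, N - n_class + 1) if n_class else 0.0
    p_hi = (stats.beta.ppf(1 - alpha / 2, n_class + 1, N - n_class)
            if n_class < N else 1.0)

    def to_omega(p):
        if p >= 1.0:
            return float("inf")
        return (p / (1.0 - p)) * (L_syn / L_class)

    p0 = L_class / (L_class + L_syn)
    p_value = stats.binomtest(n_class, N, p0).pvalue
    return DndsEstimate(scope, stratum, mutation_class, omega,
                        to_omega(p_lo), to_omega(p_hi), n_class, n_syn,
                        float(p_value), unstable)


def _class_counts(mutations, genes=None) -> dict:
    counts = {"missense": 0, "nonsense": 0, "splice": 0, "synonymous": 0}
    for m in mutations:
        if genes is not None and m.gene not in genes:
            continue
        if m.consequence in counts:
            counts[m.consequence] += 1
    return counts


def dnds_for_scope(mutations, opportunities: pd.DataFrame, genes=None,
                   scope: str = "all-genes", stratum: str = "all") -> dict:
    """Estimates for missense, nonsense, truncating and point-combined
    classes over a gene scope (None = all genes with opportunities)."""
    if genes is None:
        genes = set(opportunities.index)
    else:
        genes = set(genes) & set(opportunities.index)
    opp = opportunities.loc[sorted(genes)].sum()
    counts = _class_counts(mutations, genes)
    L_syn, n_syn = float(opp["synonymous"]), counts["synonymous"]
    out = {}
    for cls in ("missense", "nonsense"):
        out[cls] = estimate_dnds(counts[cls], float(opp[cls]), n_syn, L_syn,
                                 scope, stratum, cls)
    trunc_n = counts["nonsense"] + counts["splice"]
    trunc_L = float(opp["nonsense"] + opp["splice"]) or float(opp["nonsense"])
    out["truncating"] = estimate_dnds(trunc_n, trunc_L, n_syn, L_syn,
                                      scope, stratum, "truncating")
    point_n = sum(counts[c] for c in POINT_CLASSES)
    point_L = float(sum(opp[c] for c in POINT_CLASSES if opp[c] > 0))
    out["point-combined"] = estimate_dnds(point_n, point_L, n_syn, L_syn,
                                          scope, stratum, "point-combined")
    return out


def gene_level_dnds(mutations, opportunities: pd.DataFrame,
                    stratum: str = "all",
                    mutation_class: str = "point-combined") -> pd.DataFrame:
    """Per-gene estimates with BH q-values across genes in the stratum."""
    from nmibcgen.clinical import bh_adjust
    by_gene: dict = {}
    for m in mutations:
        if m.gene in opportunities.index:
            by_gene.setdefault(m.gene, []).append(m)
    rows = []
    for gene in sorted(by_gene):
        est = dnds_for_scope(by_gene[gene], opportunities, {gene},
                             scope=gene, stratum=stratum)[mutation_class]
        rows.append({"gene": gene, "dnds": est.dnds, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "n_class": est.n_class,
                     "n_syn": est.n_syn, "p": est.p, "unstable": est.unstable})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


@dataclass
class TimingOR:
    scope: str
    odds_ratio: float
    phase: str                  # early-favored | late-favored | none
    evaluable: bool = True


def timing_odds_ratio(scope: str, early: DndsEstimate,
                      late: DndsEstimate) -> TimingOR:
    """OR = omega_early / omega_late with the 2 / 0.5 phase cutoffs."""
    if (late.unstable or early.unstable or not np.isfinite(late.dnds)
            or not np.isfinite(early.dnds) or late.dnds == 0):
        return TimingOR(scope, float("nan"), "none", evaluable=False)
    odds = early.dnds / late.dnds
    if odds > 2.0:
        phase = "early-favored"
    elif odds < 0.5:
        phase = "late-favored"
    else:
        phase = "none"
    return TimingOR(scope, odds, phase)


def pathway_dnds(mutations, opportunities: pd.DataFrame, pathways: dict,
                 stratum: str = "all") -> pd.DataFrame:
    """Pooled dN/dS per pathway (mutations pooled over member genes)."""
    rows = []
    for name, genes in pathways.items():
        members = set(genes) & set(opportunities.index)
        if not members:
            continue
        est = dnds_for_scope(
            [m for m in mutations if m.gene in members], opportunities,
            members, scope=name, stratum=stratum)["point-combined"]
        rows.append({"pathway": name, "dnds": est.dnds, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "n_class": est.n_class,
                     "n_syn": est.n_syn, "p": est.p, "unstable": est.unstable})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation under the rate model (calibration and recovery harness)

def simulate_class_counts(opportunities: pd.DataFrame, n_mutations: int,
                          rng, selection: dict | None = None) -> pd.DataFrame:
    """Draw per-(gene, class) mutation counts multinomially from the
    opportunity weights; ``selection`` multiplies the nonsynonymous
    weights of chosen genes (neutral when empty)."""
    selection = selection or {}
    classes = ["missense", "nonsense", "synonymous"]
    weights = opportunities[classes].copy().astype(float)
    for gene, mult in selection.items():
        if gene in weights.index:
            weights.loc[gene, ["missense", "nonsense"]] *= mult
    flat = weights.to_numpy().ravel()
    draws = rng.multinomial(n_mutations, flat / flat.sum())
    counts = pd.DataFrame(draws.reshape(weights.shape), index=weights.index,
                          columns=classes)
    counts["splice"] = 0
    return counts


def dnds_from_counts(counts: pd.DataFrame, opportunities: pd.DataFrame,
                     genes=None, scope: str = "all-genes") -> dict:
    """dN/dS estimates straight from a (gene x class) count table."""
    genes = set(opportunities.index) if genes is None else (
        set(genes) & set(opportunities.index))
    sub = counts.loc[counts.index.intersection(sorted(genes))]
    opp = opportunities.loc[sorted(genes)].sum()
    n_syn = int(sub["synonymous"].sum())
    L_syn = float(opp["synonymous"])
    out = {}
    for cls in ("missense", "nonsense"):
        out[cls] = estimate_dnds(int(sub[cls].sum()), float(opp[cls]),
                                 n_syn, L_syn, scope, "all", cls)
    point_n = int(sub[["missense", "nonsense", "splice"]].to_numpy().sum())
    point_L = float(opp["missense"] + opp["nonsense"] + opp["splice"])
    out["point-combined"] = estimate_dnds(point_n, point_L, n_syn, L_syn,
                                          scope, "all", "point-combined")
    return out


__all__ = [
    "RateModel", "mutation_opportunities", "DndsEstimate", "estimate_dnds",
    "dnds_for_scope", "gene_level_dnds", "TimingOR", "timing_odds_ratio",
    "pathway_dnds", "simulate_class_counts", "dnds_from_counts",
]
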