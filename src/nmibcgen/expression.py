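"""Expression-based subtype scoring on a gene x sample counts matrix.

Counts are normalized by median-of-ratios (DESeq-style size factors).
Differential ranking is one-vs-rest rank-sum with a shrunken log2 fold
change; the top 30 genes by adjusted p are split into subtype-up and
subtype-down sets by fold-change sign.  Per-sample gene-set scores are
ssGSEA-style weighted Kolmogorov-Smirnov running-sum statistics on
within-sample ranks, rescaled linearly to [-1, 1] across the cohort;
the subtype score is the up-set score minus the down-set score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes with any zero are excluded
    from the reference)."""
    log_counts = np.log(counts.replace(0, np.nan))
    log_ref = log_counts.mean(axis=1)
    ok = np.isfinite(log_ref)
    ratios = log_counts.loc[ok].sub(log_ref[ok], axis=0)
    factors = np.exp(ratios.median(axis=0))
    return factors.fillna(1.0)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.div(size_factors(counts), axis=1)


@dataclass
class SubtypeGeneSets:
    subtype: str
    up: list
    down: list
    table: pd.DataFrame


def rank_subtype_genes(counts: pd.DataFrame, labels: pd.Series,
                       n_top: int = 30, shrinkage: float = 5.0) -> dict:
    """One-vs-rest differential ranking per subtype.

    Returns {subtype: SubtypeGeneSets}.  Rank-sum p-values are BH
    adjusted per subtype; fold changes are shrunken by adding
    ``shrinkage`` pseudocounts to both group means.  Subtypes with
    fewer than 3 samples are skipped with a warning."""
    from nmibcgen.clinical import bh_adjust
    norm = normalize_counts(counts)
    out = {}
    for subtype in sorted(labels.unique()):
        members = labels.index[labels == subtype]
        others = labels.index[labels != subtype]
        if len(members) < 3:
            warnings.warn(f"subtype {subtype}: fewer than 3 samples, skipped",
                          stacklevel=2)
            continue
        a = norm[members].to_numpy()
        b = norm[others].to_numpy()
        stat, p = stats.ranksums(a, b, axis=1)
        lfc = np.log2((a.mean(axis=1) + shrinkage) / (b.mean(axis=1) + shrinkage))
        table = pd.DataFrame({"gene": norm.index, "stat": stat, "p": p,
                              "log2fc": lfc})
        table["padj"] = bh_adjust(table.p.to_numpy())
        table = table.sort_values(["padj", "p"]).reset_index(drop=True)
        if n_top > len(table):
            warnings.warn(f"n_top={n_top} exceeds {len(table)} genes; using all",
                          stacklevel=2)
        top = table.head(n_top)
        out[subtype] = SubtypeGeneSets(
            subtype=str(subtype),
            up=sorted(top.gene[top.log2fc > 0]),
            down=sorted(top.gene[top.log2fc <= 0]),
            table=table)
    return out


def gene_set_score(expression: pd.DataFrame, gene_set,
                   weight: float = 0.25, rescale: bool = True) -> pd.Series:
    """ssGSEA-style per-sample enrichment score for one gene set.

    Within each sample, genes are ranked by expression; the score is
    the weighted KS running-sum statistic (sum of deviations).  Scores
    are invariant to any monotone within-sample transform and, when
    ``rescale``, mapped linearly onto [-1, 1] across the cohort."""
    genes = [g for g in dict.fromkeys(gene_set)]
    present = [g for g in genes if g in expression.index]
    if not present:
        missing = sorted(set(genes))[:5]
        raise ValueError(f"no gene-set genes found in matrix (e.g. {missing})")
    in_set = expression.index.isin(present)
    scores = {}
    n_genes = expression.shape[0]
    for sample in expression.columns:
        ranks = stats.rankdata(expression[sample].to_numpy())  # ascending
        order = np.argsort(-ranks)                             # descending
        set_mask = in_set[order]
        weights = ranks[order] ** weight
        hit = np.where(set_mask, weights, 0.0)
        hit_cum = np.cumsum(hit)
        denom = hit_cum[-1]
        miss = np.where(~set_mask, 1.0, 0.0)
        miss_cum = np.cumsum(miss)
        n_miss = max(n_genes - len(present), 1)
        running = hit_cum / max(denom, 1e-12) - miss_cum / n_miss
        scores[sample] = float(running.sum() / n_genes)
    series = pd.Series(scores)
    if rescale:
        lo, hi = series.min(), series.max()
        if hi > lo:
            series = 2.0 * (series - lo) / (hi - lo) - 1.0
        else:
            series = pd.Series(0.0, index=series.index)
    return series


def subtype_score(up_score: pd.Series, down_score: pd.Series) -> pd.Series:
    """Up-set score minus down-set score (antisymmetric under swap)."""
    return up_score - down_score


def score_subtypes(expression: pd.DataFrame, gene_sets: dict) -> pd.DataFrame:
    """Subtype scores for every subtype's up/down sets; samples x subtypes."""
    out = {}
    for subtype, sets in gene_sets.items():
        up = gene_set_score(expression, sets.up) if sets.up else 0.0
        down = gene_set_score(expression, sets.down) if sets.down else 0.0
        if isinstance(up, float):
            up = pd.Series(up, index=expression.columns)
        if isinstance(down, float):
            down = pd.Series(down, index=expression.columns)
        out[str(subtype)] = subtype_score(up, down)
    return pd.DataFrame(out)


def dichotomize_at_median(scores: pd.Series) -> pd.Series:
    """Low/high groups at the cohort median score."""
    return pd.Series(np.where(scores > scores.median(), "high", "low"),
                     index=scores.index)


def panel_scores(expression: pd.DataFrame, panels: dict,
                 labels: pd.Series | None = None) -> tuple:
    """Scores for the canonical marker panels, with optional per-group
    rank-sum comparisons (BH across panels)."""
    from nmibcgen.clinical import bh_adjust
    scores = pd.DataFrame({name: gene_set_score(expression, genes)
                           for name, genes in panels.items()})
    comparisons = None
    if labels is not None:
        rows = []
        for name in scores.columns:
            for group in sorted(labels.unique()):
                in_g = labels.index[labels == group]
                out_g = labels.index[labels != group]
                if len(in_g) == 0 or len(out_g) == 0:
                    continue
                stat, p = stats.ranksums(scores.loc[in_g, name],
                                         scores.loc[out_g, name])
                rows.append({"panel": name, "group": group, "stat": stat, "p": p})
        comparisons = pd.DataFrame(rows)
        if len(comparisons):
            comparisons["q"] = bh_adjust(comparisons.p.to_numpy())
    return scores, comparisons


__all__ = [
    "size_factors", "normalize_counts", "SubtypeGeneSets",
    "rank_subtype_genes", "gene_set_score", "subtype_score",
    "score_subtypes", "dichotomize_at_median", "panel_scores",
]
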