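"""Genomic subtyping by Brunet-NMF consensus clustering of the binary
event matrix.

The matrix (events x samples) is factorized with KL-divergence
multiplicative updates; samples are assigned to the factor with maximal
coefficient.  Rank selection runs consensus clustering over restarts
for each candidate rank and picks the rank with the highest cophenetic
correlation coefficient (ties favour the smaller rank).  Subtypes are
characterized by one-vs-rest Fisher enrichment of events and flags and
rank-sum comparison of mutational burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from nmibcgen._nmf import best_of_restarts, nmf_kl


def build_subtyping_matrix(frequent_events: pd.DataFrame,
                           significant_cna: pd.DataFrame | None = None) -> pd.DataFrame:
    """Union of frequent events and significant CNA columns, deduplicated.

    Duplicate column names or identical columns under different names
    are collapsed with a warning; all-constant matrices are an error."""
    parts = [frequent_events]
    if significant_cna is not None and significant_cna.shape[1]:
        parts.append(significant_cna)
    matrix = pd.concat(parts, axis=1)
    if matrix.columns.duplicated().any():
        dupes = list(matrix.columns[matrix.columns.duplicated()])
        warnings.warn(f"duplicate event columns deduplicated: {dupes}",
                      stacklevel=2)
        matrix = matrix.loc[:, ~matrix.columns.duplicated()]
    if matrix.shape[1] < 2:
        raise ValueError("subtyping needs >= 2 event columns")
    if (matrix.nunique(axis=0) <= 1).all():
        raise ValueError("all event columns are constant")
    return matrix.astype(int)


def nmf_brunet(matrix: pd.DataFrame, k: int, restarts: int = 30,
               seed: int = 0, max_iter: int = 5000, tol: float = 1e-6):
    """Best-of-restarts Brunet NMF of the samples x events matrix.

    The matrix is factorized transposed (events x samples) so samples
    are columns; returns (W events x k, H k x samples, objective trace
    of the winning run)."""
    V = matrix.to_numpy(dtype=float).T
    W, H, trace, _ = best_of_restarts(V, k, restarts, seed,
                                      max_iter=max_iter, tol=tol)
    W_df = pd.DataFrame(W, index=matrix.columns,
                        columns=[f"factor{i + 1}" for i in range(k)])
    H_df = pd.DataFrame(H, index=W_df.columns, columns=matrix.index)
    return W_df, H_df, trace


def assign_labels(H: pd.DataFrame) -> pd.Series:
    """Sample -> subtype by argmax coefficient; ties to the lowest factor."""
    return pd.Series(np.argmax(H.to_numpy(), axis=0) + 1,
                     index=H.columns, name="subtype")


@dataclass
class RankDiagnostics:
    k: int
    cophenetic: float
    consensus: pd.DataFrame
    dispersion: float


def _consensus_for_rank(V: np.ndarray, k: int, restarts: int, seed: int,
                        max_iter: int, tol: float) -> np.ndarray:
    n = V.shape[1]
    consensus = np.zeros((n, n))
    master = np.random.default_rng(seed)
    for _ in range(restarts):
        rng = np.random.default_rng(master.integers(2**31))
        _, H, _ = nmf_kl(V, k, rng, max_iter=max_iter, tol=tol)
        labels = np.argmax(H, axis=0)
        consensus += labels[:, None] == labels[None, :]
    return consensus / restarts


def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if len(condensed) else 0.0):
        return 1.0  # degenerate: all pairs equally similar
    link = average(condensed)
    coph, _ = cophenet(link, condensed)
    return float(coph)


def select_rank(matrix: pd.DataFrame, k_range=(2, 3, 4, 5, 6),
                restarts: int = 30, seed: int = 0, max_iter: int = 2000,
                tol: float = 1e-5):
    """Consensus clustering over restarts per rank; the chosen rank
    maximizes the cophenetic coefficient (ties -> smaller k)."""
    k_range = sorted(set(k_range))
    if min(k_range) < 2 or max(k_range) > 8:
        raise ValueError("k range must lie within [2, 8]")
    V = matrix.to_numpy(dtype=float).T
    diags = []
    for k in k_range:
        consensus = _consensus_for_rank(V, k, restarts, seed + k, max_iter, tol)
        coph = _cophenetic_coefficient(consensus)
        entries = consensus[np.triu_indices_from(consensus, k=1)]
        dispersion = float(np.mean((2 * entries - 1) ** 2))
        diags.append(RankDiagnostics(
            k, coph, pd.DataFrame(consensus, index=matrix.index,
                                  columns=matrix.index), dispersion))
    cophs = np.array([d.cophenetic for d in diags])
    best = int(np.argmax(cophs))  # argmax takes the first (smaller k) on ties
    if len(k_range) == 1:
        warnings.warn("single-rank range: returning it without comparison",
                      stacklevel=2)
    flat = cophs.max() - cophs.min() < 0.02
    if (flat or cophs.max() < 0.95) and len(k_range) > 1:
        warnings.warn("cophenetic curve is flat or uniformly low: matrix "
                      "may lack cluster structure", stacklevel=2)
    return k_range[best], diags


@dataclass
class SubtypeModel:
    k: int
    basis: pd.DataFrame                 # events x k
    coefficients: pd.DataFrame          # k x samples
    labels: pd.Series
    diagnostics: list
    enrichment: pd.DataFrame | None = None


def fit_subtypes(matrix: pd.DataFrame, k: int | None = None,
                 k_range=(2, 3, 4, 5, 6), restarts: int = 30,
                 seed: int = 0) -> SubtypeModel:
    """Full subtyping: optional rank selection, final factorization,
    label assignment."""
    diags = []
    if k is None:
        k, diags = select_rank(matrix, k_range, restarts=restarts, seed=seed)
    W, H, _ = nmf_brunet(matrix, k, restarts=restarts, seed=seed)
    return SubtypeModel(k, W, H, assign_labels(H), diags)


def characterize_subtypes(labels: pd.Series, matrix: pd.DataFrame,
                          tmb: pd.Series | None = None) -> pd.DataFrame:
    """One-vs-rest Fisher enrichment of every event per subtype.

    Constant features get OR = NaN; subtypes smaller than 3 samples are
    flagged but still reported.  BH within each feature family (event
    class prefix before ':')."""
    from nmibcgen.clinical import bh_adjust
    rows = []
    for subtype in sorted(labels.unique()):
        in_st = labels == subtype
        small = int(in_st.sum()) < 3
        for event in matrix.columns:
            x = matrix[event].astype(bool)
            if x.all() or not x.any():
                rows.append({"subtype": subtype, "event": event,
                             "odds_ratio": float("nan"), "p": float("nan"),
                             "small_subtype": small})
                continue
            a = int((x & in_st).sum())
            b = int((~x & in_st).sum())
            c = int((x & ~in_st).sum())
            d = int((~x & ~in_st).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]])
            rows.append({"subtype": subtype, "event": event,
                         "odds_ratio": odds, "p": p, "small_subtype": small})
    df = pd.DataFrame(rows)
    df["family"] = df.event.str.split(":").str[0]
    df["q"] = np.nan
    for fam, grp in df.groupby("family"):
        ok = grp.p.notna()
        if ok.any():
            df.loc[grp.index[ok], "q"] = bh_adjust(grp.p[ok].to_numpy())
    if tmb is not None:
        tmb_rows = []
        for subtype in sorted(labels.unique()):
            in_st = labels == subtype
            if in_st.sum() and (~in_st).sum():
                stat, p = stats.ranksums(tmb[labels.index[in_st]],
                                         tmb[labels.index[~in_st]])
                tmb_rows.append({"subtype": subtype, "event": "tmb",
                                 "odds_ratio": float("nan"), "p": p,
                                 "small_subtype": bool(in_st.sum() < 3),
                                 "family": "tmb", "q": np.nan})
        df = pd.concat([df, pd.DataFrame(tmb_rows)], ignore_index=True)
    return df


def name_subtypes(enrichment: pd.DataFrame, overrides: dict | None = None) -> dict:
    """Automatic subtype naming by dominant enriched feature."""
    naming_rules = [("sig:SBS22", "AA-like"), ("flag:wgd", "GI"),
                    ("broad:9p-del", "FGFR3&chr9Del"), ("mut:FGFR3", "FGFR3/HRAS")]
    names = {}
    used = set()
    for subtype in sorted(enrichment.subtype.unique()):
        sub = enrichment[(enrichment.subtype == subtype)
                         & enrichment.p.notna()
                         & (enrichment.odds_ratio > 1)]
        name = None
        for event, candidate in naming_rules:
            if candidate in used:
                continue
            hit = sub[(sub.event == event) & (sub.p < 0.05)]
            if len(hit):
                name = candidate
                break
        names[subtype] = name or f"subtype{subtype}"
        used.add(names[subtype])
    if overrides:
        names.update(overrides)
    return names


__all__ = [
    "build_subtyping_matrix", "nmf_brunet", "assign_labels", "select_rank",
    "SubtypeModel", "fit_subtypes", "characterize_subtypes", "name_subtypes",
    "RankDiagnostics",
]
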