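"""Co-occurrence / mutual-exclusivity testing over binary genomic events
and early-to-late ordering interactions.

The pairwise test is DISCOVER-like: instead of assuming events strike
samples uniformly, the null preserves both per-sample event loads and
per-event frequencies exactly, via curveball margin-preserving
randomization of the binary matrix.  For each event pair the observed
overlap is compared with its null distribution, one-sided in each
direction, with BH adjustment within direction.  Ordering interactions
between early and late events use per-pair Fisher tests with
Haldane-Anscombe-corrected odds ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MIN_EVENT_FREQUENCY = 0.10


def assemble_event_matrix(driver_genes_by_sample: dict | None = None,
                          cna_events: list | None = None,
                          signature_presence: pd.DataFrame | None = None,
                          instability: pd.DataFrame | None = None,
                          samples: list | None = None,
                          min_frequency: float = MIN_EVENT_FREQUENCY,
                          apply_filter: bool = True) -> pd.DataFrame:
    """Samples x events binary matrix from the upstream call sets.

    Columns: per-gene driver mutations ("mut:GENE"), focal/broad CNA
    events keyed by arm and direction ("focal:9p-del", "broad:9q-del"),
    signature presence ("sig:SBS22"), and the flags wGD / CIN /
    hypermutation / APOBEC.  Events below ``min_frequency`` are dropped
    (the filter can be disabled for strata matrices that must share
    columns)."""
    if samples is None:
        sources = []
        if driver_genes_by_sample:
            sources.extend(driver_genes_by_sample)
        if instability is not None:
            sources.extend(instability.index)
        samples = sorted(set(sources))
    columns: dict = {}

    def add(event: str, flagged) -> None:
        if event in columns:
            raise ValueError(f"duplicate event name {event!r}")
        columns[event] = pd.Series(
            [1 if s in flagged else 0 for s in samples], index=samples)

    if driver_genes_by_sample:
        genes = sorted({g for gs in driver_genes_by_sample.values() for g in gs})
        for gene in genes:
            add(f"mut:{gene}",
                {s for s, gs in driver_genes_by_sample.items() if gene in gs})
    if cna_events:
        keys = sorted({(e.kind.split("-")[0], e.arm, e.kind.split("-")[1])
                       for e in cna_events})
        for size, arm, sign in keys:
            flagged = {e.sample_id for e in cna_events
                       if e.arm == arm and e.kind == f"{size}-{sign}"}
            add(f"{size}:{arm}-{sign}", flagged)
    if signature_presence is not None:
        if signature_presence.columns.duplicated().any():
            raise ValueError("duplicate event name in signature presence")
        for sig in signature_presence.columns:
            add(f"sig:{sig}",
                set(signature_presence.index[signature_presence[sig]]))
    if instability is not None:
        for flag in ("wgd", "cin", "hypermutated"):
            if flag in instability.columns:
                add(f"flag:{flag}",
                    set(instability.index[instability[flag].astype(bool)]))
        if "group" in instability.columns:
            add("flag:apobec",
                set(instability.index[instability["group"] != "none"]))
    matrix = pd.DataFrame(columns).astype(int)
    if apply_filter:
        freq = matrix.mean(axis=0)
        keep = freq >= min_frequency
        dropped = list(matrix.columns[~keep])
        if dropped:
            import logging
            logging.getLogger(__name__).info(
                "dropped %d events below %.0f%% frequency: %s",
                len(dropped), 100 * min_frequency, dropped)
        matrix = matrix.loc[:, keep]
    if matrix.shape[1] == 0:
        raise ValueError("no qualifying events")
    return matrix


# ---------------------------------------------------------------------------
# curveball margin-preserving randomization

def curveball_trade(rows: list, rng) -> int:
    """One curveball trade between two random rows; returns the number
    of entries exchanged.  ``rows`` is a list of python sets of column
    indices (modified in place); row and column sums are preserved."""
    i, j = rng.choice(len(rows), size=2, replace=False)
    a, b = rows[i], rows[j]
    a_only = list(a - b)
    b_only = list(b - a)
    n_swappable = min(len(a_only), len(b_only))
    if n_swappable == 0:
        return 0
    k = int(rng.integers(0, n_swappable + 1))
    if k == 0:
        return 0
    give_a = set(rng.choice(a_only, size=k, replace=False).tolist())
    give_b = set(rng.choice(b_only, size=k, replace=False).tolist())
    a -= give_a
    a |= give_b
    b -= give_b
    b |= give_a
    return 2 * k


def _matrix_to_rows(matrix: np.ndarray) -> list:
    return [set(np.flatnonzero(row)) for row in matrix]


def _rows_to_matrix(rows: list, n_cols: int) -> np.ndarray:
    out = np.zeros((len(rows), n_cols), dtype=np.int8)
    for i, row in enumerate(rows):
        out[i, list(row)] = 1
    return out


def curveball_samples(matrix: np.ndarray, n_samples: int, seed: int = 0,
                      burn_in_swaps: int | None = None,
                      thin_trades: int = 10):
    """Yield margin-preserving randomizations of a binary matrix.

    Burn-in runs until >= 10 x (number of ones) entries have been
    exchanged (the default), then one matrix is emitted every
    ``thin_trades`` trades."""
    rng = np.random.default_rng(seed)
    matrix = np.asarray(matrix)
    n_ones = int(matrix.sum())
    if n_ones == 0 or n_ones == matrix.size:
        raise ValueError("degenerate all-zero or all-one matrix")
    target = 10 * n_ones if burn_in_swaps is None else burn_in_swaps
    rows = _matrix_to_rows(matrix)
    swapped = 0
    while swapped < target:
        swapped += curveball_trade(rows, rng)
    for _ in range(n_samples):
        for _ in range(thin_trades):
            curveball_trade(rows, rng)
        yield _rows_to_matrix(rows, matrix.shape[1])


def test_pairs(matrix: pd.DataFrame, n_perm: int = 1000, seed: int = 0,
               thin_trades: int = 10) -> pd.DataFrame:
    """Pairwise co-occurrence/exclusivity with a curveball null.

    For every event pair the observed overlap count is compared with
    ``n_perm`` margin-preserving null matrices: co-occurrence p is the
    fraction of null overlaps >= observed, exclusivity p the fraction
    <= observed (each +1 corrected).  BH within direction."""
    from nmibcgen.clinical import bh_adjust
    M = matrix.to_numpy(dtype=np.int8)
    n_samples_, n_events = M.shape
    if n_events < 2:
        raise ValueError("need >= 2 events")
    observed = (M.T @ M).astype(float)
    expected = np.zeros_like(observed)
    ge = np.zeros_like(observed)
    le = np.zeros_like(observed)
    for null in curveball_samples(M, n_perm, seed=seed, thin_trades=thin_trades):
        overlap = (null.T @ null).astype(float)
        expected += overlap
        ge += overlap >= observed
        le += overlap <= observed
    expected /= n_perm
    rows = []
    iu = np.triu_indices(n_events, k=1)
    for a, b in zip(*iu):
        p_co = (1.0 + ge[a, b]) / (n_perm + 1.0)
        p_ex = (1.0 + le[a, b]) / (n_perm + 1.0)
        direction = "co-occurrence" if p_co <= p_ex else "exclusivity"
        rows.append({
            "event_a": matrix.columns[a], "event_b": matrix.columns[b],
            "observed": observed[a, b], "expected": expected[a, b],
            "effect": observed[a, b] - expected[a, b],
            "p_cooccurrence": p_co, "p_exclusivity": p_ex,
            "direction": direction,
        })
    df = pd.DataFrame(rows)
    df["q_cooccurrence"] = bh_adjust(df["p_cooccurrence"].to_numpy())
    df["q_exclusivity"] = bh_adjust(df["p_exclusivity"].to_numpy())
    df["p"] = np.where(df.direction == "co-occurrence",
                       df.p_cooccurrence, df.p_exclusivity)
    df["q"] = np.where(df.direction == "co-occurrence",
                       df.q_cooccurrence, df.q_exclusivity)
    return df


def ordering_interactions(early: pd.DataFrame, late: pd.DataFrame) -> pd.DataFrame:
    """Fisher 2x2 per (early event, late event) pair across shared samples.

    Odds ratios with a zero cell are reported as infinite (or 0)
    alongside the Haldane-Anscombe corrected OR (+0.5 to every cell);
    constant columns are skipped.  BH across tested pairs."""
    from nmibcgen.clinical import bh_adjust
    shared = early.index.intersection(late.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between strata")
    E, L = early.loc[shared], late.loc[shared]
    rows = []
    for e_col in E.columns:
        e = E[e_col].to_numpy(dtype=bool)
        if e.all() or not e.any():
            continue
        for l_col in L.columns:
            l = L[l_col].to_numpy(dtype=bool)
            if l.all() or not l.any():
                continue
            a = int(np.sum(e & l))
            b = int(np.sum(e & ~l))
            c = int(np.sum(~e & l))
            d = int(np.sum(~e & ~l))
            odds, p = stats.fisher_exact([[a, b], [c, d]])
            corrected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            rows.append({"early_event": e_col, "late_event": l_col,
                         "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": odds, "odds_ratio_corrected": corrected,
                         "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


__all__ = [
    "assemble_event_matrix", "curveball_trade", "curveball_samples",
    "test_pairs", "ordering_interactions", "MIN_EVENT_FREQUENCY",
]
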