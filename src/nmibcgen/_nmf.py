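"""KL-divergence nonnegative matrix factorization (Brunet multiplicative
updates), shared by de novo signature extraction and genomic subtyping."""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized Kullback-Leibler divergence D(V || WH)."""
    V = np.asarray(V, dtype=float)
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / (WH[mask] + _EPS)))
    return float(div - V.sum() + WH.sum())


def nmf_kl(V, k: int, rng, max_iter: int = 5000, tol: float = 1e-6):
    """Factorize V ~= W @ H (V: features x samples) minimizing KL divergence.

    Returns (W, H, objective_trace); the multiplicative updates make the
    objective non-increasing, which callers may assert on the trace."""
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("NMF requires a non-negative matrix")
    if V.sum() == 0:
        raise ValueError("NMF requires a non-zero matrix")
    n, m = V.shape
    if not (1 <= k <= min(n, m)):
        raise ValueError(f"rank k={k} out of range for {V.shape}")
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    trace = [kl_divergence(V, W @ H)]
    for _ in range(max_iter):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        obj = kl_divergence(V, W @ H)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / max(prev, _EPS) < tol:
            break
    return W, H, np.array(trace)


def best_of_restarts(V, k: int, restarts: int, seed: int,
                     max_iter: int = 5000, tol: float = 1e-6):
    """Run ``restarts`` seeded factorizations, keep the lowest-KL one.

    Returns (W, H, trace, all_results) where all_results holds every
    restart's (W, H, final_kl) for stability diagnostics."""
    master = np.random.default_rng(seed)
    results = []
    best = None
    for _ in range(max(restarts, 1)):
        rng = np.random.default_rng(master.integers(2**31))
        W, H, trace = nmf_kl(V, k, rng, max_iter=max_iter, tol=tol)
        results.append((W, H, trace[-1]))
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    return best[0], best[1], best[2], results


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


__all__ = ["kl_divergence", "nmf_kl", "best_of_restarts", "cosine_similarity"]
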