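"""Independent transcription of the three-term graph D-measure.

Written as a separate code path from ``coretier.conet`` for dual-route
verification: adjacency-matrix input, Floyd-Warshall shortest paths, and
scipy entropy. Shares only the definitional constants (unreachable bin
last, NND normalized by log(diameter+1), alpha = 1/(1+spectral radius),
exogenous input degree/(N-1)).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import entropy


def floyd_warshall(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    d = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def distance_rows(A: np.ndarray) -> tuple[np.ndarray, int]:
    n = A.shape[0]
    d = floyd_warshall(A)
    finite = d[np.isfinite(d)]
    diam = int(finite.max()) if finite.size else 0
    rows = np.zeros((n, n))
    for i in range(n):
        others = [d[i, j] for j in range(n) if j != i]
        for k in range(1, n):
            rows[i, k - 1] = sum(1 for v in others if v == k)
        rows[i, n - 1] = sum(1 for v in others if not np.isfinite(v))
        rows[i] = rows[i] / (n - 1)
    return rows, diam


def js_two(p: np.ndarray, q: np.ndarray) -> float:
    size = max(len(p), len(q))
    if len(p) < size:
        p = np.concatenate([p[:-1], np.zeros(size - len(p)), p[-1:]])
    if len(q) < size:
        q = np.concatenate([q[:-1], np.zeros(size - len(q)), q[-1:]])
    m = 0.5 * (p + q)
    return max(0.0, entropy(m) - 0.5 * (entropy(p) + entropy(q)))


def nnd(A: np.ndarray) -> tuple[float, np.ndarray]:
    rows, diam = distance_rows(A)
    mu = rows.mean(axis=0)
    if diam == 0:
        return 0.0, mu
    val = entropy(mu) - np.mean([entropy(r) for r in rows])
    return max(0.0, val) / np.log(diam + 1), mu


def alpha_centrality_dist(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    deg = A.sum(axis=1)
    e = deg / (n - 1)
    eigs = np.linalg.eigvals(A)
    rho = float(np.max(np.abs(eigs)).real) if A.any() else 0.0
    alpha = 1.0 / (1.0 + rho)
    c = np.linalg.solve(np.eye(n) - alpha * A.T, e)
    c = np.sort(np.clip(c, 0.0, None))
    s = c.sum()
    if s <= 0:
        return np.full(n, 1.0 / n)
    return c / s


def d_measure_reference(A1: np.ndarray, A2: np.ndarray,
                        w1: float = 0.45, w2: float = 0.45, w3: float = 0.10) -> float:
    nnd1, mu1 = nnd(A1)
    nnd2, mu2 = nnd(A2)
    out = w1 * np.sqrt(js_two(mu1, mu2) / np.log(2.0))
    out += w2 * abs(np.sqrt(nnd1) - np.sqrt(nnd2))
    if w3 > 0:
        comp1 = (1.0 - A1) - np.eye(A1.shape[0])
        comp2 = (1.0 - A2) - np.eye(A2.shape[0])
        pg = js_two(alpha_centrality_dist(A1), alpha_centrality_dist(A2))
        pc = js_two(alpha_centrality_dist(comp1), alpha_centrality_dist(comp2))
        out += w3 / 2.0 * (np.sqrt(pg / np.log(2.0)) + np.sqrt(pc / np.log(2.0)))
    return float(out)
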