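"""Independent brute-force oracles used to check the implementations.

These deliberately avoid the code paths they validate: shortest-path
betweenness is computed by Floyd-Warshall plus path counting over the
shortest-path DAG, the signed-rank null distribution by exact enumeration
over rank-sum polynomials, and stationary VAR autocovariances from the
discrete Lyapunov equation of the companion form.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import linalg


def brute_force_edge_betweenness(lengths: np.ndarray) -> dict:
    """Edge betweenness with fractional tie attribution, by enumeration.

    Parameters
    ----------
    lengths : (d, d) array
        Directed edge lengths; np.inf marks an absent edge.

    Returns
    -------
    dict mapping (u, v) -> total shortest-path count through edge u -> v.
    """
    d = lengths.shape[0]
    dist = lengths.copy()
    np.fill_diagonal(dist, 0.0)
    # Floyd-Warshall
    for k in range(d):
        dist = np.minimum(dist, dist[:, k][:, None] + dist[k, :][None, :])

    edges = [(u, v) for u in range(d) for v in range(d)
             if u != v and np.isfinite(lengths[u, v])]
    bc = {e: 0.0 for e in edges}
    for s in range(d):
        # count shortest paths s -> x by DP in order of distance from s
        order = np.argsort(dist[s])
        nsp = np.zeros(d)
        nsp[s] = 1.0
        for x in order:
            if x == s or not np.isfinite(dist[s, x]):
                continue
            nsp[x] = sum(
                nsp[u]
                for (u, v) in edges
                if v == x and np.isclose(dist[s, u] + lengths[u, v], dist[s, x])
            )
        for t in range(d):
            if t == s or not np.isfinite(dist[s, t]) or nsp[t] == 0:
                continue
            # paths from v to t on the DAG, computed symmetrically
            nsp_to_t = np.zeros(d)
            nsp_to_t[t] = 1.0
            order_t = np.argsort(dist[:, t])
            for x in order_t:
                if x == t or not np.isfinite(dist[x, t]):
                    continue
                nsp_to_t[x] = sum(
                    nsp_to_t[v]
                    for (u, v) in edges
                    if u == x and np.isclose(lengths[u, v] + dist[v, t], dist[x, t])
                )
            for (u, v) in edges:
                if np.isclose(dist[s, u] + lengths[u, v] + dist[v, t], dist[s, t]):
                    bc[(u, v)] += nsp[u] * nsp_to_t[v] / nsp[t]
    return bc


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumeration over sign assignments.

    Assumes no zero differences and no tied absolute values (continuous
    data); enumerates the null distribution of W+ over all 2^n sign
    patterns via the rank-sum generating polynomial.
    """
    diffs = np.asarray(diffs, float)
    n = diffs.size
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
    w_plus = int(ranks[diffs > 0].sum())
    max_w = n * (n + 1) // 2
    # counts[w] = number of sign patterns with W+ == w
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        new = counts.copy()
        new[r:] += counts[: max_w + 1 - r]
        counts = new
    total = counts.sum()
    p_le = counts[: w_plus + 1].sum() / total
    p_ge = counts[w_plus:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def stationary_var_autocov(A: np.ndarray, sigma: np.ndarray, max_lag: int):
    """Lag-0..max_lag autocovariances of a stationary VAR via Lyapunov.

    Parameters
    ----------
    A : (p, d, d) lag matrices; sigma : (d, d) innovation covariance.
    """
    p, d, _ = A.shape
    comp = np.zeros((p * d, p * d))
    comp[:d] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[d:, : (p - 1) * d] = np.eye((p - 1) * d)
    Q = np.zeros((p * d, p * d))
    Q[:d, :d] = sigma
    G = linalg.solve_discrete_lyapunov(comp, Q)
    covs = [G[:d, :d]]
    Gh = G
    for _ in range(max_lag):
        Gh = comp @ Gh
        covs.append(Gh[:d, :d])
    return covs


def all_digraphs(n: int):
    """Yield adjacency (0/1) matrices of every simple digraph on n nodes."""
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in itertools.product([0, 1], repeat=len(slots)):
        adj = np.zeros((n, n))
        for b, (i, j) in zip(bits, slots):
            adj[i, j] = b
        yield adj
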