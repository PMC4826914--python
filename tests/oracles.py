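"""Independent oracles used by the tests.

These deliberately avoid the package's own algorithms: likelihoods are
exhaustive sums over internal-node state assignments with scipy's generic
matrix exponential, and centralities come from first-principles BFS
path counting.  Slow and simple on purpose.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.linalg import expm

from netsel.codon_model import RateMatrixSpec, build_rate_matrix
from netsel.codons import CODON_INDEX


def _transition(kappa, omega, pi, t, rate_scale):
    q = build_rate_matrix(RateMatrixSpec(kappa=kappa, omega=omega, pi=pi), scale=False)
    return expm(q * t / rate_scale)


def _tip_vector(p_mat, state):
    """Column of P for an observed codon; marginalized (row sums = 1) if missing."""
    if state < 0:
        return np.ones(p_mat.shape[0])
    return p_mat[:, state]


def enumeration_star_loglik(blens, states, kappa, pi, class_set, rate_scale):
    """Star tree (one internal node = root): direct sum over 61 root states."""
    total = 0.0
    for w, omega in zip(class_set.weights, class_set.omegas):
        like = np.copy(pi)
        for t, s in zip(blens, states):
            like = like * _tip_vector(_transition(kappa, omega, pi, t, rate_scale), s)
        total += w * like.sum()
    return np.log(total)


def enumeration_balanced4_loglik(blens, states, kappa, pi, class_set, rate_scale):
    """Balanced 4-taxon tree ((a,b)x,(c,d)y)root: full (61,61,61) tensor sum.

    blens = (ta, tb, tc, td, tx, ty); states = (sa, sb, sc, sd).
    """
    ta, tb, tc, td, tx, ty = blens
    sa, sb, sc, sd = states
    total = 0.0
    for w, omega in zip(class_set.weights, class_set.omegas):
        pa = _tip_vector(_transition(kappa, omega, pi, ta, rate_scale), sa)
        pb = _tip_vector(_transition(kappa, omega, pi, tb, rate_scale), sb)
        pc = _tip_vector(_transition(kappa, omega, pi, tc, rate_scale), sc)
        pd_ = _tip_vector(_transition(kappa, omega, pi, td, rate_scale), sd)
        prx = _transition(kappa, omega, pi, tx, rate_scale)
        pry = _transition(kappa, omega, pi, ty, rate_scale)
        # tensor[r, x, y] = pi_r P_rx P_ry (pa_x pb_x) (pc_y pd_y), summed exhaustively
        tensor = (
            pi[:, None, None]
            * prx[:, :, None]
            * pry[:, None, :]
            * (pa * pb)[None, :, None]
            * (pc * pd_)[None, None, :]
        )
        total += w * tensor.sum()
    return np.log(total)


def encode_column(codons_by_taxon):
    return [CODON_INDEX.get(c, -1) for c in codons_by_taxon]


# ---------------------------------------------------------------------------
# Graph centralities from scratch


def bfs_distances_and_counts(adj, source):
    """(distance, number of shortest paths) from source to every node."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def betweenness_oracle(graph) -> dict:
    """Pair-by-pair shortest-path counting, normalized by (n-1)(n-2)/2."""
    nodes = list(graph.nodes)
    adj = {v: list(graph.neighbors(v)) for v in nodes}
    n = len(nodes)
    acc = {v: 0.0 for v in nodes}
    info = {v: bfs_distances_and_counts(adj, v) for v in nodes}
    for i, s in enumerate(nodes):
        dist_s, sig_s = info[s]
        for t in nodes[i + 1 :]:
            if t not in dist_s:
                continue
            d_st = dist_s[t]
            sig_st = sig_s[t]
            dist_t, sig_t = info[t]
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d_st:
                    acc[v] += sig_s[v] * sig_t[v] / sig_st
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    return {v: acc[v] / norm for v in nodes}


def closeness_oracle(graph) -> dict:
    adj = {v: list(graph.neighbors(v)) for v in graph.nodes}
    out = {}
    for v in graph.nodes:
        dist, _ = bfs_distances_and_counts(adj, v)
        if len(dist) == 1:
            out[v] = 0.0
        else:
            out[v] = (len(dist) - 1) / sum(dist.values())
    return out


# ---------------------------------------------------------------------------
# Exact Mann-Whitney by enumeration


def mann_whitney_exact_two_sided(a, b) -> float:
    """Two-sided exact P by enumerating all group labelings (tie-free data)."""
    from itertools import combinations

    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) + 0.5 * sum(
            1 for x in group_a for y in group_b if x == y
        )

    mu = n_a * len(b) / 2.0
    obs = abs(u_stat(a, b) - mu)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= obs - 1e-12:
            count += 1
    return count / total
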