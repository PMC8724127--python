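"""Brute-force reference implementations used only as test oracles.

Deliberately naive: iterative peeling for coreness, BFS shortest-path
counting for betweenness, BFS distance sums for closeness.  They share no
code with the package implementations they check.
"""

from collections import deque

import numpy as np


def degree_strength_oracle(weights):
    n = len(weights)
    deg = np.zeros(n)
    stren = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i][j] > 0:
                deg[i] += 1
                stren[i] += weights[i][j]
    return deg, stren


def coreness_oracle(weights):
    """Iterative peeling: remove nodes of degree < k until stable, for rising k."""
    n = len(weights)
    adj = [{j for j in range(n) if j != i and weights[i][j] > 0} for i in range(n)]
    core = np.zeros(n)
    alive = set(range(n))
    k = 1
    while alive:
        while True:
            victims = {i for i in alive if sum(1 for j in adj[i] if j in alive) < k}
            if not victims:
                break
            alive -= victims
        for i in alive:
            core[i] = k
        k += 1
    return core


def _bfs_paths(adj, source):
    """BFS from source: distances and shortest-path counts."""
    n = len(adj)
    dist = [-1] * n
    sigma = [0.0] * n
    order = []
    dist[source] = 0
    sigma[source] = 1.0
    queue = deque([source])
    while queue:
        v = queue.popleft()
        order.append(v)
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma, order


def betweenness_oracle(weights):
    """Pair-by-pair sum of sigma_st(v)/sigma_st over unordered pairs, v interior."""
    n = len(weights)
    adj = [[j for j in range(n) if j != i and weights[i][j] > 0] for i in range(n)]
    if n < 3:
        return np.zeros(n)
    score = np.zeros(n)
    for s in range(n):
        dist_s, sigma_s, _ = _bfs_paths(adj, s)
        for t in range(s + 1, n):
            if dist_s[t] < 0:
                continue  # disconnected pair contributes nothing
            dist_t, sigma_t, _ = _bfs_paths(adj, t)
            for v in range(n):
                if v in (s, t) or dist_s[v] < 0 or dist_t[v] < 0:
                    continue
                if dist_s[v] + dist_t[v] == dist_s[t]:
                    score[v] += sigma_s[v] * sigma_t[v] / sigma_s[t]
    return score / ((n - 1) * (n - 2) / 2.0)


def closeness_oracle(weights):
    """1/sum(d) over the reachable set, scaled by (r-1)/(n-1)."""
    n = len(weights)
    adj = [[j for j in range(n) if j != i and weights[i][j] > 0] for i in range(n)]
    out = np.zeros(n)
    for v in range(n):
        dist, _, _ = _bfs_paths(adj, v)
        reachable = [d for d in dist if d >= 0]
        total = sum(reachable)
        if total > 0:
            out[v] = (1.0 / total) * ((len(reachable) - 1) / (n - 1))
    return out


def spearman_formula(r1, r2):
    """The closed form 1 - 6*sum(d^2)/(n(n^2-1)); valid only without ties."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    n = len(r1)
    return 1.0 - 6.0 * float(np.sum((r1 - r2) ** 2)) / (n * (n**2 - 1))
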