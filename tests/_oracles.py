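"""Independent brute-force oracles used to cross-check the implementation.

Every function here is deliberately naive (triple loops, explicit
enumeration, direct formulas) and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap for a symmetric zero-diagonal adjacency."""
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def upgma_brute_force(d: np.ndarray):
    """Naive O(n^3) UPGMA; returns the sorted list of merge heights."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    heights = []
    next_id = n
    while len(clusters) > 1:
        (ci, cj), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters.pop(ci) + clusters.pop(cj)
        new_dist = {}
        for key, val in dist.items():
            if ci in key or cj in key:
                continue
            new_dist[key] = val
        for other, leaves in clusters.items():
            # unweighted average: mean pairwise distance between leaf sets
            total = sum(d[x, y] for x in merged for y in leaves)
            pair = tuple(sorted((other, next_id)))
            new_dist[pair] = total / (len(merged) * len(leaves))
        clusters[next_id] = merged
        next_id += 1
        dist = new_dist
    return sorted(heights)


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, m * p[idx] / rank_from_top)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


def betweenness_brute_force(adj: dict[str, set], normalized: bool = True) -> dict[str, float]:
    """Betweenness by explicit enumeration of all shortest paths (BFS per pair)."""
    nodes = sorted(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for path in paths if v in path)
            score[v] += through / len(paths)
    if normalized and n > 2:
        norm = (n - 1) * (n - 2) / 2.0
        score = {v: x / norm for v, x in score.items()}
    return score


def _all_shortest_paths(adj, s, t):
    from collections import deque

    dist = {s: 0}
    parents: dict = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                parents[w] = [u]
                q.append(w)
            elif dist[w] == dist[u] + 1:
                parents[w].append(u)
    if t not in dist:
        return []
    paths = []

    def backtrack(v, acc):
        if v == s:
            paths.append(set(acc) | {s})
            return
        for p in parents[v]:
            backtrack(p, acc + [v])

    backtrack(t, [])
    return paths


def group_stats_brute_force(values: np.ndarray, labels: list[str]):
    """Per-group means and pooled within-group variance, feature by feature."""
    groups = sorted(set(labels))
    labels = np.asarray(labels)
    n, k = values.shape[1], len(groups)
    means = {}
    sse = np.zeros(values.shape[0])
    for g in groups:
        cols = labels == g
        sub = values[:, cols]
        means[g] = sub.mean(axis=1)
        sse += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return means, sse / (n - k), n - k


def pairwise_corr_mc_oracle(
    loading: float,
    noise_sd: float,
    n_samples: int,
    n_replicates: int,
    replicate_noise_sd: float,
    n_draws: int = 10_000,
    seed: int = 12345,
) -> float:
    """Monte-Carlo expected within-module pairwise correlation.

    Simulates the generative model directly: a shared standard factor, two
    member features with independent feature noise, replicate spots with
    measurement noise collapsed by the median; returns the mean sample
    correlation of the two collapsed profiles over many draws.
    """
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_draws):
        f = rng.normal(size=n_samples)
        f = (f - f.mean()) / f.std()
        profiles = []
        for _ in range(2):
            x = loading * f + rng.normal(0.0, noise_sd, size=n_samples)
            reps = x + rng.normal(0.0, replicate_noise_sd, size=(n_replicates, n_samples))
            profiles.append(np.median(reps, axis=0))
        rs.append(np.corrcoef(profiles[0], profiles[1])[0, 1])
    return float(np.mean(rs))


def cross_factor_corr_mc_oracle(
    strength: float,
    loading: float,
    noise_sd: float,
    n_samples: int,
    size_a: int,
    size_b: int,
    n_draws: int = 10_000,
    seed: int = 54321,
) -> float:
    """Monte-Carlo expected correlation between two module mean profiles.

    Module A members follow factor f; module B members follow
    -strength * f + sqrt(1 - strength^2) * g (g independent); the measured
    quantity is the correlation of the two module mean profiles.
    """
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_draws):
        f = rng.normal(size=n_samples)
        f = (f - f.mean()) / f.std()
        g = rng.normal(size=n_samples)
        h = -strength * f + np.sqrt(1.0 - strength**2) * g
        h = (h - h.mean()) / h.std()
        a = loading * f + rng.normal(0, noise_sd, size=(size_a, n_samples))
        b = loading * h + rng.normal(0, noise_sd, size=(size_b, n_samples))
        rs.append(np.corrcoef(a.mean(axis=0), b.mean(axis=0))[0, 1])
    return float(np.mean(rs))
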