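"""Independent brute-force oracles used to validate the implementations.

Everything here is written from first principles (loops, sets, explicit
enumeration) and must stay independent of the code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pi_pairwise_hamming(haps: np.ndarray, lo: int, hi: int) -> float:
    """Mean pairwise Hamming distance over sites [lo, hi) of a 0/1
    haplotype matrix, averaged over all haplotype pairs."""
    n = haps.shape[0]
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int(np.sum(haps[i, lo:hi] != haps[j, lo:hi]))
        pairs += 1
    return total / pairs


def windowed_pi_bruteforce(haps: np.ndarray, positions: np.ndarray,
                           windows: np.ndarray) -> np.ndarray:
    """Per-window diversity: pairwise Hamming sum / window length in bp."""
    out = np.zeros(len(windows))
    for w, (start, end) in enumerate(windows):
        cols = [j for j, p in enumerate(positions) if start <= p <= end]
        if not cols:
            continue
        sub = haps[:, cols]
        out[w] = pi_pairwise_hamming(sub, 0, sub.shape[1]) / (end - start + 1)
    return out


def wc_components_textbook(n_list, p_list, h_list):
    """Weir-Cockerham (1984) a, b, c for one site; plain-float arithmetic."""
    r = len(n_list)
    nbar = sum(n_list) / r
    sum_n = r * nbar
    nc = (sum_n - sum(ni * ni for ni in n_list) / sum_n) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n_list, p_list)) / sum_n
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n_list, p_list)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n_list, h_list)) / sum_n
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def ehh_enumeration(haps: np.ndarray, lo: int, hi: int) -> float:
    """EHH by direct pair enumeration: fraction of haplotype pairs identical
    over sites [lo, hi] inclusive (missing alleles match nothing)."""
    n = haps.shape[0]
    same = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        a, b = haps[i, lo:hi + 1], haps[j, lo:hi + 1]
        pairs += 1
        if np.all((a == b) & (a >= 0) & (b >= 0)) or lo > hi:
            same += 1
    return same / pairs


def trapezoid(xs, ys) -> float:
    total = 0.0
    for k in range(1, len(xs)):
        total += (xs[k] - xs[k - 1]) * (ys[k] + ys[k - 1]) / 2.0
    return total


def bh_stepup(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the step-up definition:
    q_(i) = min_{j >= i} (p_(j) * m / j), clipped to <= 1."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        val = p[order[rank - 1]] * m / rank
        running = min(running, val)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n), by direct summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    return total


def interval_membership_counts(sites, gene_intervals, cds_intervals):
    """Classify (chrom, pos) sites by scanning every interval (brute force)."""
    counts = {"intergenic": 0, "intronic": 0, "coding": 0}
    for chrom, pos in sites:
        in_cds = any(c == chrom and s <= pos <= e for c, s, e in cds_intervals)
        in_gene = any(c == chrom and s <= pos <= e for c, s, e in gene_intervals)
        if in_cds:
            counts["coding"] += 1
        elif in_gene:
            counts["intronic"] += 1
        else:
            counts["intergenic"] += 1
    return counts


def sharing_counts_sets(presence: dict[str, list[bool]]) -> dict[tuple, int]:
    """Exclusive-intersection counts from per-population presence vectors."""
    pops = list(presence)
    n_sites = len(next(iter(presence.values())))
    out: dict[tuple, int] = {}
    for j in range(n_sites):
        subset = tuple(sorted(p for p in pops if presence[p][j]))
        if subset:
            out[subset] = out.get(subset, 0) + 1
    return out


def p_distance_double_loop(G: np.ndarray) -> np.ndarray:
    """p-distances by explicit loops with pairwise deletion."""
    n, m = G.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = 0.0
            cnt = 0
            for s in range(m):
                if G[i, s] >= 0 and G[j, s] >= 0:
                    num += abs(float(G[i, s]) - float(G[j, s])) / 2.0
                    cnt += 1
            D[i, j] = D[j, i] = num / cnt if cnt else np.nan
    return D


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with branch lengths, its Newick string and the
    exact additive tip-to-tip distance matrix (path lengths).

    Built by sequential random attachment; distances computed on the edge
    graph by breadth-first search, independent of any tree library.
    """
    # nodes: 0..n_taxa-1 are tips; internal nodes numbered onwards
    edges: dict[int, dict[int, float]] = {0: {}, 1: {}}
    next_id = n_taxa
    bl = lambda: float(rng.uniform(0.5, 2.0))
    # start with 2 tips joined by an edge (via a degree-2 'root' we remove later)
    w = bl() + bl()
    edges[0][1] = w
    edges[1][0] = w
    edge_list = [(0, 1)]
    for tip in range(2, n_taxa):
        ei = rng.integers(0, len(edge_list))
        u, v = edge_list.pop(ei)
        w_uv = edges[u].pop(v)
        edges[v].pop(u)
        mid = next_id
        next_id += 1
        split = float(rng.uniform(0.25, 0.75)) * w_uv
        edges.setdefault(mid, {})
        edges[u][mid] = split
        edges[mid][u] = split
        edges[mid][v] = w_uv - split
        edges[v][mid] = w_uv - split
        pend = bl()
        edges.setdefault(tip, {})
        edges[mid][tip] = pend
        edges[tip][mid] = pend
        edge_list += [(u, mid), (mid, v), (mid, tip)]
    # all-pairs tip distances by Dijkstra-free BFS on the tree
    labels = [f"t{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w_ in edges[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w_
                    stack.append(v)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]
    D = (D + D.T) / 2.0  # remove float asymmetry from summation order
    return D, labels, edges


def tree_splits_from_edges(edges: dict[int, dict[int, float]], n_taxa: int):
    """Non-trivial tip bipartitions of the random tree, canonicalised as the
    smaller side (lexicographic tie-break on the min element)."""
    splits = set()
    seen_pairs = set()
    for u in edges:
        for v in edges[u]:
            if (v, u) in seen_pairs:
                continue
            seen_pairs.add((u, v))
            # tips on the v-side when edge (u, v) is cut
            side = set()
            stack = [v]
            visited = {u, v}
            while stack:
                x = stack.pop()
                if x < n_taxa:
                    side.add(f"t{x}")
                for y in edges[x]:
                    if y not in visited:
                        visited.add(y)
                        stack.append(y)
            other = {f"t{i}" for i in range(n_taxa)} - side
            if len(side) < 2 or len(other) < 2:
                continue
            a, b = frozenset(side), frozenset(other)
            if len(a) < len(b) or (len(a) == len(b) and min(a) < min(b)):
                splits.add(a)
            else:
                splits.add(b)
    return splits
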