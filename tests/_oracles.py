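"""Independent longhand oracles used to cross-check the implementation.

Everything here is deliberately naive (loops, BFS, exhaustive enumeration)
and shares no code with the package.
"""

from collections import deque
from itertools import combinations

import numpy as np


def longhand_modularity(g, assignment):
    """Q via the pairwise formulation (1/2m) sum_ij (A_ij - k_i k_j/2m) delta."""
    nodes = list(g.nodes)
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    k = {n: g.degree(n) for n in nodes}
    q = 0.0
    for i in nodes:
        for j in nodes:
            if assignment[i] != assignment[j]:
                continue
            a = 1.0 if g.has_edge(i, j) and i != j else 0.0
            q += a - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


def longhand_gd(g):
    """Mean BFS shortest-path length over connected ordered pairs."""
    total, pairs = 0, 0
    for source in g.nodes:
        dist = {source: 0}
        queue = deque([source])
        while queue:
            u = queue.popleft()
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for node, d in dist.items():
            if node != source:
                total += d
                pairs += 1
    return total / pairs if pairs else 0.0


def longhand_avg_cc(g):
    """Mean local clustering coefficient by explicit triangle counting."""
    vals = []
    for n in g.nodes:
        nbrs = list(g.neighbors(n))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        tri = sum(1 for a, b in combinations(nbrs, 2) if g.has_edge(a, b))
        vals.append(2.0 * tri / (k * (k - 1)))
    return sum(vals) / len(vals)


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_best_q(g):
    """Maximum modularity over all partitions (feasible for <= 8 nodes)."""
    nodes = list(g.nodes)
    assert len(nodes) <= 8
    best = -1.0
    for part in set_partitions(nodes):
        assignment = {}
        for m, block in enumerate(part):
            for n in block:
                assignment[n] = m
        best = max(best, longhand_modularity(g, assignment))
    return best


def longhand_chao1(counts):
    x = [c for c in counts if c > 0]
    f1 = sum(1 for c in x if c == 1)
    f2 = sum(1 for c in x if c == 2)
    return len(x) + f1 * (f1 - 1) / (2 * (f2 + 1))


def longhand_shannon(counts):
    x = [c for c in counts if c > 0]
    n = sum(x)
    return -sum((c / n) * np.log(c / n) for c in x)


def longhand_goods(counts):
    x = [c for c in counts if c > 0]
    return (1 - sum(1 for c in x if c == 1) / sum(x)) * 100.0
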