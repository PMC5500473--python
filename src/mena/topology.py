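"""Modular decomposition, network indices, node roles and null models.

Community structure is found by agglomerative fast-greedy modularity
optimisation on the unsigned 0/1 adjacency (edge signs are carried as
attributes only).  Node roles follow the within-module degree z-score (Zi)
and participation coefficient (Pi) scheme: peripherals (Zi <= 2.5,
Pi <= 0.62), connectors (Zi <= 2.5, Pi > 0.62), module hubs (Zi > 2.5,
Pi <= 0.62) and network hubs (Zi > 2.5, Pi > 0.62).  Statistical
significance of the network indices is assessed against a Maslov-Sneppen
degree-preserving rewired ensemble via a Z-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ContractError

logger = logging.getLogger(__name__)

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module_hub"
ROLE_NETWORK_HUB = "network_hub"

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class ModulePartition:
    """Node -> module assignment with sizes and its modularity score."""

    assignment: dict
    module_sizes: dict = field(default_factory=dict)
    modularity_q: float = float("nan")

    def __post_init__(self):
        if not self.module_sizes:
            sizes = {}
            for m in self.assignment.values():
                sizes[m] = sizes.get(m, 0) + 1
            self.module_sizes = sizes

    @property
    def n_modules(self):
        return len(self.module_sizes)

    def members(self, module_id):
        return [n for n, m in self.assignment.items() if m == module_id]


def modularity(g, assignment):
    """Newman modularity Q = sum_s [ l_s/L - (d_s/2L)^2 ] on 0/1 adjacency."""
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ContractError(f"nodes missing from partition: {missing[:5]}")
    L = g.number_of_edges()
    if L == 0:
        return 0.0
    intra = {}
    deg = {}
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            intra[assignment[u]] = intra.get(assignment[u], 0) + 1
    for n in g.nodes:
        m = assignment[n]
        deg[m] = deg.get(m, 0) + g.degree(n)
    q = 0.0
    for m in deg:
        q += intra.get(m, 0) / L - (deg[m] / (2 * L)) ** 2
    return q


def fast_greedy_modules(g):
    """Agglomerative greedy modularity optimisation (CNM scheme).

    Starts from singleton modules and repeatedly merges the pair of
    modules with the largest modularity gain

        dQ(A, B) = e_AB / L - d_A d_B / (2 L^2),

    stopping when no merge has dQ > 0.  Ties are broken by the lowest
    (module id, module id) pair, making the result deterministic.  Module
    ids in the returned partition are contiguous from 0, ordered by each
    module's first node in sorted node order.
    """
    if g.number_of_nodes() == 0:
        raise ContractError("empty network")
    nodes = sorted(g.nodes, key=str)
    L = g.number_of_edges()
    comm = {n: i for i, n in enumerate(nodes)}
    if L > 0:
        deg = {i: g.degree(n) for n, i in comm.items()}
        inter = {}  # (a, b) a < b -> edge count between current modules
        for u, v in g.edges:
            a, b = comm[u], comm[v]
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            inter[key] = inter.get(key, 0) + 1
        two_l2 = 2.0 * L * L
        while inter:
            best_key, best_dq = None, 0.0
            for key in inter:
                a, b = key
                dq = inter[key] / L - deg[a] * deg[b] / two_l2
                if dq > best_dq + 1e-15 or (
                        best_key is not None
                        and abs(dq - best_dq) <= 1e-15 and key < best_key):
                    best_key, best_dq = key, dq
            if best_key is None:
                break
            a, b = best_key  # merge b into a (a < b)
            for n, c in comm.items():
                if c == b:
                    comm[n] = a
            deg[a] += deg.pop(b)
            new_inter = {}
            for (x, y), cnt in inter.items():
                x = a if x == b else x
                y = a if y == b else y
                if x == y:
                    continue
                key = (x, y) if x < y else (y, x)
                new_inter[key] = new_inter.get(key, 0) + cnt
            inter = new_inter
    # relabel contiguous, ordered by first node in sorted order
    relabel = {}
    assignment = {}
    for n in nodes:
        c = comm[n]
        if c not in relabel:
            relabel[c] = len(relabel)
        assignment[n] = relabel[c]
    q = modularity(g, assignment)
    return ModulePartition(assignment=assignment, modularity_q=q)


class FastGreedyCommunities(BaseEstimator):
    """sklearn-style wrapper around :func:`fast_greedy_modules`.

    ``fit`` accepts a networkx graph; fitted attributes are ``labels_``
    (dict node -> module id), ``modularity_`` and ``n_modules_``.
    """

    def fit(self, X, y=None):
        part = fast_greedy_modules(X)
        self.partition_ = part
        self.labels_ = part.assignment
        self.modularity_ = part.modularity_q
        self.n_modules_ = part.n_modules
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        return self.labels_


@dataclass
class NetworkIndices:
    """The four headline indices of a co-occurrence network."""

    avg_connectivity: float
    gd: float  # average shortest-path distance over connected pairs
    avg_cc: float
    modularity_q: float


def average_path_distance(g):
    """Mean shortest-path length over all connected node pairs.

    Disconnected pairs are excluded (each component contributes its own
    pairs); 0 for an edgeless graph.
    """
    total, pairs = 0, 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if target != source:
                total += dist
                pairs += 1
    return total / pairs if pairs else 0.0


def network_indices(g, partition=None):
    """Average connectivity, GD, avgCC and modularity of a network."""
    if g.number_of_nodes() == 0:
        raise ContractError("empty network")
    n = g.number_of_nodes()
    avg_k = 2 * g.number_of_edges() / n
    avg_cc = sum(nx.clustering(g).values()) / n
    if partition is None:
        partition = fast_greedy_modules(g)
    return NetworkIndices(
        avg_connectivity=avg_k,
        gd=average_path_distance(g),
        avg_cc=avg_cc,
        modularity_q=modularity(g, partition.assignment),
    )


def zi_pi(g, partition):
    """Within-module degree z-score and participation coefficient per node.

    Zi standardises a node's intra-module degree against its module's
    intra-module degree distribution (population sd; Zi = 0 when sd = 0).
    Pi = 1 - sum_t (k_it / k_i)^2 over modules t; 0 for isolated nodes.
    """
    assignment = partition.assignment
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ContractError(f"nodes missing from partition: {missing[:5]}")
    intra = {}
    for n in g.nodes:
        m = assignment[n]
        intra[n] = sum(1 for nb in g.neighbors(n) if assignment[nb] == m)
    by_module = {}
    for n, k in intra.items():
        by_module.setdefault(assignment[n], []).append(k)
    mod_stats = {m: (np.mean(ks), np.std(ks)) for m, ks in by_module.items()}
    out = {}
    for n in g.nodes:
        k = g.degree(n)
        if k == 0:
            logger.warning("isolated node %r: zi = pi = 0", n)
            out[n] = (0.0, 0.0)
            continue
        mean, sd = mod_stats[assignment[n]]
        zi = (intra[n] - mean) / sd if sd > 0 else 0.0
        per_module = {}
        for nb in g.neighbors(n):
            t = assignment[nb]
            per_module[t] = per_module.get(t, 0) + 1
        pi = 1.0 - sum((kt / k) ** 2 for kt in per_module.values())
        out[n] = (float(zi), float(pi))
    return out


def classify_role(zi, pi):
    """Map a (Zi, Pi) pair to its topological role.

    Boundary values fall in the <= branch: (2.5, 0.62) is peripheral.
    """
    if not 0 <= pi <= 1:
        raise ContractError(f"pi must lie in [0, 1], got {pi}")
    if not math.isfinite(zi):
        raise ContractError("zi must be finite")
    if zi <= ZI_THRESHOLD:
        return ROLE_PERIPHERAL if pi <= PI_THRESHOLD else ROLE_CONNECTOR
    return ROLE_MODULE_HUB if pi <= PI_THRESHOLD else ROLE_NETWORK_HUB


def node_roles(g, partition):
    """Per-node role profile rows: module, zi, pi, role."""
    zp = zi_pi(g, partition)
    rows = []
    for n in g.nodes:
        zi, pi = zp[n]
        rows.append({
            "node": n,
            "module": partition.assignment[n],
            "zi": zi,
            "pi": pi,
            "role": classify_role(zi, pi),
        })
    return rows


def module_membership(table, partition, module_id):
    """Signed correlation of each module OTU with the module eigengene.

    The eigengene is the first right-singular vector (sample space) of the
    per-OTU standardised abundance submatrix of the module; its sign is
    fixed so the module's mean membership is >= 0.  Values near +/-1 mean
    the OTU tracks the module's consensus abundance profile.
    """
    members = [o for o in table.otu_ids if partition.assignment.get(o) == module_id]
    if len(members) < 2:
        raise ContractError(f"module {module_id} has < 2 OTUs in the table")
    if table.n_samples < 4:
        raise ContractError("need >= 4 samples for module membership")
    idx = [table.otu_ids.index(o) for o in members]
    x = table.counts[idx].astype(float)
    sd = x.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("%d constant profiles in module %s: membership 0",
                       int(const.sum()), module_id)
    z = (x - x.mean(axis=1, keepdims=True)) / np.where(const, 1.0, sd)[:, None]
    z[const] = 0.0
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eigengene = vt[0]
    memb = {}
    for otu, row, c in zip(members, z, const):
        if c:
            memb[otu] = 0.0
            continue
        r = float(np.corrcoef(row, eigengene)[0, 1])
        memb[otu] = r
    vals = np.array(list(memb.values()))
    if vals.size and vals.mean() < 0:
        memb = {o: -v for o, v in memb.items()}
    return memb


def all_module_memberships(table, partition, min_size=2):
    """Module membership for every module with >= ``min_size`` OTUs."""
    out = {}
    for m in sorted(partition.module_sizes):
        members = [o for o in table.otu_ids
                   if partition.assignment.get(o) == m]
        if len(members) >= max(min_size, 2):
            out.update(module_membership(table, partition, m))
    return out


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def maslov_sneppen(g, swaps_per_edge=100, seed=None):
    """Degree-preserving randomisation by repeated double-edge swaps.

    Attempts ``swaps_per_edge * L`` swaps: two edges (a,b), (c,d) are
    rewired to (a,d), (c,b) when neither self-loops nor duplicate edges
    would result.  The sorted degree sequence is preserved exactly; edge
    signs are reassigned at random preserving the original +/- counts.
    If no attempted swap succeeds (e.g. a star), the input is returned
    unchanged with a warning.
    """
    if g.number_of_edges() < 2:
        raise ContractError("need >= 2 edges to rewire")
    rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in g.edges]
    signs = [g.edges[e].get("sign", 1) for e in edges]
    weights = [g.edges[e].get("weight", 1.0) for e in edges]
    edge_set = set(frozenset(e) for e in edges)
    L = len(edges)
    attempts = swaps_per_edge * L
    successes = 0
    for _ in range(attempts):
        i, j = rng.integers(0, L, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if frozenset((a, d)) in edge_set or frozenset((c, b)) in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(frozenset((a, d)))
        edge_set.add(frozenset((c, b)))
        edges[i] = (a, d)
        edges[j] = (c, b)
        successes += 1
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    if successes == 0:
        logger.warning("no legal double-edge swap found; returning the "
                       "input network unchanged")
        out.add_edges_from(g.edges(data=True))
        return out
    order = rng.permutation(L)
    for k, (u, v) in enumerate(edges):
        out.add_edge(u, v, sign=signs[order[k]], weight=weights[order[k]])
    return out


@dataclass
class NullModelReport:
    """Observed index versus its rewired-ensemble distribution."""

    index: str
    observed: float
    null_mean: float
    null_sd: float
    z_score: float
    p_value: float
    n_random: int
    swaps_per_edge: int
    seed: object
    degenerate: bool = False


def null_model_test(g, n_random=100, swaps_per_edge=100, seed=None):
    """Z-tests of GD, avgCC and modularity against rewired null networks.

    Each of ``n_random`` Maslov-Sneppen rewires (independent sub-seeds
    spawned from ``seed``) is re-analysed from scratch: a fresh fast-greedy
    partition is computed per random network for the modularity index.
    P-values are two-tailed normal; sd = 0 is reported as p = 1 with the
    ``degenerate`` flag set.
    """
    if n_random < 2:
        raise ContractError("n_random must be >= 2")
    part = fast_greedy_modules(g)
    obs = network_indices(g, part)
    observed = {"gd": obs.gd, "avg_cc": obs.avg_cc,
                "modularity": obs.modularity_q}
    ss = np.random.SeedSequence(seed)
    nulls = {k: [] for k in observed}
    for child in ss.spawn(n_random):
        rnd = maslov_sneppen(g, swaps_per_edge=swaps_per_edge, seed=child)
        rpart = fast_greedy_modules(rnd)
        ridx = network_indices(rnd, rpart)
        nulls["gd"].append(ridx.gd)
        nulls["avg_cc"].append(ridx.avg_cc)
        nulls["modularity"].append(ridx.modularity_q)
    reports = []
    for name, vals in nulls.items():
        vals = np.asarray(vals)
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0:
            z, p, degen = 0.0, 1.0, True
        else:
            z = (observed[name] - mean) / sd
            p = float(2 * stats.norm.sf(abs(z)))
            p = min(max(p, np.nextafter(0, 1)), 1.0)
            degen = False
        reports.append(NullModelReport(
            index=name, observed=observed[name], null_mean=mean,
            null_sd=sd, z_score=float(z), p_value=p, n_random=n_random,
            swaps_per_edge=swaps_per_edge, seed=seed, degenerate=degen))
    return reports
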