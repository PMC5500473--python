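"""Synthetic OTU tables and toy graphs with planted, known structure.

The abundance generator plants block-correlation structure with a latent
factor per module: each module OTU's log-abundance is a loading on its
module factor plus independent noise, with the loading chosen so the
expected pairwise within-module correlation of log-abundances equals
``within_module_corr``.  A fraction of loadings is sign-flipped to create
negative associations, designated hubs get boosted loadings, and connector
OTUs load evenly on several module factors.  Counts are produced by
exponentiating to log-normal marginals, scaling by a per-sample sequencing
depth, and rounding — so rare OTUs can genuinely drop to zero.

Toy graphs (cliques, rings of cliques, stars over modules) provide exact
fixtures with hand-checkable optimal partitions and role classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ContractError, DesignError
from .io import AbundanceTable

logger = logging.getLogger(__name__)

_PLACEHOLDER_CLASSES = ("Alphaproteobacteria", "Gammaproteobacteria",
                        "Flavobacteriia", "Bacilli", "Verrucomicrobiae",
                        "Actinobacteria", "Clostridia", "Anaerolineae")


@dataclass
class PlantedDesign:
    """Parameters of a planted-structure abundance table.

    Defaults emulate the scale of a thresholded co-occurrence network from
    a gut-microbiome survey: ~600 OTUs, 4 planted modules of 120 OTUs,
    ~20% background-noise OTUs, strong within-module correlation (0.9)
    across 50 samples, 30% of within-module loadings negated (so ~42% of
    within-module pairs are negatively associated), one boosted hub per
    module, and two connectors each loading evenly on three modules.
    """

    n_otus: int = 600
    n_samples: int = 50
    n_modules: int = 4
    module_sizes: tuple = (120, 120, 120, 120)
    within_module_corr: float = 0.9
    negative_fraction: float = 0.3
    n_connectors: int = 2
    connector_span: int = 3
    hub_boost: float = 1.5
    base_abundance_log_mean: float = 3.0
    base_abundance_log_sd: float = 1.0
    depth_nominal: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.module_sizes) != self.n_modules:
            raise DesignError("module_sizes length != n_modules")
        if any(s < 2 for s in self.module_sizes):
            raise DesignError("every module needs >= 2 OTUs")
        if sum(self.module_sizes) + self.n_connectors > self.n_otus:
            raise DesignError("module_sizes (+connectors) sum > n_otus")
        if not 0 < self.within_module_corr < 1:
            raise DesignError("within_module_corr must lie in (0, 1)")
        if not 0 <= self.negative_fraction < 1:
            raise DesignError("negative_fraction must lie in [0, 1)")
        if self.n_connectors and not 2 <= self.connector_span <= self.n_modules:
            raise DesignError("connector_span must lie in [2, n_modules]")


@dataclass
class GroundTruth:
    """Planted partition and role labels for a generated table or graph.

    ``partition`` maps OTU -> module id; background-noise OTUs carry -1.
    Connectors are assigned to the lowest-indexed module they load on.
    """

    partition: dict
    role_labels: dict = field(default_factory=dict)
    realized_sparsity: float = float("nan")

    def module_nodes(self):
        """Nodes belonging to a planted module (label != -1)."""
        return [n for n, m in self.partition.items() if m != -1]


def generate_table(design):
    """Draw an (AbundanceTable, GroundTruth) pair from a planted design.

    Deterministic given ``design.seed``.
    """
    if design.n_samples < 4:
        raise ContractError("need n_samples >= 4")
    rng = np.random.default_rng(design.seed)
    n, m = design.n_otus, design.n_samples
    k = design.n_modules
    rho = design.within_module_corr
    # loading a with unit noise gives pairwise corr a^2 / (a^2 + 1) = rho
    a = np.sqrt(rho / (1.0 - rho))

    loadings = np.zeros((n, k))
    partition = {}
    roles = {}
    otu_ids = [f"OTU{i:04d}" for i in range(n)]
    pos = 0
    for mod, size in enumerate(design.module_sizes):
        members = range(pos, pos + size)
        n_neg = int(round(design.negative_fraction * size))
        neg_members = rng.choice(size, size=n_neg, replace=False)
        hub_local = int(rng.integers(size))
        for local, i in enumerate(members):
            load = a
            if local == hub_local:
                load *= design.hub_boost
                roles[otu_ids[i]] = "module_hub"
            else:
                roles[otu_ids[i]] = "peripheral"
            if local in neg_members:
                load = -load
            loadings[i, mod] = load
            partition[otu_ids[i]] = mod
        pos += size
    for c in range(design.n_connectors):
        i = pos + c
        mods = tuple((c + d) % k for d in range(design.connector_span))
        for mod in mods:
            loadings[i, mod] = a / np.sqrt(design.connector_span)
        partition[otu_ids[i]] = min(mods)
        roles[otu_ids[i]] = "connector"
    pos += design.n_connectors
    for i in range(pos, n):  # background noise OTUs
        partition[otu_ids[i]] = -1
        roles[otu_ids[i]] = "peripheral"

    factors = rng.standard_normal((k, m))
    noise = rng.standard_normal((n, m))
    signal = loadings @ factors
    signal_var = (loadings ** 2).sum(axis=1)
    z = (signal + noise) / np.sqrt(signal_var + 1.0)[:, None]
    log_abund = design.base_abundance_log_mean \
        + design.base_abundance_log_sd * z
    depth = rng.uniform(0.5, 1.5, size=m) * design.depth_nominal
    counts = np.rint(np.exp(log_abund) * depth[None, :]).astype(np.int64)
    sparsity = float((counts == 0).mean())
    logger.info("generated table %dx%d, realized sparsity %.3f", n, m, sparsity)

    taxonomy = [
        "k__Bacteria; p__Synthetic; c__{}".format(
            _PLACEHOLDER_CLASSES[partition[o] % len(_PLACEHOLDER_CLASSES)]
            if partition[o] != -1 else "Unassigned")
        for o in otu_ids
    ]
    table = AbundanceTable(
        otu_ids=otu_ids,
        sample_ids=[f"S{j:03d}" for j in range(m)],
        counts=counts,
        taxonomy=taxonomy,
    )
    truth = GroundTruth(partition=partition, role_labels=roles,
                        realized_sparsity=sparsity)
    return table, truth


def generate_group_dataset(design, groups=("Control", "PM", "G19", "FL")):
    """One planted table per treatment group, sharing the design.

    Group tables are generated with distinct sub-seeds; sample ids are
    prefixed by the group label and the group map is filled in.
    """
    ss = np.random.SeedSequence(design.seed)
    tables = {}
    truths = {}
    for sub, grp in zip(ss.spawn(len(groups)), groups):
        d = PlantedDesign(**{**design.__dict__,
                             "seed": int(sub.generate_state(1)[0] % (2 ** 31))})
        table, truth = generate_table(d)
        table.sample_ids = [f"{grp}.{s}" for s in table.sample_ids]
        table.groups = {s: grp for s in table.sample_ids}
        tables[grp] = table
        truths[grp] = truth
    return tables, truths


# ---------------------------------------------------------------------------
# toy graphs with known structure
# ---------------------------------------------------------------------------

def generate_toy_graph(kind, **params):
    """Exact fixture graphs with known optimal partition and roles.

    Kinds
    -----
    two_cliques(clique_size)
        Two disjoint cliques; true partition = the cliques.
    ring_of_cliques(n_cliques, clique_size)
        Cliques joined in a ring by single bridge edges.
    star_plus_modules(n_modules, clique_size)
        Disjoint cliques plus one hub node with exactly one edge into each
        clique — a planted connector with Pi = 1 - n_modules*(1/n_modules)^2.
    """
    if kind == "two_cliques":
        size = params.get("clique_size", 3)
        g = nx.disjoint_union(nx.complete_graph(size), nx.complete_graph(size))
        part = {n: (0 if n < size else 1) for n in g.nodes}
        roles = {n: "peripheral" for n in g.nodes}
    elif kind == "ring_of_cliques":
        k = params.get("n_cliques", 4)
        size = params.get("clique_size", 5)
        g = nx.ring_of_cliques(k, size)
        part = {n: n // size for n in g.nodes}
        roles = {n: "peripheral" for n in g.nodes}
    elif kind == "star_plus_modules":
        k = params.get("n_modules", 4)
        size = params.get("clique_size", 4)
        g = nx.Graph()
        for c in range(k):
            members = [c * size + i for i in range(size)]
            g.add_edges_from(itertools.combinations(members, 2))
        hub = k * size
        for c in range(k):
            g.add_edge(hub, c * size)
        part = {n: n // size for n in range(k * size)}
        part[hub] = -1
        roles = {n: "peripheral" for n in range(k * size)}
        roles[hub] = "connector"
    else:
        raise ContractError(f"unknown toy graph kind {kind!r}")
    nx.set_edge_attributes(g, 1, "sign")
    nx.set_edge_attributes(g, 1.0, "weight")
    return g, GroundTruth(partition=part, role_labels=roles)


# ---------------------------------------------------------------------------
# ground-truth I/O (two-column TSVs)
# ---------------------------------------------------------------------------

def write_ground_truth(truth, partition_path, roles_path=None):
    with open(partition_path, "w") as fh:
        fh.write("#otu\tmodule\n")
        for o, m in truth.partition.items():
            fh.write(f"{o}\t{m}\n")
    if roles_path:
        with open(roles_path, "w") as fh:
            fh.write("#otu\trole\n")
            for o, r in truth.role_labels.items():
                fh.write(f"{o}\t{r}\n")


def read_ground_truth(partition_path, roles_path=None):
    partition, roles = {}, {}
    with open(partition_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            o, m = line.rstrip("\n").split("\t")
            partition[o] = int(m)
    if roles_path:
        with open(roles_path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                o, r = line.rstrip("\n").split("\t")
                roles[o] = r
    return GroundTruth(partition=partition, role_labels=roles)
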