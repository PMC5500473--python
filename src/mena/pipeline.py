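"""End-to-end per-group analysis and tabular exports.

`run_pipeline` takes one abundance table with treatment labels and, per
group: computes the diversity profile, scans for the RMT threshold, builds
the signed network, decomposes it into modules, derives node roles and
module memberships, and runs the null-model significance tests.  All files
carry a provenance header (package version, seed, parameters), and a
summary table reports nodes / modules / positive / negative / total edges
per group.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import __version__
from .diversity import diversity_profile
from .errors import ContractError, MenaError
from .io import parse_lineage, to_relative
from .network import build_network, correlations, edge_sign_counts, scan_threshold
from .topology import (all_module_memberships, fast_greedy_modules,
                       network_indices, node_roles, null_model_test)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, recorded in every output."""

    output_dir: str = "mena_out"
    method: str = "pearson"
    transform: str = "log_relative"
    min_prevalence: int = 0
    st_min: float = 0.30
    step: float = 0.01
    min_nodes: int = 50
    n_random: int = 100
    swaps_per_edge: int = 100
    seed: int = 0

    def fingerprint(self):
        pairs = [f"{f.name}={getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        return f"mena v{__version__} | " + " ".join(pairs)


def _write_tsv(path, header_cols, rows, config):
    with open(path, "w") as fh:
        fh.write(f"# {config.fingerprint()}\n")
        fh.write("\t".join(header_cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_edge_list(g, path, config):
    rows = [(u, v, d.get("sign", 1), f"{d.get('weight', 1.0):.6f}")
            for u, v, d in sorted(g.edges(data=True))]
    _write_tsv(path, ["source", "target", "sign", "weight"], rows, config)


def write_graphml(g, path):
    nx.write_graphml(g, path)


def write_threshold_scan(scan, path, config):
    rows = list(zip(scan.thresholds, scan.n_nodes,
                    (f"{x:.4f}" for x in scan.chi2_poisson),
                    (f"{x:.4f}" for x in scan.chi2_goe),
                    (f"{x:.4g}" for x in scan.p_poisson)))
    _write_tsv(path, ["threshold", "n_nodes", "chi2_poisson", "chi2_goe",
                      "p_poisson"], rows, config)


def export_circos_tables(g, partition, taxonomy, band_path, link_path,
                         config=None, abundance=None):
    """Circos-ready band and link tables for a signed network.

    The band table lists each node with its class-level taxon and an
    abundance value (mean relative abundance if supplied, else degree);
    the link table lists edges with their sign encoded as the two Fig.-style
    colour classes (positive/negative).
    """
    if g.number_of_nodes() == 0:
        raise ContractError("empty network")
    config = config or RunConfig()
    bands = []
    for n in sorted(g.nodes, key=str):
        tax = taxonomy.get(n, "") if isinstance(taxonomy, dict) else ""
        parts = parse_lineage(tax)
        cls = parts[2] if len(parts) > 2 and parts[2] else "Unclassified"
        ab = abundance.get(n, g.degree(n)) if abundance else g.degree(n)
        bands.append((n, cls, partition.assignment.get(n, -1), ab))
    _write_tsv(band_path, ["node", "class", "module", "abundance"],
               bands, config)
    links = [(u, v, "positive" if d.get("sign", 1) > 0 else "negative")
             for u, v, d in sorted(g.edges(data=True))]
    _write_tsv(link_path, ["source", "target", "color"], links, config)


@dataclass
class GroupResult:
    """All per-group artifacts of a pipeline run."""

    group: str
    diversity: list
    scan: object
    network: object
    partition: object
    indices: object
    roles: list
    memberships: dict
    null_reports: list


def analyze_group(table, config, seed=None):
    """Run the full per-group analysis on one group's table."""
    if table.n_samples < 4:
        raise ContractError(f"group table has {table.n_samples} < 4 samples")
    seed = config.seed if seed is None else seed
    corr = correlations(table, method=config.method,
                        transform=config.transform,
                        min_prevalence=config.min_prevalence)
    scan = scan_threshold(corr, st_min=config.st_min, step=config.step,
                          min_nodes=config.min_nodes)
    net = build_network(corr, scan.chosen_threshold)
    if net.number_of_nodes() == 0:
        raise MenaError("network is empty at the chosen threshold")
    partition = fast_greedy_modules(net)
    indices = network_indices(net, partition)
    roles = node_roles(net, partition)
    memberships = all_module_memberships(
        _restrict(table, list(net.nodes)), partition)
    nulls = null_model_test(net, n_random=config.n_random,
                            swaps_per_edge=config.swaps_per_edge, seed=seed)
    return GroupResult(
        group="", diversity=diversity_profile(table), scan=scan,
        network=net, partition=partition, indices=indices, roles=roles,
        memberships=memberships, null_reports=nulls)


def _restrict(table, otu_ids):
    idx = [table.otu_ids.index(o) for o in otu_ids if o in table.otu_ids]
    from .io import AbundanceTable
    return AbundanceTable(
        otu_ids=[table.otu_ids[i] for i in idx],
        sample_ids=list(table.sample_ids),
        counts=table.counts[idx].copy(),
        taxonomy=[table.taxonomy[i] for i in idx],
        groups=dict(table.groups),
    )


def run_pipeline(table, config):
    """Per-group analysis over every treatment group in the table.

    Writes all artifacts under ``config.output_dir`` and returns the dict
    of :class:`GroupResult` keyed by group label.  Deterministic given
    ``config.seed`` (per-group sub-seeds are spawned from it).
    """
    groups = table.group_labels()
    if not groups:
        raise ContractError("table has no group labels")
    os.makedirs(config.output_dir, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    subs = ss.spawn(len(groups))
    results = {}
    summary_rows = []
    for sub, grp in zip(subs, groups):
        gtable = table.subset_group(grp)
        try:
            res = analyze_group(gtable, config,
                                seed=int(sub.generate_state(1)[0] % (2 ** 31)))
        except MenaError as exc:
            raise type(exc)(f"[group {grp}] {exc}") from exc
        res.group = grp
        results[grp] = res
        _write_group_outputs(res, gtable, config)
        pos, neg = edge_sign_counts(res.network)
        summary_rows.append((grp, res.network.number_of_nodes(),
                             res.partition.n_modules, pos, neg, pos + neg))
    _write_tsv(os.path.join(config.output_dir, "summary.tsv"),
               ["group", "n_nodes", "n_modules", "positive_edges",
                "negative_edges", "total_edges"], summary_rows, config)
    return results


def _write_group_outputs(res, gtable, config):
    out = config.output_dir
    grp = res.group
    div_rows = [(d["sample"], d["group"], d["observed_otus"],
                 f"{d['chao1']:.2f}", f"{d['ace']:.2f}",
                 f"{d['shannon']:.4f}", f"{d['goods_coverage']:.2f}")
                for d in res.diversity]
    _write_tsv(os.path.join(out, f"{grp}.diversity.tsv"),
               ["sample", "group", "observed_otus", "chao1", "ace",
                "shannon", "goods_esc"], div_rows, config)
    write_threshold_scan(res.scan, os.path.join(out, f"{grp}.scan.tsv"),
                         config)
    write_edge_list(res.network, os.path.join(out, f"{grp}.edges.tsv"),
                    config)
    write_graphml(res.network, os.path.join(out, f"{grp}.graphml"))
    tax = dict(zip(gtable.otu_ids, gtable.taxonomy))
    role_rows = []
    for r in res.roles:
        parts = parse_lineage(tax.get(r["node"], ""))
        cls = parts[2] if len(parts) > 2 else ""
        role_rows.append((r["node"], r["module"], f"{r['zi']:.4f}",
                          f"{r['pi']:.4f}", r["role"],
                          f"{res.memberships.get(r['node'], float('nan')):.4f}",
                          cls))
    _write_tsv(os.path.join(out, f"{grp}.roles.tsv"),
               ["otu", "module", "zi", "pi", "role", "module_membership",
                "class"], role_rows, config)
    null_rows = [(n.index, f"{n.observed:.6f}", f"{n.null_mean:.6f}",
                  f"{n.null_sd:.6f}", f"{n.z_score:.4f}", f"{n.p_value:.4g}",
                  n.n_random, n.swaps_per_edge, int(n.degenerate))
                 for n in res.null_reports]
    _write_tsv(os.path.join(out, f"{grp}.nulls.tsv"),
               ["index", "observed", "null_mean", "null_sd", "z",
                "p_value", "n_random", "swaps_per_edge", "degenerate"],
               null_rows, config)
    rel = to_relative(gtable)
    ab = dict(zip(rel.otu_ids, rel.values.mean(axis=1)))
    export_circos_tables(
        res.network, res.partition, tax,
        os.path.join(out, f"{grp}.circos_bands.tsv"),
        os.path.join(out, f"{grp}.circos_links.tsv"),
        config=config, abundance=ab)
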