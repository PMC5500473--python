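"""OTU abundance table containers and I/O.

Supports the QIIME-classic tab-separated OTU table (``#OTU ID`` header row,
optional trailing ``taxonomy`` column) and BIOM 1.0 JSON (sparse or dense),
plus a two-column sample metadata table mapping sample id to treatment group.
Counts are kept as integers; relative abundances as floats.  No rarefaction
is applied anywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateInputError, FormatError

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class AbundanceTable:
    """OTU x sample matrix of nonnegative integer counts.

    Parameters
    ----------
    otu_ids : list of str
        Unique OTU identifiers (rows).
    sample_ids : list of str
        Unique sample identifiers (columns).
    counts : ndarray of int, shape (n_otus, n_samples)
    taxonomy : list of str
        Per-OTU semicolon-delimited lineage (kingdom..species); ranks may be
        empty and the whole string may be ``""`` when unknown.
    groups : dict
        Maps sample_id -> treatment label; may cover a subset of samples.
    """

    otu_ids: list
    sample_ids: list
    counts: np.ndarray
    taxonomy: list = field(default_factory=list)
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ContractError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ContractError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.otu_ids)}, {len(self.sample_ids)})"
            )
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ContractError(f"negative count at OTU {self.otu_ids[i]!r}, "
                                f"sample {self.sample_ids[j]!r}")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ContractError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ContractError("duplicate sample ids")
        if not self.taxonomy:
            self.taxonomy = [""] * len(self.otu_ids)
        if len(self.taxonomy) != len(self.otu_ids):
            raise ContractError("taxonomy length != number of OTUs")
        unknown = set(self.groups) - set(self.sample_ids)
        if unknown:
            raise ContractError(f"group labels for unknown samples: {sorted(unknown)}")

    @property
    def n_otus(self):
        return len(self.otu_ids)

    @property
    def n_samples(self):
        return len(self.sample_ids)

    def group_labels(self):
        """Distinct treatment labels in insertion order."""
        seen = {}
        for s in self.sample_ids:
            if s in self.groups:
                seen.setdefault(self.groups[s], None)
        return list(seen)

    def subset_samples(self, sample_ids):
        """Return a new table restricted to the given samples (order kept)."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(
            otu_ids=list(self.otu_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            taxonomy=list(self.taxonomy),
            groups={s: g for s, g in self.groups.items() if s in sample_ids},
        )

    def subset_group(self, group):
        """Restrict to the samples carrying a given treatment label."""
        keep = [s for s in self.sample_ids if self.groups.get(s) == group]
        if not keep:
            raise ContractError(f"no samples labelled {group!r}")
        return self.subset_samples(keep)

    def filter_prevalence(self, min_prevalence):
        """Drop OTUs present (count > 0) in fewer than ``min_prevalence`` samples."""
        keep = np.flatnonzero((self.counts > 0).sum(axis=1) >= min_prevalence)
        return AbundanceTable(
            otu_ids=[self.otu_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep].copy(),
            taxonomy=[self.taxonomy[i] for i in keep],
            groups=dict(self.groups),
        )

    def __eq__(self, other):
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and self.taxonomy == other.taxonomy
            and self.groups == other.groups
        )


@dataclass
class RelativeAbundanceTable:
    """Same axes as :class:`AbundanceTable`; each sample column sums to 1."""

    otu_ids: list
    sample_ids: list
    values: np.ndarray
    taxonomy: list = field(default_factory=list)
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ContractError("values shape mismatch")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ContractError("relative abundances must lie in [0, 1]")
        colsums = self.values.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = self.sample_ids[int(np.argmax(np.abs(colsums - 1)))]
            raise ContractError(f"sample {bad!r} does not sum to 1")
        if not self.taxonomy:
            self.taxonomy = [""] * len(self.otu_ids)


def to_relative(table):
    """Convert counts to per-sample proportions.

    Raises
    ------
    DegenerateInputError
        If any sample has zero total count.
    """
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise DegenerateInputError(f"sample {bad!r} has zero total count")
    return RelativeAbundanceTable(
        otu_ids=list(table.otu_ids),
        sample_ids=list(table.sample_ids),
        values=table.counts / totals,
        taxonomy=list(table.taxonomy),
        groups=dict(table.groups),
    )


def parse_lineage(taxonomy):
    """Split a lineage string on ';' (optionally followed by whitespace)."""
    if not taxonomy:
        return []
    return [part.strip() for part in taxonomy.split(";")]


def aggregate_by_rank(rel, rank, cutoff=0.0):
    """Sum relative abundances within identical lineage prefixes at ``rank``.

    Rows whose mean relative abundance across samples falls below ``cutoff``
    are pooled into an ``"Other"`` row, mirroring the common "classes above a
    cutoff" barplot convention.  Column sums are preserved.
    """
    if rank not in RANKS:
        raise ContractError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank) + 1
    labels = []
    for tax in rel.taxonomy:
        parts = parse_lineage(tax)[:depth]
        labels.append("; ".join(parts) if any(parts) else "Unclassified")
    order = {}
    for lab in labels:
        order.setdefault(lab, len(order))
    agg = np.zeros((len(order), rel.values.shape[1]))
    for lab, row in zip(labels, rel.values):
        agg[order[lab]] += row
    names = list(order)
    means = agg.mean(axis=1)
    keep = means >= cutoff
    if keep.all():
        out_names, out = names, agg
    else:
        other = agg[~keep].sum(axis=0)
        out_names = [n for n, k in zip(names, keep) if k] + ["Other"]
        out = np.vstack([agg[keep], other])
    return RelativeAbundanceTable(
        otu_ids=out_names,
        sample_ids=list(rel.sample_ids),
        values=out,
        taxonomy=list(out_names),
        groups=dict(rel.groups),
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_table(path, format="tsv_classic"):
    """Read an OTU table from ``tsv_classic`` or ``biom_json``."""
    if format == "tsv_classic":
        return _read_tsv_classic(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ContractError(f"unknown format {format!r}")


def write_table(table, path, format="tsv_classic"):
    if format == "tsv_classic":
        return _write_tsv_classic(table, path)
    if format == "biom_json":
        return _write_biom_json(table, path)
    raise ContractError(f"unknown format {format!r}")


def _read_tsv_classic(path):
    header = None
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if header is None:
                if line.startswith("#OTU ID"):
                    header = line.split("\t")
                    continue
                if line.startswith("#"):
                    continue  # pre-header comment, e.g. "# Constructed from biom"
                raise FormatError(
                    f"{path}:{lineno}: expected '#OTU ID' header, got {line!r}")
            if line.startswith("# "):
                continue
            rows.append((lineno, line.split("\t")))
    if header is None:
        raise FormatError(f"{path}: no '#OTU ID' header line found")
    has_tax = header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1:-1] if has_tax else header[1:]
    otu_ids, taxonomy, counts = [], [], []
    ncol = len(header)
    for lineno, fields in rows:
        if len(fields) != ncol:
            raise FormatError(
                f"{path}:{lineno}: expected {ncol} fields, got {len(fields)}")
        otu_ids.append(fields[0])
        tax = fields[-1] if has_tax else ""
        taxonomy.append(tax)
        vals = fields[1:-1] if has_tax else fields[1:]
        row = []
        for j, v in enumerate(vals):
            try:
                x = float(v)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric count {v!r} for OTU "
                    f"{fields[0]!r}, sample {sample_ids[j]!r}") from None
            if x < 0 or x != int(x):
                raise FormatError(
                    f"{path}:{lineno}: invalid count {v!r} for OTU "
                    f"{fields[0]!r}, sample {sample_ids[j]!r}")
            row.append(int(x))
        counts.append(row)
    return AbundanceTable(
        otu_ids=otu_ids,
        sample_ids=list(sample_ids),
        counts=np.asarray(counts, dtype=np.int64).reshape(len(otu_ids), len(sample_ids)),
        taxonomy=taxonomy,
    )


def _write_tsv_classic(table, path):
    with open(path, "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
        for otu, row, tax in zip(table.otu_ids, table.counts, table.taxonomy):
            fh.write(otu + "\t" + "\t".join(str(int(v)) for v in row)
                     + "\t" + tax + "\n")


def _read_biom_json(path):
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from None
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise FormatError(f"{path}: BIOM document missing {key!r}")
    n, m = doc["shape"]
    otu_ids = [r["id"] for r in doc["rows"]]
    taxonomy = []
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy", "")
        if isinstance(tax, list):
            tax = "; ".join(tax)
        taxonomy.append(tax)
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = np.zeros((n, m), dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            _check_biom_count(path, v, otu_ids[i], sample_ids[j])
            counts[i, j] = int(v)
    elif doc["matrix_type"] == "dense":
        for i, row in enumerate(doc["data"]):
            for j, v in enumerate(row):
                _check_biom_count(path, v, otu_ids[i], sample_ids[j])
                counts[i, j] = int(v)
    else:
        raise FormatError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    return AbundanceTable(otu_ids=otu_ids, sample_ids=sample_ids,
                          counts=counts, taxonomy=taxonomy)


def _check_biom_count(path, v, otu, sample):
    if not isinstance(v, (int, float)) or v < 0 or v != int(v):
        raise FormatError(
            f"{path}: invalid count {v!r} for OTU {otu!r}, sample {sample!r}")


def _write_biom_json(table, path):
    rows = [{"id": o, "metadata": {"taxonomy": t}}
            for o, t in zip(table.otu_ids, table.taxonomy)]
    cols = [{"id": s, "metadata": None} for s in table.sample_ids]
    data = [[int(i), int(j), int(table.counts[i, j])]
            for i, j in zip(*np.nonzero(table.counts))]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "mena",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": rows,
        "columns": cols,
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_metadata(path):
    """Read a two-column (sample_id, group) TSV into a dict."""
    groups = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            groups[fields[0]] = fields[1]
    return groups


def write_metadata(groups, path):
    with open(path, "w") as fh:
        fh.write("#sample_id\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")
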