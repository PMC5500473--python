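"""Alpha-diversity estimators, Bray-Curtis dissimilarity and classical PCoA.

The estimators operate on a single sample's vector of OTU counts.  Richness
estimators (Chao1, ACE) extrapolate total richness from the frequency counts
of rare OTUs; Good's coverage estimates the fraction of individuals in the
community belonging to already-observed OTUs.  Shannon entropy defaults to
natural log, so values are directly comparable with ln(observed richness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ContractError, DegenerateInputError


def _validate_counts(counts):
    x = np.asarray(counts)
    if x.ndim != 1:
        raise ContractError("expected a 1-D vector of counts for one sample")
    if (x < 0).any():
        raise ContractError("counts must be nonnegative")
    x = x[x > 0]
    if x.size == 0:
        raise DegenerateInputError("all-zero count vector")
    return x.astype(np.int64)


def observed_otus(counts):
    """Number of OTUs with count > 0."""
    return int(_validate_counts(counts).size)


def chao1(counts, bias_corrected=True):
    """Chao1 richness estimate from singleton/doubleton frequencies.

    Bias-corrected form: S_obs + F1*(F1-1) / (2*(F2+1)), defined even when
    there are no doubletons.  The classic form S_obs + F1^2/(2*F2) is
    available with ``bias_corrected=False`` (it falls back to the corrected
    form when F2 = 0, where it is undefined).
    """
    x = _validate_counts(counts)
    s_obs = x.size
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return s_obs + f1 * f1 / (2 * f2)


def ace(counts, rare_cutoff=10):
    """Abundance-based coverage estimator of richness.

    OTUs with count <= ``rare_cutoff`` form the rare class.  With
    C_ace = 1 - F1/N_rare the sample coverage of the rare class,

        S_ace = S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2,

    where gamma^2 is the rare-class coefficient of variation estimate,
    floored at 0.  When every rare OTU is a singleton C_ace = 0 and the
    estimator is undefined; Chao1 is returned instead.
    """
    x = _validate_counts(counts)
    rare = x[x <= rare_cutoff]
    s_abund = int((x > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(x.size)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(counts)
    sum_k = sum(k * (k - 1) * int((rare == k).sum())
                for k in range(1, rare_cutoff + 1))
    gamma2 = (s_rare / c_ace) * sum_k / (n_rare * (n_rare - 1)) - 1.0 \
        if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def shannon(counts, base=None):
    """Shannon entropy H = -sum p_i log p_i over OTUs with p_i > 0.

    Natural log by default; pass ``base`` to change (e.g. 2 for bits).
    """
    x = _validate_counts(counts)
    p = x / x.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def goods_coverage(counts):
    """Good's estimated sample coverage, (1 - F1/N) * 100 (percent)."""
    x = _validate_counts(counts)
    f1 = int((x == 1).sum())
    return (1.0 - f1 / int(x.sum())) * 100.0


def diversity_profile(table):
    """Per-sample diversity indices as a list of dict rows.

    Columns mirror the standard per-sample report: observed OTUs, Chao1,
    ACE, Shannon (nats) and Good's coverage in percent.
    """
    rows = []
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows.append({
            "sample": sample,
            "group": table.groups.get(sample, ""),
            "observed_otus": observed_otus(col),
            "chao1": chao1(col),
            "ace": ace(col),
            "shannon": shannon(col),
            "goods_coverage": goods_coverage(col),
        })
    return rows


def bray_curtis_matrix(rel):
    """Pairwise Bray-Curtis dissimilarity between samples.

    For proportion vectors p, q (each summing to 1) this equals
    1 - sum_i min(p_i, q_i).
    """
    if len(rel.sample_ids) < 2:
        raise ContractError("need at least 2 samples")
    return squareform(pdist(rel.values.T, metric="braycurtis"))


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) output.

    ``coordinates`` has one row per sample; axes are ordered by decreasing
    eigenvalue and only positive-eigenvalue axes are kept.  Negative
    eigenvalues (non-Euclidean distance matrices) are reported separately.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(distances, atol=1e-8):
    """Principal coordinates analysis by classical scaling.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ContractError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ContractError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ContractError("distance matrix must have zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > atol * max(abs(evals[0]), 1.0)
    neg = evals[evals < -atol * max(abs(evals[0]), 1.0)]
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total = evals[pos].sum()
    prop = evals[pos] / total if total > 0 else evals[pos]
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=evals[pos],
        proportion_explained=prop,
        negative_eigenvalues=neg,
    )
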