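"""Correlation networks with random-matrix-theory threshold selection.

The co-occurrence network is built by thresholding a pairwise correlation
matrix of (transformed) OTU abundance profiles.  The threshold is chosen
automatically by scanning candidate cutoffs and testing, at each, whether
the nearest-neighbour spacing distribution (NNSD) of the unfolded eigenvalue
spectrum of the retained correlation submatrix follows Poisson statistics
(uncorrelated eigenvalues, the signature of decoupled modular structure)
rather than the Wigner-Dyson statistics of the Gaussian orthogonal ensemble
(GOE), which characterise a noise-dominated random matrix.  The smallest
cutoff at which the spectrum is Poisson-consistent is taken as the network
threshold; edges keep the sign of the underlying correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator
from sklearn.base import BaseEstimator

from .errors import ContractError, DegenerateInputError
from .io import AbundanceTable, to_relative

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix over OTUs with provenance of its making."""

    otu_ids: list
    values: np.ndarray
    method: str = "pearson"
    transform: str = "log_relative"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.otu_ids), len(self.otu_ids)):
            raise ContractError("correlation matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ContractError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ContractError("correlation matrix diagonal must be 1")
        if (np.abs(v) > 1 + 1e-9).any():
            raise ContractError("correlations must lie in [-1, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = np.clip(v, -1.0, 1.0)
        np.fill_diagonal(self.values, 1.0)


def correlations(table, method="pearson", transform="log_relative",
                 min_prevalence=0):
    """Pairwise correlations of OTU abundance profiles across samples.

    ``transform`` is applied per profile before correlating:

    - ``log_relative``: ln(relative abundance + pseudocount), pseudocount =
      half the smallest nonzero relative abundance in the table;
    - ``relative``: per-sample proportions;
    - ``none``: raw counts.

    OTUs present in fewer than ``min_prevalence`` samples are dropped first.
    Constant profiles get correlation 0 against everything (logged).
    """
    if table.n_samples < 4:
        raise ContractError(
            f"need >= 4 samples for correlations, got {table.n_samples}")
    if table.n_samples < 10:
        logger.warning("only %d samples: correlation estimates will be noisy",
                       table.n_samples)
    if min_prevalence > 0:
        table = table.filter_prevalence(min_prevalence)
    if transform == "log_relative":
        rel = to_relative(table).values
        nz = rel[rel > 0]
        pseudo = nz.min() / 2 if nz.size else 1e-6
        x = np.log(rel + pseudo)
    elif transform == "relative":
        x = to_relative(table).values
    elif transform == "none":
        x = table.counts.astype(float)
    else:
        raise ContractError(f"unknown transform {transform!r}")

    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    elif method != "pearson":
        raise ContractError(f"unknown method {method!r}")

    const = x.std(axis=1) == 0
    if const.any():
        logger.warning("%d constant OTU profiles: correlations set to 0",
                       int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[const, :] = 0.0
    r[:, const] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(otu_ids=list(table.otu_ids), values=r,
                             method=method, transform=transform)


# ---------------------------------------------------------------------------
# spectral unfolding and NNSD model fits
# ---------------------------------------------------------------------------

def unfold_spectrum(eigenvalues, n_knots=None):
    """Unfold a spectrum so the mean level spacing is 1.

    Fits a monotone cubic (PCHIP) estimate of the cumulative spectral
    function through ``n_knots`` quantile knots, maps each eigenvalue
    through it, and returns the successive differences, rescaled to mean 1.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    n = ev.size
    if n < 20:
        raise ContractError(f"need >= 20 eigenvalues to unfold, got {n}")
    if n_knots is None:
        n_knots = max(10, n // 20)
    n_knots = min(n_knots, n)
    # knots at evenly spaced quantiles; x must be strictly increasing
    idx = np.unique(np.linspace(0, n - 1, n_knots).round().astype(int))
    kx, ky = [], []
    for i in idx:
        if kx and ev[i] <= kx[-1]:
            continue
        kx.append(ev[i])
        ky.append(i + 0.5)
    if len(kx) < 3:
        # (near-)fully degenerate spectrum; spacing of ranks is the unfolding
        unfolded = np.arange(n, dtype=float)
    else:
        unfolded = PchipInterpolator(kx, ky)(ev)
    spacings = np.diff(unfolded)
    spacings = np.clip(spacings, 0.0, None)
    mean = spacings.mean()
    if mean <= 0:
        raise DegenerateInputError("degenerate spectrum: zero mean spacing")
    return spacings / mean


class NnsdFit(NamedTuple):
    """Goodness of fit of unfolded spacings to a reference NNSD."""

    statistic: float
    dof: int
    pvalue: float


def _poisson_cdf(s):
    return 1.0 - np.exp(-s)


def _goe_cdf(s):
    # Wigner surmise (pi/2) s exp(-pi s^2 / 4)
    return 1.0 - np.exp(-np.pi * s * s / 4.0)


def nnsd_fit(spacings, model, n_bins=20, s_max=3.0):
    """Chi-square fit of spacings to the Poisson or GOE (Wigner) NNSD.

    Spacings are histogrammed into ``n_bins`` bins on [0, s_max] (the last
    bin absorbs the upper tail); observed counts are compared with the
    model's bin probabilities by Pearson chi-square, after merging bins with
    expected count < 1 into their left neighbour.
    """
    s = np.asarray(spacings, dtype=float)
    if s.size < 20:
        raise ContractError(f"need >= 20 spacings, got {s.size}")
    if model == "poisson":
        cdf = _poisson_cdf
    elif model == "goe":
        cdf = _goe_cdf
    else:
        raise ContractError(f"unknown model {model!r}")
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(s, bins=edges)
    obs = obs.astype(float)
    obs[-1] += (s > s_max).sum()  # tail mass into last bin
    p = np.diff(cdf(edges))
    p[-1] += 1.0 - cdf(np.array([s_max]))[0]
    exp = p * s.size
    # merge bins with expected count < 1 into the previous bin
    m_obs, m_exp = [], []
    for o, e in zip(obs, exp):
        if m_exp and (e < 1.0 or m_exp[-1] < 1.0):
            m_obs[-1] += o
            m_exp[-1] += e
        else:
            m_obs.append(o)
            m_exp.append(e)
    m_obs, m_exp = np.array(m_obs), np.array(m_exp)
    ok = m_exp > 0
    chi2 = float(((m_obs[ok] - m_exp[ok]) ** 2 / m_exp[ok]).sum())
    dof = max(int(ok.sum()) - 1, 1)
    return NnsdFit(statistic=chi2, dof=dof,
                   pvalue=float(stats.chi2.sf(chi2, dof)))


# ---------------------------------------------------------------------------
# threshold scan and network assembly
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Per-candidate NNSD statistics and the automatically chosen threshold."""

    thresholds: list = field(default_factory=list)
    n_nodes: list = field(default_factory=list)
    chi2_poisson: list = field(default_factory=list)
    chi2_goe: list = field(default_factory=list)
    p_poisson: list = field(default_factory=list)
    chosen_threshold: float = float("nan")
    no_transition: bool = False


def scan_threshold(corr, st_min=0.30, step=0.01, min_nodes=50):
    """Scan ascending cutoffs for the GOE-to-Poisson spectral transition.

    At each candidate ``st``: entries with \\|r\\| < st are zeroed, OTUs with
    no surviving off-diagonal entry are dropped, and the NNSD of the
    unfolded spectrum of the retained submatrix is fitted against both
    reference models.  The chosen threshold is the smallest ``st`` whose
    Poisson chi-square does not exceed the GOE chi-square and whose Poisson
    fit p-value is >= 0.05.  The scan stops once fewer than ``min_nodes``
    OTUs survive; if no candidate qualifies, the best (lowest Poisson
    chi-square) candidate is reported with ``no_transition`` set.
    """
    v = corr.values
    scan = ThresholdScan()
    st = st_min
    chosen = None
    while st <= 1.0 + 1e-12:
        mask = np.abs(v) >= st
        np.fill_diagonal(mask, False)
        keep = np.flatnonzero(mask.any(axis=0))
        if keep.size < min_nodes:
            break
        sub = v[np.ix_(keep, keep)].copy()
        sub[np.abs(sub) < st] = 0.0
        np.fill_diagonal(sub, 1.0)
        ev = np.linalg.eigvalsh(sub)
        try:
            spac = unfold_spectrum(ev)
            fit_p = nnsd_fit(spac, "poisson")
            fit_g = nnsd_fit(spac, "goe")
        except (ContractError, DegenerateInputError):
            st = round(st + step, 10)
            continue
        scan.thresholds.append(round(st, 10))
        scan.n_nodes.append(int(keep.size))
        scan.chi2_poisson.append(fit_p.statistic)
        scan.chi2_goe.append(fit_g.statistic)
        scan.p_poisson.append(fit_p.pvalue)
        if chosen is None and fit_p.statistic <= fit_g.statistic \
                and fit_p.pvalue >= 0.05:
            chosen = round(st, 10)
        st = round(st + step, 10)
    if not scan.thresholds:
        scan.no_transition = True
        scan.chosen_threshold = st_min
        logger.warning("threshold scan found no candidate with >= %d nodes",
                       min_nodes)
        return scan
    if chosen is None:
        scan.no_transition = True
        chosen = scan.thresholds[int(np.argmin(scan.chi2_poisson))]
        logger.warning("no GOE-to-Poisson transition detected; "
                       "reporting best candidate %.2f", chosen)
    scan.chosen_threshold = chosen
    return scan


def build_network(corr, threshold):
    """Signed co-occurrence graph: edge iff \\|r\\| >= threshold.

    Edge attributes: ``sign`` (+1/-1 from the correlation sign) and
    ``weight`` = \\|r\\|.  Isolated nodes are dropped.
    """
    if not 0 < threshold <= 1:
        raise ContractError("threshold must lie in (0, 1]")
    v = corr.values
    g = nx.Graph()
    n = len(corr.otu_ids)
    iu, ju = np.triu_indices(n, k=1)
    hits = np.abs(v[iu, ju]) >= threshold
    for i, j in zip(iu[hits], ju[hits]):
        r = v[i, j]
        g.add_edge(corr.otu_ids[i], corr.otu_ids[j],
                   sign=1 if r > 0 else -1, weight=abs(float(r)))
    g.graph["threshold"] = threshold
    return g


def edge_sign_counts(g):
    """(positive, negative) edge counts of a signed graph."""
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    return pos, g.number_of_edges() - pos


class RMTCorrelationNetwork(BaseEstimator):
    """Estimator wrapping correlation + RMT threshold + network assembly.

    Follows the sklearn covariance-estimator idiom: ``fit`` takes a
    samples x OTUs matrix (or an :class:`~mena.io.AbundanceTable`) and
    exposes the fitted correlation matrix, threshold scan and graph as
    trailing-underscore attributes.

    Parameters
    ----------
    method : {'pearson', 'spearman'}
    transform : {'log_relative', 'relative', 'none'}
    min_prevalence : int
        Drop OTUs present in fewer samples than this before correlating.
    st_min, step, min_nodes :
        Threshold-scan controls (start cutoff, increment, node floor).
    threshold : float or None
        If given, skip the scan and threshold at this value.
    """

    def __init__(self, method="pearson", transform="log_relative",
                 min_prevalence=0, st_min=0.30, step=0.01, min_nodes=50,
                 threshold=None):
        self.method = method
        self.transform = transform
        self.min_prevalence = min_prevalence
        self.st_min = st_min
        self.step = step
        self.min_nodes = min_nodes
        self.threshold = threshold

    def fit(self, X, y=None):
        if isinstance(X, AbundanceTable):
            table = X
        else:
            X = np.asarray(X)
            if X.ndim != 2:
                raise ContractError("X must be 2-D (samples x OTUs)")
            table = AbundanceTable(
                otu_ids=[f"OTU{i}" for i in range(X.shape[1])],
                sample_ids=[f"S{j}" for j in range(X.shape[0])],
                counts=X.T,
            )
        self.correlation_ = correlations(
            table, method=self.method, transform=self.transform,
            min_prevalence=self.min_prevalence)
        if self.threshold is not None:
            self.scan_ = None
            self.threshold_ = float(self.threshold)
        else:
            self.scan_ = scan_threshold(
                self.correlation_, st_min=self.st_min, step=self.step,
                min_nodes=self.min_nodes)
            self.threshold_ = self.scan_.chosen_threshold
        self.graph_ = build_network(self.correlation_, self.threshold_)
        self.n_nodes_ = self.graph_.number_of_nodes()
        self.n_edges_ = self.graph_.number_of_edges()
        return self
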