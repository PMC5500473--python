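# Methods

This note records the models, defaults and design choices behind `mena`,
and what the synthetic validation does and does not demonstrate.

## Correlation networks and the RMT threshold

Abundance profiles are transformed to ln(relative abundance + pseudocount)
before correlating (`transform="log_relative"`, the default). The
pseudocount is half the smallest nonzero relative abundance in the group's
table, a standard choice that keeps zeros finite without dominating the
dynamic range. Pearson correlation is the default; Spearman is available.
Correlation requires at least 4 samples and warns below 10 — with few
samples the estimates are noisy and the automatic threshold will drift
upward. Constant profiles get correlation 0 with a logged warning rather
than NaN. An optional prevalence filter (`min_prevalence`) is exposed but
off by default: no rarefaction or prevalence filtering is applied unless
asked for.

The threshold scan zeroes |r| < st, drops OTUs with no surviving
off-diagonal entry, and eigendecomposes the retained correlation submatrix
(not the 0/1 adjacency — the RMT argument concerns the similarity matrix).
The spectrum is unfolded by mapping eigenvalues through a monotone cubic
(PCHIP) fit of the empirical cumulative spectral function over
max(10, n/20) quantile knots, then rescaling spacings to mean 1. Goodness
of fit to the Poisson and Wigner-surmise NNSDs is a Pearson chi-square over
20 bins on [0, 3] (the last bin absorbs the tail; bins with expected count
below 1 are merged leftward). The chosen threshold is the smallest st with
Poisson chi-square ≤ GOE chi-square and Poisson fit p ≥ 0.05; candidates
run from 0.30 in steps of 0.01 until fewer than `min_nodes` (default 50)
OTUs survive. If no candidate qualifies the best Poisson candidate is
reported with a `no_transition` flag instead of failing. Exact chi-square
ties prefer Poisson (accept the threshold); this degenerate case is logged.

We validated the knot rule empirically: on planted tables, denser knots
push the fit toward the genuinely GOE-like short-range correlations of the
mid-scan spectra and do not change the detected transition; the default
rule is kept.

## Modules, indices, roles

Fast-greedy modularity optimisation is the classic agglomerative scheme:
start from singletons, repeatedly apply the merge with the largest
ΔQ = e_AB/L − d_A d_B/(2L²), stop when no merge increases Q. Ties are
broken by the lowest (module id, module id) pair so results are
deterministic; module ids are relabelled contiguously from 0 by first node
in sorted order. Modularity and all indices use the unsigned 0/1 adjacency;
edge signs are carried as attributes only (signed modularity is out of
scope). GD averages shortest-path lengths over connected pairs only, so
disconnected networks are handled naturally.

Zi uses the population standard deviation of intra-module degrees
(Guimerà–Amaral convention) and is set to 0 when that sd is 0, which
avoids infinities in tiny modules. Isolated nodes get Zi = Pi = 0 with a
warning. Role boundaries (2.5 for Zi, 0.62 for Pi) are closed on the
lower side: a node exactly at a boundary falls in the ≤ branch.

Module membership follows the eigengene idiom: per-OTU z-scored module
submatrix, first right-singular vector as the module's consensus sample
profile, membership = Pearson correlation of each OTU with it, eigengene
sign fixed so mean membership ≥ 0. Constant profiles get membership 0.

## Null models

Maslov–Sneppen randomisation attempts `swaps_per_edge × L` double-edge
swaps ((a,b),(c,d) → (a,d),(c,b)), rejecting self-loops and duplicates, so
the degree sequence is preserved exactly. Edge signs are then reassigned
by random permutation, preserving the positive/negative counts. Graphs
admitting no legal swap (stars, triangles) are returned unchanged with a
warning. The significance test draws `n_random` (default 100) rewired
networks from sub-seeds spawned deterministically from the user seed,
recomputes GD, avgCC and modularity on each — modularity via a *fresh*
fast-greedy partition per null network, the statistically coherent choice
since the observed Q is also the result of a search — and reports
two-tailed normal Z-test p-values. A null ensemble with zero variance is
reported as p = 1 with a `degenerate` flag. Defaults
`swaps_per_edge = 100, n_random = 100` are conventional and configurable.

## Diversity and growth

Chao1 defaults to the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)),
defined even when F2 = 0; the classic form is available by flag. ACE uses
the standard rare-class cutoff of 10 and falls back to Chao1 when the rare
class is all singletons (C_ace = 0). Shannon entropy uses the natural log
by default — the conventional base is not universal, so the base is a
parameter; natural log makes values directly comparable to ln(richness).
Good's coverage is reported as a percentage. Ordination is classical
scaling (double-centre −D²/2, eigendecompose); negative eigenvalues are
dropped and reported separately, and UniFrac is out of scope (no
phylogenetic tree handling) — Bray–Curtis is the provided dissimilarity.

SGR group comparisons operate on replicate-level SGRs, not the SGR of mean
weights. Duncan's multiple range test uses the protected significance
levels α_p = 1 − (1−α)^(p−1) with studentized-range quantiles, the
harmonic mean group size for unbalanced designs, and the step-down rule
(a non-significant span is declared homogeneous and not subdivided); the
result is a compact letter display.

## Synthetic data: what it emulates, and what it does not

`PlantedDesign` draws one standard-normal latent factor per module per
sample. A module member's log-abundance is a·f + e with a = √(ρ/(1−ρ)),
so the expected pairwise within-module correlation of log-abundances is
ρ (`within_module_corr`). A fraction `negative_fraction` of member
loadings is negated; flipping a fraction f makes 2f(1−f) of within-module
pairs negatively associated, and the default f = 0.3 yields ≈ 42%
negative pairs, matching the negative-edge share observed in published
gut-microbiota co-occurrence networks of this kind. One hub per module
gets its loading multiplied by `hub_boost` (default 1.5). Connectors load
evenly on `connector_span` modules; the default span of 3 is deliberate —
even loading on k modules bounds the participation coefficient near
1 − 1/k, and k ≥ 3 is needed for a connector to clear the 0.62 role
threshold. Latent values are standardised, mapped to log-normal marginals
(default ln-mean 3, ln-sd 1), multiplied by a per-sample depth uniform in
[0.5, 1.5] × nominal, and rounded to integers; rounding can zero out rare
OTUs and the generator reports the realised sparsity.

Defaults (600 OTUs = 4 modules of 120 + 2 connectors + 118 noise OTUs,
50 samples, ρ = 0.9) emulate the scale of a thresholded single-group
co-occurrence network. Recovery experiments and the acceptance script run
a scaled problem of 300 OTUs (4 × 60, ~19% noise), which keeps the full
five-seed pipeline under ten seconds; partition recovery is equally strong
at both scales.

Recovery is scored as the adjusted Rand index between the fast-greedy
partition and the planted one **over network nodes that belong to planted
modules**: background-noise OTUs have no planted module to recover, and
which of them survive thresholding is arbitrary.

What passing does *not* show: the generator is compositional only through
the closure step (relative abundance), has Gaussian factor structure, a
single abundance scale, light-tailed module-size distribution and
placeholder taxonomy. Real 16S tables have far heavier taxon-abundance
tails, thousands of rare OTUs, sequencing-depth artefacts and phylogenetic
correlation that the generator does not emulate; recovery here validates
the algorithmic chain, not performance on real data.

## Known limitations

- The mapping from planted structure to network is attenuated by count
  rounding, the pseudocount and compositional closure: realised
  within-module correlations average ~0.80–0.88 when ρ = 0.9.
- The automatically chosen threshold rises with table size (more OTU pairs
  mean more extreme noise correlations). A connector loading evenly on
  k modules can correlate with any single module's members at most
  √ρ/√k (≈ 0.55 for ρ = 0.9, k = 3), so on large tables the RMT threshold
  approaches this ceiling and planted connectors become marginal in the
  recovered network — a genuine property of the model, visible in the
  default 600-OTU design and the reason recovery experiments report the
  median connector Pi.
- Fast-greedy modularity is a greedy heuristic: on planted tables it
  occasionally peels part of a module into a neighbouring community
  (observed ARI ≈ 0.81–0.84 in roughly 1 seed in 8), which is why the
  recovery claim is stated over seeds with one failure allowed.
- The NNSD chi-square is computed on binned spacings; for spectra near the
  Poisson/GOE crossover the p ≥ 0.05 criterion can flicker between
  adjacent thresholds. The full scan table is exported so the transition
  region can be inspected.
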