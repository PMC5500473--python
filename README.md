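# mena

Molecular ecological network analysis of microbial communities.

Gut microbiomes are more than species lists: the co-occurrence structure of
their members — who rises and falls with whom across hosts — carries
information about cooperation, competition, and the stability of the
community. `mena` takes an OTU abundance table (QIIME-classic TSV or BIOM
JSON) and builds, per treatment group, a **signed co-occurrence network**
whose correlation threshold is chosen automatically by a random-matrix-theory
(RMT) criterion, decomposes it into **modules** by fast-greedy modularity
optimisation, classifies every node's **topological role** from its
within-module degree z-score (*Zi*) and participation coefficient (*Pi*),
and tests the network indices against **Maslov–Sneppen degree-preserving
null models**. The package also provides the alpha-diversity estimators
(observed OTUs, Chao1, ACE, Shannon, Good's coverage), Bray–Curtis + PCoA
ordination, and growth statistics (specific growth rate, one-way ANOVA,
Duncan's multiple range test) that typically accompany such studies, and a
synthetic-data generator that plants known modular structure so the whole
pipeline can be validated without sequencing data.

It is aimed at microbial ecologists comparing community organisation across
treatments (probiotics, antibiotics, diets) rather than just composition.

## The model in brief

- **Network inference.** Pairwise Pearson correlation of
  ln(relative abundance + pseudocount) profiles across a group's samples.
  For ascending candidate thresholds *st*, entries with |r| < *st* are
  removed and the nearest-neighbour spacing distribution (NNSD) of the
  unfolded eigenvalue spectrum of the retained matrix is fitted against the
  Gaussian orthogonal ensemble (Wigner surmise,
  p(d) = (π/2) d exp(−π d²/4)) and Poisson (p(d) = e^(−d)) references.
  The chosen threshold is the smallest *st* whose spectrum is
  Poisson-consistent — the RMT signature that system-specific modular
  structure has decoupled from noise. Edges keep the correlation sign.
- **Modules.** Agglomerative fast-greedy maximisation of Newman modularity
  Q = Σ_s [l_s/L − (d_s/2L)²] on the unsigned adjacency.
- **Roles.** Zi = (k_is − mean k_s)/sd k_s, Pi = 1 − Σ_t (k_it/k_i)²;
  peripherals (Zi ≤ 2.5, Pi ≤ 0.62), connectors (Zi ≤ 2.5, Pi > 0.62),
  module hubs (Zi > 2.5, Pi ≤ 0.62), network hubs (Zi > 2.5, Pi > 0.62).
  Module membership is each OTU's signed correlation with its module
  eigengene (first singular vector of the standardised module submatrix).
- **Significance.** Observed GD (average path distance), avgCC (mean
  clustering coefficient) and modularity are compared with an ensemble of
  degree-preserving double-edge-swap rewirings via a two-tailed Z-test.
- **Growth.** SGR = (ln W_t − ln W_0) × 100 / t (% per day), one-way ANOVA,
  and Duncan's multiple range test with a compact letter display.

## Worked example

```python
from mena import (PlantedDesign, generate_table, correlations,
                  scan_threshold, build_network, fast_greedy_modules,
                  network_indices, node_roles, null_model_test,
                  edge_sign_counts)

design = PlantedDesign(n_otus=300, module_sizes=(60,) * 4, seed=1)
table, truth = generate_table(design)            # counts + ground truth
corr = correlations(table)                       # Pearson on ln(rel. ab.)
scan = scan_threshold(corr)                      # RMT threshold scan
net = build_network(corr, scan.chosen_threshold)
part = fast_greedy_modules(net)
idx = network_indices(net, part)
```

prints (via the obvious formatting):

```
threshold      : 0.36
nodes / edges  : 282 / 7698 (4529 positive, 3169 negative)
modules        : 6  (Q = 0.694)
avgK / GD / CC : 54.60 / 2.24 / 0.87
roles          : {'peripheral': 280, 'connector': 2}
gd         obs=2.243 null=1.932+/-0.004 z=70.5
avg_cc     obs=0.867 null=0.241+/-0.006 z=113.2
modularity obs=0.694 null=0.084+/-0.002 z=264.8
```

The scan settles at |r| ≥ 0.36; the surviving network keeps the four
planted 60-OTU modules (the two extra modules are small noise-OTU
fragments), a ~40% share of negative edges reflecting the planted
sign-flipped loadings, and the two planted connectors are the only nodes
with Pi above 0.62. All three indices sit far outside the rewired-null
distribution (z ≫ 3), as expected for strongly modular structure.

The same analysis is available from the shell:

```bash
mena simulate --seed 1 --output-dir sim/
mena all sim/Control.otu_table.tsv --metadata sim/metadata.tsv --output-dir out/
mena report growth_records.tsv          # SGR + ANOVA + Duncan letters
```

Every output file carries a provenance header with the package version,
seed and all parameters.

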