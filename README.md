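# xgakit

Analysis toolkit for **pooled combinatorial-knockout genetics** ("X-gene"
genetic analysis, XGA): experiments in which thousands of barcoded yeast
strains, each deleted for a random subset of up to 16 genes (here, ABC
transporters), compete in liquid pools under a panel of drugs, and strain
abundances are tracked by barcode sequencing (BarSeq) over time. From the
raw tagged reads to interpretable mechanistic models, the package covers:

- **simdata** — a synthetic-experiment generator with known ground truth at
  every stage: 1:1-segregating 16-locus genotypes (with optional weak
  linkage), 25-nt UP/DN strain tags, competitive pool growth over
  timepoints of 0/5/10/15/20 pool generations, multinomial sequencing
  depth, read errors, plate OD curves and qPCR tables.
- **barcodes** — exact-tag demultiplexing, mismatch-tolerant strain
  identification (≤ 2 mismatches, runner-up ≥ 2 further away), count
  assembly with sample floors and UP/DN consistency checks, a
  threshold-based genotype caller, and the asymmetric genotyping-accuracy
  estimator.
- **fitness** — frequency normalization, growth-rate estimation by matching
  the observed area under the frequency-abundance curve, resistance
  r = g_drug / g_solvent, count/baseline filters, between-pool rescaling,
  and the liquid-growth (IC50) and qPCR helper calculations.
- **epistasis** — the multiplicative genetic-effects model
  r̂ = exp(Σ l_i + Σ ε_J + c_d + b_p), fit as a Gaussian GLM with log link;
  marginal-association, stepwise-expansion (2–5-way) and Bonferroni
  elimination; 2^k grouped combinatorial profiles with Mann-Whitney
  adjacency tests and wheel-path tables.
- **nnmodel** — the interpretable genotype → activity → resistance network:
  sigmoid activity nodes gated to 0 for knocked-out genes, signed
  "influence" weights I between transporters, non-negative "efflux"
  weights E to each drug, L1 sparsity, multi-run merging with a |Z|
  reproducibility filter, paired-rank-test pruning, λ search, the
  always-present hidden-factor extension, and the three-layer
  influence-mediator extension with model-derived activity ratios.
- **cli** — `xgakit simulate | map | fitness | epistasis | netfit | report`
  over a JSON/YAML config, writing TSV tables and JSON manifests.

## The model in brief

A strain's abundance in a competitive pool follows A_t = A_0 · 2^(g t),
with t in *pool generations* (doublings of the whole pool) and g the
strain's relative rate (g = 1 ⇔ keeps pace with the pool). Growth is
estimated by solving

∫₀ᵀ f(t)·2ᵗ dt = f₀ · (2^(ĝT) − 1) / (ĝ ln 2)

for ĝ, where f(t) is the measured strain frequency, linearly interpolated
between timepoints. Resistance is r = ĝ_drug / ĝ_DMSO.

Multi-knockout resistance defaults to the product of single-knockout
resistances; interaction terms ε_J = log(r_observed / r̂_multiplicative)
capture deviations, fit jointly to any order up to 5.

The network model predicts normalized resistance as
R̂_d = σ(Σ_j A_j E_{j,d} + B_d) with A_j = σ(Σ_{i≠j} I_{i,j} G_i + B_{A,j}) · G_j,
so that a knocked-out transporter contributes exactly nothing, every
activity node is attached to a named gene, and the learned I/E supports
read directly as regulatory-influence and efflux-capability maps.

## Worked example

```python
import numpy as np, pandas as pd
from xgakit import simdata, fitness, epistasis

strains = simdata.simulate_population(n_strains=2000, seed=7)
truth   = simdata.simulate_truth(n_drugs=4, n_influences=3, n_effluxes=8, seed=7)
counts  = simdata.simulate_pool_counts(strains, truth, depth=10**6, seed=7)
result  = fitness.growth_and_resistance(counts)
print(result.r.head(3).round(3))
```

```
        drug01  drug02  drug03  drug04
S00000   0.735   0.764   0.511   1.121
S00001   0.964   0.598   1.059   0.140
S00002   0.357   0.480   0.549   0.852
```

All 2,000 strains pass the t=0 count and baseline-growth filters at this
depth. The planted truth gives drug01 four parallel effluxers
(transporters 9, 10, 12, 13 with E between 2.6 and 3.5) and an
inhibitory influence of gene 7 on transporter 10 (I = −1.99). The
interaction search reads that architecture back out of the pool data:

```python
masks = pd.DataFrame({s.strain_id: s.knockout_mask for s in strains}).T.astype(int)
y     = np.clip(result.r["drug01"].to_numpy(float), 1e-10, None)
model = epistasis.stepwise_expansion(y, masks.loc[result.r.index].to_numpy())
print(model.coefficients[["term", "order", "estimate", "p"]].head(7).round(4))
```

```
   term  order  estimate      p
   (7,)      1    0.0662 0.0000
   (9,)      1   -0.0643 0.0000
  (10,)      1   -0.0415 0.0000
  (12,)      1   -0.3757 0.0000
  (13,)      1   -0.0527 0.0000
 (7, 9)      2    0.0390 0.0000
(7, 10)      2   -0.0704 0.0000
```

Knockouts of the four effluxers are sensitivities (negative l, strongest
for the highest-E transporter 12), knocking out the inhibitor gene 7
*increases* resistance (positive l), and the model continues into the
negative pairwise terms characteristic of parallel efflux — 25 significant
terms up to order 4 in this drug, all Bonferroni-controlled.

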