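# Methods

This note documents the models implemented in xgakit, the conventions and
defaults they use, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Pool-growth model and the growth estimator

**Convention.** Time is counted in *pool generations*: timepoint τ means
the pool in that condition has doubled τ times. A strain's relative growth
rate g is doublings per pool generation, so g = 1 is a strain that exactly
keeps pace with its pool. The default timepoints are {0, 5, 10, 15, 20},
matching a protocol in which each passage grows the culture from a fixed
starting density to a fixed final density (~5 doublings) before dilution.

**Estimator.** With strain frequencies f(t) measured per sample and the
pool expanding as 2^t, the observed area under the abundance curve is
∫₀ᵀ f(t)·2ᵗ dt with f piecewise-linear between timepoints; each segment is
integrated in closed form (∫(a+bt)2ᵗ dt = 2ᵗ((a+bt)/ln2 − b/ln2²)). The
growth rate ĝ solves

    ∫₀ᵀ f(t) 2ᵗ dt = f₀ (2^(ĝT) − 1)/(ĝ ln 2),

found by bounded scalar minimization of the squared residual on
ĝ ∈ [−10, 10] (xatol 1e-10); the right-hand side is strictly increasing in
ĝ so the solution is unique, and the ĝ → 0 limit (f₀·T) is evaluated
explicitly. For downstream modeling ĝ is floored at 1e-10. A constant
frequency series yields ĝ = 1 exactly under this form. (An alternative
normalization that divides the right-hand side by T additionally would
change all ĝ by a drug-independent rescaling; the form above is the one
consistent with the antiderivative.)

**Interpolation bias.** Linear interpolation of a frequency curve that
decays ≥ 16-fold per sampling interval overestimates the integral
substantially: a strain at constant absolute abundance (g = 0) is
estimated at ĝ ≈ 0.12 with 5-generation spacing, converging to 0 as the
grid refines. For g in the working range [0.6, 1.4] the bias is under
0.015. This is a property of the definition, verified against adaptive
quadrature, and is documented rather than corrected.

**Filters.** Strains need a mean t = 0 solvent count (over available tags)
of at least 30 (inclusive), and a solvent growth rate of at least 70% of
the median over count-passing strains. Defaults: `min_t0_count=30`,
`baseline_fraction=0.7`, sample floor 200,000 mapped reads (scaled down on
fixtures).

**Resistance.** r = ĝ_drug / ĝ_DMSO; per-drug normalized resistance is
r / max(r), floored at 1e-10, which places it in (0, 1] for the network
model. Because every rate is measured relative to its own pool, r carries
a per-drug scale factor (the pool-typical strain defines 1); the
between-pool rescaling step (OLS of one pool's 2^k genotype-group means on
the other's, applied per drug) removes relative scale between mating
pools, but the absolute per-drug scale is not identifiable from pool data
alone. Grouped means are used because strains are not shared across pools.

## Synthetic experiments

The generator emulates: 1:1 segregation at 16 loci (independent Bernoulli
0.5 per locus, with optional weakly linked pairs drawn from a joint
Bernoulli hitting a requested Pearson correlation — the default study
condition links one pair at r = 0.49); unique 25-nt UP/DN tags with a
minimum pairwise Hamming distance of 5 within a pool so that two-mismatch
matching is well-posed; mating pools split 50/50 and arrayed on 96-well
plates; competitive growth; two independent t = 0 runs; multinomial
sequencing counts per tag at configurable depth; per-base substitution
errors in reads; logistic plate OD curves with a sigmoidal dose response;
and qPCR Cq tables.

**Competitive growth.** Each condition's pool is passaged to fixed density,
so the timepoint label τ counts that pool's own doublings. Frequencies at
label τ are the exponential abundances at the real time T solving
Σ_s f₀ₛ 2^(gₛT) = 2^τ. This choice is faithful to the protocol and makes
the per-drug distortion of estimated resistance a multiplicative factor
(absorbed by the interaction model's per-drug intercept). A naive shared
clock instead yields an additive per-drug offset whose log-curvature
masquerades as tiny spurious interaction terms (ε ~ 0.01–0.02) at deep
sequencing depth — an instructive failure mode, not used.

**Drug effect direction.** g_drug = r_true × g_solvent, so the estimator's
ratio recovers r_true (to within the pool-relative scale above); under the
default conditions (effects expressed as knockout sensitivities, true r in
(0, 1]) recovery is within ±0.05 for > 95% of strains at depth 10⁶.

**Ground-truth networks.** `simulate_truth` draws sparse efflux positions
first and targets influence links at transporters that carry efflux, so
every planted influence is identifiable in principle. Default magnitudes
(E in [1.5, 4], |I| in [0.8, 2], drug offsets B_d in [−2, 0]) give each
drug a realistic dynamic range — baseline (transporter-less) resistance
σ(B_d) ∈ [0.12, 0.5] and effluxer-carrying strains approaching 1 — rather
than compressing the pool into the saturated top of the dose-response
sigmoid, where influence effects would be invisible. Phenotype noise is
log-normal with sd 0.03.

**Not emulated:** PCR amplification bias, chimeras, index hopping, lag
phases, saturation effects in pool growth, or count overdispersion beyond
multinomial. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated generative model, not robustness to every
artifact of real sequencing data.

**Dose-response curves.** `simulate_plate_growth` uses a logistic in
*linear* concentration, symmetric about the IC50, so the downstream
linear-interpolation IC50 readout is unbiased on symmetric concentration
grids; concentration 0 is defined as exactly the solvent curve. The
saturation-time detector takes windowed first and second derivatives
(window 4 readings) and reports the extreme curvature in the deceleration
phase — for a logistic with midpoint m and scale s this sits at
m + 1.317 s analytically; a literal global-argmax mode is available behind
a flag.

## Genetic-effects model and interaction search

The multiplicative null for a knockout combination is the product of
single-knockout resistances; ε_J = log(r_obs / r̂_mult). Jointly:
r̂ = exp(Σ l_i + Σ ε_J + c_d + b_p). The GLM uses Gaussian error with a log
link (ε is defined on observed r, which is floored near 0; a log-normal
alternative — OLS on ln r — is behind `family="lognormal"`). Per-term
significance uses Wald chi-square, which coincides with Type-III marginal
tests for these single-degree-of-freedom indicator/product terms. Plate
biases are always included when plate labels are supplied, never tested.

Search protocol per drug: (1) *marginal association* — all 16
single-knockout terms, eliminate the worst until every survivor passes
p ≤ 0.05/16; (2) *stepwise expansion* — for n = 2…5, propose all n-way
products among genes currently in the model, drop terms with p > 0.05 in
one pass; (3) *final elimination* at p ≤ 0.05/k where k counts all 1–5-gene
combinations among the marginal genes. Elimination ties break toward the
larger subset, then lexically. Degenerate subsets (no observed strains)
are inestimable and reported absent, never imputed.

**Known blind spot.** A positive pair interaction with ε ≈ −2l cancels a
member gene's marginal effect, so the gene never enters the marginal set
and the interaction cannot be proposed — an intrinsic limitation of any
marginal-first hierarchical search.

## Network model

Forward pass: A_j = σ(Σ_{i≠j} I_{i,j} G_i + B_{A,j}) · G_j and
R̂_d = σ(Σ_j A_j E_{j,d} + B_d), all outputs in [0, 1]. Self-influence is
structurally absent; E ≥ 0 is enforced by projection after every optimizer
step; gating makes a knocked-out transporter contribute exactly nothing.

**Training.** Mini-batch Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) on MSE against
normalized resistance; batches are 30% of the training split, 10% of the
data is held out for monitoring only (no early stopping), 10,000 epochs by
default and learning rate 0.05 (0.01 for single-drug fits, which lowers
between-run variance). Reduced-epoch settings (~1,000) are used throughout
the test suite; at the suite's data sizes (≈ 24k observations) training
converges well before that. L1 regularization with coefficient λ applies
to I and B_A only and enters twice: as a subgradient in the gradient
(giving, under Adam's normalization, a constant-magnitude pull toward
zero) and as a proximal soft-threshold after each step (converting the
residual oscillation around zero into exact zeros). Initialization is
fan-balanced uniform, with |init| for E so the constraint holds from step
one. Run i of n seeds its generator with seed + i, making every run
independently reproducible.

**Merging and pruning.** Ten runs are merged element-wise: mean with a
reproducibility filter |Z| = |mean|/sd ≥ 4 (sd = 0 with non-zero mean
counts as infinitely reproducible; sd at rounding noise relative to the
mean is treated as zero), or median without the Z filter for the
three-layer architecture. Each surviving non-zero weight is then tested
for predictive value: squared residuals with and without the weight,
restricted to observations differing beyond 1e-4, compared by a paired
two-sided Wilcoxon signed-rank test (exact p for ≤ 25 informative pairs,
normal approximation beyond); keep iff p < 0.05/k with k the number of
non-zero weights. Weights whose removal changes no prediction are zeroed
outright. Merging, the Z filter, and pruning apply uniformly to all
parameter tensors (I, E, B_A, B_d).

**λ selection.** `lambda_search` runs the full train/merge/prune stack per
grid point and reports post-prune MSE and support size; a helper flags the
largest λ before an MSE jump exceeding a configurable factor. The
appropriate λ is dataset-dependent: 5e-4 is the documented default for
multi-drug two-layer fits at full scale, 1e-5 for the three-layer
architecture, and the search on this package's synthetic class (8 drugs ×
3,000 strains) also lands at 1e-5 — at that scale the Z filter and
predictive pruning carry most of the sparsity burden.

**Extensions.** The always-present factor adds one genotype slot fixed at
1 with its own influence column and row, activity offset, and efflux row;
its gate can never be zeroed. The three-layer (mediator) model restricts
the genotype to ≤ 5 focal loci and a single focal activity, which receives
direct influences I₁ plus a weighted input from a mediator node
A′ = σ(Σ I₂ G + B_{A′}); λ applies to I₁, I₂, B_{A′} and the focal B_A but
not to the mediator-to-activity weight. The mediator parameterization has
an exact sign symmetry ((w, I₂, B_{A′}) ↔ (−w, −I₂, −B_{A′}) with an
activity-bias shift, since σ(−x) = 1 − σ(x)); every run is canonicalized
to w ≥ 0 before merging, otherwise element-wise statistics mix the two
branches and produce a non-functional merged model. Activity ratios
(predicted fold change of the focal activity versus the all-present
genotype) are computed on the ungated sigmoid; `indirect_only` zeroes I₁
in both numerator and denominator, leaving only the mediator path.

**Identifiability note.** Several influences converging on one activity
node saturate its sigmoid near a rail, making individual weights nearly
redundant at the wild-type corner; recovery tests plant such architectures
with the factor's baseline offset in the responsive range, mirroring
systems where each additional knockout produces a graded phenotypic step.

## Genotype calling and accuracy

The simplified caller marks a locus knocked out iff its deletion-tag count
exceeds `presence_threshold` (default 0.1) × the well's total for that
locus's amplicon family; wells or loci without informative reads are
flagged unknown, never guessed. The asymmetric accuracy estimator assumes
knockout→wild-type miscalls only: with n loci, e expected and m observed
mean knockouts, per-locus accuracy is (n − e + m)/n — for (16, 8, 7.0)
this gives 0.9375 (93.8%). A warning is raised if m > e, where the model's
assumption fails.

## Problem sizes used in the test suite

Recovery suites simulate 2,000–3,000 strains at sequencing depth 10⁶ with
8 drugs plus solvent, 10 training runs of ~1,000 epochs, and 10
independent replicates for support-recovery statistics; unit fixtures use
tens of strains and depths of a few thousand. These sizes were chosen so
the full suite characterizes estimator behavior at well-powered scale
while remaining convenient to run locally.
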