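# Methods

This note records the models the package implements, the numerical
choices behind them, what the synthetic benchmarks do and do not show,
and the design decisions taken where the design was genuinely open.

## The two-step translation model

**Step 1 — unpaired domain translation.** Landmark-space profiles from
two platforms (an L1000-like domain X and an RNA-seq-like domain Y, same
genes, different per-gene response) are mapped into each other by a
CycleGAN: generators *G*: X→Y and *F*: Y→X, discriminators *D_X*, *D_Y*.
The adversarial terms use the least-squares form — the discriminator is
a linear-output network trained toward 1 on real profiles and 0 on
generated ones, the generator toward 1 on its fakes:

    d_loss = mean((D(real) - 1)^2) + mean(D(fake)^2)
    g_loss = mean((1 - D(fake))^2)

Cycle consistency `mean((F(G(x))-x)^2) + mean((G(F(y))-y)^2)` and
identity `mean((F(x)-x)^2) + mean((G(y)-y)^2)` penalties (both weighted
10 by default) anchor the translation: the two platforms measure the
same biology, so a generator fed a profile already in its output domain
should return it unchanged, and a round trip through both generators
must reproduce the input. All four networks are two-hidden-layer fully
connected ReLU nets; generator outputs pass a final ReLU because log2
expression is nonnegative. Training alternates one discriminator update
and one joint generator update per mini-batch (Adam, learning rate
2·10⁻⁴, batch 100, 100 epochs by default); epochs iterate over the
larger pool with the smaller pool resampled.

**Step 2 — full-genome extrapolation.** A fully connected network maps
landmark profiles to all remaining ("target") genes; full profiles are
assembled as input landmarks ∪ predicted targets. Transcriptomes are
strongly low-rank — co-regulated genes move together — which is what
makes this extrapolation well-posed. Default hidden widths scale from
the landmark count in the proportions of the full-scale architecture
(962 → 2048 → 8162 → 23,614). MSE objective, Adam (2·10⁻⁴, batch 100),
a seeded 10% validation split, early stopping with patience 3, and
restoration of the best-epoch weights.

**Baselines.** Per-gene ratio scaling (factor = mean expression in Y /
mean expression in X, unpaired pools suffice; genes with ~0 domain-X
mean get factor 1) benchmarks step 1. Per-target OLS on the landmarks
(joint solve, minimum-norm fallback for rank-deficient designs,
optional ridge) benchmarks step 2.

## Numerical and training choices

- **numpy networks.** All networks are explicit-matrix MLPs with
  hand-written reverse-mode gradients and Adam. At package scale
  (≤ a few hundred genes, ≤ thousands of samples) this is seconds-fast
  on one CPU and — with `np.random.default_rng(seed)` driving
  initialization, shuffling and resampling — bit-reproducible. Gradients
  are validated against central finite differences in the test suite.
- **Near-identity generator initialization** (default on). Each
  generator starts as the identity map — exactly representable through
  ReLU layers on nonnegative inputs — plus N(0, 0.01²) noise. Because
  the two platforms share most structure, the cycle and identity losses
  then start near zero and the adversarial gradient only has to learn
  the per-gene platform correction. Without it, the adversarial
  equilibrium at desk-scale sample counts is reached far too slowly and
  translation can end worse than the raw input.
- **Extrapolator standardization.** The extrapolation network trains in
  per-gene z-score space (means/sds stored on the model); predictions
  are de-standardized and rectified. Raw log2 magnitudes (≈ 0–14)
  condition the optimization poorly; standardization roughly halves the
  held-out error at equal budget.
- **Quantile normalization.** The reference is the across-sample mean of
  within-sample sorted values; new samples are mapped onto a persisted
  reference so inference-time normalization matches training. Ties take
  the mean of the reference entries they span (deterministic and
  permutation-invariant; on tied data a column's sorted vector therefore
  deviates from the reference at tie positions). Columns that already
  share one value multiset pass through bit-identically — checked before
  averaging, which makes repeated normalization exactly idempotent.
- **Bridge walks** rise 1/m at each of the m set genes and fall 1/(N−m)
  otherwise. The running sum is evaluated as cumulative-count ratios
  `hits/m − misses/(N−m)`, so a top-placed set peaks at exactly 1.0 and
  every unweighted walk ends at exactly 0 — a balanced bridge. Weighted
  walks rescale the per-gene |differential-expression| weights into
  [0, 1] by their maximum, then normalize up-steps within the set, so
  weighted peaks also lie in [0, 1]. Permutation p-values use the
  add-one estimator `(1 + #{null ≥ observed}) / (n_perm + 1)`.
- **Characteristic direction.** The CD is the unit vector
  `b ∝ (γΣ_pooled + (1−γ)I)⁻¹ (μ_t − μ_c)` with shrinkage γ = 0.5 by
  default; γ is forced to 0 (normalized mean difference) when either
  group has fewer than 2 samples. For p ≫ n the inverse is applied via
  the Woodbury identity in the span of the centered data, verified
  against the dense solve in the tests. Sign convention: the gene with
  the largest |coefficient| carries the sign of its own mean difference.
- **Ranking ties** inside a signature break lexicographically on the
  gene symbol; the reverse search combines fold change, CD coefficient
  and within-signature rank by a rank-sum (Borda) because the three
  criteria live on incomparable scales. Signatures where fold change and
  CD disagree in sign are retained and flagged — CD favors the
  consistent direction of movement across replicates, which can oppose
  the average.
- **Random pairing** uses a seeded derangement (no sample compared with
  itself), one permutation per call by default with an option to average
  over several.
- **Constant vectors** have undefined correlation; they are reported as
  missing and excluded from metric summaries (with a count) rather than
  coerced to 0, which would bias means toward zero.

## The synthetic worlds

`simulate_world` emulates the statistical skeleton of a cross-platform
corpus. Full-genome truth follows a low-rank factor model: gene
baselines U(2, 10) log2 units, each gene loading on one of `n_factors`
contiguous blocks with strength U(0.6, 1.4) and random sign, standard
normal per-sample factors, residual sd 0.2, rectified at 0. Landmarks
are drawn stratified across blocks so every factor is observable from
the landmark panel. The L1000-like platform measures landmark truth
through a per-gene monotone saturating map

    x = gain · y / (1 + y / saturation) + offset + N(0, noise_sd),  clipped at 0

with gain ∈ 1 + strength·U(−0.3, 0.6), offset ∈ strength·U(0, 0.5) and
curvature strength·U(0.02, 0.08) (saturation = 1/curvature; identity
map at strength 0). Gain/offset mimic probe-specific response,
saturation mimics signal compression at high abundance, and
monotonicity keeps the map invertible — a learnable, verifiable target
for the translator. Unpaired training pools and the paired evaluation
set are disjoint sample blocks of one world, preserving the CycleGAN
assumption of shared underlying structure without pairing. Default
study conditions: 300 genes, 50 landmarks, 10 factors, 1000 samples per
training pool, 200 paired evaluation samples, platform noise sd 0.1.

`simulate_regression_world` builds worlds with a *known* landmark→target
link for the extrapolation benchmark: each target is driven by a sparse
positive combination of three landmarks rescaled to mean 4, sd 2.2
(clipped at 0), passed through either an affine map or a saturating
curve `z → a·z/(1 + z/s)` with half-saturation s ∈ U(1.5, 3). The
driver's spread is deliberately large relative to s so the curve bends
materially across the sampled range — the regime a nonlinear
extrapolator exists for; with a gentler bend an OLS fit is locally
sufficient and, at desk-scale sample counts, statistically hard to
beat. In the affine variant the driver sits ~5 sd above zero so
rectification essentially never binds and the world stays truly linear
— the guard case where the network must *not* beat OLS beyond a 0.02
mean-PCC noise margin.

`simulate_perturbation_study` draws batched treatment/control samples
from a world's factor model (per-batch shift sd 0.1 shared by both
arms) and adds `effect_size` log2 units to a random target set in
treatment samples — the testbed for per-batch signatures, bridge
enrichment and reverse search.

**What the synthetic benchmarks do not show.** The worlds are Gaussian,
low-rank and per-gene monotone by construction; real cross-platform
data add probe saturation heterogeneity, batch and library-size
effects, count noise, and nonlinear gene–gene couplings that no
low-rank factor model captures. Passing these benchmarks demonstrates
that the implementation optimizes the stated objectives, inverts the
kind of distortion it is designed for, and beats its baselines exactly
where nonlinearity exists — not that the published full-scale accuracy
figures transfer to any particular real corpus. The published
benchmarks (trained on ~50,000-profile public pools, evaluated on 2929
paired samples) can be reproduced with this package by supplying those
corpora to the same entry points.

## Desk-scale study sizes

The test suite and the acceptance script run the translation study at
300 genes / 50 landmarks / 1000 + 1000 unpaired training samples / 200
paired evaluation samples (CycleGAN hidden width 128, 100 epochs), the
extrapolation study at 50 landmarks / 250 targets / 1600 training +
400 held-out samples (learning rate 1·10⁻³ at this corpus size — with
16 mini-batches per epoch the full-scale rate of 2·10⁻⁴ yields too few
effective steps), and the signature study at 5 batches × (5 treated +
5 control) with a 20-gene target set at +2 log2 units, 200
permutations per bridge null. These sizes were chosen so each study
carries clear signal while the whole suite runs in well under an hour
on a laptop CPU.

## Known limitations

- Like the full-scale model, the pipeline predicts *global* expression
  structure; the expression of a single directly-perturbed gene (e.g. a
  knockout target) is exactly the kind of landmark-orthogonal signal
  the extrapolator cannot recover.
- The adversarial printed objective follows canonical least-squares GAN
  conventions; CycleGAN equilibria are sensitive to pool composition,
  and at very small pool sizes the discriminators can overfit before
  the generators converge.
- limma-style moderated statistics are deliberately out of scope; the
  signature methods are characteristic direction and fold change.
- GCTX (HDF5) containers are not read or written; the interchange
  formats are GCT 1.2 text and TSV.
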