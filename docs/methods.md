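# Methods

This note documents the models, numerical choices, and design decisions
behind `phyloacoustics`, and states precisely what the synthetic-data
checks do and do not establish.

## The analysis model

The pipeline asks whether species-level acoustic traits carry phylogenetic
signal — whether close relatives sound more alike than species drawn at
random from the tree — after removing the allometric effect of body size.
It is organized as: descriptor extraction → species aggregation and log
transform → PGLS size correction → standardization → signal tests →
multivariate (Mantel) model selection.

### Acoustic descriptors

Recordings are analyzed at their native sample rate in 40 ms windows with a
20 ms hop (window and hop converted to samples by rounding; FFT size equals
the window length, no zero padding; Hann window before the FFT). Per-frame
quantities are averaged over frames to give one value per recording.

Choices the descriptor definitions leave open, and our defaults:

- **Window function**: Hann. The descriptors' definitions are
  window-agnostic; Hann is the common default in music-information-
  retrieval toolchains of this kind.
- **Frame RMS** is computed on the raw (unwindowed) frame, since CVA
  measures envelope variation, not spectral content.
- **Silence handling**: all frames enter CVA (the envelope *is* the
  measurand). Frames with RMS < 1e-6 are excluded from DF, SI and TON
  (arg-max and flatness are undefined on silence); SF uses all consecutive
  frame pairs.
- **SI partials** are interior spectral peaks (local maxima within 40 dB of
  the frame maximum). The raw sum Σ(aₖ−aₖ₊₁)² is gain-dependent, so by
  default it is normalized by Σaₖ² with a trailing zero closing the sum
  (`si_normalized=True`): a lone partial scores exactly 1, an
  equal-amplitude comb of N partials scores 1/N. The unnormalized variant
  is available via the flag.
- **TON floor**: power bins are floored at 1e-12 × frame maximum before
  the geometric mean, avoiding log(0) while leaving the flatness of any
  realistic spectrum unchanged.
- **Gain sensitivity**: CVA, DF, SI (normalized) and TON are invariant to
  scaling the waveform by a positive constant; SF scales linearly with
  gain and is the one level-dependent descriptor. This is asserted by
  tests.

Species values average the recording means on the linear scale (one or two
recordings per species), then DF, SF, SI, TON and SVL are log₁₀-transformed;
CVA, already a dimensionless coefficient of variation, is not. Averaging
before the log keeps the two-recording species on the same footing as the
transform order used for the single-recording species; the difference from
log-before-average is below 1% of a log unit at the within-species
variation the generator produces, and all downstream statistics are
invariant to the log base (base change rescales residual columns by a
constant; Moran/Geary/K/Mantel are location-scale invariant — asserted to
1e-10).

### Relatedness models

- **Pairwise genetic distances** from an alignment: p-distance,
  JC69 d = −(3/4)ln(1−(4/3)p), or K2P from transition/transversion
  proportions. Sites with a gap, N, or ambiguity code in either sequence of
  a pair are deleted for that pair only (pairwise deletion). Saturated
  pairs (non-positive log arguments) raise an error naming the pair.
  Any externally computed matrix can be supplied as TSV instead.
- **Abouheif proximities** (topology only): off-diagonal A_ij is the
  product over interior nodes on the i→j path of 1/(direct descendants);
  the diagonal completes each row to sum 1 (oriAbouheif). Zero-length
  internal branches are collapsed to polytomies first. Rescaling branch
  lengths leaves A unchanged (tested).
- **BM variance–covariance matrix**: C_ii is the root-to-tip path length,
  C_ij the root-to-MRCA path. For a taxon subset the matrix is shifted to
  the subtree rooted at the subset's MRCA.

Where a test needs neighbour *weights* (Moran, Geary), distances become
weights by inversion (w_ij = 1/d_ij; zero distances replaced by half the
smallest positive distance) and row standardization; `inverse_squared` and
`rank` schemes are available. Abouheif proximities are used directly as
weights after zeroing the diagonal and re-standardizing rows. Where a test
needs a *dissimilarity* (Mantel against proximities), we use
max_offdiag(A) − A_ij: Mantel r is invariant to positive affine maps of
matrix entries, so this is exactly the sign-flip of correlating with A and
makes "signal" come out as positive r everywhere.

### PGLS size correction

β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with X = [1, logSVL], C the BM matrix (λ fixed at 1;
no Pagel-λ estimation). C is factored by Cholesky; failure surfaces as an
error, never a silent pseudo-inverse. Downstream tests use the
*ordinary-scale* residuals y − Xβ̂ (the phylogenetic-residual construction;
this implementation reproduces `phytools::phyl.resid` to machine
precision), with GLS-whitened residuals available for sensitivity
analysis. Whole-sample analyses use one regression per trait on the full
tree; intra-clade analyses refit per clade on the pruned subtree (clades
with fewer than three species are skipped with a warning) and standardize
residuals within the analysis group (a flag switches to global
standardization).

### Signal tests and inference

All four tests use one-sided permutation inference with the add-one
convention p = (1 + #{T_perm ⪰ T_obs})/(1 + n_perm), ties counted toward
the tail (conservative), 10,000 permutations by default, and a recorded
seed. Moran's I and Mantel are upper-tailed, Geary's C lower-tailed
(C < 1 ⇒ similarity among neighbours), K upper-tailed. Moran's and Geary's
analytic standard deviates use the randomization (permutation-moment)
variance, not the normality variance; both formulas are verified against
empirical permutation moments in the tests, and Geary's deviate is
reported as (1−C)/sd so positive deviates mean positive autocorrelation
for every test.

The Mantel bootstrap subsamples ⌈0.9·n⌉ taxa *without replacement* —
with-replacement draws would create zero self-distances that corrupt the
submatrices — and recomputes r on the induced submatrices; degenerate
(constant) subsamples are redrawn and counted. Fraction and replacement
are configurable.

### Forward stepwise trait selection

The multivariate trait distance is the Euclidean distance over a subset of
the standardized residual columns. The search starts from the single trait
with the highest Mantel r (ties broken lexicographically), then repeatedly
evaluates every remaining candidate, takes the best, and accepts it only if
the enlarged model's r exceeds at least 95% of the incumbent model's
bootstrap r sample (10,000 iterations by default) *and* strictly increases
r. Each comparison is seeded as `seed + 1000·step + candidate_index`, so
the outcome does not depend on candidate evaluation order (tested). The
search runs on the whole sample only; clade-level Mantel rows re-evaluate
the whole-sample winner on clade-pruned matrices. An empty-start variant
is deliberately not offered as a default because the single-best-trait
start is the natural reading of a forward search over traits that are all
individually testable.

## The synthetic-data generator

The generator reproduces the *statistical shape* of a four-clade,
~90-species call study with known ground truth:

- **Trees**: pure-birth (Yule) trees conditioned on n tips; epoch k lasts
  Exp(k·birth_rate), so the expected root height is Σ_{k=2..n} 1/(k·b)
  (used as a closed-form oracle). Clades are the subtrees created by the
  oldest splits, emulating a sample of named basal clades.
- **Traits**: tips drawn from MVN(root, σ²·C(λ)) where C(λ) multiplies the
  off-diagonal BM covariances by λ. λ-dilution was chosen over additive
  white noise as the signal-strength dial because it maps directly onto
  the covariance model used by K and PGLS (λ=1 pure BM, λ=0 iid tips).
- **Allometry**: logSVL evolves by BM (rate 0.05 around log₁₀ 50 mm — a
  realistic anuran body-size spread) and the frequency-like trait is
  a + b·logSVL + ε with b = −0.33 by default (the negative call-frequency
  allometry ubiquitous in anurans) and ε a λ-diluted BM of rate 0.02.
- **Sequences**: JC69 evolution along the tree at a configurable rate
  (default 0.05 subs/site per unit time, keeping a ~3-unit-deep tree far
  from saturation, comparable to an alignment of a moderately variable
  marker).
- **Audio**: a harmonic stack at f0 with per-harmonic rolloff, sinusoidal
  AM (rate, depth), and white noise at a target SNR. Expected descriptor
  values are known: DF ≈ f0 when the fundamental dominates, and for slow
  AM the frame-RMS envelope of (1+m·sin) gives CVA = m/√2 (the 40 ms
  window low-passes the envelope, so the identity holds for AM periods ≫
  40 ms; the oracle test uses 2 Hz AM over 50 cycles, where agreement is
  within 2%). Latent traits map monotonically into valid synthesis ranges
  (f0 in 300–3000 Hz log-scale, AM depth 0.1–0.9, rolloff 2–12 dB).

What the generator does *not* emulate: realistic anuran call morphology
(pulse trains, formants, frequency modulation), recording-channel effects,
within-species variation beyond one synthetic call, and non-ultrametric or
extinction-bearing trees. Passing tests therefore demonstrate correctness
of the statistical machinery under its stated models, not robustness to
real-world recording conditions.

**Study-level λ.** In the full study generator the λ dial dilutes *every*
evolving quantity, body size included: λ=0 is a study with no heritable
signal anywhere, which is the coherent null for end-to-end type-I checks
(see limitation below), while `simulate_allometric` retains an independent
`lambda_svl` (default 1, pure BM body size) for targeted experiments.

## Problem sizes used in the checks

Simulation-based checks are sized to run on one CPU in minutes: 500
replicates of 100-tip trees for the mean-K anchor; 2,000 replicates at
n = 50 with 199 permutations for type-I calibration (199 makes
α·(n_perm+1) an integer, so the permutation test has exact size and the
nominal 5% envelope is ±2 binomial SE, [0.04, 0.06]); 200 replicates for
PGLS and JC69 recovery; 100 replicates each at λ ∈ {0, 1} with 90 tips for
the end-to-end contrast; 20 seeded replicates with 2,000-draw bootstraps
for stepwise recovery (the analysis default remains 10,000).

## Known limitations

- **Permuting GLS residuals is anticonservative for K.** Ordinary-scale
  PGLS residuals are orthogonal to the design only in the C⁻¹ metric, so
  they are not exchangeable across tips. Measured on fully signal-free
  90-tip studies, tip-permutation tests of Blomberg's K on PGLS residuals
  reject at ≈ 0.13 at α = 0.05 (vs exactly 0.05 on OLS residuals), while
  Moran-on-Abouheif remains calibrated (≈ 0.045). The corresponding
  acceptance test asserts the nominal envelope and is expected to fail —
  it documents a property of the residual-permutation design itself, not
  an implementation defect.
- **Size correction leaks covariate signal under misspecification.** When
  body size carries strong phylogenetic signal but the true trait residual
  is phylogeny-free, the GLS slope error re-injects body-size structure
  into the residuals: Moran tests then reject at ≈ 0.35 on 90 tips. In
  real data, where the BM residual assumption motivates PGLS in the first
  place, this regime is the boundary case — but users should read
  residual-signal tests as conditional on the residual covariance model.
- p / JC69 / K2P stand in for composite maximum-likelihood distances; the
  pipeline accepts any externally computed distance matrix for users who
  need a richer substitution model.
- Moran weights from pairwise distances require a weighting scheme the
  analysis tradition leaves open; inverse distance with row
  standardization is the default and is recorded in output metadata, with
  `inverse_squared` and `rank` as declared alternatives.
- No multiple-testing correction is applied across the results table by
  default (matching the analysis tradition of reporting per-test stars);
  a Holm-adjusted column can be requested.
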