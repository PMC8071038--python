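# Methods

This note records the models, conventions and numerical choices behind
`brainwcn`, in the order the pipeline applies them, together with the
reasoning for the choices that were genuinely open.

## Feature schema and normalization

The canonical schema has 419 morphometric features: 31 bilateral
cortical regions × 6 measures × 2 hemispheres (372), 28 bilateral
subcortical/cerebellar volumes, 12 midline/unpaired subcortical volumes
(corpus callosum segments, brainstem, ventricles, ...), and 7
whole-brain summaries (left/right cortex volume, left/right cerebral
white-matter volume, total gray volume, left/right mean cortical
thickness). The global normalizer `BrainSegVolNotVent` is carried as a
420th, flagged column: it is used as a denominator but is not a network
node by default (configurable).

Normalization is per subject: volume-like features are divided by
`BrainSegVolNotVent`, thickness-like features by the mean of the two
hemisphere mean thicknesses, area-like features by the sum of all
cortical surface areas; curvature features are not normalized. The
transform is one-shot and refuses already-normalized tables, because
re-applying it silently changes values.

Augmentation appends, for each homologous left/right pair, the
bilateral average (L+R)/2 and the asymmetry (L−R)/2 (sign convention:
left minus right; the sign cannot affect the magnitude of any
rank-correlation result downstream). The canonical schema has 203 pairs
(186 cortical + 14 subcortical + 3 global), so the full augmented node
set has 419 + 2·203 = 825 features, minus one: after thickness
normalization the bilateral average of the two mean-thickness columns
is identically 1 (L/((L+R)/2) + R/((L+R)/2) ≡ 2) and would enter the
network as a pure-noise node. The augmenter therefore drops augmented
features that are constant up to floating-point jitter, with a warning
and a record (`drop_degenerate=False` restores the literal behavior).
Pipeline order is normalize-then-augment, so averages and asymmetries
are computed on normalized values.

## Network construction

Spearman correlation (mid-ranked ties) is used throughout; a constant
feature is an error naming the feature. Thresholding links exactly
m = P − 1 − ⌊q(P−1)⌋ of the P off-diagonal pairs, the pairs with the
largest *signed* correlation (negative correlations can never link at
high q). When all pair values are distinct this is identical to
"link iff r_S strictly exceeds the empirical q-quantile under linear
interpolation"; when values are tied at the cut, ties break
deterministically by pair index. The fixed link count is deliberate:
under bootstrap resampling, tied correlations at the cut would
otherwise make the edge count fluctuate between repetitions and destroy
the fixed-density property that makes the degree comparison an exact
negative control.

Weights are w = exp(−S²/σ²), S = sin(½ arccos r_S), σ = 1 by default;
linked weights therefore lie in [e^(−1/σ²), 1]. A disconnected network
is built successfully with a warning; the default density ρ = 0.15 is
chosen (as in the reference design) large enough that realistic inputs
stay connected.

## Centrality measures and conventions

Twelve per-node measures; conventions that the formulas do not fix:

- **Weighted distance.** No canonical edge length exists for a
  similarity weight; the default is ℓ = 1/w (strong similarity = short
  edge). The alternative ℓ = S (the chordal distance itself, recovered
  from the weight) is selectable; it changes WCC and WBC values but not
  the topology of shortest-path trees at σ = 1 beyond the length scale.
- **Knn/Snn** are the plain arithmetic mean of neighbor degrees /
  strengths (not strength-weighted).
- **Betweenness** excludes endpoints and is normalized by C(N−1, 2);
  **closeness** is (N−1)/Σd, with per-component Wasserman–Faust scaling
  (and a warning) on disconnected networks.
- **Clustering** is (A³)_ii/2 over C(K_i, 2), undefined (NaN) for
  K_i < 2.
- **IPR** has no universal definition; the default is the edge-weight
  disparity Y_i = Σ_j (W_ij/S_i)², which is 1/K_i for uniform weights
  and → 1 when one edge dominates. An eigenvector-localization variant
  (ν_i⁴ of the weighted Fiedler vector) is available behind
  `ipr_variant="fiedler"`; both are interpretations, not canon.
- **Spectral centrality** uses the combinatorial Laplacian L = D − M
  (binary or weighted) and the unit-norm eigenvector of the
  second-smallest eigenvalue, sign-fixed by making the first nonzero
  entry positive. A disconnected graph raises by default; the engine
  uses a giant-component fallback (NaN outside the giant component,
  flagged) exactly where a failing graph cannot be redrawn — the single
  case network and case-side resamples. A degenerate Fiedler eigenvalue
  (e.g. complete graphs, stars) triggers a warning; the returned vector
  is then one deterministic representative of the eigenspace, and only
  eigenvector-choice-free functionals (such as Σ_i SC_i = 2λ₂) are
  comparable across linear-algebra backends.

Undefined values (Clust for K < 2, Knn/Snn/IPR for isolated nodes)
propagate as NaN and are excluded from node averages, with counts
reported.

## Group comparison

The control group is subsampled at the subject level with replacement
(without-replacement available), M_sub per repetition, default
M_sub = case-group size — which reproduces the reference design's
"M_sub = min(group sizes)" without hard-coding any cohort size — and
K = 5×10⁴ repetitions by default (tests and examples use K = 10–100;
the empirical-p floor 1/K is reported alongside every bound). A
repetition whose network cannot be profiled is logged and redrawn;
per-repetition seeds come from a spawned `SeedSequence`, so results are
bit-reproducible for a given seed and independent of the retry history
of other repetitions, and parallel execution combines repetitions in
index order.

Each control distribution (whole-network statistic, or node × measure
entry) is Box-Cox transformed at its maximum-likelihood λ, fitted on
control values only; the case value is mapped through the same (λ,
shift). Two numerical guards matter in practice: (i) data far from zero
with small relative spread drive |λ| to very large values where the
textbook transform collapses below double precision — the z-score is
therefore evaluated on exp(λ(log x − max)) using the affine invariance
of z; (ii) a constant control distribution yields an identity transform
with a flag, and z := 0 flagged "by construction" when the
case-minus-mean difference also vanishes (degree is the canonical
case). Degenerate-zero tests use relative tolerances (1e−12 on the sd,
1e−9 on the difference) because the mean of K identical doubles differs
from them at the ulp level.

Empirical p-values are one-tailed in the direction of the case's
deviation from the control mean, p = (# control values strictly more
extreme)/K, floored at 1/K with a flag; p is computed on raw values
(rank-based, hence identical under the monotone Box-Cox map). A
two-tailed mode doubles p. In the symmetric ("both") design the case
group is subsampled identically and summarized by the mean of its
distribution before scoring.

Rankings take the top-k nodes by |z| (sign retained, ties broken by
feature id). The measure cluster map is the 12×12 Spearman matrix of
node-value vectors (pairwise-complete), clustered by average linkage on
1 − r_S with a configurable flat cut (default 4 clusters).

No multiple-testing correction is applied across nodes; raw z and p are
reported and documented as such.

## Synthetic cohort generator

The generator is a Gaussian copula: a latent multivariate normal pushed
through strictly monotone per-feature maps to realistic positive scales
(lognormal-like volumes/areas/thicknesses, linear curvatures). Because
the analysis is rank-based, only the latent correlation matters; the
marginal maps are interchangeable by construction.

The latent correlation is a factor model, PSD by construction, with
unit-variance factors and loadings:

- a **global (head-size) factor**: every feature √0.15, volumes √0.30 —
  volumes carry far more head-size variance than thickness or
  curvature, and at corr(volume, total volume) ≈ 0.5 ratio
  normalization leaves pairwise correlations approximately unchanged
  instead of inducing spurious shared-denominator structure;
- an **anatomical block factor** per region/structure, √0.45 — same-
  region measures are strongly coupled (volume ≈ area × thickness);
- a **measure-kind factor** per measure type, √0.12 — all volumes
  co-scale beyond head size, which keeps midline volumes embedded in
  the volume covariance web;
- a **mirrored lateralization factor**, ±√0.10 (left +, right −) — a
  subject lateralized one way is consistently lateralized across
  regions; this is what gives the derived asymmetry features genuine
  mutual correlation (under an exchangeable L/R model they would be
  mutually uncorrelated and detach from the network);
- **aggregate summary features** (`BrainSegVolNotVent`, the hemisphere
  mean thicknesses) load ≈ 0.85 on the factor they summarize, because a
  sum is dominated by its common component — without this, dividing by
  a noisy normalizer would correlate all ratio features through the
  shared denominator (Pearson's spurious ratio correlation);
- per-feature multiplicative **loading jitter** (±25%, drawn
  deterministically from the seed, identical in both groups) so pair
  correlations form a continuum rather than a few discrete levels, as
  in real covariance data. Structured variance per feature is capped at
  0.9 so the idiosyncratic residual stays positive.

The planted group difference attenuates every non-global loading of the
planted nodes by (1 − δ) in the case group only: planted features
decouple from their anatomical covariance structure while still
tracking brain scale. Ages default to the same truncated normal
(mean 17, sd 8, minimum 7 years) in both groups so the
Kolmogorov–Smirnov balance gate passes; `age_shift_case` injects a
deliberate bias for testing the gate. Group sizes default to 235 cases
vs 418 controls for demonstration at the reference scale; tests and the
acceptance script use reduced cohorts.

**What the generator does not emulate.** Site/scanner effects,
realistic marginal shapes, measurement noise structure, and the
empirical covariance spectrum of real morphometry. Two desk-scale
findings are worth stating because they are properties of the *method*,
not artifacts: (i) with ratio normalization, a feature can never fully
decorrelate from the features sharing its denominator, so planted
decoupling of volumes/thicknesses is intrinsically harder to detect
than for areas/curvatures — the planted-recovery test plants features
without shared normalizers; (ii) very small schemas (≲40 base features)
fragment at 15% density because too few weak pairs exist below the
structured families, so statistical tests run on a ≥67-feature schema
whose networks stay connected. Passing tests therefore demonstrate the
machinery and its calibration on a plausible covariance structure, not
performance on real MRI data.

## Problem sizes used in tests and the acceptance script

Stochastic checks run at reduced but representative sizes chosen once:
networks of ~90–280 nodes, cohorts of 100–180 subjects per group,
K = 60–100 subsampling repetitions; the null-calibration check uses 5
independent cohorts, and the planted-recovery check uses a δ = 0.9
attenuation of two regions' area/curvature features with recovery
measured as precision of the top-|z| strength ranking at the planted
size. The single-case vs symmetric-design sign agreement is asserted
for measures with |z| ≥ 0.5 in both designs on connected-regime data
(δ = 0.45): under near-disconnection the Fiedler vector is unstable
and the spectral measures can legitimately flip sign between designs.

## Known limitations

- Empirical p-values inherit the bootstrap's conditioning: the null is
  "resampling variation around this control sample", not "fresh
  control cohorts"; calibration was verified empirically (≈7% of null
  whole-network |z| exceed 2) but is approximate by nature.
- Per-node Box-Cox fits at K = 5×10⁴ and ~800 nodes are the runtime
  bottleneck at full scale; per-node values are held as one
  (K × nodes × 12) float array, which at reference scale is ~2 GB —
  adequate for a workstation, not for much larger K.
- The weighted betweenness counts shortest paths under floating-point
  lengths; exactly tied path lengths (measure-zero for continuous
  weights) could be counted differently by other implementations.
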