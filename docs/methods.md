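# Methods

This note documents the models, numerical choices, and limitations behind
`narranet`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the pipeline itself.

## Narrative networks and centrality

A movie with M events yields a symmetric M × M adjacency with zero
diagonal. Semantic edges are unthresholded cosine similarities between
event embedding vectors (negative cosines are retained; thresholding is a
visualization device only). Causal edges are the fraction of coders who
listed the pair as causally related, in either direction (an undirected
reading; weights are rational with denominator `n_coders`).

Centrality is the weighted degree `d_i = Σ_j w_ij`, normalized by the
movie's degree sum, then z-scored **within movie** using the sample
standard deviation (denominator M − 1). The denominator choice is
affine-equivalent for all correlation- and regression-based analyses but
changes printed z values, so it is pinned and exercised by a hand example
(weights .6/.4/.2 → z = (1, 0, −1)). Networks with fewer than 3 events or
all-equal degrees raise rather than return undefined z's.

The high/low split takes the top and bottom `floor(0.4·M)` events per
movie; ties at the boundary go to the earlier event index (a deterministic
rule the data themselves cannot fix). `partial_centrality` recomputes
centrality on the leading submatrix, emulating the network a viewer could
have built mid-movie.

## Embeddings

The encoder is a protocol: anything mapping texts to fixed-length finite
vectors. The bundled `HashingStubEncoder` gives each token a fixed
pseudo-random Gaussian direction seeded from its MD5 hash, sums
token-count-weighted directions, and unit-normalizes. Tokenization is
pinned (lowercase, split on non-alphanumerics, drop empties) so outputs
are bit-stable across runs and platforms. This preserves the properties
the pipeline needs — determinism, fixed dimension, similar texts → similar
vectors, disjoint vocabularies → near-orthogonal vectors (inner products
have sd ≈ 1/√D) — without pretrained weights. A real 512-d sentence
encoder can be plugged in through the same interface; no analysis in this
package depends on which encoder produced the vectors.

Annotator averaging happens in embedding space (element-wise vector mean),
not text space. Recall-derived similarity matrices average cells over
whichever participants contribute them (plain unweighted mean); cells no
participant contributes stay missing and are dropped pairwise downstream.

## Statistical machinery

**Permutation p-values** use the add-one convention
`p = (b + 1)/(m + 1)`, never returning 0; with 1000 permutations the floor
is 1/1001 ≈ .000999. Two-tailed tests measure extremity as absolute
distance from zero, appropriate because every two-tailed statistic in the
package is a difference whose permutation null is mean-zero by
construction.

**FDR** is Benjamini-Hochberg step-up (via statsmodels), applied across
parcels for maps and across the 18 time points for boundary curves. The
test suite checks exact agreement with a from-the-definition step-up
implementation on 1000 random p-vectors.

**Mixed models.** The recall model is logistic with crossed participant
and movie random intercepts; no pre-installed Python package provides a
frequentist logistic GLMM with likelihood-ratio tests, so the package
fits one by maximum likelihood under the Laplace approximation: an inner
penalized IRLS over the joint fixed/random coefficient vector (assembled
with group-index bincounts, so a 20 000-row fit takes well under a
second), and an outer Nelder-Mead over log standard deviations of the
variance components. This is the same deviance lme4's `glmer` uses at
`nAGQ = 1`; a test fits the same simulated data with lme4 via Rscript and
checks β, SE, log-likelihood, and LRT χ² agree to ~2 decimal places.
Random effects are intercepts only. Non-convergence, rank-deficient fixed
designs, and quasi-separation (|β| > 15 on the logit scale) are flagged on
the result, never silent. Wald SEs come from the joint-Hessian inverse at
the optimum (conditional on the variance components, as in lme4); CI
coverage measured over 200 generator replicates at 100 × 200 sits at
93–94%, the usual mild anticonservatism of Wald/Laplace intervals.

**Dependent correlations.** The ISFC analysis compares two correlations
sharing the centrality variable; the CI for their difference uses Zou's
(2007) asymptotic method for overlapping correlations, with the
correlation between the two ISFC series as the overlap term. A simulation
oracle (trivariate normal data with the study-like structure) confirms
~95% coverage. Sample correlations of exactly ±1 (noiseless toys) are
nudged inside the open interval before the Fisher transform.

## Neural measures

**Event patterns.** A TR belongs to an event if the TR's start time lies
in `[onset, offset)`; the hemodynamic delay is a fixed 3-TR shift
(≈ 4.5 s at TR = 1.5 s) applied to the resulting indices. Events whose
shifted window leaves the run raise. The first event of each movie is
excluded in the movie phase (onset transient) — toggleable. Recall-phase
patterns exist only for recalled events; events recalled by fewer than a
threshold number of participants (default 5 in the pipeline, with an
all-events mode) can be excluded from pISC.

**pISC** correlates each participant's event pattern with every other
participant's pattern of the same event and averages over partners.
The randomization map precomputes all cross-participant, cross-event
pattern correlations once, so each of the 1000 event-relabelings (global,
or within movie — both scopes are explicit because different analyses use
different scopes) costs only an index gather. The map statistic averages
pISC over events within participant, then over participants.

**RSA** correlates lower triangles (diagonal excluded, missing cells
dropped pairwise, ≥3 usable cells required) of the neural cross-event
matrix — symmetrized as (A + Aᵀ)/2 and averaged over the N − 1 partners —
against the embedding similarity matrix; the null shuffles reference
event labels within movie.

**Boundary time courses** span −2..15 TRs around the aligned boundary,
baseline-corrected per event by the mean of the two pre-boundary TRs (so
the baseline window averages exactly zero), averaged events → movies →
participants, with pointwise paired t-tests and BH-FDR over time points.
First and last events of each movie are excluded (between-movie
transitions). The offset response is the 10–13-TR post-offset mean minus
the same 2-TR baseline.

**Mediation** fits three participant-intercept mixed models (total:
outcome ~ centrality, logistic; mediator ~ centrality, linear; direct:
outcome ~ centrality + mediator, logistic) and simulates the ACME
quasi-Bayesian-style: coefficient draws from each model's asymptotic
normal, expected potential outcomes per observation conditional on the
estimated participant intercepts, contrasting centrality at 1 vs 0 (one
z-unit) and averaging the two treatment arms. With a logistic outcome the
ACME is on the outcome-probability scale — the scale is a documented
parameter because a probability-scale ACME of ~.001 is not comparable to
logit-scale coefficients. In the all-linear vanishing-noise limit the
ACME reduces to a·b exactly (asserted). The exclusion rule keeps interior
events with complete mediators and retains both recall outcomes: dropping
unrecalled events, read literally, would leave the outcome constant.

**ISFC** for each qualifying event (≥ 22.5 s by default, i.e. ≥ 15 TRs)
correlates participant s's region-A event series with the mean of the
other participants' region-B series, averages over s, repeats with roles
swapped, and averages the two directions; the measure is symmetric in the
regions to numerical precision.

## Synthetic generator

The generator's defaults are the emulated study conditions, fixed once:

- **Design**: 10 movies × 20 events, 3 annotators, 13 coders, 15
  participants, 512-d embeddings, TR 1.5 s, shift 3 TRs.
- **Semantic structure**: event vector = s·topic + √(1−s²)·specific, with
  hub events (40%) drawing s ≈ .75 and others s ≈ .25; pairwise cosine ≈
  s_i·s_j, so computed centrality tracks the planted loadings (rank
  correlation > .9). Annotator copies add Gaussian noise with σ = .53,
  chosen so cross-annotator cosine ≈ .78. An optional shared direction
  added to hub events across movies gives the cross-movie high/low test a
  positive case.
- **Causal structure**: per coder, pair inclusion is Bernoulli with
  probability .03 baseline, +.70 for adjacent events (causal links are
  sparse and mostly adjacent), plus a small semantic coupling (.06·s_i·s_j).
  These give coder Jaccard ≈ .34 and a semantic-causal centrality
  correlation ≈ .33, near the descriptive values the analyses expect
  (.31, .28).
- **Recall**: P(recall) = logistic(1.45 + .17·z_sem + .38·z_cau + u_p +
  u_m), u_p ~ N(0, .5²), u_m ~ N(0, .3²) → overall recall ≈ .78. Recall
  order follows presentation with adjacent transpositions (event-level
  Spearman ρ ≈ .97–.98) and jittered movie order (ρ ≈ .5–.65).
- **Neural**: per event a shared template; participant pattern =
  √ρ·template + √(1−ρ)·noise with ρ = clip(base + slope·z). Region
  defaults: "pmc" base .12 (movie) / .06 (recall) with slope +.008,
  "evc" .30 / .01 with slope −.006 — giving high-low pISC differences of
  roughly ±.015–.02. A hippocampus-like channel adds post-offset
  responses of amplitude .3 + .15·z under a Gaussian lag kernel peaking
  11.5 TRs (~17 s) after the offset — a generic smooth kernel, not a
  fitted hemodynamic model; only the peak window matters to the tested
  operations. Two 1-D channels share a per-event stimulus signal whose
  region-B loading is .3 + .1·z, planting the ISFC-centrality coupling.
  Event durations are uniform 6–16 TRs, so roughly 28–45 of 200 events
  pass the 22.5-s ISFC filter.
- **Media**: frames and audio are drawn independently of centrality by
  default (the control test's null); `planted_dependence` adds a linear
  luminance term in z for power checks.

What the generator does **not** emulate: cross-event similarity structure
in the neural templates (so RSA against the embedding matrix is null on
default output — RSA's positive cases are constructed directly in tests),
a mediator → outcome path (recall is generated from centrality only, so
the pipeline's ACME is null; mediation power is tested with purpose-built
data), spatial voxel geometry, hemodynamic convolution of the
event-pattern channels, autocorrelated scanner noise, or annotator
idiosyncrasies beyond isotropic embedding noise. Passing tests therefore
show the estimators recover planted effects under the stated noise model,
not that real fMRI data would show these effects.

## Problem sizes in the test suite

The acceptance-level checks run at: 200 replicates for each null
calibration (6–8 participants, 2 movies, 5–6 events each, ~120
permutations — small because type-I error is size-free); 200 replicates
at the full 100 participants × 200 events for mixed-model recovery; 100
replicates at 15 × 200 for the high-low pISC power check (planted Δ =
.02, F = 100 features); 20 study-scale replicates for ISFC direction
recovery; and 100 replicates at 30 × 60 for mediation null coverage. The
full suite runs in under 5 minutes on one CPU.

## Known limitations

- The logistic GLMM uses Laplace (nAGQ = 1); for binary outcomes with few
  observations per group, adaptive quadrature would be more accurate.
- Wald CIs do not propagate variance-component uncertainty (coverage
  ≈ 93–94% at nominal 95% in the recovery setting).
- The mediation ACME scale for logistic outcomes is a modeling decision
  (probability scale, centrality 0 → 1); other contrasts change the
  number, not the sign.
- `compare_dependent_correlations` is asymptotic; very small n (< ~15)
  would warrant the bootstrap instead.
- The stub encoder captures lexical overlap only; real sentence encoders
  also place paraphrases nearby. Analyses consuming embeddings are
  agnostic to this, but stub-based end-to-end runs understate semantic
  similarity between differently-worded descriptions of the same event.
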