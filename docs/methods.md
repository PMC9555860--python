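# Methods

This note records the models, estimators, numerical conventions and design
choices behind `gradflex`, and what the synthetic benchmarks do and do not
establish about real data.

## Measurement model and analysis chain

The unit of data is a parcellated trial pattern: one multivoxel activation
vector per trial, per parcel, per participant, obtained by averaging a
fixed window of volumes after trial onset (1-based TR offsets; the default
windows are TRs 4–6 for the main task and TRs 9–10 for the interleaved
baseline task, matching a 1.5-s TR slow event-related design with 13.5-s
trials). Trials are split into weak / middle / strong association terciles
by a corpus-derived word2vec score; extreme terciles hold `floor(n/3)`
trials each, remainders go to the middle set, and ties are broken by a
stable sort on trial id so the split is deterministic.

**Informational connectivity.** Per parcel, between-trial pattern
similarity is Pearson correlation across voxels (Spearman available).
Within-run trial pairs are excluded throughout: with a slow event-related
design residual temporal autocorrelation inflates within-run similarity,
and excluding those pairs removes that route into the connectivity
estimate. Parcel-pair informational connectivity is the Pearson
correlation between Fisher-z-transformed valid-pair similarity vectors
(the Fisher step is a flag; default on). Participant matrices are
aggregated by Fisher-z averaging. Because pattern correlations are
invariant to per-trial offset and positive scaling, the whole chain is
unaffected by parcel-wise gain or baseline differences (tested).

**Gradients.** Connectivity rows may be sparsified (keep the
`min(ceil(density·P), P−1)` largest off-diagonal entries per row); a
cosine affinity between connectivity profiles is then decomposed by PCA of
the column-centred affinity. Scores are ordered by explained variance and
sign-fixed deterministically (largest-magnitude entry positive).
**Default density is 1.0 (dense affinity).** The common toolbox
convention of keeping the top ~10% per row was evaluated and rejected as a
default here: on kernel-structured connectivity the top-k neighbour graph
discards the global amplitude structure that carries both the first
component's dominance (the first-mode/hub-mode eigengap collapsed from
roughly 7:1 to near-degenerate at density 0.1) and the condition contrast.
Sparsification remains available via `AnalysisConfig.sparsity_density`.

Condition gradients are aligned to the all-trials template by per-component
sign matching (orthogonal Procrustes is available) before score
subtraction; unaligned subtraction is refused because PCA leaves signs
undetermined. When an external reference map is supplied (in synthetic
mode, the planted axis; in real use, a resting-state gradient), the
template's principal component is oriented to it so difference maps have a
well-defined sign.

**Dimensionality.** For one trial and one cube searchlight (or one
parcel), participants' patterns form a participants × voxels matrix;
columns are mean-centred across participants (so "variance" means
between-participant variance, and any pattern component shared by all
participants does not count), and the dimensionality is the smallest m
whose cumulative singular-value variance strictly exceeds the criterion
(0.90 by default; 0.60 and 0.75 as robustness thresholds — strict
inequality, so a criterion of 1.0 returns full rank). Counts are
monotone in the threshold by construction. Edge searchlights are retained
when at least half the cube is in-mask (configurable, logged). The
weak-minus-strong contrast uses a two-sided Wilcoxon rank-sum per location
(exact enumeration for pooled n ≤ 12, normal approximation with tie
correction otherwise) with Benjamini–Hochberg correction.

**Second-order RSA.** The semantic model is the participants ×
participants Pearson matrix of rating vectors; the brain model at a
location correlates participants' vectorised valid-pair similarity
structures. Their alignment is the correlation of lower triangles
(diagonal excluded), Fisher-z transformed after clipping at ±(1−1e−6) so
the degenerate equality case stays finite. Because participant-pair
entries are not independent, per-location inference uses a Mantel-style
permutation: the semantic model's rows and columns are permuted together,
the same permutation set is applied at every location, and
`p = (1 + #{|z_perm| ≥ |z_obs|}) / (1 + n_perm)` (default 5000).

**Spin test.** Map-to-map correlations over parcels are tested against a
null that preserves spatial autocorrelation: the parcel centroids (unit
sphere) are rotated by uniform random rotations, values are reassigned by
nearest rotated centroid, and the two-tailed p compares |r| to the
rotation null with the +1 correction. Rotations apply to the second map
only; the test is invariant to additive constants in either map.

**rm-ANOVA.** The network × task analysis of per-participant gradient
differences uses a balanced two-way within-subject ANOVA written from the
sums-of-squares decomposition, with effect-specific Greenhouse–Geisser
epsilon estimated from the covariance of orthonormal contrast scores, and
partial eta squared as `SS_effect / (SS_effect + SS_error)`. F statistics
agree with pingouin's two-way rm-ANOVA to 1e-6; the sphericity-corrected p
is checked property-wise because pingouin documents an accuracy caveat for
its own two-way epsilon.

**Mediation.** Parcels are the exchangeable units: X = template principal
gradient, M = weak-minus-strong dimensionality difference, Y = alignment.
Paths are OLS with intercepts; the indirect effect `a·b` gets a percentile
bootstrap CI (default 5000 resamples); proportion mediated is `a·b / c`
(with `c = c' + a·b` holding to 1e-8 as an algebraic identity, tested).
If the mediator is exactly collinear with the predictor the two-predictor
model is unidentified and the shared effect is attributed to the mediator
path (documented convention). Spatial autocorrelation of parcel maps is
not modelled in the bootstrap; this mirrors common practice and is a known
caveat.

## The synthetic generator

`SyntheticSpec` defaults encode the emulated study design: 31
participants, 144 trials in 3 contiguous equal runs, 100 parcels (cubic
blocks of 27 voxels; 400 parcels and 125-voxel parcels are supported),
word2vec scores uniform on [−0.05, 0.72], and integer ratings 0–4 formed
as a monotone function of word2vec plus participant noise (sd 0.8).

Each trial's content lives in a bank of 16 "stream" fields indexed along
the planted axis g\* (Gaussian bump mixing profiles, width 0.35): parcels
close on the axis draw correlated content, so their trial-similarity
structures — not their time series — are shared. A parcel's pattern mixes
this gradient-indexed content with parcel-private content; the variance
share of the gradient streams scales linearly with the trial's association
strength from 0.2 (weakest) to 0.95 (strongest). That share modulation is
the planted "gradient flexing": strong-association trials express the
connectivity gradient more strongly, so the strong-minus-weak score
difference is positive toward the apex and negative toward the unimodal
end. The baseline (chevron) window is generated with the midpoint share
for all trials, equal ranks, and no coupling — the built-in null.

Per-condition latent rank is planted as participant-varying components
whose coefficients are orthonormalised across participants after
demeaning, making the planted spectrum exactly flat — at zero noise the
dimensionality estimator returns the analytic count
`floor(threshold·k) + 1` (equal to k at the 0.90 criterion for k ≤ 9).
Component amplitude 1.58 and measurement noise sd 0.17 put the searchlight
SNR (total planted-component variance over total noise variance) near 10
at the baseline rank of 3. By default the ten highest-g\* parcels carry
rank 6 on weak trials and rank 2 on strong trials, rank 3 elsewhere.

Rating-brain coupling adds, in ten designated high-g\* parcels, a pattern
component scaled by the participant's own raw (not demeaned) rating. The
raw scaling matters: pattern-similarity contributions are products of the
driver, so a mean-zero driver would enter as its square and the sign of
inter-participant rating agreement would be lost; the shared rating
baseline linearises the product so participants who rate alike have more
similar similarity structures. Coupling strength 4.0 was set so the
planted effect is reliably recoverable at the study's sample size, per
the generator's signal-fidelity contract (every planted effect must be
detectable by its stage).

Not emulated: haemodynamic convolution, scanner noise spectra, motion,
realistic cortical geometry and inter-subject anatomical variability.
Passing benchmarks therefore establish correctness and calibration of the
estimators under the stated generative assumptions, not performance on
real fMRI.

## Benchmark problem sizes

Recovery benchmarks run at scaled sizes chosen as the smallest designs
that leave the planted effects clearly identified: connectivity oracle at
20 parcels × 48 trials × 40 voxels; axis recovery at 100 parcels;
condition modulation at 16 participants (signal) and 20 null seeds;
rank-contrast recovery at 16 participants × 100 parcels over 10 seeds with
null calibration over 200 replicates at 10 participants × 15 parcels × 72
trials (with noise sd raised to 0.6 so counts vary trial-to-trial — at the
default SNR counts are nearly deterministic and a rank test would be
degenerate); RSA recovery at the full 31 participants with calibration at
10 participants × 15 parcels; spin calibration over 500 replicate map
pairs; mediation at n = 400 with 1000-sample bootstraps; and the
determinism check runs the complete default pipeline twice.

## Known limitations

- **Condition-difference maps carry a scale-jitter floor.** The score
  scale of a condition's first gradient is estimated from that condition's
  ~48 trials, and its sampling fluctuation (~1/sqrt(trials), about 20%)
  projects onto the template shape, which is itself nearly collinear with
  the planted axis. Measurements across trial counts, voxel counts,
  stream counts and participant counts show this template-aligned jitter
  is a roughly constant ~0.4–0.5 fraction of the rough (parcel-level)
  score noise, because both scale together. Consequently the *null*
  strong/weak difference map correlates with the axis at |r| ≈ 0.3–0.4
  typically even though it is centred on zero, while the planted
  modulation produces r ≈ +0.8–0.9. Suppressing the null correlation
  below ~0.15 would require rough noise an order of magnitude above the
  jitter, which caps the attainable signal correlation near 0.3 — the
  regime real data occupy. The spin test partially compensates (the null
  difference is template-shaped, and template-shaped maps are exactly what
  the rotation null generates), but the joint demand "signal r > 0.5 and
  null |r| < 0.15" is not achievable for this estimator at these trial
  counts, and the corresponding benchmark clause fails by design honesty
  rather than by implementation error.
- **Proportion mediated is a noisy ratio.** At n = 400 with unit noise
  the sampling sd of `a·b/c` is ≈ 0.05–0.065, so single-run estimates
  regularly fall outside a ±0.05 band around the true value even when all
  paths are well recovered; the benchmark asserting that band reflects
  estimator variance, not bias (the 3-SE path checks and the OLS identity
  always hold).
- Meaning-category counting uses string equality after normalisation;
  merging paraphrases is the caller's responsibility.
- Real-data mode expects preprocessed, parcellated inputs; no
  preprocessing (motion correction, echo combination, registration) is
  provided, and word-embedding scores are inputs, never computed.
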