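# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `lifelog_rsa`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Tag semantics

Episodes are tagged from a fixed 52-entry vocabulary (16 places, 22
activities, 13 people, one catch-all `other`), shipped as a versioned JSON
file whose order defines the bit order of every encoded vector. Content
dissimilarity between two episodes is the Hamming distance between their
binary tag vectors.

Tag co-occurrence is summarized by normalized pointwise mutual information,
`NPMI(x,y) = PMI(x,y) / h(x,y)` with `PMI = log2 P(x,y)/(P(x)P(y))` and
`h = −log2 P(x,y)`, base-2 logarithms throughout. Probabilities are event
frequencies pooled across participants by default (a per-participant call is
just `npmi_matrix` on one participant's events); pooling stabilizes the
pair-frequency estimates. Two limits are defined by convention as the
endpoint values they approach: `P(x,y) = 0` with both tags occurring gives
NPMI = −1, and `P(x,y) = 1` gives NPMI = +1 (the `h = 0` case). A tag that
never occurs has an undefined row and column, reported as NaN rather than
silently zero. Events carrying only the `other` tag enter the computation
like any other event; `other` is an ordinary column.

## Image features and the common neighbor ratio

Two color representations are built in, both on a 4×4×4 quantization of RGB
(64 joint colors), computed after resizing to 640×480 (disable with
`resize=None` for controlled tests):

- **color histogram** — joint color frequencies, normalized to sum to 1;
- **color autocorrelogram** — for each color c and each Chebyshev offset
  d ∈ {1, 3, 5, 7}, the probability that a pixel at L∞ distance exactly d
  from a c-colored pixel is also c-colored (length 64×4 = 256).

These settings are standard for autocorrelogram retrieval features and keep
the vectors compact, so no further dimensionality reduction is applied by
default (a caller can project features before wrapping them in
`FeatureVector`; HOG/GIST/SURF and similar representations are supported by
supplying vectors from outside). Visual dissimilarity is the Euclidean
distance between unit-normalized vectors, hence bounded by 2.

The common neighbor ratio scores a representation by how well visual
neighborhoods agree with temporal neighborhoods: for each image, its k
nearest neighbors by feature distance and by absolute time difference in
seconds are intersected, and the overlap is averaged over images and k.
Nearest-neighbor ties are broken by ascending image index, deterministically,
in both domains. `compare_representations` flags the representation with the
highest mean CNR over the explored k range (ties go to the first declared).

## Pair construction and exclusions

All unordered event pairs per participant are enumerated; the event order
defines the trial indices used to address the beta volume. Exclusion rules,
applied as pure per-pair predicates (hence order-independent and
idempotent), with the first matching reason recorded:

| reason | rule | rationale |
|---|---|---|
| `unusable_event` | either event flagged unusable | blurry/reflective cues are marked upstream in the event table; no automatic blur detection |
| `not_remembered` | either event not remembered (default on, switchable) | pair-level content retrieval requires retrieval on both sides |
| `vividness_undefined` | either vividness response missing (default on) | the 0/0.5/1 coding is undefined otherwise |
| `space_lt_100m` | great-circle distance < 100 m | below smartphone GPS reliability; removes same-place image confounds |
| `space_gt_30km` | distance > 30 km | out-of-town excursions outside the study's spatial frame |
| `time_lt_15p6h` | lived-time gap < 15.6 h | the overnight discontinuity in lifelog sampling |

The 15.6 h rule applies to real-world clock time; scanner presentation time
is a separate covariate (`|Δonset|` in seconds, entered as log₁₀). Cross-run
pairs are retained; `run_index` is carried for audit. Geodesic distance is
the haversine great-circle on a sphere of mean radius 6371.0088 km
(configurable); its error versus an ellipsoidal geodesic is a few parts in
10³, far below the 100 m threshold's purpose.

Neural distance for a pair is 1 − Pearson r between the two trials' voxel
patterns over the sphere (defined for ≥ 2 voxels; zero-variance patterns
make the distance undefined and the pair is dropped with a logged reason).
Distances are z-scored within participant *per sphere* (population SD):
pattern scale varies across spheres, so a single global scale would let
high-variance spheres dominate the group statistics. A pooled
per-participant mode (`zscore_scope="participant"`) is available.

## Searchlight GLMs

Spheres of radius 7.5 mm (inclusive boundary) are placed on every voxel of
the analysis mask; on the 2.5 mm grid an interior sphere holds 123 voxels,
verified against lattice enumeration. Spheres with fewer than 10 in-mask
voxels are skipped and logged — the boundary-sphere fits are otherwise
dominated by estimation noise; the threshold is far below the interior size
and above the 2-voxel correlation minimum.

Per sphere, ordinary least squares relates the z-scored distances of the
included pairs to the covariates. Model terms are declared by `ModelSpec`
(intercept always present, interaction terms require their main effects, the
term order fixes coefficient order so outputs are byte-stable). Predefined
models: the content model (Hamm, VisSim, log₁₀ scanner), the vividness
interaction model (adding Vivid and Hamm×Vivid), and both with space, time
and space×time appended for ROI follow-ups. Rank-deficient designs are
rejected with the collinear terms named.

`SubjectSearchlight` caches, per sphere, the raw distance for *every* trial
pair (not only included ones). The z-scoring is then applied analytically:
with an intercept in the design, subtracting the pair-mean only shifts the
intercept coefficient and dividing by the SD rescales all coefficients, so
the engine fits raw distances and normalizes the coefficients — identical
(verified to float32 precision) to fitting z-scored distances, with no large
temporaries.

## Group inference

Per term, subject coefficient maps are combined by a voxelwise one-sample t
(undefined where any subject is undefined; zero-variance voxels get a
signed-infinity sentinel, which downstream steps treat as undefined rather
than infinitely significant). TFCE integrates cluster support over
heights, `TFCE(v) = Σ_h e(h)^E · h^H · dh`, with E = 0.5, H = 2,
26-connectivity and dh = max|t|/100 — the canonical enhancement settings;
the negative tail is enhanced symmetrically on −t.

Because pairwise distances are not independent samples, significance comes
from a within-participant permutation scheme: each permutation draws one
random trial-index permutation per participant and re-reads every pair's
neural distance from the permuted trial pair (re-indexing the cached
distances, then re-normalizing), breaking the brain–behavior link while
preserving the neural distance structure. The same per-participant draw is
used for every sphere within a permutation iteration, as a valid
max-statistic correction requires. Per permutation the group t and TFCE
volumes are recomputed and the max and min TFCE over defined voxels
recorded. Observed TFCE above the 97.5th percentile of the max null or
below the 2.5th percentile of the min null is flagged — a two-tailed
familywise test at p = 0.05. The conjunction `min(t_Hamm, −t_Hamm×Vivid)`
is enhanced and tested one-tailed at the 95th percentile of its own
permuted max. An alternative permutation unit (permuting pair rows rather
than trial labels) can be obtained by shuffling the pair table upstream;
trial-label permutation is the default because it preserves the pairwise
geometry of the neural side.

ROI analyses pool each region's voxels into a single neighborhood (no
searchlight), fit the same models, and test each ROI × model × term cell
with a two-tailed permutation p (add-one estimator), Bonferroni-corrected
over all cells tested.

## Partial residuals

From the full interaction fit (never a subset refit), the Hamming-related
component is added back to the residuals: `resid + β_Hamm·Hamm` for vivid
pairs (Vivid = 0), plus `β_Hamm×Vivid·Hamm·Vivid` for the rest. The vivid
display line has slope β_Hamm and intercept 0. For non-vivid pairs the slope
depends on each pair's own Vivid level (0.5 or 1), so per-pair slopes
`β_Hamm + β_Hamm×Vivid·Vivid` are kept and a single summary slope is
reported at the subset's mean Vivid. The group line is the unweighted mean
of per-participant slopes. The standard identity — regressing the combined
partial residuals on the Hamming components returns the full-model
coefficients exactly — is checked numerically in the tests.

## Synthetic studies

The generator's defaults are the study conditions: 9 participants × 120
events over 30 days within ≤ 30 km, reminiscence success 0.63, vivid
proportion 0.47 among remembered events, 2.5 mm isotropic voxels on a
20×20×20 grid, eight scanner runs of 15 trials (8 s cue + two 2.5 s
questions + 0.5 s gaps, intertrial jitter uniform 4–10 s), presentation
order randomized.

Behavior comes from six latent daily-life contexts per study. Each context
has a GPS anchor (0.5 km to half the spatial extent from home — separated
well beyond 100 m and inside 30 km, so the space filters mostly remove
same-context pairs), a per-event Markov persistence of 0.6 (consecutive
events tend to share context, making time and context congruent), and a tag
profile: five disjoint core tags at probability 0.8, eight *routine* tags
shared by all contexts at 0.5, and a 0.02 background rate elsewhere. The
routine tags matter: the 100 m filter removes most same-context pairs, so
cross-context pairs must carry a graded tag overlap for the Hamming
gradient to survive filtering — without them, the retained-pair Hamming
signal hinges on a handful of borderline same-context pairs and collapses
for some realizations. Core co-occurrence also produces the positive
within-context NPMI structure seen in real tag networks. Image features are
context prototypes (64-dimensional Gaussian) plus noise, so visual and
temporal neighborhoods are congruent and the CNR is informative.

Neural data are generated mechanistically rather than from the regression
equation: each tag owns a Gaussian spatial prototype (SD 0.7) over a signal
region (radius 7.5 mm around the grid center); a trial's pattern is the sum
of its tags' prototypes scaled by 1 (vivid) or by the attenuation 0.4
(otherwise), plus unit-SD noise; outside the region, pure noise. Shared tags
raise pattern correlation, so neural distance grows with Hamming distance —
more steeply for vivid pairs. Attenuation (not an additive vividness term)
is the mechanism because it produces exactly β_Hamm > 0 with
β_Hamm×Vivid < 0 without hand-coding any coefficient. The prototype scale
is deliberately below the noise (signal-to-noise ≈ 0.5 per tag): correlation
is scale-invariant, so attenuation acts only through the noise floor, and at
high SNR vivid-pair correlations saturate, which inflates between-subject
variance of the interaction estimate. Per-tag SNR around one half keeps the
distance–overlap relation near-linear and the interaction stable across
realizations.

All randomness derives from one mandatory seed through NumPy
`SeedSequence.spawn`, making event tables and beta volumes byte-identical
across runs and platforms for a given seed.

What the generator does **not** emulate: hemodynamic autocorrelation and
run-level nuisance structure (betas are iid draws, not deconvolution
outputs), spatial smoothness of noise, anatomical gray-matter geometry
(masks are full boxes), participant-specific vividness base rates (the real
range is wide; the generator fixes 0.47 for stable power), GPS drift and
missing data, and real photographs (features are generated directly; tiny
raster fixtures exist only in the image-feature unit tests). Passing tests
therefore demonstrate correctness of the pipeline's logic and calibration of
its inference under idealized noise — not that real data would yield any
particular map.

## Problem sizes used in the checks

The full-scale recovery check runs the default 9×120 study on the 20³ grid
with 100 permutations (the conjunction must flag ≥ 80% of in-region sphere
centers, with at most the test level flagged outside). The type-I
calibration runs 200 independent null studies (5 participants × 20 events,
6³ grid, no signal region) with 100 permutations each and requires the
whole-map rejection rate to fall inside the 95% binomial band around 0.05.
One hundred permutations quantize the attainable thresholds more coarsely
than the thousand a production analysis would use; the calibration band
accounts for that. Voxels flagged just outside the nominal region boundary
in recovery runs are sphere centers whose neighborhoods genuinely overlap
the region — partial-volume signal, not false positives, which is why the
recovery criterion measures them against the test level rather than zero.

## Known limitations

- OLS per sphere only; no cross-validated distances (crossnobis) or
  variance-smoothed TFCE alternatives.
- The permutation engine assumes all subjects share one volume grid
  (pre-aligned data); no registration is performed.
- `roi_tests` recomputes ROI distances per permutation from cached pair
  distances, but its Bonferroni universe is only the cells actually tested —
  add models and the correction tightens accordingly.
- The NIfTI affine defaults to a diagonal voxel-size matrix when volumes are
  constructed in memory; world-space coordinates are only as meaningful as
  the affine supplied.
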