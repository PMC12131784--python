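# Methods

## Model

`mbssm` implements linear point-distribution models over corresponded point
clouds.  The modelling assumptions are the classical ones: (i) correspondence
— the i-th point denotes the same anatomical location on every subject, and
point order is never permuted; (ii) inputs are already aligned (rotationally
groomed upstream) so that after per-body centroid centering the residual
variation is shape, not pose; (iii) shape vectors are drawn from a Gaussian
with low-rank structure, so PCA coefficients are independent with
b_i ~ N(0, λ_i).  No scale normalization is applied: overall size is a real
and clinically meaningful mode of variation and stays in the model.

Construction uses the thin SVD of the row-centered data matrix rather than an
explicit covariance (numerically stabler, identical spectrum); eigenvalues
follow the 1/(n−1) sample-covariance convention.  The convention only rescales
λ uniformly and is applied consistently in sampling, clipping and the χ²
plausibility bound, so every reported ratio is convention-invariant.  A
training set of n samples has at most n−1 non-trivial eigenvectors; modes are
additionally discarded below a relative floor (λ_i < 1e−10·λ_1) and an
absolute floor (1e−20 × the mean squared datum) that distinguishes genuine
variance from centering cancellation noise.  Eigenvector signs are fixed by
making each column's largest-magnitude entry positive, so results are
bit-reproducible across runs.

Fitting uses b = Φᵀ(x − x̄).  The pseudoinverse of a tall matrix with
orthonormal *columns* is its transpose because ΦᵀΦ = I_r; the occasionally
seen justification "ΦΦᵀ = I" is false for truncated bases and matters below
(counterpart prediction).  Regularization is clip-then-scale, in that order:
each coefficient is clipped into ±3√λ_i, then a single uniform scale
s = min(1, √(χ²_{0.997, n−1}/Q)) is applied, with Q the post-clip Mahalanobis
sum.  Minimizing (s−1)² subject to one quadratic constraint admits this closed
form; the test suite keeps a generic SLSQP constrained optimizer as an
independent oracle.  The degrees of freedom are always n_train − 1 (also when
a model is truncated to k modes), and the certainty level defaults to 0.997.

## Distances

Three measures, all in mm: RMS over all 3m coordinates, average Euclidean
point distance d (the headline metric — it reads directly as a 3D error), and
the bidirectional Hausdorff distance (worst case; ignores correspondence).
Hausdorff uses exact brute-force nearest neighbours up to 2048 points and a
KD-tree beyond; both paths agree to 1e−9 on random inputs.  The relation
between d and RMS is tested in its provable (Jensen) form — the mean of
per-point distances never exceeds the root mean of their squares, hence
d ≤ √3·RMS — rather than the loose strict inequality d > RMS, which fails
when per-point distances are equal.

## Validation battery

All procedures derive their randomness from one master seed via
`SeedSequence([master, procedure_id, k, fold])`, so reports are reproducible
and procedures comparable fold-for-fold.

* Ground-truth accuracy: leave-one-out; each fold refits on n−1 subjects and
  fits the left-out shape with all (n−1)−1 modes, regularized.  The distance
  from the fold's training mean to the target is recorded as the baseline that
  isolates the value of the weighted modes over the mean alone.
* Generalization by training samples: for each size k, each fold trains on k
  subjects drawn without replacement from the remaining n−1 (one subset per
  (k, fold) pair).  At k = n−1 the subset is the whole remainder and the
  procedure reduces to ground-truth accuracy record-for-record.
* Generalization by components: full leave-one-out per k with the fitted model
  truncated to its k leading modes before regularization; k = n−2 equals
  ground-truth accuracy exactly.
* Specificity: per mode count k, sample b_i ~ N(0, λ_i) over the leading k
  modes and record the distance to the closest training member (closest by
  average point distance; the Hausdorff value is reported against that same
  member).  The default draw count is 10,000; the tests use 500 and the
  acceptance script 500, which stabilizes means to well under the effect sizes
  examined.

Summaries report median, IQR and mean of d per (procedure, k).

## Coupled-variation decomposition

The combined eigenvector matrix row-partitions by the block layout into
Φ_{C,S} and Φ_{C,H}.  Because both the combined and the single-body models
are trained on the same centered data, each block column lies exactly in the
corresponding single-body data span, so γ_j = Φ_Sᵀ φ_{C,S,j} decomposes it
with residuals at machine precision (asserted < 1e−8).  Normalized absolute
weights form the contribution heatmap A (rows sum to 1; an all-zero row is
flagged degenerate rather than normalized).

Two variance summaries are provided and must not be conflated:

* `variance_attribution(γ, shares)` = Σ_i γ_{j,i}²·share_i — the
  *unit-coefficient profile* of combined mode j: which single-body variation a
  unit step along the mode touches.
* `variance_described(γ, λ_single, λ_C)` = λ_{C,j}·Σ_i γ_{j,i}² / Σ_i λ_{S,i}
  — the proportion of the body's dataset variance actually described by
  combined mode j.  The body's shape varies along mode j with coefficient
  variance λ_{C,j}, so the body variance carried by the mode is λ_{C,j} times
  the squared block norm; summed over all non-trivial modes these proportions
  equal exactly 1 (a trace identity).  The per-unit-mode profile, by contrast,
  caps near ½ per body under perfect coupling simply because a unit combined
  eigenvector splits its norm between the two bodies — it cannot answer "how
  much variation occurs in tandem".

The coupled variation of mode j is v_{J,j} = min over bodies of the described
proportions, and its cumulative sum is the headline coupling quantity; on
generated cohorts it tracks the ground-truth coupling fraction closely
(≈0.008 / 0.26 / 0.50 / 0.75 / 0.996 for f = 0…1 under the default
conditions).  The covariance of the two bodies' contributions to the combined
coefficients is computed both in closed form (Φ_{C,S}ᵀ Σ_{S,H} Φ_{C,H}) and
empirically from per-subject contributions; the two agree to relative 1e−8 by
an algebraic identity, and the normalized magnitude matrix A_B is exported for
heatmaps.

## Counterpart prediction

To predict a missing body from its observed partner: train the combined model
on the remaining n−1 pairs, compute the observed body's contribution
b_1 = Φ_{C,1}ᵀ(x_1 − x̄_1), predict the missing contribution b_2 from b_1
with a multi-output random forest (200 trees, unlimited depth, per-fold
deterministic seed; the regressor and its size are config-overridable, and
all non-trivial modes are used as inputs and outputs), regularize b̂_2 with
the same clip-then-scale procedure over the combined eigenvalues, and read the
missing body's block off the full combined reconstruction:

    y_2 = x̄_2 + Φ_{C,2}(b_1 + b̂_2)

The observed body's contribution must be kept in the readout: for a truncated
column-orthonormal Φ_C the identity is x_2 − x̄_2 = Φ_{C,2}·b with the *full*
coefficient b = b_1 + b_2.  Dropping b_1 (which would be valid only if
ΦΦᵀ = I) shrinks every coupled mode by its squared block norm — about half at
equal body variances — and empirically caps the achievable accuracy near 0.7×
the baseline even with an oracle regressor.  The baseline predictor is the
training mean of the missing body, which is the best possible predictor when
no coupled variation exists.  On fully coupled synthetic cohorts the forest
reaches ≈0.26× the baseline median error; on independent cohorts it stays
within a few percent of the baseline (the regression finds no signal, and the
regularized prediction collapses toward the mean).

## Synthetic populations and plausibility

The plausibility of a shape (pair) is 1 − F_χ²(Σ b_i²/λ_i; n−1) — the
probability of a more extreme shape under the model.  For shapes sampled from
the model itself the Mahalanobis sum is exactly χ²-distributed, so
plausibilities are Uniform(0, 1) (probability integral transform); departures
from uniformity expose generation bias.  Uniformity is assessed with the
conventional one-sample Kolmogorov–Smirnov test against Uniform(0, 1) and the
conventional p-value (small p = non-uniform); descriptions of this test that
invert the role of the p-value appear in the literature and are deliberately
not reproduced.

The independent scheme samples each body from its own single-body model,
concatenates the pair, and fits combined coefficients *without*
regularization — plausibility must be free to fall anywhere in [0, 1] for the
bias to be measurable.  The concatenated pair may have components outside the
combined model's span; the per-draw out-of-span residual norm is reported as a
diagnostic.  On coupled training cohorts the independent scheme both produces
mismatched pairs (too extreme along anti-coupled directions) and
under-disperses along coupled ones; at a coupling fraction of 0.75 and 2000
draws the KS test rejects at p < 0.001 for every tested seed, while the
combined scheme does not reject.

## Ground-truth generator

The generator emulates a paired two-body cohort with known structure.  The
default study conditions, fixed once: n = 45 subjects; a 160-point curved
plate (scapula stand-in, ~150 mm extent) and a 154-point cylinder-plus-
hemisphere (proximal-humerus stand-in, shaft r = 11 mm, head r = 23 mm);
6 shared and 6 body-specific latent modes per body; geometric latent spectra
with 0.6 decay and per-body leads of 8.0 and 6.2 mm; i.i.d. coordinate noise
of 0.04 mm (~1% of each body's deformation variance).  Point counts of
1600/1536 (full anatomical resolution) are available by configuration.

Deformation fields are smooth random Gaussian-bump fields (coherent, low
spatial frequency — bodies deform as anatomy does, not as white noise), with
one designed field per body: a localized inward dent at the point farthest
from the centroid, an analog of the coupled glenoid/humeral-head erosion
pattern.  Per body, the shared and own fields are jointly QR-orthonormalized,
which makes the shared/own variance split exact; the shared amplitudes are
rescaled per body so the achieved coupling fraction equals f exactly.  The
per-body lead separation (8.0 vs 6.2 mm at a common decay: a constant ratio,
so the spectra never cross) is deliberate: if the two bodies had degenerate
spectra, the f = 0 combined covariance would have coincident eigenvalue pairs
across bodies and PCA could mix the independent bodies arbitrarily,
fabricating coupling.

Latent scores are *exactly conditioned*: the (n × q_total) matrix of shared
and own scores is column-centered, QR-orthonormalized and rescaled to unit
sample variance.  The realized cohort therefore carries exactly the specified
coupling — at f = 0 the empirical cross-body latent correlation is zero, not
the O(1/√n) of raw i.i.d. draws, which at n = 45 would contribute a spurious
coupled-variation floor of about 1/(n−1) ≈ 0.023 per effective cross-body
mode pair and confound any test of independence.  The cost is that generated
cohorts are slightly more regular than true i.i.d. samples (no sampling
fluctuation in latent second moments); all downstream randomness —
specificity draws, population generation, regression — remains genuinely
stochastic.

What the generator does *not* emulate: real scapular/humeral geometry (the
templates are abstract smooth bodies), correspondence-optimization error with
its spatially structured artifacts, pose misalignment, laterality, and
non-Gaussian or multimodal population structure.  Passing tests therefore
demonstrate that the pipeline recovers known low-rank Gaussian structure at
anatomical scale and sample size — they do not certify accuracy on clinical
data, where correspondence quality and alignment dominate the error budget.

## Problem sizes and tolerances

Unit tests run on 12–16-subject cohorts with 40/36-point bodies; the
acceptance battery and `scripts/acceptance.py` use the full study conditions
(n = 45, 160/154 points) with 2000-draw generation tests, 500-draw
specificity and 200-tree forests.  Exact linear-algebra identities are
asserted at 1e−8…1e−12; statistical assertions use fixed seeds with margins
chosen from the analyses above.  Degenerate inputs (identical shapes,
all-zero decomposition rows, sub-8-draw KS requests) raise or flag rather
than silently producing numbers.

## Known limitations

* The coupling quantification is eigenvector-based and inherits PCA's
  rotational ambiguity under (near-)degenerate eigenvalues; cumulative v_J is
  stable but per-mode attributions can swap between close modes.
* The forest regressor shrinks predictions toward the training mean at the
  extremes of the latent range; counterpart predictions for outlier subjects
  are conservative.
* Plausibility uses df = n−1 even when trivial modes were discarded (r < n−1);
  for the generic cohorts used here r = n−1, but heavily rank-deficient
  cohorts would make the transform sub-uniform.
* The tool assumes pre-aligned, pre-corresponded inputs; no Procrustes
  alignment or correspondence optimization is performed.
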