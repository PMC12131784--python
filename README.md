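# mbssm — multi-body statistical shape models of corresponded point clouds

Statistical shape models (SSMs) describe the anatomical variation of a
population from corresponded point clouds: the *i*-th point marks the same
anatomical location on every subject, so the cohort can be analysed by PCA
over flattened coordinate vectors.  Most published SSMs model one bone at a
time.  For articulating structures — the canonical example here is the
glenohumeral joint, a scapula paired with a proximal humerus — shape variation
of the two bodies is partly *coupled* (e.g. glenoid erosion co-occurring with
humeral-head erosion), and a combined two-body model can capture what two
independent single-body models cannot: how much variation is shared, how to
predict one body from its partner, and how to generate synthetic joint
populations without bias.

`mbssm` is a toolkit for building and interrogating such one- and two-body
models.  It is aimed at computational-anatomy and biomechanics researchers who
have corresponded point clouds (e.g. ShapeWorks `.particles` output) and want
the full model-quality battery plus the two-body coupling analyses.

## The model

Each subject's per-body clouds are centroid-centered (removing position, not
shape), flattened point-major (`[x1, y1, z1, ..., xm, ym, zm]`) and, for the
combined model, concatenated scapula-first into a 3m-vector (m = 1600 + 1536
points gives 9408 entries at full anatomical resolution).  PCA of the sample
covariance of n training vectors yields the mean shape x̄, orthonormal
eigenvectors Φ = [φ₁ … φᵣ] and eigenvalues λ₁ ≥ … ≥ λᵣ (r ≤ n − 1):

    y = x̄ + Φ b,   bᵢ ~ N(0, λᵢ)

New shapes are fitted by projection b = Φᵀ(x − x̄) and made statistically
plausible by clipping |bᵢ| ≤ 3√λᵢ and then scaling with the s closest to 1
such that Σ (s·bᵢ)²/λᵢ ≤ χ²₀.₉₉₇,ₙ₋₁ (the Mahalanobis plausibility
ellipsoid; the scale has the closed form s = min(1, √(χ²/Q))).

On top of this core the package provides:

* **Validation battery** — leave-one-out ground-truth accuracy (against a
  training-mean baseline), generalization across training-set size and across
  retained modes, specificity (distance of sampled shapes to the closest
  training member), and compactness c(Φ, k) = Σ₁ᵏ λᵢ / Σ λᵢ; distances are
  the average Euclidean point distance and the bidirectional Hausdorff metric.
* **Coupling decomposition** — each combined-model eigenvector splits by body
  into blocks that are decomposed in the single-body mode bases
  (γⱼ = Φ_Sᵀ φ_{C,S,j}); per combined mode, the proportion of each body's
  training variance it describes and the coupled variation
  v_{J,j} = min(v_{C,S,j}, v_{C,H,j}) with its cumulative sum.
* **Counterpart prediction** — leave-one-out prediction of a missing body from
  its partner via a random-forest regression between the bodies'
  combined-coefficient contributions, compared against the training-mean
  baseline.
* **Synthetic populations** — de novo generation from the combined model or
  from two independent single-body models, with plausibility
  1 − F_χ²(Σ bᵢ²/λᵢ; n−1) per generated pair and a Kolmogorov–Smirnov
  uniformity test that exposes the bias of the independent scheme on coupled
  cohorts.
* **Ground-truth generator** — synthetic paired cohorts at anatomical scale
  with an exactly controllable coupled-variance fraction f, standing in for
  clinical cohorts that cannot be redistributed (see `docs/methods.md`).

## Worked example

```python
from mbssm import (ShapeModel, SyntheticCohortSpec, coupling_report,
                   generate_cohort, loo_ground_truth)

spec = SyntheticCohortSpec(n_subjects=45, coupling_fraction=0.5, seed=3)
cohort, record = generate_cohort(spec)

results = ShapeModel.from_cohort(cohort).fit()
print(results.summary())

report = coupling_report(cohort)
print(report.summary())

loo = loo_ground_truth(cohort).to_frame()
print(f"LOO median error: {loo.d_avg.median():.3f} mm "
      f"(training-mean baseline: {loo.baseline_d_avg.median():.3f} mm)")
```

prints (abridged):

```
Point-distribution shape model
==============================================
training shapes (n):        45
vector dimension (3m):      942
bodies:                     scapula (m=160), humerus (m=154)
non-trivial modes (r):      44
plausibility ellipsoid:     chi2(level=0.997, df=44) = 74.140
per-mode clip:              ±3·sqrt(lambda_i)

mode    sqrt(lambda) [mm]    var. share    cumulative
   1            7.1624        0.3184        0.3184
   2            5.6548        0.1985        0.5169
   3            4.3877        0.1195        0.6363
   ...

Coupled two-body variation
==============================================
bodies:                    scapula, humerus
combined modes:            44
cumulative coupled var.:   0.5034

mode    v_scap   v_hume   v_joint    cumulative
   1      0.3190   0.3173   0.3173       0.3173
   2      0.3178   0.0003   0.0003       0.3176
   3      0.0005   0.3171   0.0005       0.3181
   ...

LOO median error: 0.081 mm (training-mean baseline: 0.605 mm)
```

Reading the output: the 45-subject cohort was generated with half of each
body's deformation variance driven by latents shared between the bodies, and
the cumulative coupled variation recovered by the two-body model is 0.503.
Combined mode 1 is a shared deformation (it carries ~32% of *both* bodies'
variance), modes 2 and 3 are body-specific (each touches only one body), and
the leave-one-out test shows the model describes unseen subjects about 7×
more accurately than the training mean alone.

The same analyses are available from the shell:

```bash
mbssm synth --n 45 --f 0.5 --seed 3 --out-dir cohort/
mbssm build --manifest cohort/manifest.yaml --out model.npz
mbssm validate --manifest cohort/manifest.yaml --procedures loo --seed 3 --out loo.csv
mbssm couple --manifest cohort/manifest.yaml --out coupling.csv
mbssm predict --manifest cohort/manifest.yaml --given humerus --target scapula --seed 3 --out pred.csv
mbssm generate --manifest cohort/manifest.yaml --scheme independent --m 2000 --seed 3 --report plaus.csv
```

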