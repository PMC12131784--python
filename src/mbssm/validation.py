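"""Model evaluation battery: ground-truth accuracy, generalization, specificity.

Four procedures, each producing a :class:`ValidationReport` of per-test
records (distances in mm):

* ``loo_ground_truth`` — leave-one-out: rebuild the model without subject i,
  fit the left-out shape with all (n−1)−1 non-trivial modes, regularize, and
  measure average point distance and Hausdorff distance of the reconstruction
  against the target.  The distance from the training mean to the target is
  recorded as a baseline isolating what the weighted modes add over the mean.
* ``generalization_by_samples`` — the same leave-one-out loop, but training on
  k subjects sampled without replacement from the remaining n−1, for each k;
  at k = n−1 the procedure reduces to ground-truth accuracy fold-for-fold.
* ``generalization_by_components`` — full leave-one-out per k, truncating the
  model to the k leading modes before regularization and reconstruction; at
  k = n−2 it equals ground-truth accuracy exactly.
* ``specificity_test`` — samples M shapes from the model per mode count k and
  measures the distance from each to its closest training member: a specific
  model generates only shapes resembling the training population.

Randomness is governed by one master seed; each (procedure, k, fold) gets a
deterministically derived child seed so reports are reproducible and
procedures comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import avg_point_distance, hausdorff_distance
from .model import ShapeModel, ShapeModelResults
from .shapes import Cohort

__all__ = [
    "ValidationRecord",
    "ValidationReport",
    "loo_ground_truth",
    "generalization_by_samples",
    "generalization_by_components",
    "specificity_test",
]

# stable per-procedure ids entering child-seed derivation
_PROC_IDS = {
    "loo_ground_truth": 1,
    "generalization_by_samples": 2,
    "generalization_by_components": 3,
    "specificity": 4,
    "predict_counterpart": 5,
}


def child_rng(master_seed: int, procedure: str, k: int, fold: int) -> np.random.Generator:
    """Deterministic per-(procedure, k, fold) generator from one master seed."""
    seq = np.random.SeedSequence([int(master_seed), _PROC_IDS[procedure], int(k), int(fold)])
    return np.random.default_rng(seq)


@dataclass(frozen=True)
class ValidationRecord:
    """One test observation (distances in mm; baselines where applicable)."""

    procedure: str
    k: int
    fold: int
    d_avg: float
    d_hausdorff: float
    baseline_d_avg: float | None = None
    baseline_d_hausdorff: float | None = None


class ValidationReport:
    """Collection of validation records with tabular summaries."""

    def __init__(self, records: Sequence[ValidationRecord]):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {
                    "procedure": r.procedure,
                    "k": r.k,
                    "fold": r.fold,
                    "d_avg": r.d_avg,
                    "d_hausdorff": r.d_hausdorff,
                    "baseline_d_avg": r.baseline_d_avg,
                    "baseline_d_hausdorff": r.baseline_d_hausdorff,
                }
                for r in self.records
            ]
        )
        for col in ("d_avg", "d_hausdorff", "baseline_d_avg", "baseline_d_hausdorff"):
            frame[col] = frame[col].astype(float)
        return frame

    def summary(self) -> pd.DataFrame:
        """Median, IQR and mean of d_avg per (procedure, k)."""
        frame = self.to_frame()

        def _iqr(x):
            return x.quantile(0.75) - x.quantile(0.25)

        return (
            frame.groupby(["procedure", "k"])["d_avg"]
            .agg(median="median", iqr=_iqr, mean="mean", count="count")
            .reset_index()
        )


def _check_model_ok(results: ShapeModelResults, context: str) -> None:
    if results.n_components == 0:
        raise ValueError(f"{context}: degenerate model with no non-trivial modes")


def _distances(reconstruction: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    return avg_point_distance(reconstruction, target), hausdorff_distance(reconstruction, target)


def loo_ground_truth(cohort: Cohort, bodies: Sequence[str] | None = None) -> ValidationReport:
    """Leave-one-out ground-truth accuracy with training-mean baselines."""
    if cohort.n < 3:
        raise ValueError("leave-one-out requires at least 3 subjects")
    data, layout = cohort.combined_matrix(bodies)
    records = []
    for fold, sid in enumerate(cohort.subject_ids):
        mask = np.arange(cohort.n) != fold
        try:
            results = ShapeModel(data[mask], layout).fit()
            _check_model_ok(results, f"fold {fold} (left out {sid!r})")
        except ValueError as exc:
            raise ValueError(f"fold {fold} (left out {sid!r}): {exc}") from exc
        target = data[fold]
        fit = results.fit_shape(target)
        d, dh = _distances(fit.reconstruction, target)
        bd, bdh = _distances(results.mean, target)
        records.append(
            ValidationRecord("loo_ground_truth", results.n_components, fold, d, dh, bd, bdh)
        )
    return ValidationReport(records)


def generalization_by_samples(
    cohort: Cohort,
    bodies: Sequence[str] | None = None,
    sizes: Sequence[int] | None = None,
    seed: int = 0,
) -> ValidationReport:
    """Generalization across training-set size k (k subjects drawn without
    replacement from the n−1 others, all k−1 modes used)."""
    n = cohort.n
    data, layout = cohort.combined_matrix(bodies)
    if sizes is None:
        sizes = range(2, n)
    records = []
    for k in sizes:
        if not 2 <= k <= n - 1:
            raise ValueError(f"training size k={k} must lie in [2, {n - 1}]")
        for fold in range(n):
            others = np.delete(np.arange(n), fold)
            if k == n - 1:
                subset = others  # the full remainder: reduces to ground truth
            else:
                rng = child_rng(seed, "generalization_by_samples", k, fold)
                subset = rng.choice(others, size=k, replace=False)
            results = ShapeModel(data[subset], layout).fit()
            _check_model_ok(results, f"k={k} fold {fold}")
            target = data[fold]
            fit = results.fit_shape(target)
            d, dh = _distances(fit.reconstruction, target)
            records.append(ValidationRecord("generalization_by_samples", k, fold, d, dh))
    return ValidationReport(records)


def generalization_by_components(
    cohort: Cohort,
    bodies: Sequence[str] | None = None,
    ks: Sequence[int] | None = None,
) -> ValidationReport:
    """Generalization across number of retained modes k (full leave-one-out,
    model truncated to the k leading modes before regularization)."""
    n = cohort.n
    if n < 3:
        raise ValueError("leave-one-out requires at least 3 subjects")
    data, layout = cohort.combined_matrix(bodies)
    if ks is None:
        ks = range(1, n - 1)
    ks = list(ks)
    for k in ks:
        if not 1 <= k <= n - 2:
            raise ValueError(f"component count k={k} must lie in [1, {n - 2}]")
    records = []
    for fold in range(n):
        mask = np.arange(n) != fold
        results = ShapeModel(data[mask], layout).fit()
        _check_model_ok(results, f"fold {fold}")
        target = data[fold]
        for k in ks:
            truncated = results.truncate(min(k, results.n_components))
            fit = truncated.fit_shape(target)
            d, dh = _distances(fit.reconstruction, target)
            records.append(ValidationRecord("generalization_by_components", k, fold, d, dh))
    return ValidationReport(records)


def specificity_test(
    results: ShapeModelResults,
    training_vectors: np.ndarray,
    n_draws: int = 10_000,
    ks: Sequence[int] | None = None,
    seed: int = 0,
) -> ValidationReport:
    """Specificity: distance from model-sampled shapes to the closest training
    member (closest by average point distance; Hausdorff to that member)."""
    training = np.atleast_2d(np.asarray(training_vectors, dtype=float))
    if training.shape[0] == 0:
        raise ValueError("training set must be non-empty")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    _check_model_ok(results, "specificity")
    if ks is None:
        ks = range(1, results.n_components + 1)
    train_pts = training.reshape(training.shape[0], -1, 3)
    records = []
    for k in ks:
        rng = child_rng(seed, "specificity", k, 0)
        b = results.sample_coefficients(rng, n_draws, k)
        shapes = results.mean + b @ results.components[:, :k].T
        shape_pts = shapes.reshape(n_draws, -1, 3)
        # (n_draws, n_train) mean point distances, one training member at a time
        dmat = np.empty((n_draws, training.shape[0]))
        for j in range(training.shape[0]):
            dmat[:, j] = np.linalg.norm(shape_pts - train_pts[j], axis=2).mean(axis=1)
        closest = dmat.argmin(axis=1)
        for draw in range(n_draws):
            dh = hausdorff_distance(shape_pts[draw], train_pts[closest[draw]])
            records.append(
                ValidationRecord("specificity", k, draw, float(dmat[draw, closest[draw]]), dh)
            )
    return ValidationReport(records)
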