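"""Coupled two-body variation: eigenvector decomposition, variance
attribution, contribution covariance, and missing-counterpart prediction.

A combined two-body model concatenates both bodies into one vector, so each
combined eigenvector φ_C,j splits by the block layout into a scapula portion
φ_{C,S,j} and a humerus portion φ_{C,H,j}.  Each portion lies in the span of
the corresponding single-body model (both models see the same centered data),
so it can be decomposed exactly as a linear combination of single-body modes:

    γ_j = Φ_Sᵀ φ_{C,S,j}

Normalized absolute weights α give the contribution matrix A (row j: which
single-body modes make up combined mode j).  Since the body's shape varies
along combined mode j with coefficient variance λ_{C,j}, the proportion of the
scapula training variance described by that mode is
v_{C,S,j} = λ_{C,j} Σ_i γ_{j,i}² / Σ_i λ_{S,i} (summing to 1 over modes); the
coupled variation of mode j is v_{J,j} = min(v_{C,S,j}, v_{C,H,j}) — variance
of the two bodies that co-occurs along one combined mode — and its cumulative
sum quantifies how much of the joint's variation is shared rather than
body-specific.

For prediction, combined-model coefficients split additively into per-body
contributions b = b_S + b_H with b_X = Φ_{C,X}ᵀ(x_X − x̄_X).  Their linear
covariation has the closed form Cov(b_S, b_H) = Φ_{C,S}ᵀ Σ_{S,H} Φ_{C,H}
(Σ_{S,H} the cross-covariance block of the training data), computed here both
in closed form and empirically as a consistency check.  When only one body is
observed, a random-forest regressor mapping b_given → b_missing (trained on
the leave-one-out cohort) predicts the counterpart; with no coupled variation
the best predictor degenerates to the training mean, which is the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import avg_point_distance, hausdorff_distance
from .model import ShapeModel, ShapeModelResults
from .shapes import Cohort
from .validation import ValidationRecord, ValidationReport, child_rng

__all__ = [
    "BlockEigenDecomposition",
    "CouplingReport",
    "CounterpartPrediction",
    "split_blocks",
    "decompose_combined_eigenvectors",
    "variance_attribution",
    "variance_described",
    "coupled_variation",
    "contribution_covariance",
    "coupling_report",
    "predict_counterpart_loo",
]


@dataclass(frozen=True)
class BlockEigenDecomposition:
    """Decomposition of one body's block of combined eigenvectors into
    single-body modes.

    ``gamma[j, i]`` is the weight of single-body mode i in combined mode j's
    block; ``contribution[j]`` is the normalized absolute row (NaN if the row
    is degenerate, i.e. all-zero); ``residuals[j]`` is the out-of-span norm
    ‖Φ_single γ_j − φ_block,j‖.
    """

    gamma: np.ndarray  # (r_combined, r_single)
    contribution: np.ndarray  # (r_combined, r_single), rows sum to 1 or NaN
    residuals: np.ndarray  # (r_combined,)
    degenerate: np.ndarray  # (r_combined,) bool


@dataclass(frozen=True)
class CouplingReport:
    """Per-mode coupled-variation quantification of a two-body model."""

    bodies: tuple[str, str]
    contribution: dict[str, np.ndarray]  # body -> A matrix
    v_body: dict[str, np.ndarray]  # body -> v_{C,X,j} per combined mode
    v_joint: np.ndarray  # per-mode min over bodies
    v_joint_cumulative: np.ndarray
    contribution_cov: np.ndarray  # raw Cov(b_S, b_H)
    contribution_cov_empirical: np.ndarray
    a_b: np.ndarray  # |Cov| / max |Cov|

    def summary(self) -> str:
        s, h = self.bodies
        lines = [
            "Coupled two-body variation",
            "=" * 46,
            f"bodies:                    {s}, {h}",
            f"combined modes:            {self.v_joint.size}",
            f"cumulative coupled var.:   {self.v_joint_cumulative[-1]:.4f}",
            "",
            f"mode    v_{s[:4]:<6} v_{h[:4]:<6} v_joint    cumulative",
        ]
        for j in range(min(self.v_joint.size, 10)):
            lines.append(
                f"{j + 1:>4}    {self.v_body[s][j]:>8.4f} {self.v_body[h][j]:>8.4f} "
                f"{self.v_joint[j]:>8.4f}    {self.v_joint_cumulative[j]:>9.4f}"
            )
        if self.v_joint.size > 10:
            lines.append(f"   ... ({self.v_joint.size - 10} further modes)")
        return "\n".join(lines)


@dataclass(frozen=True)
class CounterpartPrediction:
    """One leave-one-out counterpart prediction."""

    fold: int
    subject_id: str
    given_body: str
    predicted_body: str
    predicted_shape: np.ndarray
    b_given: np.ndarray
    b_predicted: np.ndarray  # regularized


def split_blocks(results: ShapeModelResults) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Row-partition a combined model's Φ and x̄ by body.

    Returns ``body_label -> (Φ_block, mean_block)``; stacking the blocks in
    layout order restores the originals exactly.
    """
    phi_blocks = results.layout.split_rows(results.components)
    mean_blocks = results.layout.split(results.mean)
    return {label: (phi_blocks[label], mean_blocks[label]) for label in results.layout.labels}


def decompose_combined_eigenvectors(
    phi_block: np.ndarray, single_results: ShapeModelResults
) -> BlockEigenDecomposition:
    """Express a body's block of combined eigenvectors in single-body modes."""
    phi_block = np.asarray(phi_block, dtype=float)
    phi_single = single_results.components
    if phi_block.shape[0] != phi_single.shape[0]:
        raise ValueError(
            f"block has {phi_block.shape[0]} rows, single-body model has {phi_single.shape[0]}"
        )
    gamma = (phi_single.T @ phi_block).T  # (r_combined, r_single)
    sums = np.abs(gamma).sum(axis=1)
    degenerate = sums == 0
    contribution = np.full_like(gamma, np.nan)
    ok = ~degenerate
    contribution[ok] = np.abs(gamma[ok]) / sums[ok, None]
    residuals = np.linalg.norm(phi_block - phi_single @ gamma.T, axis=0)
    return BlockEigenDecomposition(gamma, contribution, residuals, degenerate)


def variance_attribution(
    decomposition: BlockEigenDecomposition, eigenvalue_shares: np.ndarray
) -> np.ndarray:
    """Per combined mode j: v_j = Σ_i γ_{j,i}² · share_i.

    This is the unit-coefficient profile of combined mode j: it weights the
    squared decomposition of the (unit-norm) eigenvector block by the
    single-body variance shares, answering "which single-body variation does
    a unit step along this combined direction touch".  Because a unit
    combined eigenvector splits its norm between the bodies, these values do
    not sum to 1 over modes; for the proportion of a body's dataset variance
    actually described by each combined mode, weight by the combined
    eigenvalues instead — see :func:`variance_described`.
    """
    shares = np.asarray(eigenvalue_shares, dtype=float)
    if np.any(shares < 0):
        raise ValueError("eigenvalue shares must be non-negative")
    if not np.isclose(shares.sum(), 1.0, atol=1e-8):
        raise ValueError(f"eigenvalue shares must sum to 1, got {shares.sum():.6f}")
    if shares.size != decomposition.gamma.shape[1]:
        raise ValueError("share vector length must equal the single-body mode count")
    return decomposition.gamma**2 @ shares


def variance_described(
    decomposition: BlockEigenDecomposition,
    single_eigenvalues: np.ndarray,
    combined_eigenvalues: np.ndarray,
) -> np.ndarray:
    """Proportion of one body's training variance described by each combined mode.

    Under the combined model the body's shape varies as Σ_j φ_block,j b_j with
    Var[b_j] = λ_{C,j}, so the body variance carried by combined mode j is
    λ_{C,j} ‖φ_block,j‖² = λ_{C,j} Σ_i γ_{j,i}² (the block lies in the
    single-body span).  Divided by the body's total training variance Σ_i
    λ_{single,i}, these proportions are non-negative and sum to exactly 1 over
    all non-trivial combined modes.
    """
    lam_single = np.asarray(single_eigenvalues, dtype=float)
    lam_combined = np.asarray(combined_eigenvalues, dtype=float)
    if np.any(lam_single <= 0) or np.any(lam_combined <= 0):
        raise ValueError("eigenvalues must be positive")
    if lam_combined.size != decomposition.gamma.shape[0]:
        raise ValueError("combined eigenvalue count must equal the combined mode count")
    block_norms_sq = np.sum(decomposition.gamma**2, axis=1)
    return lam_combined * block_norms_sq / lam_single.sum()


def coupled_variation(v_a: np.ndarray, v_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode coupled variation min(v_a, v_b) and its cumulative sum."""
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape:
        raise ValueError(f"length mismatch: {v_a.shape} vs {v_b.shape}")
    v_joint = np.minimum(v_a, v_b)
    return v_joint, np.cumsum(v_joint)


def contribution_covariance(
    cohort: Cohort,
    combined_results: ShapeModelResults,
    bodies: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariance of the two bodies' contributions to combined coefficients.

    Returns ``(cov_closed_form, cov_empirical, A_B)``: the closed form
    Φ_{C,S}ᵀ Σ_{S,H} Φ_{C,H}, the empirical covariance of per-subject
    contributions b_S, b_H, and the normalized magnitude heatmap
    A_B = |Cov| / max|Cov|.
    """
    if cohort.n < 3:
        raise ValueError("contribution covariance requires at least 3 subjects")
    bodies = tuple(bodies) if bodies is not None else combined_results.layout.labels
    if len(bodies) != 2:
        raise ValueError("contribution covariance is defined for exactly two bodies")
    blocks = split_blocks(combined_results)
    data, layout = cohort.combined_matrix(bodies)
    if layout.total_dim != combined_results.layout.total_dim:
        raise ValueError("cohort layout does not match the combined model")
    split = layout.split(data)

    contribs = {}
    for body in bodies:
        phi_b, mean_b = blocks[body]
        contribs[body] = (split[body] - mean_b) @ phi_b  # (n, r)

    a, b = bodies
    n = cohort.n
    ca = contribs[a] - contribs[a].mean(axis=0)
    cb = contribs[b] - contribs[b].mean(axis=0)
    cov_emp = ca.T @ cb / (n - 1)

    xa = split[a] - split[a].mean(axis=0)
    xb = split[b] - split[b].mean(axis=0)
    sigma_ab = xa.T @ xb / (n - 1)
    cov_closed = blocks[a][0].T @ sigma_ab @ blocks[b][0]

    max_abs = np.abs(cov_closed).max()
    a_b = np.abs(cov_closed) / max_abs if max_abs > 0 else np.abs(cov_closed)
    return cov_closed, cov_emp, a_b


def coupling_report(cohort: Cohort, bodies: Sequence[str] | None = None) -> CouplingReport:
    """Full coupled-variation analysis: builds the two single-body models and
    the combined model on the same cohort and assembles all quantities."""
    bodies = tuple(bodies) if bodies is not None else cohort.bodies
    if len(bodies) != 2:
        raise ValueError("coupling analysis is defined for exactly two bodies")
    combined = ShapeModel.from_cohort(cohort, bodies).fit()
    singles = {body: ShapeModel.from_cohort(cohort, [body]).fit() for body in bodies}
    blocks = split_blocks(combined)

    contribution, v_body = {}, {}
    for body in bodies:
        decomp = decompose_combined_eigenvectors(blocks[body][0], singles[body])
        contribution[body] = decomp.contribution
        v_body[body] = variance_described(
            decomp, singles[body].eigenvalues, combined.eigenvalues
        )

    v_joint, v_cum = coupled_variation(v_body[bodies[0]], v_body[bodies[1]])
    cov_closed, cov_emp, a_b = contribution_covariance(cohort, combined, bodies)
    return CouplingReport(
        bodies=(bodies[0], bodies[1]),
        contribution=contribution,
        v_body=v_body,
        v_joint=v_joint,
        v_joint_cumulative=v_cum,
        contribution_cov=cov_closed,
        contribution_cov_empirical=cov_emp,
        a_b=a_b,
    )


def predict_counterpart_loo(
    cohort: Cohort,
    given_body: str,
    predicted_body: str,
    n_estimators: int = 200,
    seed: int = 0,
) -> tuple[ValidationReport, list[CounterpartPrediction]]:
    """Leave-one-out missing-counterpart prediction through the combined model.

    Per fold: train the combined model on the other n−1 pairs, regress the
    missing body's contribution vector on the given body's with a random
    forest, regularize the prediction (per-mode clip then uniform scaling into
    the χ² ellipsoid over the combined eigenvalues), and read the missing
    body's block off the full combined reconstruction,
    y_2 = x̄_2 + Φ_{C,2}(b_1 + b̂_2) — the full coefficient is the sum of both
    contributions, so the observed body's contribution stays in.  The baseline
    is the training mean of the missing body — the best predictor absent any
    coupled variation.
    """
    from sklearn.ensemble import RandomForestRegressor

    if given_body == predicted_body:
        raise ValueError("given and predicted bodies must differ")
    for body in (given_body, predicted_body):
        if body not in cohort.bodies:
            raise ValueError(f"unknown body label {body!r}; cohort has {cohort.bodies}")
    if cohort.n < 4:
        raise ValueError("counterpart prediction requires at least 4 subjects")

    bodies = (given_body, predicted_body)
    data, layout = cohort.combined_matrix(bodies)
    records, predictions = [], []
    for fold, sid in enumerate(cohort.subject_ids):
        mask = np.arange(cohort.n) != fold
        results = ShapeModel(data[mask], layout).fit()
        blocks = split_blocks(results)
        phi_1, mean_1 = blocks[given_body]
        phi_2, mean_2 = blocks[predicted_body]
        split = layout.split(data)

        b1_train = (split[given_body][mask] - mean_1) @ phi_1
        b2_train = (split[predicted_body][mask] - mean_2) @ phi_2

        rng = child_rng(seed, "predict_counterpart", 0, fold)
        forest = RandomForestRegressor(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        forest.fit(b1_train, b2_train)

        b1_test = (split[given_body][fold] - mean_1) @ phi_1
        b2_pred = forest.predict(b1_test[None, :])[0]
        fit = results.regularize_params(b2_pred)
        # the missing body's block of the full combined reconstruction: the
        # full coefficient is the sum of both bodies' contributions, so the
        # observed body's contribution must be kept (dropping it would shrink
        # every coupled mode by its squared block norm)
        y2 = mean_2 + phi_2 @ (b1_test + fit.b_hat)

        target = split[predicted_body][fold]
        d = avg_point_distance(y2, target)
        dh = hausdorff_distance(y2, target)
        bd = avg_point_distance(mean_2, target)
        bdh = hausdorff_distance(mean_2, target)
        records.append(
            ValidationRecord("predict_counterpart", results.n_components, fold, d, dh, bd, bdh)
        )
        predictions.append(
            CounterpartPrediction(fold, sid, given_body, predicted_body, y2, b1_test, fit.b_hat)
        )
    return ValidationReport(records), predictions


def plot_heatmap(matrix: np.ndarray, path, title: str = "", xlabel: str = "", ylabel: str = "") -> None:
    """Save a simple matrix heatmap (diagnostic figure for A_S/A_H/A_B)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.asarray(matrix), aspect="auto", cmap="viridis")
    ax.set_title(title)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
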