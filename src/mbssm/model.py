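"""PCA point-distribution shape models: construction, fitting, regularization.

The model is the classical linear point-distribution model.  Given n training
shape vectors x_1..x_n (each per-body centroid-centered, coordinates in mm),
PCA of the sample covariance yields a mean shape x̄, an orthonormal matrix of
eigenvectors Φ = [φ_1 .. φ_r] and eigenvalues λ_1 ≥ ... ≥ λ_r > 0 (mm²).  New
shapes are synthesized as

    y = x̄ + Φ b,        b_i ~ N(0, λ_i) independently,

and a target x is fitted by projection, b = Φᵀ(x − x̄) (Φ has orthonormal
columns, so its pseudoinverse is its transpose).  A training set of n samples
yields at most n − 1 non-trivial eigenvectors.  No scaling normalization is
applied to the data, so overall size variation stays in the model; centering
removes position ("pose") only.

Fitted coefficients are made statistically plausible in two steps: each b_i is
clipped into ±3√λ_i, then a uniform scale s closest to 1 is applied so the
Mahalanobis sum Q = Σ (s b_i)²/λ_i stays inside the chi-squared ellipsoid
Q ≤ χ²_{0.997, n−1}.  Minimizing (s − 1)² under this single quadratic
constraint has the closed form s = min(1, sqrt(χ²_bound / Q)).

The public surface follows the model/results split: :class:`ShapeModel` holds
the training data and ``fit()`` performs the eigendecomposition, returning a
:class:`ShapeModelResults` that carries x̄, Φ, λ and all downstream operations
(fitting, sampling, compactness, mode sweeps, serialization).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .shapes import BlockLayout, Cohort

__all__ = ["ShapeModel", "ShapeModelResults", "FitResult", "build_ssm"]

#: eigenvalues below this fraction of the leading one are treated as numerical zero
TRIVIAL_EIGENVALUE_RTOL = 1e-10

#: tolerance on per-block centroid norms when checking that inputs are centered
CENTERING_TOL = 1e-6


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting a shape model to one target vector.

    Attributes
    ----------
    b_raw : ndarray
        Unregularized projection coefficients Φᵀ(x − x̄).
    b_hat : ndarray
        Regularized coefficients after per-mode clipping and uniform scaling.
    scale_s : float
        Applied uniform scale; 1 when the ellipsoid constraint is slack.
    reconstruction : ndarray
        y = x̄ + Φ b_hat.
    mahalanobis_q : float
        Σ b_hat_i² / λ_i of the regularized coefficients.
    residual_norm : float
        Out-of-span residual ‖x − x̄ − Φ b_raw‖ of the projection.
    """

    b_raw: np.ndarray
    b_hat: np.ndarray
    scale_s: float
    reconstruction: np.ndarray
    mahalanobis_q: float
    residual_norm: float


class ShapeModel:
    """PCA shape model specification over a matrix of training shape vectors.

    Parameters
    ----------
    data : ndarray, shape (n, p)
        Training shape vectors as rows, already per-body centroid-centered.
    layout : BlockLayout, optional
        Body block structure of the vectors.  Defaults to a single anonymous
        block covering the whole vector.
    check_centered : bool
        If true (default), reject inputs whose per-block centroids exceed
        ``CENTERING_TOL`` rather than silently re-centering.
    """

    def __init__(
        self,
        data: np.ndarray | Sequence[np.ndarray],
        layout: BlockLayout | None = None,
        check_centered: bool = True,
    ) -> None:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.ndim != 2:
            raise ValueError("data must be a 2-D (n, p) array of shape vectors")
        n, p = data.shape
        if n < 2:
            raise ValueError(f"need at least 2 training shapes, got {n}")
        if p % 3 != 0:
            raise ValueError(f"vector length {p} is not divisible by 3")
        if layout is None:
            layout = BlockLayout.from_counts([("body", p // 3)])
        if layout.total_dim != p:
            raise ValueError(f"layout covers {layout.total_dim} entries, data has {p}")
        if check_centered:
            for blk in layout.blocks:
                centroids = data[:, blk.slice].reshape(n, blk.m, 3).mean(axis=1)
                worst = np.abs(centroids).max()
                if worst > CENTERING_TOL:
                    raise ValueError(
                        f"block {blk.body_label!r} is not centroid-centered "
                        f"(max |centroid component| = {worst:.3g} mm); center per body first"
                    )
        self.data = data
        self.layout = layout

    @classmethod
    def from_cohort(cls, cohort: Cohort, bodies: Sequence[str] | None = None, **kwargs) -> "ShapeModel":
        """Build the model spec from a cohort, concatenating the named bodies."""
        data, layout = cohort.combined_matrix(bodies)
        return cls(data, layout, **kwargs)

    def fit(self) -> "ShapeModelResults":
        """Estimate mean, eigenvectors and eigenvalues via thin SVD.

        The SVD of the centered data matrix is used instead of forming the
        p x p covariance explicitly; eigenvalues follow the 1/(n−1) sample
        covariance convention.  At most n − 1 non-trivial components are
        retained and eigenvector signs are fixed so each column's
        largest-magnitude entry is positive.
        """
        n = self.data.shape[0]
        mean = self.data.mean(axis=0)
        centered = self.data - mean
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        eigenvalues = svals**2 / (n - 1)
        components = vt.T  # columns are candidate eigenvectors

        r_max = min(n - 1, components.shape[1])
        eigenvalues = eigenvalues[:r_max]
        components = components[:, :r_max]
        # absolute floor guards against pure cancellation noise (identical
        # shapes give lambda ~ (eps * |x|)^2, far below any real variance)
        floor = 1e-20 * max(1.0, float(np.mean(self.data**2)))
        if eigenvalues.size and eigenvalues[0] > floor:
            keep = eigenvalues > TRIVIAL_EIGENVALUE_RTOL * eigenvalues[0]
        else:
            keep = np.zeros(eigenvalues.size, dtype=bool)
        eigenvalues = eigenvalues[keep]
        components = components[:, keep]

        # deterministic sign: largest-|value| entry of each eigenvector positive
        for j in range(components.shape[1]):
            i = np.argmax(np.abs(components[:, j]))
            if components[i, j] < 0:
                components[:, j] = -components[:, j]

        return ShapeModelResults(
            mean=mean,
            components=components,
            eigenvalues=eigenvalues,
            n_train=n,
            layout=self.layout,
        )


class ShapeModelResults:
    """Fitted PCA shape model: x̄, Φ, λ, and the operations built on them."""

    def __init__(
        self,
        mean: np.ndarray,
        components: np.ndarray,
        eigenvalues: np.ndarray,
        n_train: int,
        layout: BlockLayout,
        chi2_level: float = 0.997,
        clip_multiple: float = 3.0,
    ) -> None:
        self.mean = np.asarray(mean, dtype=float)
        self.components = np.asarray(components, dtype=float)
        self.eigenvalues = np.asarray(eigenvalues, dtype=float)
        self.n_train = int(n_train)
        self.layout = layout
        if not 0 < chi2_level < 1:
            raise ValueError("chi2_level must lie in (0, 1)")
        if clip_multiple <= 0:
            raise ValueError("clip_multiple must be positive")
        self.chi2_level = float(chi2_level)
        self.clip_multiple = float(clip_multiple)
        if self.components.shape != (self.mean.size, self.eigenvalues.size):
            raise ValueError("components must have shape (p, r)")
        if np.any(np.diff(self.eigenvalues) > 0):
            raise ValueError("eigenvalues must be sorted non-increasing")

    # ------------------------------------------------------------------
    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    @property
    def dof(self) -> int:
        """Degrees of freedom of the plausibility ellipsoid: n_train − 1."""
        return self.n_train - 1

    @property
    def chi2_bound(self) -> float:
        """χ² quantile bounding the Mahalanobis sum of plausible coefficients."""
        return float(stats.chi2.ppf(self.chi2_level, self.dof))

    def truncate(self, k: int) -> "ShapeModelResults":
        """Results view retaining only the k leading modes (n_train unchanged)."""
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k must lie in [1, {self.n_components}], got {k}")
        return ShapeModelResults(
            self.mean,
            self.components[:, :k],
            self.eigenvalues[:k],
            self.n_train,
            self.layout,
            self.chi2_level,
            self.clip_multiple,
        )

    # ------------------------------------------------------------------
    def fit_params(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        """Project a centered target onto the modes: b = Φᵀ(x − x̄).

        Returns the raw coefficients and the out-of-span residual norm.
        """
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.size != self.mean.size:
            raise ValueError(f"target length {x.size} != model dimension {self.mean.size}")
        delta = x - self.mean
        b = self.components.T @ delta
        residual = float(np.linalg.norm(delta - self.components @ b))
        return b, residual

    def regularize_params(self, b: np.ndarray) -> FitResult:
        """Clip per-mode, then uniformly scale into the plausibility ellipsoid."""
        b = np.asarray(b, dtype=float).reshape(-1)
        if b.size != self.n_components:
            raise ValueError(f"coefficient length {b.size} != r = {self.n_components}")
        lam = self.eigenvalues
        if np.any(lam <= 0):
            raise ValueError("all eigenvalues in scope must be positive")
        bound = self.clip_multiple * np.sqrt(lam)
        b_clip = np.clip(b, -bound, bound)
        q = float(np.sum(b_clip**2 / lam))
        chi2_bound = self.chi2_bound
        s = 1.0 if q <= chi2_bound else float(np.sqrt(chi2_bound / q))
        b_hat = s * b_clip
        return FitResult(
            b_raw=b,
            b_hat=b_hat,
            scale_s=s,
            reconstruction=self.reconstruct(b_hat),
            mahalanobis_q=float(np.sum(b_hat**2 / lam)),
            residual_norm=0.0,
        )

    def fit_shape(self, x: np.ndarray, regularize: bool = True) -> FitResult:
        """Project a target and (optionally) regularize; returns the full fit."""
        b, residual = self.fit_params(x)
        if regularize:
            res = self.regularize_params(b)
            return FitResult(b, res.b_hat, res.scale_s, res.reconstruction, res.mahalanobis_q, residual)
        lam = self.eigenvalues
        return FitResult(b, b, 1.0, self.reconstruct(b), float(np.sum(b**2 / lam)), residual)

    def reconstruct(self, b: np.ndarray) -> np.ndarray:
        """y = x̄ + Φ b.  Coefficients shorter than r address leading modes."""
        b = np.asarray(b, dtype=float).reshape(-1)
        if b.size > self.n_components:
            raise ValueError(f"coefficient length {b.size} exceeds r = {self.n_components}")
        return self.mean + self.components[:, : b.size] @ b

    def sample_shape(self, rng: np.random.Generator, k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Draw b_i ~ N(0, λ_i) for the k leading modes and synthesize a shape."""
        if k is None:
            k = self.n_components
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k must lie in [1, {self.n_components}], got {k}")
        b = rng.standard_normal(k) * np.sqrt(self.eigenvalues[:k])
        return self.reconstruct(b), b

    def sample_coefficients(self, rng: np.random.Generator, size: int, k: int | None = None) -> np.ndarray:
        """Vectorized draw of ``size`` coefficient vectors over the k leading modes."""
        if k is None:
            k = self.n_components
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k must lie in [1, {self.n_components}], got {k}")
        return rng.standard_normal((size, k)) * np.sqrt(self.eigenvalues[:k])

    def compactness(self, k: int) -> float:
        """Proportion of total training variance in the k leading modes."""
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k must lie in [1, {self.n_components}], got {k}")
        return float(self.eigenvalues[:k].sum() / self.eigenvalues.sum())

    def mode_sweep(self, mode_index: int, n_steps: int = 7) -> list[tuple[float, np.ndarray, np.ndarray]]:
        """Sweep one mode across ±clip_multiple·√λ_i.

        Returns ``(b_value, shape, per-point displacement magnitudes)`` per
        step; mode_index is 1-based as modes are conventionally numbered.
        """
        if not 1 <= mode_index <= self.n_components:
            raise ValueError(f"mode_index must lie in [1, {self.n_components}], got {mode_index}")
        if n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        phi = self.components[:, mode_index - 1]
        limit = self.clip_multiple * np.sqrt(self.eigenvalues[mode_index - 1])
        out = []
        for b_val in np.linspace(-limit, limit, n_steps):
            shape = self.mean + b_val * phi
            disp = np.linalg.norm((shape - self.mean).reshape(-1, 3), axis=1)
            out.append((float(b_val), shape, disp))
        return out

    # ------------------------------------------------------------------
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def summary(self) -> str:
        """Human-readable summary of the fitted model."""
        lines = [
            "Point-distribution shape model",
            "=" * 46,
            f"training shapes (n):        {self.n_train}",
            f"vector dimension (3m):      {self.mean.size}",
            f"bodies:                     {', '.join(f'{b.body_label} (m={b.m})' for b in self.layout.blocks)}",
            f"non-trivial modes (r):      {self.n_components}",
            f"plausibility ellipsoid:     chi2(level={self.chi2_level}, df={self.dof}) = {self.chi2_bound:.3f}",
            f"per-mode clip:              ±{self.clip_multiple:g}·sqrt(lambda_i)",
            "",
            "mode    sqrt(lambda) [mm]    var. share    cumulative",
        ]
        shares = self.explained_variance_ratio()
        cum = np.cumsum(shares)
        for i in range(min(self.n_components, 10)):
            lines.append(
                f"{i + 1:>4}    {np.sqrt(self.eigenvalues[i]):>14.4f}    {shares[i]:>10.4f}    {cum[i]:>10.4f}"
            )
        if self.n_components > 10:
            lines.append(f"   ... ({self.n_components - 10} further modes)")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz archive (mean, Φ, λ, layout, n_train)."""
        import json

        np.savez(
            path,
            format_version=np.array("mbssm-model-1"),
            mean=self.mean,
            components=self.components,
            eigenvalues=self.eigenvalues,
            n_train=np.array(self.n_train),
            layout=np.array(json.dumps(self.layout.to_dict())),
            chi2_level=np.array(self.chi2_level),
            clip_multiple=np.array(self.clip_multiple),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModelResults":
        import json

        with np.load(path, allow_pickle=False) as archive:
            version = str(archive["format_version"])
            if version != "mbssm-model-1":
                raise ValueError(f"unsupported model format {version!r}")
            return cls(
                mean=archive["mean"],
                components=archive["components"],
                eigenvalues=archive["eigenvalues"],
                n_train=int(archive["n_train"]),
                layout=BlockLayout.from_dict(json.loads(str(archive["layout"]))),
                chi2_level=float(archive["chi2_level"]),
                clip_multiple=float(archive["clip_multiple"]),
            )


def build_ssm(
    vectors: np.ndarray | Sequence[np.ndarray],
    layout: BlockLayout | None = None,
    **kwargs,
) -> ShapeModelResults:
    """Convenience: construct a :class:`ShapeModel` and fit it in one call."""
    return ShapeModel(vectors, layout, **kwargs).fit()
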