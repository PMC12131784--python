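"""Ground-truth synthetic paired-body cohorts with controllable coupling.

Real two-body cohorts (scapula + proximal humerus pairs segmented from CT)
cannot be redistributed, so this module generates stand-in cohorts whose
population structure is known exactly.  Each body starts from a deterministic
smooth template at anatomical scale (~150 mm): a curved plate for the
scapula-like body and a cylinder capped by a hemisphere for the humerus-like
body.  Per-subject shapes are the template plus a low-rank smooth deformation:

    x_body = template + B_shared (sqrt(f) * sigma_shared ∘ z)
                      + B_own    (sqrt(1-f) * sigma_own ∘ u_body) + noise

where z ~ N(0, I) are latent weights shared by both bodies, u_body ~ N(0, I)
are body-specific, ∘ is elementwise scaling, and B_shared/B_own are mutually
orthonormal smooth deformation fields.  The coupling fraction f in [0, 1] is
the fraction of each body's deformation variance driven by the shared
latents: f = 0 gives statistically independent bodies, f = 1 makes each
body's deformation a deterministic linear function of z.  Because the bases
are orthonormal and the shared amplitudes are rescaled per body against that
body's own spectrum, the achieved fraction equals f exactly (computable from
the stored record, not estimated).  The default own-mode spectra of the two
bodies are deliberately separated (8.0 vs 6.2 mm leads, common 0.6 decay) so
the f = 0 combined covariance has no cross-body eigenvalue degeneracy; with
degenerate spectra PCA could mix the independent bodies arbitrarily.

One shared deformation field per body is a localized inward "erosion" dent
(a glenoid-face / humeral-head analog), so that coupled local erosion — not
just global size — exists in the synthetic population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .shapes import Cohort, PointCloud, center_cloud, vectorize

__all__ = [
    "SyntheticCohortSpec",
    "GroundTruthRecord",
    "make_templates",
    "generate_cohort",
    "ground_truth_coupling",
]

#: default per-latent standard deviations (mm): geometric decay from 8 mm
_DEFAULT_LEAD_SD = 8.0
_DEFAULT_DECAY = 0.6
#: per-body lead ratio separating the default own-mode spectra across bodies.
#: A constant ratio with a common decay keeps the two bodies' spectra apart at
#: every index, so the combined covariance has no cross-body eigenvalue
#: degeneracy at f=0 (degenerate spectra would let PCA mix independent bodies
#: arbitrarily and fabricate coupling).
_BODY_LEAD_RATIO = 0.775


def _default_spectrum(q: int, body_index: int = 0) -> np.ndarray:
    return _DEFAULT_LEAD_SD * _BODY_LEAD_RATIO**body_index * _DEFAULT_DECAY ** np.arange(q)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one synthetic paired cohort.

    Defaults are the package's standard study conditions: 45 subjects, a
    160-point scapula-like and 154-point humerus-like body, 6 shared and 6
    body-specific latent modes with geometric 0.6-decay spectra (8.0 mm and
    6.2 mm leads), and 0.04 mm i.i.d. coordinate noise (about 1% of each
    body's deformation variance).
    """

    n_subjects: int = 45
    m_per_body: Mapping[str, int] = field(
        default_factory=lambda: {"scapula": 160, "humerus": 154}
    )
    q_shared: int = 6
    q_own: Mapping[str, int] | int = 6
    coupling_fraction: float = 0.5
    shared_sd: tuple[float, ...] | None = None
    own_sd: Mapping[str, tuple[float, ...]] | tuple[float, ...] | None = None
    noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not self.m_per_body:
            raise ValueError("need at least one body")
        for label, m in self.m_per_body.items():
            if m < 12:
                raise ValueError(f"body {label!r}: m must be >= 12, got {m}")
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ValueError("coupling_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.q_shared < 1:
            raise ValueError("q_shared must be >= 1")

    @property
    def bodies(self) -> tuple[str, ...]:
        return tuple(self.m_per_body)

    def q_own_for(self, body: str) -> int:
        q = self.q_own[body] if isinstance(self.q_own, Mapping) else int(self.q_own)
        if q < 1:
            raise ValueError("q_own must be >= 1 per body")
        return q

    def shared_spectrum(self) -> np.ndarray:
        sd = np.asarray(
            self.shared_sd if self.shared_sd is not None else _default_spectrum(self.q_shared),
            dtype=float,
        )
        if sd.size != self.q_shared or np.any(sd < 0):
            raise ValueError("shared_sd must hold q_shared non-negative values")
        return sd

    def own_spectrum(self, body: str) -> np.ndarray:
        q = self.q_own_for(body)
        if self.own_sd is None:
            sd = _default_spectrum(q, body_index=self.bodies.index(body))
        elif isinstance(self.own_sd, Mapping):
            sd = np.asarray(self.own_sd[body], dtype=float)
        else:
            sd = np.asarray(self.own_sd, dtype=float)
        if sd.size != q or np.any(sd < 0):
            raise ValueError(f"own_sd for {body!r} must hold {q} non-negative values")
        return sd


@dataclass(frozen=True)
class GroundTruthRecord:
    """Everything needed to recover the generative truth of a cohort."""

    spec: SyntheticCohortSpec
    templates: dict[str, PointCloud]
    shared_basis: dict[str, np.ndarray]  # body -> (3m, q_shared), orthonormal
    own_basis: dict[str, np.ndarray]  # body -> (3m, q_own), orthonormal
    shared_amplitude: dict[str, np.ndarray]  # sqrt(f) * sigma_shared per body
    own_amplitude: dict[str, np.ndarray]  # sqrt(1-f) * sigma_own per body
    shared_latents: np.ndarray  # (n, q_shared)
    own_latents: dict[str, np.ndarray]  # body -> (n, q_own)


# ---------------------------------------------------------------------------
# templates

def _plate_template(m: int) -> np.ndarray:
    """Curved plate ~150 x 95 mm, a scapula blade stand-in."""
    golden = (np.sqrt(5.0) - 1.0) / 2.0
    i = np.arange(m)
    u = (i + 0.5) / m
    v = np.mod(i * golden + 0.5 / m, 1.0)
    x = (u - 0.5) * 150.0
    y = (v - 0.5) * 95.0
    z = 12.0 * np.sin(np.pi * u) * np.cos(np.pi * (v - 0.5)) + 6.0 * (v - 0.5) ** 2
    return np.column_stack([x, y, z])


def _cylinder_hemisphere_template(m: int) -> np.ndarray:
    """Cylindrical shaft (r=11 mm, length 110 mm) capped by a hemispherical
    head (r=23 mm), a proximal-humerus stand-in; axis along +z."""
    golden = (np.sqrt(5.0) - 1.0) / 2.0
    m_head = max(4, int(round(0.4 * m)))
    m_shaft = m - m_head
    i = np.arange(m_shaft)
    theta = 2.0 * np.pi * np.mod(i * golden, 1.0)
    z = (i + 0.5) / m_shaft * 110.0 - 110.0
    shaft = np.column_stack([11.0 * np.cos(theta), 11.0 * np.sin(theta), z])
    j = np.arange(m_head)
    # spherical Fibonacci points on the upper hemisphere
    cos_phi = (j + 0.5) / m_head  # in (0, 1]: equator to pole
    sin_phi = np.sqrt(1.0 - cos_phi**2)
    theta_h = 2.0 * np.pi * np.mod(j * golden, 1.0)
    head = np.column_stack(
        [23.0 * sin_phi * np.cos(theta_h), 23.0 * sin_phi * np.sin(theta_h), 23.0 * cos_phi]
    )
    return np.vstack([shaft, head])


def _ellipsoid_template(m: int, index: int) -> np.ndarray:
    """Generic body stand-in for layouts beyond the first two bodies."""
    golden = (np.sqrt(5.0) - 1.0) / 2.0
    j = np.arange(m)
    cos_phi = 2.0 * (j + 0.5) / m - 1.0
    sin_phi = np.sqrt(1.0 - cos_phi**2)
    theta = 2.0 * np.pi * np.mod(j * golden, 1.0)
    radii = np.array([70.0, 45.0, 30.0]) * (0.9 + 0.1 * index)
    return np.column_stack(
        [radii[0] * sin_phi * np.cos(theta), radii[1] * sin_phi * np.sin(theta), radii[2] * cos_phi]
    )


def make_templates(spec: SyntheticCohortSpec) -> dict[str, PointCloud]:
    """Deterministic centered base shapes, one per body in layout order."""
    out: dict[str, PointCloud] = {}
    for idx, (label, m) in enumerate(spec.m_per_body.items()):
        if idx == 0:
            pts = _plate_template(m)
        elif idx == 1:
            pts = _cylinder_hemisphere_template(m)
        else:
            pts = _ellipsoid_template(m, idx)
        out[label] = center_cloud(PointCloud(pts, label, "template"))
    return out


# ---------------------------------------------------------------------------
# deformation bases

def _smooth_field(points: np.ndarray, rng: np.random.Generator, length_scale: float = 45.0) -> np.ndarray:
    """One random smooth (m, 3) displacement field: a few Gaussian bumps with
    random 3D amplitudes, so nearby points move coherently."""
    m = points.shape[0]
    n_bumps = 10
    centers = points[rng.integers(0, m, size=n_bumps)]
    amps = rng.normal(size=(n_bumps, 3))
    field = np.zeros((m, 3))
    for c, a in zip(centers, amps):
        w = np.exp(-np.sum((points - c) ** 2, axis=1) / (2.0 * length_scale**2))
        field += w[:, None] * a
    return field


def _erosion_field(points: np.ndarray, length_scale: float = 15.0) -> np.ndarray:
    """Localized inward dent at the point farthest from the centroid (an
    erosion analog); displacement is toward the centroid, Gaussian-weighted."""
    center = points[np.argmax(np.linalg.norm(points, axis=1))]
    direction = -center / np.linalg.norm(center)
    w = np.exp(-np.sum((points - center) ** 2, axis=1) / (2.0 * length_scale**2))
    return w[:, None] * direction


def _remove_translation(field: np.ndarray) -> np.ndarray:
    """Subtract the per-axis mean so the field does not move the centroid."""
    return field - field.mean(axis=0)


def _deformation_bases(
    template: np.ndarray, q_shared: int, q_own: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mutually orthonormal shared and own bases, (3m, q_shared) and (3m, q_own).

    The first shared column is the normalized erosion dent (Gram–Schmidt via
    QR keeps the first column's direction).  Mutual orthonormality makes the
    per-body variance decomposition between shared and own parts exact.
    """
    fields = [_erosion_field(template)]
    for _ in range(q_shared + q_own - 1):
        fields.append(_smooth_field(template, rng))
    raw = np.column_stack([_remove_translation(f).reshape(-1) for f in fields])
    q_mat, r_mat = np.linalg.qr(raw)
    signs = np.sign(np.diag(r_mat))
    signs[signs == 0] = 1.0
    q_mat = q_mat * signs
    return q_mat[:, :q_shared], q_mat[:, q_shared : q_shared + q_own]


# ---------------------------------------------------------------------------
# cohort generation

def _draw_latents(
    spec: SyntheticCohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw the (n, q_total) latent score matrix with exact conditioning.

    Scores start as i.i.d. standard normals, then the columns are centered,
    QR-orthonormalized, and rescaled to unit sample variance.  This makes the
    *realized* cohort carry exactly the specified latent structure: every
    latent has sample mean 0 and variance 1, and distinct latents — in
    particular the two bodies' own latents — have exactly zero empirical
    correlation.  Without this, O(1/sqrt(n)) sampling correlation between
    independent bodies would masquerade as coupled variation in any analysis
    of a finite cohort, so the coupling fraction f would only hold in
    expectation rather than in the generated data.  Falls back to raw draws
    when q_total > n - 1 (orthogonalization impossible).
    """
    n = spec.n_subjects
    qs = [spec.q_shared] + [spec.q_own_for(body) for body in spec.bodies]
    q_total = int(np.sum(qs))
    raw = rng.standard_normal((n, q_total))
    if q_total <= n - 1:
        centered = raw - raw.mean(axis=0)
        q_mat, r_mat = np.linalg.qr(centered)
        signs = np.sign(np.diag(r_mat))
        signs[signs == 0] = 1.0
        scores = q_mat * signs * np.sqrt(n - 1)
    else:
        scores = raw
    z = scores[:, : spec.q_shared]
    own, pos = {}, spec.q_shared
    for body in spec.bodies:
        q = spec.q_own_for(body)
        own[body] = scores[:, pos : pos + q]
        pos += q
    return z, own


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[Cohort, GroundTruthRecord]:
    """Generate a paired cohort plus the exact generative record.

    Reproducible: identical spec (including seed) yields identical clouds.
    """
    n = spec.n_subjects
    for body in spec.bodies:
        if spec.q_shared + spec.q_own_for(body) >= n:
            warnings.warn(
                f"body {body!r}: q_shared + q_own = "
                f"{spec.q_shared + spec.q_own_for(body)} >= n = {n}; "
                "PCA will truncate the recoverable spectrum",
                stacklevel=2,
            )
    rng = np.random.default_rng(spec.seed)
    templates = make_templates(spec)
    f = spec.coupling_fraction

    shared_basis, own_basis = {}, {}
    shared_amp, own_amp = {}, {}
    for body in spec.bodies:
        b_sh, b_own = _deformation_bases(
            templates[body].points, spec.q_shared, spec.q_own_for(body), rng
        )
        shared_basis[body] = b_sh
        own_basis[body] = b_own
        # scale shared amplitudes per body so the achieved shared-variance
        # fraction equals f exactly regardless of the per-body own spectrum
        shared_shape = spec.shared_spectrum()
        own_sd = spec.own_spectrum(body)
        scale = np.sqrt(np.sum(own_sd**2) / np.sum(shared_shape**2))
        shared_amp[body] = np.sqrt(f) * scale * shared_shape
        own_amp[body] = np.sqrt(1.0 - f) * own_sd

    z, own_latents = _draw_latents(spec, rng)

    subject_ids = tuple(f"s{i:03d}" for i in range(n))
    clouds: dict[str, dict[str, PointCloud]] = {body: {} for body in spec.bodies}
    for body in spec.bodies:
        base = vectorize(templates[body])
        disp = z * shared_amp[body] @ shared_basis[body].T
        disp += own_latents[body] * own_amp[body] @ own_basis[body].T
        if spec.noise_sd > 0:
            disp += spec.noise_sd * rng.standard_normal(disp.shape)
        for i, sid in enumerate(subject_ids):
            cloud = PointCloud((base + disp[i]).reshape(-1, 3), body, sid)
            clouds[body][sid] = center_cloud(cloud)

    cohort = Cohort(subject_ids, clouds)
    record = GroundTruthRecord(
        spec=spec,
        templates=templates,
        shared_basis=shared_basis,
        own_basis=own_basis,
        shared_amplitude=shared_amp,
        own_amplitude=own_amp,
        shared_latents=z,
        own_latents=own_latents,
    )
    return cohort, record


def ground_truth_coupling(record: GroundTruthRecord) -> dict[str, float]:
    """Exact per-body shared-variance fraction from the stored construction.

    With mutually orthonormal bases, each body's deformation variance splits
    as sum(shared_amplitude²) + sum(own_amplitude²); the shared fraction is
    computed from those amplitudes directly (noise excluded), not estimated.
    """
    out = {}
    for body in record.spec.bodies:
        shared_var = float(np.sum(record.shared_amplitude[body] ** 2))
        own_var = float(np.sum(record.own_amplitude[body] ** 2))
        total = shared_var + own_var
        out[body] = 0.0 if total == 0 else shared_var / total
    return out
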