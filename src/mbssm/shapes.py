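"""Corresponded point clouds, shape vectors, block layouts, and cohort I/O.

A statistical shape model operates on *corresponded* point clouds: the i-th
point denotes the same anatomical location on every subject, so point order is
meaningful and is never permuted by any operation in this package.  Clouds are
flattened into shape vectors by point-major interleaving ``[x1, y1, z1, ...,
xm, ym, zm]``; multiple bodies (e.g. a scapula and a proximal humerus) are
concatenated into one combined vector whose per-body index ranges are recorded
in a :class:`BlockLayout`.

Coordinates are millimeters throughout.  On disk a cloud is either a
ShapeWorks-style ``.particles`` file (one ``x y z`` row per point, whitespace
separated, no header) or a CSV with header ``x,y,z``.  A cohort is described
by a YAML manifest mapping ``subject_id -> body_label -> file path``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PointCloud",
    "Block",
    "BlockLayout",
    "Cohort",
    "read_particles",
    "write_particles",
    "read_cloud",
    "write_cloud",
    "center_cloud",
    "vectorize",
    "devectorize",
    "concatenate_bodies",
    "read_manifest",
    "write_cohort",
]


@dataclass(frozen=True)
class PointCloud:
    """One subject's corresponded ``m x 3`` point cloud for one body.

    Parameters
    ----------
    points : ndarray, shape (m, 3)
        Ordered 3D coordinates in mm.  The order is the correspondence order.
    body_label : str
        Body identifier, e.g. ``"scapula"`` or ``"humerus"``.
    subject_id : str
        Subject identifier.
    """

    points: np.ndarray
    body_label: str
    subject_id: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must have shape (m, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def m(self) -> int:
        """Number of correspondence points."""
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class Block:
    """One body's contiguous index range in a concatenated shape vector."""

    body_label: str
    m: int
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop - self.start != 3 * self.m:
            raise ValueError(
                f"block [{self.start}, {self.stop}) does not span 3*{self.m} entries"
            )

    @property
    def slice(self) -> slice:
        return slice(self.start, self.stop)


@dataclass(frozen=True)
class BlockLayout:
    """Ordered partition of a concatenated shape vector into body blocks.

    Ranges are 0-based half-open, contiguous, non-overlapping, and cover
    ``[0, 3 * sum(m_k))``.
    """

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        blocks = tuple(self.blocks)
        if not blocks:
            raise ValueError("layout must contain at least one block")
        pos = 0
        for blk in blocks:
            if blk.start != pos:
                raise ValueError("block ranges must be contiguous from 0")
            pos = blk.stop
        labels = [b.body_label for b in blocks]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate body labels in layout")
        object.__setattr__(self, "blocks", blocks)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int] | Sequence[tuple[str, int]]) -> "BlockLayout":
        items = counts.items() if isinstance(counts, Mapping) else counts
        blocks, pos = [], 0
        for label, m in items:
            blocks.append(Block(label, int(m), pos, pos + 3 * int(m)))
            pos += 3 * int(m)
        return cls(tuple(blocks))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.body_label for b in self.blocks)

    @property
    def total_dim(self) -> int:
        return self.blocks[-1].stop

    def __getitem__(self, label: str) -> Block:
        for b in self.blocks:
            if b.body_label == label:
                return b
        raise KeyError(f"no block labelled {label!r}")

    def split(self, vector: np.ndarray) -> dict[str, np.ndarray]:
        """Split a concatenated vector (or matrix of row vectors) by body."""
        vector = np.asarray(vector)
        if vector.shape[-1] != self.total_dim:
            raise ValueError(
                f"last axis has length {vector.shape[-1]}, layout expects {self.total_dim}"
            )
        return {b.body_label: vector[..., b.slice] for b in self.blocks}

    def split_rows(self, matrix: np.ndarray) -> dict[str, np.ndarray]:
        """Row-partition a ``(total_dim, k)`` matrix (e.g. an eigenvector matrix)."""
        matrix = np.asarray(matrix)
        if matrix.shape[0] != self.total_dim:
            raise ValueError(
                f"matrix has {matrix.shape[0]} rows, layout expects {self.total_dim}"
            )
        return {b.body_label: matrix[b.slice] for b in self.blocks}

    def to_dict(self) -> list[dict]:
        return [
            {"body_label": b.body_label, "m": b.m, "start": b.start, "stop": b.stop}
            for b in self.blocks
        ]

    @classmethod
    def from_dict(cls, items: Iterable[Mapping]) -> "BlockLayout":
        return cls(tuple(Block(d["body_label"], d["m"], d["start"], d["stop"]) for d in items))


# ---------------------------------------------------------------------------
# vectorization

def vectorize(cloud: PointCloud) -> np.ndarray:
    """Flatten an (m, 3) cloud to the length-3m vector [x1,y1,z1,...,xm,ym,zm]."""
    return cloud.points.reshape(-1).copy()


def devectorize(values: np.ndarray, body_label: str = "body", subject_id: str = "subject") -> PointCloud:
    """Inverse of :func:`vectorize`."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size % 3 != 0:
        raise ValueError(f"vector length {values.size} is not divisible by 3")
    return PointCloud(values.reshape(-1, 3), body_label, subject_id)


def as_points(vector_or_points: np.ndarray) -> np.ndarray:
    """Coerce a flat length-3m vector or an (m, 3) array to (m, 3)."""
    arr = np.asarray(vector_or_points, dtype=float)
    if arr.ndim == 1:
        if arr.size % 3 != 0:
            raise ValueError(f"vector length {arr.size} is not divisible by 3")
        return arr.reshape(-1, 3)
    if arr.ndim == 2 and arr.shape[1] == 3:
        return arr
    raise ValueError(f"expected flat 3m vector or (m, 3) array, got shape {arr.shape}")


def center_cloud(cloud: PointCloud) -> PointCloud:
    """Translate so the centroid sits at the origin.

    A pure translation: all pairwise inter-point distances (the shape) are
    unchanged, only position is removed.
    """
    return PointCloud(cloud.points - cloud.centroid, cloud.body_label, cloud.subject_id)


def concatenate_bodies(
    vectors: Mapping[str, np.ndarray] | Sequence[tuple[str, np.ndarray]],
) -> tuple[np.ndarray, BlockLayout]:
    """Concatenate per-body shape vectors in caller-supplied order.

    Returns the combined vector and the :class:`BlockLayout` recording each
    body's index range (e.g. bodies of 1600 and 1536 points produce a
    9408-element vector).
    """
    items = list(vectors.items()) if isinstance(vectors, Mapping) else list(vectors)
    if not items:
        raise ValueError("need at least one body")
    parts, counts = [], []
    for label, vec in items:
        vec = np.asarray(vec, dtype=float).reshape(-1)
        if vec.size % 3 != 0:
            raise ValueError(f"body {label!r}: vector length {vec.size} not divisible by 3")
        parts.append(vec)
        counts.append((label, vec.size // 3))
    return np.concatenate(parts), BlockLayout.from_counts(counts)


# ---------------------------------------------------------------------------
# file I/O

def read_particles(path: str | os.PathLike, body_label: str = "body", subject_id: str = "subject") -> PointCloud:
    """Read a ShapeWorks-style ``.particles`` file (whitespace x y z rows).

    Fields beyond the first three on a line are ignored; blank lines are
    skipped.  A malformed line raises a parse error naming the line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 fields, got {len(fields)}")
            try:
                rows.append([float(fields[0]), float(fields[1]), float(fields[2])])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
    if not rows:
        raise ValueError(f"{path}: empty point cloud file")
    return PointCloud(np.array(rows, dtype=float), body_label, subject_id)


def write_particles(cloud: PointCloud, path: str | os.PathLike) -> None:
    """Write a ``.particles`` file at full double precision (17 sig. digits)."""
    with open(path, "w") as fh:
        for x, y, z in cloud.points:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


def _read_csv(path: Path, body_label: str, subject_id: str) -> PointCloud:
    import pandas as pd

    frame = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: CSV missing columns {sorted(missing)}")
    if len(frame) == 0:
        raise ValueError(f"{path}: empty point cloud file")
    return PointCloud(frame[["x", "y", "z"]].to_numpy(dtype=float), body_label, subject_id)


def _write_csv(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("x,y,z\n")
        for x, y, z in cloud.points:
            fh.write(f"{x:.17g},{y:.17g},{z:.17g}\n")


def read_cloud(path: str | os.PathLike, body_label: str = "body", subject_id: str = "subject") -> PointCloud:
    """Read a cloud, dispatching on extension (``.csv`` vs ``.particles``)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path, body_label, subject_id)
    return read_particles(path, body_label, subject_id)


def write_cloud(cloud: PointCloud, path: str | os.PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_csv(cloud, path)
    else:
        write_particles(cloud, path)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class Cohort:
    """A paired cohort: every subject has one cloud per body, with per-body
    point counts constant across subjects."""

    subject_ids: tuple[str, ...]
    clouds: dict[str, dict[str, PointCloud]]  # body_label -> subject_id -> cloud

    def __post_init__(self) -> None:
        self.subject_ids = tuple(self.subject_ids)
        if len(self.subject_ids) < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if not self.clouds:
            raise ValueError("cohort needs at least one body")
        for body, by_subject in self.clouds.items():
            missing = set(self.subject_ids) - set(by_subject)
            if missing:
                raise ValueError(f"body {body!r}: missing subjects {sorted(missing)}")
            ms = {by_subject[s].m for s in self.subject_ids}
            if len(ms) != 1:
                raise ValueError(f"body {body!r}: inconsistent point counts {sorted(ms)}")

    @classmethod
    def from_clouds(cls, clouds: Iterable[PointCloud]) -> "Cohort":
        by_body: dict[str, dict[str, PointCloud]] = {}
        subjects: list[str] = []
        for cloud in clouds:
            by_body.setdefault(cloud.body_label, {})[cloud.subject_id] = cloud
            if cloud.subject_id not in subjects:
                subjects.append(cloud.subject_id)
        return cls(tuple(subjects), by_body)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def bodies(self) -> tuple[str, ...]:
        return tuple(self.clouds)

    def m(self, body: str) -> int:
        return self.clouds[body][self.subject_ids[0]].m

    def cloud(self, body: str, subject_id: str) -> PointCloud:
        return self.clouds[body][subject_id]

    def centered(self) -> "Cohort":
        """Center every cloud (per body, per subject) at the origin."""
        return Cohort(
            self.subject_ids,
            {
                body: {sid: center_cloud(c) for sid, c in by_subject.items()}
                for body, by_subject in self.clouds.items()
            },
        )

    def body_matrix(self, body: str) -> np.ndarray:
        """Stack one body's shape vectors as rows: shape ``(n, 3m)``."""
        return np.stack([vectorize(self.clouds[body][sid]) for sid in self.subject_ids])

    def combined_matrix(self, bodies: Sequence[str] | None = None) -> tuple[np.ndarray, BlockLayout]:
        """Stack per-subject concatenated vectors as rows: ``(n, sum 3 m_k)``."""
        bodies = tuple(bodies) if bodies is not None else self.bodies
        layout = BlockLayout.from_counts([(b, self.m(b)) for b in bodies])
        mats = [self.body_matrix(b) for b in bodies]
        return np.concatenate(mats, axis=1), layout

    def layout(self, bodies: Sequence[str] | None = None) -> BlockLayout:
        bodies = tuple(bodies) if bodies is not None else self.bodies
        return BlockLayout.from_counts([(b, self.m(b)) for b in bodies])

    def drop_subject(self, subject_id: str) -> "Cohort":
        keep = tuple(s for s in self.subject_ids if s != subject_id)
        return Cohort(
            keep,
            {
                body: {s: by_subject[s] for s in keep}
                for body, by_subject in self.clouds.items()
            },
        )


def read_manifest(path: str | os.PathLike) -> Cohort:
    """Load a cohort from a YAML manifest.

    Format::

        subjects:
          subj01:
            scapula: relative/or/absolute/path.particles
            humerus: ...
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "subjects" not in doc:
        raise ValueError(f"{path}: manifest must contain a 'subjects' mapping")
    base = path.parent
    clouds = []
    for sid, body_paths in doc["subjects"].items():
        for body, rel in body_paths.items():
            p = Path(rel)
            if not p.is_absolute():
                p = base / p
            clouds.append(read_cloud(p, body_label=body, subject_id=str(sid)))
    return Cohort.from_clouds(clouds)


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike, fmt: str = "particles") -> Path:
    """Write every cloud plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".csv" if fmt == "csv" else ".particles"
    subjects: dict[str, dict[str, str]] = {}
    for sid in cohort.subject_ids:
        subjects[sid] = {}
        for body in cohort.bodies:
            fname = f"{sid}_{body}{ext}"
            write_cloud(cohort.cloud(body, sid), out_dir / fname)
            subjects[sid][body] = fname
    manifest = out_dir / "manifest.yaml"
    with open(manifest, "w") as fh:
        # body order matters (it fixes the block layout): keep insertion order
        yaml.safe_dump({"subjects": subjects}, fh, sort_keys=False)
    return manifest
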