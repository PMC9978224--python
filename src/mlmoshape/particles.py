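"""Correspondence-particle container and plain-text particle file I/O."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParticleSystem", "write_particles", "read_particles"]


@dataclass
class ParticleSystem:
    """Ensemble correspondence particles.

    ``points`` has shape (N subjects, M total particles, 3) in millimetres,
    with particles stored organ-major (all of organ 0, then organ 1, ...).
    Flattening a subject row therefore yields the organ-major,
    particle-minor, xyz-innermost order used throughout the statistics.
    ``face_ids`` tracks the mesh face each particle currently lies on (for
    tangent-plane projection); -1 if unknown.
    """

    points: np.ndarray
    counts: list  # particles per organ, shared across subjects
    subject_ids: list
    organ_labels: list
    face_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must have shape (N, M, 3)")
        if sum(self.counts) != self.points.shape[1]:
            raise ValueError("organ particle counts do not sum to M")
        if len(self.subject_ids) != self.points.shape[0]:
            raise ValueError("one subject id per row required")
        if len(self.organ_labels) != len(self.counts):
            raise ValueError("one label per organ required")
        if self.face_ids is None:
            self.face_ids = -np.ones(self.points.shape[:2], dtype=np.int64)

    # -- structure ---------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.points.shape[0]

    @property
    def n_organs(self) -> int:
        return len(self.counts)

    @property
    def total_particles(self) -> int:
        return self.points.shape[1]

    @property
    def organ_slices(self) -> list:
        offsets = np.concatenate([[0], np.cumsum(self.counts)])
        return [slice(int(offsets[k]), int(offsets[k + 1])) for k in range(self.n_organs)]

    def organ_points(self, n: int, k: int) -> np.ndarray:
        """(M_k, 3) view of subject n's particles on organ k."""
        return self.points[n, self.organ_slices[k]]

    def flattened(self) -> np.ndarray:
        """(3M, N) data matrix: one column per subject."""
        return self.points.reshape(self.n_subjects, -1).T

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.points.copy(),
            list(self.counts),
            list(self.subject_ids),
            list(self.organ_labels),
            None if self.face_ids is None else self.face_ids.copy(),
        )


def write_particles(system: ParticleSystem, directory: str) -> None:
    """Write one ``<subject>_<organ>_<M>.particles`` text file per
    (subject, organ), plus an ``organs.json`` sidecar with the partition."""
    os.makedirs(directory, exist_ok=True)
    for n, sid in enumerate(system.subject_ids):
        for k, label in enumerate(system.organ_labels):
            pts = system.organ_points(n, k)
            path = os.path.join(directory, f"{sid}_{label}_{len(pts)}.particles")
            np.savetxt(path, pts, fmt="%.17g")
    sidecar = {
        "organ_labels": list(system.organ_labels),
        "counts": [int(c) for c in system.counts],
        "subject_ids": list(system.subject_ids),
    }
    with open(os.path.join(directory, "organs.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_particles(directory: str) -> ParticleSystem:
    """Read a particle set written by :func:`write_particles`."""
    with open(os.path.join(directory, "organs.json")) as fh:
        sidecar = json.load(fh)
    counts = sidecar["counts"]
    labels = sidecar["organ_labels"]
    sids = sidecar["subject_ids"]
    rows = []
    for sid in sids:
        parts = []
        for k, label in enumerate(labels):
            path = os.path.join(directory, f"{sid}_{label}_{counts[k]}.particles")
            pts = np.loadtxt(path, ndmin=2)
            if pts.shape != (counts[k], 3):
                raise ValueError(f"{path}: expected {counts[k]} x-y-z rows")
            parts.append(pts)
        rows.append(np.vstack(parts))
    return ParticleSystem(np.stack(rows), counts, sids, labels)
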