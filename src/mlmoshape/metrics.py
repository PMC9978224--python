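"""Model-quality metrics (compactness / generalization / specificity) per
subspace, and the joint coverage-area measurement.

Compactness is in variance units (mm^2); generalization and specificity are
Euclidean distances in mm, measured in the coordinate system of the
subspace they evaluate (full shape space for G, within-organ deviations for
W_k, stacked centroid deviations for B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import SubspaceModel, _pca
from .geometry import SurfaceMesh
from .mlmo import decompose
from .particles import ParticleSystem

__all__ = [
    "MetricCurve",
    "compactness",
    "generalization",
    "generalization_curve",
    "specificity",
    "coverage_area",
    "relative_error",
    "dominant_mode_count",
]


@dataclass
class MetricCurve:
    """Metric values indexed by the number of retained modes P = 1..P_max."""

    metric: str
    tag: object
    values: np.ndarray  # values[p - 1] is the metric at P = p

    def at(self, p: int) -> float:
        return float(self.values[p - 1])


# ---------------------------------------------------------------------------
# Compactness
# ---------------------------------------------------------------------------

def compactness(model: SubspaceModel, p: int) -> float:
    """Cumulative variance ``sum_{i<=P} lambda_i`` of the leading P modes."""
    if not 1 <= p <= model.rank:
        raise ValueError(f"P={p} out of range 1..{model.rank}")
    return float(model.eigenvalues[:p].sum())


# ---------------------------------------------------------------------------
# Generalization (leave-one-out)
# ---------------------------------------------------------------------------

def _subspace_data(system: ParticleSystem, tag) -> np.ndarray:
    """(D, N) raw data matrix of the requested subspace."""
    if tag == "G":
        return system.flattened()
    dec = decompose(system)
    if tag == "B":
        return dec.between
    _, k = tag
    return dec.within[k]


def generalization_curve(system: ParticleSystem, tag, p_max: int | None = None) -> MetricCurve:
    """Mean leave-one-out reconstruction error (mm) for P = 1..p_max.

    Each held-out subject's subspace vector is projected onto the model
    refit from the remaining N-1 subjects and reconstructed with P modes;
    the error is the Euclidean distance between vector and reconstruction.
    Decomposition is per-subject, so holding out a subject just drops a
    column of the subspace data matrix.
    """
    data = _subspace_data(system, tag)
    n = data.shape[1]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    limit = n - 2  # rank of the N-1 training matrix is at most N-2
    p_max = limit if p_max is None else min(p_max, limit)
    errors = np.zeros((n, p_max))
    for i in range(n):
        train = np.delete(data, i, axis=1)
        model = _pca(train, tag, system.counts, system.organ_labels)
        held = data[:, i]
        coeffs = model.eigenvectors.T @ (held - model.mean)
        resid = held - model.mean
        # error at P modes: ||resid - U_P c_P||; accumulate incrementally
        rec = np.zeros_like(held)
        for p in range(p_max):
            if p < model.rank:
                rec = rec + model.eigenvectors[:, p] * coeffs[p]
            errors[i, p] = np.linalg.norm(resid - rec)
    return MetricCurve("generalization", tag, errors.mean(axis=0))


def generalization(system: ParticleSystem, tag, p: int) -> float:
    """Mean leave-one-out error (mm) with P = ``p`` retained modes."""
    return generalization_curve(system, tag, p).at(p)


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def specificity(
    model: SubspaceModel,
    training: np.ndarray,
    p: int,
    t_samples: int = 1000,
    seed: int = 0,
) -> float:
    """Mean distance (mm) from model-sampled vectors to the nearest
    training sample, in the subspace's own coordinates.

    ``training`` is the (D, N) raw data matrix of the subspace. T vectors
    are drawn from the generative model: coefficients independently
    ~ N(0, lambda_p) on the leading P modes.
    """
    if not 0 <= p <= model.rank:
        raise ValueError(f"P={p} out of range 0..{model.rank}")
    rng = np.random.default_rng(seed)
    coeff = rng.standard_normal((t_samples, p)) * np.sqrt(model.eigenvalues[:p])[None, :]
    samples = model.mean[None, :] + coeff @ model.eigenvectors[:, :p].T  # (T, D)
    # nearest training sample per draw
    d2 = (
        np.sum(samples**2, axis=1)[:, None]
        - 2.0 * samples @ training
        + np.sum(training**2, axis=0)[None, :]
    )
    return float(np.mean(np.sqrt(np.clip(d2.min(axis=1), 0.0, None))))


# ---------------------------------------------------------------------------
# Coverage area
# ---------------------------------------------------------------------------

def _rays_hit_any(origins: np.ndarray, directions: np.ndarray,
                  triangles: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Möller–Trumbore: does each ray hit any triangle (t > eps)?

    origins, directions: (R, 3); triangles: (F, 3, 3). Chunked over rays to
    bound memory.
    """
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    out = np.zeros(len(origins), dtype=bool)
    chunk = max(1, int(2_000_000 / max(len(triangles), 1)))
    for s in range(0, len(origins), chunk):
        o = origins[s : s + chunk][:, None, :]  # (r,1,3)
        d = directions[s : s + chunk][:, None, :]
        h = np.cross(d, e2[None, :, :])  # (r,F,3)
        a = np.sum(e1[None, :, :] * h, axis=-1)
        valid = np.abs(a) > 1e-14
        f = np.where(valid, 1.0 / np.where(valid, a, 1.0), 0.0)
        sv = o - v0[None, :, :]
        u = f * np.sum(sv * h, axis=-1)
        q = np.cross(sv, e1[None, :, :])
        v = f * np.sum(d * q, axis=-1)
        t = f * np.sum(e2[None, :, :] * q, axis=-1)
        hit = valid & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > eps)
        out[s : s + chunk] = hit.any(axis=1)
    return out


def coverage_area(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh) -> float:
    """Area (mm^2) of ``mesh_a`` covered by ``mesh_b``.

    A face of ``mesh_a`` counts as covered iff the ray from its centroid
    along its face normal intersects any face of ``mesh_b``. Normals follow
    the winding of ``mesh_a``; self-intersections with ``mesh_a`` are not
    considered.
    """
    if len(mesh_a.faces) == 0 or len(mesh_b.faces) == 0:
        raise ValueError("both meshes must be nonempty")
    centroids = mesh_a.triangles.mean(axis=1)
    covered = _rays_hit_any(centroids, mesh_a.face_normals, mesh_b.triangles)
    return float(mesh_a.face_areas[covered].sum())


def relative_error(a_hat: float, a: float) -> float:
    """``|a_hat - a| / a`` for a positive reference area."""
    if a <= 0:
        raise ValueError("reference area must be positive")
    return abs(a_hat - a) / a


# ---------------------------------------------------------------------------
# Spectrum summaries
# ---------------------------------------------------------------------------

def dominant_mode_count(eigenvalues, fraction_threshold: float = 0.05) -> int:
    """Number of modes holding at least ``fraction_threshold`` of the total
    variance."""
    lam = np.asarray(eigenvalues, dtype=float)
    total = lam.sum()
    if total <= 0:
        raise ValueError("spectrum has no variance")
    return int(np.sum(lam / total >= fraction_threshold))
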