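"""Post-optimization statistics: shared-space PCA and multilevel component
analysis (MLCA) of correspondence particles.

The shared model is an ordinary PCA of the flattened (3M-dimensional)
particle vectors. The MLCA model fits one PCA per organ to the within-organ
deviations and one PCA to the between-organs centroid deviations; together
with the per-subject offset these form K + 1 mutually orthogonal subspaces,
so morphology modes and pose modes can be swept independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mlmo import decompose
from .particles import ParticleSystem

__all__ = [
    "SubspaceModel",
    "MLCAModel",
    "Coefficients",
    "fit_shared_pca",
    "fit_mlca",
    "project",
    "reconstruct_shape",
    "mode_sweep",
]

_RANK_TOL = 1e-12


@dataclass
class SubspaceModel:
    """Mean + orthonormal eigenvectors + eigenvalues of one subspace.

    tag is ``"G"`` (shared), ``("W", k)`` (within organ k) or ``"B"``
    (between organs). ``mean`` lives in the subspace's own coordinate
    system (3M for G, 3M_k for W_k, 3K for B).
    """

    tag: object
    mean: np.ndarray
    eigenvectors: np.ndarray  # (D, r), orthonormal columns
    eigenvalues: np.ndarray  # (r,), nonincreasing
    counts: list
    organ_labels: list

    @property
    def rank(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def coefficients(self, vector: np.ndarray) -> np.ndarray:
        """Orthogonal projection coefficients of a subspace vector."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != self.mean.shape:
            raise ValueError("dimension mismatch with subspace mean")
        return self.eigenvectors.T @ (vector - self.mean)

    def reconstruct(self, coeffs: np.ndarray, n_modes: int | None = None) -> np.ndarray:
        if n_modes is None:
            n_modes = self.rank
        if not 0 <= n_modes <= self.rank:
            raise ValueError(f"mode count {n_modes} out of range 0..{self.rank}")
        return self.mean + self.eigenvectors[:, :n_modes] @ coeffs[:n_modes]


def _pca(y_raw: np.ndarray, tag, counts, labels) -> SubspaceModel:
    """PCA of the columns of ``y_raw`` through the N x N Gram matrix.

    Eigenvalues use the 1/(N-1) sample-covariance convention; components
    below ``1e-12 * lambda_max`` are truncated; each eigenvector's
    largest-magnitude entry is made positive for reproducible signs.
    """
    y_raw = np.asarray(y_raw, dtype=float)
    d, n = y_raw.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = y_raw.mean(axis=1)
    y = y_raw - mean[:, None]
    gram = y.T @ y / (n - 1)
    nu, v = np.linalg.eigh(gram)
    order = np.argsort(nu)[::-1]
    nu, v = np.clip(nu[order], 0.0, None), v[:, order]
    lam_max = nu.max(initial=0.0)
    keep = nu > _RANK_TOL * lam_max if lam_max > 0 else np.zeros(n, dtype=bool)
    nu, v = nu[keep], v[:, keep]
    u = y @ v / np.sqrt(nu * (n - 1))[None, :] if keep.any() else np.zeros((d, 0))
    # sign convention
    if u.shape[1]:
        idx = np.argmax(np.abs(u), axis=0)
        signs = np.sign(u[idx, np.arange(u.shape[1])])
        signs[signs == 0] = 1.0
        u *= signs[None, :]
    return SubspaceModel(tag, mean, u, nu, list(counts), list(labels))


def fit_shared_pca(system: ParticleSystem) -> SubspaceModel:
    """PCA of the full flattened shape vectors (<= N-1 nonzero modes)."""
    return _pca(system.flattened(), "G", system.counts, system.organ_labels)


@dataclass
class MLCAModel:
    """K within models + 1 between model + the offset statistics.

    ``consolidated_mean`` is the full 3M ensemble-mean shape vector, which
    equals mean offset (broadcast) + within means + between means
    (broadcast per organ) by linearity of the decomposition.
    """

    within: list  # list[SubspaceModel]
    between: SubspaceModel
    mean_offset: np.ndarray  # (3,)
    consolidated_mean: np.ndarray  # (3M,)
    counts: list
    organ_labels: list

    @property
    def n_organs(self) -> int:
        return len(self.counts)

    def organ_block(self, k: int) -> slice:
        off = np.concatenate([[0], np.cumsum(self.counts)]) * 3
        return slice(int(off[k]), int(off[k + 1]))


def fit_mlca(system: ParticleSystem) -> MLCAModel:
    """Fit the multilevel model: one PCA per within subspace, one for the
    between subspace. The between covariance is 3K x 3K regardless of the
    particle counts."""
    dec = decompose(system)
    within = [
        _pca(w, ("W", k), [system.counts[k]], [system.organ_labels[k]])
        for k, w in enumerate(dec.within)
    ]
    between = _pca(dec.between, "B", system.counts, system.organ_labels)
    return MLCAModel(
        within,
        between,
        dec.offset.mean(axis=0),
        system.flattened().mean(axis=1),
        list(system.counts),
        list(system.organ_labels),
    )


@dataclass
class Coefficients:
    """MLCA coordinates of one shape sample: per-organ within coefficients,
    between coefficients, and the sample's offset deviation from the mean
    offset (the offset is carried, not modeled)."""

    alpha_within: list  # list of (r_k,) arrays
    alpha_between: np.ndarray
    offset_deviation: np.ndarray  # (3,)


def _split_sample(model: MLCAModel, sample: np.ndarray):
    """Decompose one flattened 3M sample vector into (offset, within list,
    between vector) with the same algebra as :func:`decompose`."""
    sample = np.asarray(sample, dtype=float)
    if sample.shape != model.consolidated_mean.shape:
        raise ValueError("sample dimension does not match the model")
    pts = sample.reshape(-1, 3)
    counts = np.asarray(model.counts)
    offset = pts.mean(axis=0)  # NOTE: unweighted over particles = global centroid
    within, between = [], []
    start = 0
    for mk in counts:
        organ = pts[start : start + mk]
        cent = organ.mean(axis=0)
        within.append((organ - cent).ravel())
        between.append(cent - offset)
        start += mk
    return offset, within, np.concatenate(between)


def project(model: MLCAModel, sample: np.ndarray) -> Coefficients:
    """Orthogonal projection of a flattened sample onto every subspace."""
    offset, within, between = _split_sample(model, sample)
    return Coefficients(
        [model.within[k].coefficients(within[k]) for k in range(model.n_organs)],
        model.between.coefficients(between),
        offset - model.mean_offset,
    )


def reconstruct_shape(
    model: MLCAModel,
    coeffs: Coefficients,
    p_within: int | None = None,
    p_between: int | None = None,
) -> np.ndarray:
    """Rebuild a flattened 3M shape vector from MLCA coefficients.

    ``p_within`` / ``p_between`` limit the mode counts (None = all). The
    between eigenvector blocks (one 3-vector per organ) are broadcast
    uniformly to all particles of their organ."""
    out = model.consolidated_mean.copy()
    out += np.tile(coeffs.offset_deviation, sum(model.counts))
    for k in range(model.n_organs):
        wm = model.within[k]
        rec = wm.reconstruct(coeffs.alpha_within[k], p_within) - wm.mean
        out[model.organ_block(k)] += rec
    b = model.between.reconstruct(coeffs.alpha_between, p_between) - model.between.mean
    b = b.reshape(model.n_organs, 3)
    for k in range(model.n_organs):
        out[model.organ_block(k)] += np.tile(b[k], model.counts[k])
    return out


def expand_between_vector(model: MLCAModel, b: np.ndarray) -> np.ndarray:
    """Broadcast a 3K between-subspace vector to the full 3M shape space."""
    b = np.asarray(b, dtype=float).reshape(model.n_organs, 3)
    return np.concatenate(
        [np.tile(b[k], model.counts[k]) for k in range(model.n_organs)]
    )


def expand_within_vector(model: MLCAModel, k: int, w: np.ndarray) -> np.ndarray:
    """Place an organ-k within vector into the full 3M shape space."""
    out = np.zeros_like(model.consolidated_mean)
    out[model.organ_block(k)] = w
    return out


def mode_sweep(model, tag, mode_index: int, sigmas=(-2.0, -1.0, 0.0, 1.0, 2.0)):
    """Shape vectors ``mean + c * sqrt(lambda) * u`` for each multiple c.

    ``model`` is an :class:`MLCAModel` for tags ``("W", k)`` / ``"B"`` or a
    shared :class:`SubspaceModel` (tag ``"G"``). Returns a list of full 3M
    vectors (for G/W/B alike, between displacements broadcast per organ)."""
    if isinstance(model, SubspaceModel):
        if model.tag != "G":
            raise ValueError("bare SubspaceModel sweeps require the shared model")
        if not 0 <= mode_index < model.rank:
            raise ValueError(f"mode index {mode_index} out of range")
        u = model.eigenvectors[:, mode_index]
        lam = model.eigenvalues[mode_index]
        return [model.mean + c * np.sqrt(lam) * u for c in sigmas]
    if tag == "B":
        sub = model.between
        expand = lambda v: expand_between_vector(model, v)  # noqa: E731
    else:
        _, k = tag
        sub = model.within[k]
        expand = lambda v: expand_within_vector(model, k, v)  # noqa: E731
    if not 0 <= mode_index < sub.rank:
        raise ValueError(f"mode index {mode_index} out of range")
    u = sub.eigenvectors[:, mode_index]
    lam = sub.eigenvalues[mode_index]
    return [
        model.consolidated_mean + c * np.sqrt(lam) * expand(u) for c in sigmas
    ]
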