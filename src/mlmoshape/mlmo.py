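"""Within/between decomposition of multi-organ particle systems and the
disentangled (multi-level multi-organ, MLMO) correspondence objective.

Every particle of subject n decomposes exactly as

    x = zbar_n (offset)  +  (x - zbar_{n,k}) (within-organ)
      + (zbar_{n,k} - zbar_n) (between-organs)

where ``zbar_{n,k}`` is organ k's particle centroid and ``zbar_n`` the
global particle centroid of the complex. The within terms carry pure
morphology, the between terms carry relative organ pose; the two are
orthogonal by construction. The MLMO objective minimizes the entropy of
each within subspace and of the between subspace separately, instead of one
entangled shape-space entropy over all organs, and its between statistics
live in a (3K x 3K) covariance no matter how many particles each organ has.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import (
    center_columns,
    correspondence_gradient,
    sampling_entropy,
    subspace_entropy,
)
from .particles import ParticleSystem

__all__ = [
    "MLCADecomposition",
    "decompose",
    "mlmo_objective",
    "mlmo_step",
    "map_within_gradient",
    "map_between_gradient",
]


@dataclass
class MLCADecomposition:
    """Exact algebraic split of a particle system (raw deviations, not
    centered across subjects).

    offset : (N, 3) global particle centroid per subject.
    within : list of (3 M_k, N) matrices of ``x - zbar_{n,k}``.
    between : (3K, N) matrix of ``zbar_{n,k} - zbar_n`` stacked over organs.
    """

    offset: np.ndarray
    within: list
    between: np.ndarray
    counts: list
    organ_labels: list

    @property
    def n_subjects(self) -> int:
        return self.offset.shape[0]

    @property
    def n_organs(self) -> int:
        return len(self.counts)

    # -- sums of squares ---------------------------------------------------
    @property
    def ssq_within(self) -> float:
        return float(sum(np.sum(w**2) for w in self.within))

    @property
    def ssq_between(self) -> float:
        """Between SSQ with each organ's centroid deviation counted once per
        particle (M_k weighting), so the ANOVA identity
        ssq_total = ssq_within + ssq_between holds exactly."""
        b = self.between.reshape(self.n_organs, 3, self.n_subjects)
        w = np.asarray(self.counts, dtype=float)[:, None, None]
        return float(np.sum(w * b**2))

    @property
    def ssq_total(self) -> float:
        """Total SSQ of particle deviations about the per-subject offset."""
        return self.ssq_within + self.ssq_between  # identity; see reassemble tests

    def ssq_total_direct(self, system: ParticleSystem) -> float:
        dev = system.points - self.offset[:, None, :]
        return float(np.sum(dev**2))

    def reassemble(self) -> np.ndarray:
        """(N, M, 3) particles rebuilt from offset + within + between."""
        n, k = self.n_subjects, self.n_organs
        m = int(sum(self.counts))
        out = np.empty((n, m, 3))
        b = self.between.reshape(k, 3, n)
        start = 0
        for ki, mk in enumerate(self.counts):
            w = self.within[ki].T.reshape(n, mk, 3)
            out[:, start : start + mk] = (
                w + b[ki].T[:, None, :] + self.offset[:, None, :]
            )
            start += mk
        return out


def decompose(system: ParticleSystem) -> MLCADecomposition:
    """Split a particle system into offset, within and between components."""
    n = system.n_subjects
    offset = system.points.mean(axis=1)  # (N, 3)
    within, between_blocks = [], []
    for k, sl in enumerate(system.organ_slices):
        organ = system.points[:, sl]  # (N, M_k, 3)
        cent = organ.mean(axis=1)  # (N, 3)
        dev = organ - cent[:, None, :]
        within.append(dev.reshape(n, -1).T.copy())  # (3 M_k, N)
        between_blocks.append((cent - offset).T)  # (3, N)
    between = np.vstack(between_blocks)
    return MLCADecomposition(
        offset, within, between, list(system.counts), list(system.organ_labels)
    )


# ---------------------------------------------------------------------------
# Gradient chain rules (centering Jacobians)
# ---------------------------------------------------------------------------

def map_within_gradient(g: np.ndarray, m_k: int) -> np.ndarray:
    """Map a gradient w.r.t. organ k's within matrix (3 M_k, N) to a
    per-particle gradient (N, M_k, 3) through the organ-centering Jacobian
    ``d(x_m - zbar_k)/dx_j = delta_mj I - (1/M_k) I``."""
    per = g.T.reshape(-1, m_k, 3)
    return per - per.mean(axis=1, keepdims=True)


def map_between_gradient(g: np.ndarray, counts) -> np.ndarray:
    """Map a gradient w.r.t. the between matrix (3K, N) to per-particle
    gradients (N, M, 3) through
    ``d(zbar_k - zbar)/dx_m = delta_{k, organ(m)} (1/M_k) I - (1/M) I``."""
    counts = np.asarray(counts, dtype=int)
    k, m_total = len(counts), int(counts.sum())
    n = g.shape[1]
    blocks = g.reshape(k, 3, n).transpose(2, 0, 1)  # (N, K, 3)
    total = blocks.sum(axis=1)  # (N, 3): sum over organs
    out = np.empty((n, m_total, 3))
    start = 0
    for ki, mk in enumerate(counts):
        out[:, start : start + mk] = (
            blocks[:, ki] / mk - total / m_total
        )[:, None, :]
        start += mk
    return out


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def mlmo_objective(
    system: ParticleSystem,
    alpha_within: float,
    alpha_between: float,
    alpha_reg_within,
    alpha_reg_between: float,
    sigmas=None,
):
    """MLMO cost ``Q = aW * sum_k H(Z_k^W) + aB * H(Z^B) - sum_{n,k} H(X_nk)``.

    ``alpha_reg_within`` may be a scalar or one value per organ. ``sigmas``
    is a list of per-(subject, organ) kernel-width arrays indexed
    ``sigmas[n][k]``; if omitted the sampling term is skipped (weights-only
    entropy of the subspaces).

    Returns ``(Q, breakdown)`` where the breakdown maps term names to
    values; the within/between entropies use covariances of size
    (3 M_k x 3 M_k) and (3K x 3K) computed in their dual (N x N) form.
    """
    if system.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    dec = decompose(system)
    regs_w = np.broadcast_to(
        np.asarray(alpha_reg_within, dtype=float), (system.n_organs,)
    )
    h_within = [
        subspace_entropy(center_columns(w), regs_w[k])
        for k, w in enumerate(dec.within)
    ]
    h_between = subspace_entropy(center_columns(dec.between), alpha_reg_between)
    h_sampling = 0.0
    if sigmas is not None:
        for n in range(system.n_subjects):
            for k in range(system.n_organs):
                h, _ = sampling_entropy(system.organ_points(n, k), sigmas[n][k])
                h_sampling += h
    q = alpha_within * sum(h_within) + alpha_between * h_between - h_sampling
    breakdown = {
        "within_entropies": h_within,
        "between_entropy": h_between,
        "sampling_entropy": h_sampling,
        "Q": q,
    }
    return q, breakdown


def mlmo_shape_gradients(
    system: ParticleSystem,
    alpha_reg_within,
    alpha_reg_between: float,
):
    """Per-particle ascent gradients of the within and between entropies.

    Returns ``(grad_within, grad_between)``, each (N, M, 3):
    ``grad_within`` stacks ``dH(Z_k^W)/dx`` over organs (each organ's block
    touched only by its own within entropy) and ``grad_between`` is
    ``dH(Z^B)/dx`` including the global-centroid coupling.
    """
    dec = decompose(system)
    n = system.n_subjects
    regs_w = np.broadcast_to(
        np.asarray(alpha_reg_within, dtype=float), (system.n_organs,)
    )
    gw = np.empty_like(system.points)
    start = 0
    for k, w in enumerate(dec.within):
        mk = system.counts[k]
        g = correspondence_gradient(center_columns(w), regs_w[k])
        gw[:, start : start + mk] = map_within_gradient(g, mk)
        start += mk
    gb_mat = correspondence_gradient(center_columns(dec.between), alpha_reg_between)
    gb = map_between_gradient(gb_mat, system.counts)
    return gw, gb


def export_decomposition(dec: MLCADecomposition, directory, subject_ids) -> None:
    """Write ``within_<organ>.csv``, ``between.csv`` and ``offsets.csv``
    (rows = flattened coordinates, columns = subjects)."""
    import os

    import pandas as pd

    os.makedirs(directory, exist_ok=True)
    cols = list(subject_ids)
    for k, label in enumerate(dec.organ_labels):
        pd.DataFrame(dec.within[k], columns=cols).to_csv(
            os.path.join(directory, f"within_{label}.csv"), index=False
        )
    pd.DataFrame(dec.between, columns=cols).to_csv(
        os.path.join(directory, "between.csv"), index=False
    )
    pd.DataFrame(dec.offset.T, columns=cols).to_csv(
        os.path.join(directory, "offsets.csv"), index=False
    )


def mlmo_step(system: ParticleSystem, subjects, config, seed: int | None = None):
    """Run one alternating within-then-between MLMO iteration and return the
    updated system (convenience wrapper over the optimizer loop)."""
    from .optimizer import _Optimizer  # deferred: optimizer imports this module

    opt = _Optimizer(subjects, config)
    state = opt.level_state(system)
    return opt.iterate(system, state)
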