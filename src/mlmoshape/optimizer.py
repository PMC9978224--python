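"""Particle-based correspondence optimization.

Three modes share one loop:

* ``single``  — each organ is its own model: per-organ shape-space entropy
  plus per-surface sampling entropy (the classic single-structure objective).
* ``global``  — all organs concatenated into one shared shape space:
  ``Q = alpha * H(Z) - sum_{n,k} H(X_nk)``.
* ``mlmo``    — disentangled: per-organ within entropies plus one
  between-organs (pose) entropy, updated in alternating phases.

Particles are initialized with a coarse-to-fine splitting strategy (start
with one particle per organ, double by splitting until the requested count)
and every update is tangent-projected and snapped back to its organ's
surface, so particles never leave the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mlmo as _mlmo
from .entropy import (
    center_columns,
    correspondence_gradient,
    eigenvalue_scale,
    parzen_sigmas,
    sampling_entropy,
    subspace_entropy,
)
from .geometry import MultiOrganSubject, closest_points
from .particles import ParticleSystem

__all__ = [
    "OptimizerConfig",
    "initialize_particles",
    "split_particles",
    "sampling_entropy_gradient",
    "optimize",
    "subspace_entropy",
    "correspondence_gradient",
]


@dataclass
class OptimizerConfig:
    """Optimization knobs.

    particles_per_organ : target counts, each a power of two.
    mode : ``single`` | ``global`` | ``mlmo``.
    alpha_global / alpha_within / alpha_between : relative weights of the
        shape-space entropy terms against the (unit-weight) sampling term.
    alpha_reg_* : the covariance regularization decays geometrically from
        ``start_factor * mean(lambda)`` to ``end_factor * mean(lambda)``
        across split levels (recomputed at each level).
    step_factor : initial trial step per level, as a multiple of the mean
        kernel width; adapted by backtracking (halve on energy increase,
        grow 1.1x on success).
    repair_below : consensus repair is attempted at the end of every split
        level while the organ has at most this many particles. On nearly
        symmetric organs a subject's coarse particles can settle on the
        wrong symmetry position (label switching), which later levels
        inherit; repair detects such subjects as within-configuration
        outliers, re-snaps the ensemble-consensus configuration onto their
        surface, and keeps the result only if it reduces the deviation.
        Deterministic; set 0 to disable.
    tau_surf : maximum tolerated particle-to-surface distance (mm).
    """

    particles_per_organ: list
    mode: str = "mlmo"
    iterations_per_split_level: int = 30
    alpha_global: float = 1.0
    alpha_within: float = 1.0
    alpha_between: float = 1.0
    alpha_reg_start_factor: float = 10.0
    alpha_reg_end_factor: float = 1e-2
    step_factor: float = 0.5
    step_growth: float = 1.1
    repair_below: int = 64
    max_backtracks: int = 10
    tau_surf: float = 1e-6
    seed: int = 0
    convergence_tol: float = 1e-6
    convergence_window: int = 10
    sigma_floor_rel: float = 1e-3
    sigma_neighbors: int = 6

    def __post_init__(self) -> None:
        if self.mode not in ("single", "global", "mlmo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for m in self.particles_per_organ:
            m = int(m)
            if m < 1 or (m & (m - 1)) != 0:
                raise ValueError("particles_per_organ entries must be powers of two")
        for name in ("alpha_global", "alpha_within", "alpha_between"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.alpha_reg_start_factor <= 0 or self.alpha_reg_end_factor <= 0:
            raise ValueError("regularization factors must be positive")
        if self.iterations_per_split_level < 1:
            raise ValueError("iterations_per_split_level must be >= 1")


# ---------------------------------------------------------------------------
# Initialization and splitting
# ---------------------------------------------------------------------------

def _check_ensemble(subjects) -> None:
    if len(subjects) < 1:
        raise ValueError("empty ensemble")
    labels = subjects[0].organ_labels
    for s in subjects:
        if list(s.organ_labels) != list(labels):
            raise ValueError("inconsistent organ sets across subjects")


def _anchor_point(organ):
    """Surface point nearest the organ centroid (argmin tie-break: lowest
    face id, so placement is deterministic)."""
    q, fid, _ = closest_points(organ, organ.centroid.reshape(1, 3))
    return q[0], int(fid[0])


def initialize_particles(subjects, particles_per_organ, seed: int = 0) -> ParticleSystem:
    """Level-0 particle system: one particle per organ, placed at the
    surface point nearest that organ's vertex centroid.
    ``particles_per_organ`` (the eventual targets) must be powers of two."""
    _check_ensemble(subjects)
    for m in particles_per_organ:
        m = int(m)
        if m < 1 or (m & (m - 1)) != 0:
            raise ValueError("particles_per_organ entries must be powers of two")
    k_organs = subjects[0].n_organs
    if len(particles_per_organ) != k_organs:
        raise ValueError("one particle count per organ required")
    n = len(subjects)
    points = np.empty((n, k_organs, 3))
    fids = np.empty((n, k_organs), dtype=np.int64)
    for i, subj in enumerate(subjects):
        for k, organ in enumerate(subj.organs):
            points[i, k], fids[i, k] = _anchor_point(organ)
    return ParticleSystem(
        points, [1] * k_organs, [s.subject_id for s in subjects],
        list(subjects[0].organ_labels), fids,
    )


def split_particles(system: ParticleSystem, subjects, seed: int = 0, organs=None) -> ParticleSystem:
    """Double the particle count of the selected organs (default: all).

    Each particle spawns a child at a small tangential offset, re-projected
    to the surface. The offset direction is drawn once per (organ, particle)
    and shared across subjects, so the initial correspondence of the
    children mirrors that of their parents. Children of organ k are appended
    after the parents (child of parent m sits at index M_k + m)."""
    _check_ensemble(subjects)
    if organs is None:
        organs = list(range(system.n_organs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    new_blocks, new_fids, new_counts = [], [], []
    for k, sl in enumerate(system.organ_slices):
        parents = system.points[:, sl]  # (N, M_k, 3)
        pfids = system.face_ids[:, sl]
        if k not in organs:
            new_blocks.append(parents)
            new_fids.append(pfids)
            new_counts.append(system.counts[k])
            continue
        mk = parents.shape[1]
        dirs = rng.normal(size=(mk, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        children = np.empty_like(parents)
        cfids = np.empty_like(pfids)
        for i, subj in enumerate(subjects):
            mesh = subj.organs[k]
            eps = 0.02 * mesh.bbox_diagonal
            normals = mesh.face_normals[pfids[i]]
            tang = dirs - np.einsum("mj,mj->m", dirs, normals)[:, None] * normals
            nrm = np.linalg.norm(tang, axis=1, keepdims=True)
            degenerate = nrm[:, 0] < 1e-8
            if degenerate.any():  # direction parallel to normal: pick another axis
                alt = np.cross(normals[degenerate], np.array([1.0, 0.0, 0.0]))
                bad = np.linalg.norm(alt, axis=1) < 1e-8
                alt[bad] = np.cross(normals[degenerate][bad], np.array([0.0, 1.0, 0.0]))
                tang[degenerate] = alt
                nrm = np.linalg.norm(tang, axis=1, keepdims=True)
            tang /= nrm
            q, fid, _ = closest_points(mesh, parents[i] + eps * tang)
            children[i] = q
            cfids[i] = fid
        new_blocks.append(np.concatenate([parents, children], axis=1))
        new_fids.append(np.concatenate([pfids, cfids], axis=1))
        new_counts.append(2 * mk)
    return ParticleSystem(
        np.concatenate(new_blocks, axis=1),
        new_counts,
        list(system.subject_ids),
        list(system.organ_labels),
        np.concatenate(new_fids, axis=1),
    )


def sampling_entropy_gradient(system: ParticleSystem, n: int, k: int,
                              sigmas=None, sigma_floor: float | None = None,
                              k_neighbors: int = 6):
    """Parzen repulsion for subject ``n``'s particles on organ ``k``.

    Returns ``(grad, H)``: the ascent direction on the configuration-space
    entropy (to be tangent-projected by the caller) and the entropy
    estimate. Kernel widths default to the median-of-6-nearest rule floored
    at 1e-3 of the particle bounding-box diagonal."""
    pts = system.organ_points(n, k)
    if sigmas is None:
        if sigma_floor is None:
            diag = np.linalg.norm(pts.max(0) - pts.min(0)) if len(pts) > 1 else 1.0
            sigma_floor = max(1e-3 * diag, 1e-12)
        sigmas = parzen_sigmas(pts, sigma_floor, k_neighbors)
    h, grad = sampling_entropy(pts, sigmas)
    return grad, h


# ---------------------------------------------------------------------------
# Optimization loop
# ---------------------------------------------------------------------------

@dataclass
class _LevelState:
    """Per-split-level frozen quantities: regularizations and step sizes."""

    alpha_regs: dict
    steps: dict = field(default_factory=dict)
    step_caps: dict = field(default_factory=dict)
    last_q: float = np.nan


class _Optimizer:
    """Holds the ensemble and drives mode-specific iterations."""

    def __init__(self, subjects, config: OptimizerConfig):
        _check_ensemble(subjects)
        self.subjects = list(subjects)
        self.config = config
        self.trace: list = []
        self._mean_diag = float(
            np.mean([o.bbox_diagonal for s in subjects for o in s.organs])
        )
        if config.mode == "single":
            self.groups = [[k] for k in range(subjects[0].n_organs)]
        elif config.mode == "global":
            self.groups = [list(range(subjects[0].n_organs))]
        else:
            self.groups = None

    # -- surface ops -------------------------------------------------------
    def snap(self, system: ParticleSystem, organs=None) -> ParticleSystem:
        """Project particles of the selected organs (default all) back onto
        their surfaces; returns a new system with updated face ids."""
        if organs is None:
            organs = range(system.n_organs)
        pts = system.points.copy()
        fids = system.face_ids.copy()
        for n, subj in enumerate(self.subjects):
            for k in organs:
                sl = system.organ_slices[k]
                q, fid, _ = closest_points(subj.organs[k], system.points[n, sl])
                pts[n, sl] = q
                fids[n, sl] = fid
        return ParticleSystem(pts, list(system.counts), list(system.subject_ids),
                              list(system.organ_labels), fids)

    def tangent_project(self, system: ParticleSystem, vecs: np.ndarray,
                        organs=None) -> np.ndarray:
        if organs is None:
            organs = range(system.n_organs)
        out = np.zeros_like(vecs)
        for n, subj in enumerate(self.subjects):
            for k in organs:
                sl = system.organ_slices[k]
                normals = subj.organs[k].face_normals[system.face_ids[n, sl]]
                v = vecs[n, sl]
                out[n, sl] = v - np.einsum("mj,mj->m", v, normals)[:, None] * normals
        return out

    # -- statistics --------------------------------------------------------
    def sigmas(self, system: ParticleSystem):
        out = []
        for n, subj in enumerate(self.subjects):
            row = []
            for k in range(system.n_organs):
                floor = max(self.config.sigma_floor_rel * subj.organs[k].bbox_diagonal,
                            1e-12)
                row.append(parzen_sigmas(system.organ_points(n, k), floor,
                                         self.config.sigma_neighbors))
            out.append(row)
        return out

    def _group_matrix(self, system: ParticleSystem, group) -> np.ndarray:
        cols = [system.points[:, system.organ_slices[k]] for k in group]
        stacked = np.concatenate(cols, axis=1)  # (N, Mg, 3)
        return center_columns(stacked.reshape(system.n_subjects, -1).T)

    def level_state(self, system: ParticleSystem, frac: float = 1.0) -> _LevelState:
        """Freeze regularizations and initial steps for one split level.

        ``frac`` in [0, 1] positions the level on the geometric decay from
        ``alpha_reg_start_factor`` to ``alpha_reg_end_factor``.
        """
        cfg = self.config
        rel = cfg.alpha_reg_start_factor * (
            cfg.alpha_reg_end_factor / cfg.alpha_reg_start_factor
        ) ** float(np.clip(frac, 0.0, 1.0))
        floor = 1e-10 * self._mean_diag**2 + 1e-300
        regs: dict = {}
        if cfg.mode == "mlmo":
            dec = _mlmo.decompose(system)
            for k, w in enumerate(dec.within):
                regs[("W", k)] = max(rel * eigenvalue_scale(center_columns(w)), floor)
            regs[("B",)] = max(
                rel * eigenvalue_scale(center_columns(dec.between)), floor
            )
        else:
            for gi, group in enumerate(self.groups):
                regs[("G", gi)] = max(
                    rel * eigenvalue_scale(self._group_matrix(system, group)), floor
                )
        state = _LevelState(alpha_regs=regs)
        sig = self.sigmas(system)
        msig = float(np.concatenate(
            [np.atleast_1d(a) for row in sig for a in row]
        ).mean())
        if max(system.counts) < 2:
            step0 = 0.02 * self._mean_diag
        else:
            step0 = cfg.step_factor * msig
        if cfg.mode == "mlmo":
            keys = [("W", k) for k in range(system.n_organs)] + [("B",)]
        else:
            keys = [("G", gi) for gi in range(len(self.groups))]
        for key in keys:
            state.steps[key] = step0
            state.step_caps[key] = 4.0 * step0
        return state

    # -- energy ------------------------------------------------------------
    def total_energy(self, system: ParticleSystem, sigmas, state: _LevelState):
        cfg = self.config
        h_samp = 0.0
        for n in range(system.n_subjects):
            for k in range(system.n_organs):
                h, _ = sampling_entropy(system.organ_points(n, k), sigmas[n][k])
                h_samp += h
        if cfg.mode == "mlmo":
            dec = _mlmo.decompose(system)
            shape = cfg.alpha_within * sum(
                subspace_entropy(center_columns(w), state.alpha_regs[("W", k)])
                for k, w in enumerate(dec.within)
            ) + cfg.alpha_between * subspace_entropy(
                center_columns(dec.between), state.alpha_regs[("B",)]
            )
        else:
            shape = cfg.alpha_global * sum(
                subspace_entropy(self._group_matrix(system, g), state.alpha_regs[("G", gi)])
                for gi, g in enumerate(self.groups)
            )
        q = shape - h_samp
        if not np.isfinite(q):
            raise RuntimeError(
                f"non-finite energy (shape={shape!r}, sampling={h_samp!r}); "
                "diagnostic: check for coincident particles or zero covariance"
            )
        return q, shape, h_samp

    def sampling_gradients(self, system: ParticleSystem, sigmas) -> np.ndarray:
        grad = np.zeros_like(system.points)
        for n in range(system.n_subjects):
            for k, sl in enumerate(system.organ_slices):
                _, g = sampling_entropy(system.organ_points(n, k), sigmas[n][k])
                grad[n, sl] = g
        return grad

    def shape_gradient_shared(self, system: ParticleSystem, state: _LevelState) -> np.ndarray:
        grad = np.zeros_like(system.points)
        n = system.n_subjects
        for gi, group in enumerate(self.groups):
            y = self._group_matrix(system, group)
            g = correspondence_gradient(y, state.alpha_regs[("G", gi)])
            cols = g.T  # (N, 3*Mg)
            start = 0
            for k in group:
                sl = system.organ_slices[k]
                mk = system.counts[k]
                grad[:, sl] = cols[:, start : start + 3 * mk].reshape(n, mk, 3)
                start += 3 * mk
        return grad

    # -- stepping ----------------------------------------------------------
    def organ_energy(self, system, sigmas, state, k: int, weight: float):
        """Energy terms involving only organ k's particles (within mode)."""
        h_samp = 0.0
        for n in range(system.n_subjects):
            h, _ = sampling_entropy(system.organ_points(n, k), sigmas[n][k])
            h_samp += h
        dec_w = system.points[:, system.organ_slices[k]]
        cent = dec_w.mean(axis=1, keepdims=True)
        y = center_columns((dec_w - cent).reshape(system.n_subjects, -1).T)
        shape = weight * subspace_entropy(y, state.alpha_regs[("W", k)])
        return shape - h_samp, shape, h_samp

    def group_energy(self, system, sigmas, state, gi: int, weight: float):
        """Energy terms of one shared-space group (single/global modes)."""
        group = self.groups[gi]
        h_samp = 0.0
        for n in range(system.n_subjects):
            for k in group:
                h, _ = sampling_entropy(system.organ_points(n, k), sigmas[n][k])
                h_samp += h
        shape = weight * subspace_entropy(
            self._group_matrix(system, group), state.alpha_regs[("G", gi)]
        )
        return shape - h_samp, shape, h_samp

    def _phase(self, system, state, sigmas, key, phase_name, direction,
               organs, energy_fn, level, iteration):
        """One backtracking step of the particles of ``organs`` along
        ``direction``, judged by ``energy_fn`` (the objective terms those
        particles affect). Step length is per-phase-key adaptive."""
        cfg = self.config
        q0, shape0, samp0 = energy_fn(system)
        if not np.isfinite(q0):
            raise RuntimeError(
                f"non-finite energy in phase {phase_name} "
                f"(shape={shape0!r}, sampling={samp0!r})"
            )
        direction = self.tangent_project(system, direction, organs)
        sls = [system.organ_slices[k] for k in organs]
        dmax = max(
            float(np.max(np.linalg.norm(direction[:, sl], axis=-1))) for sl in sls
        )
        row = {
            "level": level, "iteration": iteration, "phase": phase_name,
            "Q_pre": q0, "shape_term": shape0, "sampling_term": samp0,
        }
        if dmax <= 0 or not np.isfinite(dmax):
            row.update(Q_post=q0, step=0.0, accepted=False)
            self.trace.append(row)
            return system, q0
        unit = direction / dmax
        s = state.steps[key]
        accepted = False
        tol = 1e-12 * max(1.0, abs(q0))
        for _ in range(cfg.max_backtracks + 1):
            trial = system.copy()
            for sl in sls:
                trial.points[:, sl] = system.points[:, sl] + s * unit[:, sl]
            trial = self.snap(trial, organs)
            q1, _, _ = energy_fn(trial)
            if q1 <= q0 + tol:
                accepted = True
                break
            s *= 0.5
        if accepted:
            state.steps[key] = min(s * cfg.step_growth, state.step_caps[key])
            row.update(Q_post=q1, step=s, accepted=True)
            self.trace.append(row)
            return trial, q1
        state.steps[key] = s
        row.update(Q_post=q0, step=0.0, accepted=False)
        self.trace.append(row)
        return system, q0

    def consensus_repair(self, system: ParticleSystem) -> tuple:
        """Re-align within-configuration outliers to the ensemble consensus.

        For each organ, a subject whose centered particle configuration
        deviates from the consensus far more than the ensemble median is
        treated as label-switched (settled on the wrong symmetry position
        of a nearly symmetric surface). The consensus configuration of the
        healthy subjects, shifted to the outlier's organ centroid, is
        snapped onto the outlier's surface and kept iff it reduces the
        deviation. Returns ``(system, n_repaired)``.
        """
        pts = system.points
        repaired = 0
        out = None
        for k, sl in enumerate(system.organ_slices):
            mk = system.counts[k]
            if mk < 2:
                continue
            organ = pts[:, sl]  # (N, M_k, 3)
            cent = organ.mean(axis=1, keepdims=True)
            w = organ - cent  # per-subject centered configurations
            n_sub = w.shape[0]
            flat = w.reshape(n_sub, -1)
            d2 = (
                np.sum(flat**2, axis=1)[:, None]
                - 2.0 * flat @ flat.T
                + np.sum(flat**2, axis=1)[None, :]
            )
            # label-switched configurations differ from healthy ones by
            # orders of magnitude; split the pairwise distances at their
            # largest multiplicative gap (none -> nothing to repair), so
            # legitimately extreme shapes (a few-fold off) are never touched
            floor = 1e-6 * mk * self._mean_diag**2
            off_diag = np.sort(d2[~np.eye(n_sub, dtype=bool)]) + floor
            ratios = off_diag[1:] / off_diag[:-1]
            gap = int(np.argmax(ratios))
            if ratios[gap] < 20.0:
                continue
            theta = off_diag[gap + 1] - floor
            # largest mutually consistent cluster = reference labeling
            # (greedy: the subject with the most close neighbors, then its
            # neighborhood; lowest index wins ties)
            close = (d2 < theta) & ~np.eye(n_sub, dtype=bool)
            seed_subj = int(np.argmax(close.sum(axis=1)))
            cluster = close[seed_subj].copy()
            cluster[seed_subj] = True
            if cluster.all() or cluster.sum() < 2:
                continue
            consensus = w[cluster].mean(axis=0)
            for n in np.flatnonzero(~cluster):
                mesh = self.subjects[n].organs[k]
                q, fid, _ = closest_points(mesh, consensus + cent[n])
                new_dev = float(np.sum((q - q.mean(axis=0) - consensus) ** 2))
                old_dev = float(np.sum((w[n] - consensus) ** 2))
                if new_dev < old_dev:
                    if out is None:
                        out = system.copy()
                    out.points[n, sl] = q
                    out.face_ids[n, sl] = fid
                    repaired += 1
        system = system if out is None else out
        system, n_particles = self._repair_particles(system)
        return system, repaired + n_particles

    def _repair_particles(self, system: ParticleSystem):
        """Second repair stage: individual mislabeled particles.

        A particle sitting on the wrong symmetry position of its organ
        deviates from the ensemble-mean position of its correspondence
        index by orders of magnitude more than shape variation allows.
        Detection uses the same multiplicative-gap rule on the per-particle
        deviations; flagged particles are re-snapped from the consensus
        position (kept iff closer to it) and local spacing is left to the
        subsequent relaxation pass.
        """
        repaired = 0
        copied = False
        for k, sl in enumerate(system.organ_slices):
            mk = system.counts[k]
            if mk < 2:
                continue
            organ = system.points[:, sl]
            cent = organ.mean(axis=1, keepdims=True)
            w = organ - cent
            wbar = w.mean(axis=0)  # consensus position per particle index
            e = np.sum((w - wbar) ** 2, axis=2)  # (N, M_k)
            floor = 1e-4 * self._mean_diag**2
            es = np.sort(e.ravel()) + floor
            ratios = es[1:] / es[:-1]
            gap = int(np.argmax(ratios))
            if ratios[gap] < 20.0:
                continue
            theta = es[gap + 1] - floor
            bad_n, bad_m = np.nonzero(e + floor >= theta + floor)
            if len(bad_n) == 0 or len(bad_n) > 0.5 * e.size:
                continue
            for n, m in zip(bad_n, bad_m):
                mesh = self.subjects[n].organs[k]
                q, fid, _ = closest_points(mesh, (wbar[m] + cent[n, 0]).reshape(1, 3))
                new_e = float(np.sum((q[0] - cent[n, 0] - wbar[m]) ** 2))
                if new_e < e[n, m]:
                    if not copied:
                        system = system.copy()
                        copied = True
                    idx = sl.start + m
                    system.points[n, idx] = q[0]
                    system.face_ids[n, idx] = fid[0]
                    repaired += 1
        return system, repaired

    def iterate(self, system: ParticleSystem, state: _LevelState,
                level: int = 0, iteration: int = 0) -> ParticleSystem:
        """One full optimization iteration. Kernel widths are computed once
        per iteration and lagged through the phases (the lagged-statistics
        rule). In mlmo mode each organ's within phase steps independently
        (the within objective is separable per organ, and per-organ step
        lengths keep one organ's gradient scale from starving another's),
        followed by the global between phase."""
        cfg = self.config
        sigmas = self.sigmas(system)
        samp = self.sampling_gradients(system, sigmas)
        if cfg.mode == "mlmo":
            aw = cfg.alpha_within
            regs_w = [state.alpha_regs[("W", k)] for k in range(system.n_organs)]
            gw, _ = _mlmo.mlmo_shape_gradients(system, regs_w, state.alpha_regs[("B",)])
            for k in range(system.n_organs):
                system, _ = self._phase(
                    system, state, sigmas, ("W", k), f"within_{k}",
                    -aw * gw + samp, [k],
                    lambda s, k=k: self.organ_energy(s, sigmas, state, k, aw),
                    level, iteration,
                )
            _, gb = _mlmo.mlmo_shape_gradients(system, regs_w, state.alpha_regs[("B",)])
            system, q = self._phase(
                system, state, sigmas, ("B",), "between",
                -cfg.alpha_between * gb, list(range(system.n_organs)),
                lambda s: self.total_energy(s, sigmas, state),
                level, iteration,
            )
            state.last_q = q
        else:
            ag = cfg.alpha_global
            g = self.shape_gradient_shared(system, state)
            q_total = 0.0
            for gi, group in enumerate(self.groups):
                system, q = self._phase(
                    system, state, sigmas, ("G", gi), f"shared_{gi}",
                    -ag * g + samp, list(group),
                    lambda s, gi=gi: self.group_energy(s, sigmas, state, gi, ag),
                    level, iteration,
                )
                q_total += q
            state.last_q = q_total
        return system


def optimize(subjects, config: OptimizerConfig):
    """Run the full splitting + relaxation schedule.

    Returns ``(system, trace)`` where ``trace`` is a DataFrame with one row
    per (iteration, phase): energy before/after the step, the term
    breakdown and the accepted step length. Deterministic given the seed.
    """
    _check_ensemble(subjects)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    targets = [int(m) for m in config.particles_per_organ]
    system = initialize_particles(subjects, targets, config.seed)
    opt = _Optimizer(subjects, config)
    n_levels = int(max(np.log2(t) for t in targets))
    seeds = np.random.SeedSequence(config.seed).spawn(max(n_levels, 1))
    for level in range(n_levels + 1):
        if level > 0:
            organs = [k for k in range(system.n_organs)
                      if system.counts[k] < targets[k]]
            if organs:
                system = split_particles(
                    system, subjects,
                    seed=seeds[level - 1].generate_state(1)[0] % (2**31),
                    organs=organs,
                )
        for attempt in range(2):
            state = opt.level_state(system, frac=level / max(n_levels, 1))
            qhist: list = []
            for it in range(config.iterations_per_split_level):
                system = opt.iterate(system, state, level=level, iteration=it)
                qhist.append(state.last_q)
                w = config.convergence_window
                if len(qhist) > w:
                    rel = abs(qhist[-1] - qhist[-1 - w]) / max(1.0, abs(qhist[-1]))
                    if rel < config.convergence_tol:
                        break
            if attempt == 1 or max(system.counts) > config.repair_below:
                break
            system, n_repaired = opt.consensus_repair(system)
            if n_repaired == 0:
                break  # nothing to fix; skip the second relaxation pass
    return system, pd.DataFrame(opt.trace)
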