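"""Synthetic multi-object ensembles built from Gielis supershapes.

Each subject is a row of K supershape objects. One superformula exponent per
object is drawn from a scaled chi-squared distribution (the known
"within-object" morphology factor), and the object centroids are placed on a
parabola ``y = a * x**2`` with ``a ~ U(0, 0.001)`` (the known
"between-objects" pose factor). The generator records every draw in a
manifest so recovery of these two latent factors can be checked exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import MultiOrganSubject, SurfaceMesh

__all__ = [
    "SupershapeSpec",
    "EnsembleConfig",
    "GroundTruthManifest",
    "superformula_radius",
    "build_supershape_mesh",
    "generate_synthetic_ensemble",
]


@dataclass(frozen=True)
class SupershapeSpec:
    """Parameters of one 2-D superformula.

    ``r(theta) = (|cos(m*theta/4)/a|**n2 + |sin(m*theta/4)/b|**n3)**(-1/n1)``
    """

    m: float
    n1: float
    n2: float
    n3: float
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.m, self.n1, self.n2, self.n3, self.a, self.b)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("supershape parameters must be finite")
        if self.a <= 0 or self.b <= 0 or self.n1 <= 0:
            raise ValueError("a, b and n1 must be positive")


def superformula_radius(theta, spec: SupershapeSpec):
    """Evaluate the superformula radius at angle(s) ``theta`` (radians)."""
    theta = np.asarray(theta, dtype=float)
    base = (
        np.abs(np.cos(spec.m * theta / 4.0) / spec.a) ** spec.n2
        + np.abs(np.sin(spec.m * theta / 4.0) / spec.b) ** spec.n3
    )
    if np.any(base <= 0):
        raise FloatingPointError("superformula base reached zero (undefined radius)")
    r = base ** (-1.0 / spec.n1)
    if not np.all(np.isfinite(r)):
        raise FloatingPointError("superformula radius is not finite")
    return r if r.shape else float(r)


def build_supershape_mesh(
    spec_theta: SupershapeSpec,
    spec_phi: SupershapeSpec,
    resolution: int = 24,
    scale: float = 1.0,
) -> SurfaceMesh:
    """Triangulate the spherical product of two superformulas.

    Longitude theta in [-pi, pi) and latitude phi in [-pi/2, pi/2]:

        x = scale * r1(theta) cos(theta) * r2(phi) cos(phi)
        y = scale * r1(theta) sin(theta) * r2(phi) cos(phi)
        z = scale * r2(phi) sin(phi)

    The mesh has ``resolution * (resolution - 1) + 2`` vertices (the poles
    are single merged points) and is star-shaped about the origin because
    both radii are strictly positive.
    """
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    res = int(resolution)
    theta = -np.pi + 2.0 * np.pi * np.arange(res) / res
    phi = -np.pi / 2.0 + np.pi * np.arange(1, res) / res  # interior latitudes
    r1 = superformula_radius(theta, spec_theta)
    r2 = superformula_radius(phi, spec_phi)

    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    # grid[j, i] = vertex at latitude j, longitude i
    x = scale * np.outer(cp * r2, r1 * ct)
    y = scale * np.outer(cp * r2, r1 * st)
    z = scale * np.outer(sp * r2, np.ones(res))
    grid = np.stack([x, y, z], axis=-1).reshape(-1, 3)

    r2_south = superformula_radius(-np.pi / 2.0, spec_phi)
    r2_north = superformula_radius(np.pi / 2.0, spec_phi)
    south = np.array([0.0, 0.0, -scale * r2_south])
    north = np.array([0.0, 0.0, scale * r2_north])
    vertices = np.vstack([grid, south, north])
    i_south = len(vertices) - 2
    i_north = len(vertices) - 1

    def vid(j, i):
        return j * res + (i % res)

    faces = []
    for i in range(res):  # south cap (phi increasing upward => CCW from outside)
        faces.append((i_south, vid(0, i + 1), vid(0, i)))
    for j in range(res - 2):  # latitude bands
        for i in range(res):
            v00, v01 = vid(j, i), vid(j, i + 1)
            v10, v11 = vid(j + 1, i), vid(j + 1, i + 1)
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))
    for i in range(res):  # north cap
        faces.append((i_north, vid(res - 2, i), vid(res - 2, i + 1)))
    return SurfaceMesh(vertices, np.array(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    """Study conditions for the synthetic multi-object benchmark.

    ``n1 = n1_base + chi2_scale * Chi2(chi2_df)`` is the single varying
    morphology parameter per object; object k (1-based) has ``k + 2`` lobes.
    Object centroids sit at ``(x_k, a_n * x_k**2, 0)`` with
    ``a_n ~ U(*pose_coeff_range)``.
    """

    n_subjects: int = 20
    n_objects: int = 3
    chi2_df: float = 4.0
    chi2_scale: float = 0.25
    n1_base: float = 2.0
    n2: float = 4.0
    n3: float = 4.0
    pose_coeff_range: tuple = (0.0, 0.001)
    object_x_positions: tuple | None = None  # default: 0, 60, 120, ... mm
    object_spacing: float = 60.0
    scale: float = 20.0
    mesh_resolution: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if self.n_objects < 2:
            raise ValueError("need at least 2 objects")
        lo, hi = self.pose_coeff_range
        if lo < 0 or hi < lo:
            raise ValueError("pose_coeff_range must be within [0, inf)")
        if self.object_x_positions is not None and len(self.object_x_positions) != self.n_objects:
            raise ValueError("object_x_positions must have one entry per object")
        if self.mesh_resolution < 8:
            raise ValueError("mesh_resolution must be >= 8")

    @property
    def x_positions(self) -> np.ndarray:
        if self.object_x_positions is not None:
            return np.asarray(self.object_x_positions, dtype=float)
        return self.object_spacing * np.arange(self.n_objects, dtype=float)


@dataclass
class GroundTruthManifest:
    """Latent factors behind a generated ensemble: one record per
    (subject, object) plus the per-subject parabola coefficient."""

    records: list = field(default_factory=list)

    def add(self, subject_id, organ, chi2_draw, n1, m, pose_a, center) -> None:
        self.records.append(
            {
                "subject": subject_id,
                "organ": organ,
                "chi2_draw": float(chi2_draw),
                "n1": float(n1),
                "m": float(m),
                "pose_a": float(pose_a),
                "center": [float(c) for c in center],
            }
        )

    def pose_coefficients(self) -> dict:
        return {r["subject"]: r["pose_a"] for r in self.records}

    def to_json(self, path=None) -> str:
        text = json.dumps({"records": self.records}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(records=data["records"])


def generate_synthetic_ensemble(config: EnsembleConfig):
    """Generate the supershape ensemble and its ground-truth manifest.

    Deterministic: one master seed spawns an independent substream per
    subject, so the ensemble is a pure function of the config.
    """
    xs = config.x_positions
    subjects = []
    manifest = GroundTruthManifest()
    lo, hi = config.pose_coeff_range
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    spec_phi = SupershapeSpec(m=0.0, n1=2.0, n2=2.0, n3=2.0)
    for n in range(config.n_subjects):
        rng = np.random.default_rng(children[n])
        a_n = rng.uniform(lo, hi)
        organs, labels = [], []
        sid = f"subject_{n:03d}"
        for k in range(config.n_objects):
            chi2 = rng.chisquare(config.chi2_df)
            n1 = config.n1_base + config.chi2_scale * chi2
            m = k + 3  # object k (1-based) has k + 2 lobes
            spec_theta = SupershapeSpec(m=m, n1=n1, n2=config.n2, n3=config.n3)
            mesh = build_supershape_mesh(
                spec_theta, spec_phi, config.mesh_resolution, config.scale
            )
            center = np.array([xs[k], a_n * xs[k] ** 2, 0.0])
            organs.append(mesh.translated(center))
            label = f"object{k}"
            labels.append(label)
            manifest.add(sid, label, chi2, n1, m, a_n, center)
        subjects.append(MultiOrganSubject(sid, organs, labels))
    return subjects, manifest


def config_to_dict(config: EnsembleConfig) -> dict:
    d = dataclasses.asdict(config)
    d["pose_coeff_range"] = list(config.pose_coeff_range)
    if config.object_x_positions is not None:
        d["object_x_positions"] = list(config.object_x_positions)
    return d
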