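"""Synthetic cohorts of spherical head models with anatomical variability.

Each subject is a four-shell concentric sphere (brain / CSF / skull / scalp)
with per-shell lognormal radius jitter emulating inter-subject variability in
head size and tissue thickness, an analytic lead-field, a circular cortical
target patch, and anatomical features (scalp geodesic perimeters, tissue
volumes from a nested-shell tetrahedral mesh with distinct GM/WM sub-shells).
Optional conductivity jitter produces repeated models that differ only in the
lead-field, never in geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import geodesic_perimeters
from .electrodes import LANDMARK_DIRECTIONS, ideal_1010_positions
from .forward import SphericalHeadSpec, spherical_leadfield
from .geometry import CorticalSurface, TetMesh, icosphere, tissue_volumes
from .model import AnatomicalFeatures, SubjectModel, TargetMap

__all__ = [
    "TargetPatch",
    "CohortSpec",
    "generate_cohort",
    "conductivity_variants",
    "nested_shell_tetmesh",
]

_RETRY_CAP = 50


def _default_patch_center() -> np.ndarray:
    # centred under F3, the standard scalp proxy for the left DLPFC
    return ideal_1010_positions(("F3",))["F3"]


@dataclass
class TargetPatch:
    """Circular cortical target: En target and weight inside an angular patch,
    zero target with a lower weight everywhere else."""

    center: np.ndarray = field(default_factory=_default_patch_center)
    angular_radius: float = 0.35  # radians
    target_en: float = 0.25  # V/m
    target_weight: float = 10.0
    off_weight: float = 2.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.center = self.center / np.linalg.norm(self.center)
        if not 0.0 < self.angular_radius < np.pi:
            raise ValueError("angular radius must lie in (0, pi)")

    def target_map(self, surface: CorticalSurface) -> TargetMap:
        inside = surface.unit_directions() @ self.center >= np.cos(self.angular_radius)
        en = np.where(inside, self.target_en, 0.0)
        w = np.where(inside, self.target_weight, self.off_weight)
        return TargetMap(en, w)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    n_subjects: int = 6
    base: SphericalHeadSpec = field(default_factory=SphericalHeadSpec)
    radius_jitter: float = 0.03  # relative s.d. per shell
    conductivity_jitter: float = 0.0  # > 0 enables conductivity variability
    target: TargetPatch = field(default_factory=TargetPatch)
    seed: int = 0
    surface_subdivisions: int = 3  # 642 cortical nodes
    tet_subdivisions: int = 2
    wm_fraction: float = 0.8  # WM sub-shell radius as fraction of brain radius
    compute_features: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.radius_jitter < 0 or self.conductivity_jitter < 0:
            raise ValueError("jitters must be nonnegative")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative factors with relative s.d. ``cv``."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def nested_shell_tetmesh(
    tissue_radii: dict[str, float], subdivisions: int = 2
) -> TetMesh:
    """Tetrahedral mesh of nested spherical tissue shells.

    ``tissue_radii`` maps each tissue to its outer radius; the innermost
    tissue fills the central ball. Shells between consecutive sphere layers
    are meshed as triangular prisms split into three tetrahedra each, with
    face diagonals chosen by the minimum-vertex rule so neighbouring prisms
    conform.
    """
    items = sorted(tissue_radii.items(), key=lambda kv: kv[1])
    radii = [r for _, r in items]
    if len(set(radii)) != len(radii):
        raise ValueError("tissue radii must be distinct")
    base = icosphere(subdivisions, 1.0)
    n_layer = base.n_nodes
    unit_nodes, faces = base.nodes, base.triangles

    nodes = [np.zeros((1, 3))]
    for r in radii:
        nodes.append(unit_nodes * r)
    nodes = np.vstack(nodes)

    tets: list[tuple[int, int, int, int]] = []
    labels: list[str] = []

    # central ball: apex at the origin
    inner_offset = 1
    for a, b, c in faces:
        tets.append((0, inner_offset + a, inner_offset + b, inner_offset + c))
        labels.append(items[0][0])

    # shells between consecutive layers
    for k in range(1, len(radii)):
        lo = 1 + (k - 1) * n_layer
        hi = 1 + k * n_layer
        tissue = items[k][0]
        for a, b, c in faces:
            prism = (lo + a, lo + b, lo + c, hi + a, hi + b, hi + c)
            tets.extend(_split_prism(prism))
            labels.extend([tissue] * 3)

    return TetMesh(np.asarray(nodes), np.asarray(tets), np.asarray(labels, dtype=object))


# orientation-preserving prism symmetries (bottom 0,1,2 / top 3,4,5)
_PRISM_MAPS = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1),
    (4, 3, 5, 1, 0, 2),
    (5, 4, 3, 2, 1, 0),
]


def _split_prism(v: tuple[int, ...]) -> list[tuple[int, int, int, int]]:
    """Split a triangular prism into 3 tetrahedra (minimum-vertex diagonals)."""
    argmin = min(range(6), key=lambda i: v[i])
    for m in _PRISM_MAPS:
        if m[0] == argmin:
            p = [v[i] for i in m]
            break
    if min(p[1], p[5]) < min(p[2], p[4]):
        idx = [(0, 1, 2, 5), (0, 1, 5, 4), (0, 4, 5, 3)]
    else:
        idx = [(0, 1, 2, 4), (0, 4, 2, 5), (0, 4, 5, 3)]
    return [tuple(p[i] for i in t) for t in idx]


def _landmark_nodes(surface: CorticalSurface) -> dict[str, int]:
    dirs = surface.unit_directions()
    return {
        name: int(np.argmax(dirs @ d)) for name, d in LANDMARK_DIRECTIONS.items()
    }


def _draw_radii(
    rng: np.random.Generator, base_radii: tuple[float, ...], cv: float
) -> tuple[np.ndarray, np.ndarray]:
    for _ in range(_RETRY_CAP):
        factors = _lognormal_factors(rng, cv, len(base_radii))
        radii = np.asarray(base_radii) * factors
        if np.all(np.diff(radii) > 0):
            return radii, factors
    raise RuntimeError(
        f"could not draw strictly increasing shell radii in {_RETRY_CAP} tries; "
        "reduce radius_jitter"
    )


def _unit_scalp_perimeters(spec: CohortSpec) -> dict[str, float]:
    """Geodesic perimeter features of the unit scalp icosphere.

    All cohort scalps share this mesh up to a uniform scale, and geodesic
    lengths scale exactly with the coordinates, so per-subject perimeters are
    the unit values times the scalp radius.
    """
    unit = icosphere(spec.surface_subdivisions, 1.0)
    return geodesic_perimeters(unit, _landmark_nodes(unit))


def _make_subject(
    spec: CohortSpec,
    head: SphericalHeadSpec,
    subject_id: str,
    metadata: dict,
    unit_perimeters: dict[str, float] | None = None,
) -> SubjectModel:
    surface = icosphere(spec.surface_subdivisions, head.cortical_radius)
    leadfield = spherical_leadfield(head, surface)
    target = spec.target.target_map(surface)

    features = scalp = mesh = None
    if spec.compute_features:
        if unit_perimeters is None:
            unit_perimeters = _unit_scalp_perimeters(spec)
        scalp = icosphere(spec.surface_subdivisions, head.scalp_radius)
        brain, csf, skull, scalp_r = head.shell_radii
        mesh = nested_shell_tetmesh(
            {
                "wm": spec.wm_fraction * brain,
                "gm": brain,
                "csf": csf,
                "skull": skull,
                "scalp": scalp_r,
            },
            subdivisions=spec.tet_subdivisions,
        )
        perims = {k: v * head.scalp_radius for k, v in unit_perimeters.items()}
        features = AnatomicalFeatures(volumes=tissue_volumes(mesh), **perims)
    return SubjectModel(
        subject_id=subject_id,
        surface=surface,
        leadfield=leadfield,
        target=target,
        features=features,
        scalp_surface=scalp,
        tet_mesh=mesh,
        metadata=metadata,
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectModel]:
    """Generate ``spec.n_subjects`` subject models; deterministic given the seed."""
    if len(spec.base.shell_radii) != 4:
        raise ValueError("cohort generation expects a 4-shell (brain/CSF/skull/scalp) base")
    rng = np.random.default_rng(spec.seed)
    unit_perims = _unit_scalp_perimeters(spec) if spec.compute_features else None
    subjects = []
    for s in range(spec.n_subjects):
        radii, radius_factors = _draw_radii(rng, spec.base.shell_radii, spec.radius_jitter)
        cond_factors = _lognormal_factors(
            rng, spec.conductivity_jitter, len(spec.base.shell_conductivities)
        )
        conductivities = tuple(np.asarray(spec.base.shell_conductivities) * cond_factors)
        head = replace(
            spec.base,
            shell_radii=tuple(radii),
            shell_conductivities=conductivities,
            cortical_radius=None,
            electrode_positions=dict(spec.base.electrode_positions),
        )
        metadata = {
            "seed": spec.seed,
            "shell_radii_mm": [float(r) for r in radii],
            "shell_conductivities_S_per_m": [float(c) for c in conductivities],
            "radius_factors": radius_factors.tolist(),
            "conductivity_factors": cond_factors.tolist(),
        }
        subjects.append(_make_subject(spec, head, f"sub-{s:02d}", metadata, unit_perims))
    return subjects


def conductivity_variants(
    spec: CohortSpec, subject: SubjectModel, n_variants: int, seed: int = 0
) -> list[SubjectModel]:
    """Repeated models of one subject with jittered conductivities.

    All variants share the subject's geometry, target and features exactly;
    only the lead-field differs (the conductivity-uncertainty extension of
    the group framework).
    """
    if spec.conductivity_jitter <= 0:
        raise ValueError("spec.conductivity_jitter must be > 0 for variants")
    radii = tuple(subject.metadata["shell_radii_mm"])
    base_cond = np.asarray(subject.metadata["shell_conductivities_S_per_m"])
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_variants):
        factors = _lognormal_factors(rng, spec.conductivity_jitter, len(base_cond))
        head = replace(
            spec.base,
            shell_radii=radii,
            shell_conductivities=tuple(base_cond * factors),
            cortical_radius=None,
            electrode_positions=dict(spec.base.electrode_positions),
        )
        leadfield = spherical_leadfield(head, subject.surface)
        out.append(
            SubjectModel(
                subject_id=f"{subject.subject_id}-cond{k:02d}",
                surface=subject.surface,
                leadfield=leadfield,
                target=subject.target,
                features=subject.features,
                scalp_surface=subject.scalp_surface,
                tet_mesh=subject.tet_mesh,
                metadata={**subject.metadata, "conductivity_factors": factors.tolist()},
            )
        )
    return out
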