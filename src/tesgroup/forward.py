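"""Analytic forward model: point-electrode tES on concentric spherical shells.

The potential from a point current source on the outer surface of an
N-layer concentric sphere is a Legendre series in the cosine of the angle
to the electrode. Per degree n the radial coefficients of every layer
follow from potential/current continuity at the shell interfaces and the
injected current density at the scalp; the innermost-layer solution then
gives the radial E-field at the cortical evaluation sphere.

Sign convention: positive En points *into* the cortical surface (the
depolarising direction for radially oriented pyramidal cells), so the
cortex under an anode sees positive En.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import legval

from .electrodes import ideal_1010_positions
from .geometry import CorticalSurface
from .model import LeadField

__all__ = ["SphericalHeadSpec", "spherical_leadfield"]

#: Isotropic tissue conductivities (S/m): skin 0.33, skull 0.008, CSF 1.79,
#: GM 0.40 (white matter is merged into the brain shell).
DEFAULT_CONDUCTIVITIES = (0.40, 1.79, 0.008, 0.33)  # brain, csf, skull, scalp
DEFAULT_RADII = (78.0, 80.0, 86.0, 92.0)  # outer radii, mm


def _default_electrodes() -> dict[str, np.ndarray]:
    return ideal_1010_positions()


@dataclass
class SphericalHeadSpec:
    """Geometry, conductivities and electrode layout of one spherical head.

    ``shell_radii`` are outer radii (mm) from innermost (brain) to outermost
    (scalp); ``shell_conductivities`` match them. The cortical evaluation
    sphere defaults to the brain shell's outer surface.
    """

    shell_radii: tuple[float, ...] = DEFAULT_RADII
    shell_conductivities: tuple[float, ...] = DEFAULT_CONDUCTIVITIES
    electrode_positions: dict[str, np.ndarray] = field(default_factory=_default_electrodes)
    reference_label: str = "Cz"
    cortical_radius: float | None = None  # defaults to shell_radii[0]
    series_order: int = 300
    tail_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        self.shell_radii = tuple(float(r) for r in self.shell_radii)
        self.shell_conductivities = tuple(float(s) for s in self.shell_conductivities)
        if len(self.shell_radii) != len(self.shell_conductivities):
            raise ValueError("one conductivity per shell required")
        if len(self.shell_radii) < 1:
            raise ValueError("at least one shell required")
        if any(np.diff(self.shell_radii) <= 0) or self.shell_radii[0] <= 0:
            raise ValueError("shell radii must be positive and strictly increasing")
        if any(s <= 0 for s in self.shell_conductivities):
            raise ValueError("conductivities must be positive")
        if self.cortical_radius is None:
            self.cortical_radius = self.shell_radii[0]
        if not 0 < self.cortical_radius <= self.shell_radii[0]:
            raise ValueError("cortical radius must lie within the innermost shell")
        if self.series_order < 1:
            raise ValueError("series_order must be >= 1")
        if self.reference_label not in self.electrode_positions:
            raise ValueError(f"reference {self.reference_label!r} not among electrodes")
        for lab, d in self.electrode_positions.items():
            d = np.asarray(d, dtype=float)
            if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-6:
                raise ValueError(f"electrode {lab!r} direction is not a unit vector")
            self.electrode_positions[lab] = d

    @property
    def scalp_radius(self) -> float:
        return self.shell_radii[-1]

    def electrode_labels(self) -> tuple[str, ...]:
        """Non-reference labels, in insertion order."""
        return tuple(l for l in self.electrode_positions if l != self.reference_label)


def _en_series_coefficients(spec: SphericalHeadSpec) -> np.ndarray:
    """Legendre coefficients e_n of the inward-positive En (V/m) at the
    cortical radius for a +1 mA point injection on the scalp.

    Per degree n the layer coefficients (A'_1; A'_j, B'_j for j >= 2) are
    scaled by each layer's outer radius so the interface systems stay well
    conditioned at high n.
    """
    radii_m = np.asarray(spec.shell_radii) * 1e-3
    sigma = np.asarray(spec.shell_conductivities)
    n_layers = len(radii_m)
    R = radii_m[-1]
    x = radii_m / R  # normalised outer radii, x[-1] == 1
    x_c = spec.cortical_radius * 1e-3 / R
    current = 1e-3  # 1 mA in amperes

    nmax = spec.series_order
    coefs = np.zeros(nmax + 1)
    for n in range(1, nmax + 1):
        m = 2 * n_layers - 1
        M = np.zeros((m, m))
        rhs = np.zeros(m)
        # unknown order: A'_1, A'_2, B'_2, ..., A'_L, B'_L
        for j in range(n_layers - 1):  # interface at outer radius of layer j
            rho = x[j] / x[j + 1]
            rn, rm = rho**n, rho ** -(n + 1)
            row_v, row_f = 2 * j, 2 * j + 1
            if j == 0:
                M[row_v, 0] = 1.0
                M[row_f, 0] = sigma[0] * n
            else:
                ia, ib = 2 * j - 1, 2 * j
                M[row_v, ia], M[row_v, ib] = 1.0, 1.0
                M[row_f, ia] = sigma[j] * n
                M[row_f, ib] = -sigma[j] * (n + 1)
            ja, jb = 2 * j + 1, 2 * j + 2
            M[row_v, ja], M[row_v, jb] = -rn, -rm
            M[row_f, ja] = -sigma[j + 1] * n * rn
            M[row_f, jb] = sigma[j + 1] * (n + 1) * rm
        # scalp surface: radial current density of the point source
        if n_layers == 1:
            M[-1, 0] = sigma[-1] * n
        else:
            M[-1, -2] = sigma[-1] * n
            M[-1, -1] = -sigma[-1] * (n + 1)
        rhs[-1] = current * (2 * n + 1) / (4.0 * np.pi * R)
        sol = np.linalg.solve(M, rhs)
        a1 = sol[0]
        # V_1(x) = a1 (x/x_1)^n; En = +dV/dr = (n / (x_c R)) a1 (x_c/x_1)^n
        coefs[n] = a1 * n * (x_c / x[0]) ** n / (x_c * R)

    # geometric tail estimate from the trailing terms (worst case P_n = 1)
    tail_terms = np.abs(coefs[-6:])
    scale = np.abs(coefs[1:]).sum()
    ratios = tail_terms[1:] / np.where(tail_terms[:-1] > 0, tail_terms[:-1], np.inf)
    ratio = float(np.clip(np.median(ratios), 0.0, 0.999999))
    if ratio >= 1.0 or not np.isfinite(ratio):
        raise ValueError("Legendre series is not decaying; increase series_order")
    tail = tail_terms[-1] * ratio / (1.0 - ratio)
    if tail > spec.tail_tolerance * scale:
        raise ValueError(
            f"Legendre series tail {tail / scale:.2e} exceeds the relative tolerance "
            f"{spec.tail_tolerance:.0e} at order {nmax}; increase series_order"
        )
    return coefs


def _unipolar_en(
    spec: SphericalHeadSpec,
    node_dirs: np.ndarray,
    normal_proj: np.ndarray,
    electrode_dir: np.ndarray,
    coefs: np.ndarray,
) -> np.ndarray:
    cosg = np.clip(node_dirs @ electrode_dir, -1.0, 1.0)
    return legval(cosg, coefs) * normal_proj


def spherical_leadfield(spec: SphericalHeadSpec, surface: CorticalSurface) -> LeadField:
    """Lead-field matrix of the spherical head on a cortical sphere surface.

    Column e holds En (V/m) per node for +1 mA at electrode e and -1 mA at
    the reference, by superposition of the two point-source solutions. The
    surface must be a sphere of the spec's cortical radius centred at the
    origin.
    """
    radii = np.linalg.norm(surface.nodes, axis=1)
    if not np.allclose(radii, spec.cortical_radius, rtol=1e-3):
        raise ValueError(
            "surface is not a sphere of the spec's cortical radius centred at the origin"
        )
    node_dirs = surface.nodes / radii[:, None]
    # project onto the (outward) node normals, then flip to inward-positive
    normal_proj = np.einsum("ij,ij->i", surface.node_normals, node_dirs)

    coefs = _en_series_coefficients(spec)
    labels = spec.electrode_labels()
    ref_en = _unipolar_en(
        spec, node_dirs, normal_proj, spec.electrode_positions[spec.reference_label], coefs
    )
    K = np.empty((surface.n_nodes, len(labels)))
    for j, lab in enumerate(labels):
        en = _unipolar_en(spec, node_dirs, normal_proj, spec.electrode_positions[lab], coefs)
        K[:, j] = en - ref_en
    return LeadField(K, labels, reference_label=spec.reference_label)
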