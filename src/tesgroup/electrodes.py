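"""Idealised 10-10 EEG electrode directions on a spherical scalp.

Positions follow the standard arc construction on the unit sphere: Nz, Iz,
LPA and RPA sit on the equator with Cz at the vertex; midline and coronal
chains subdivide their half great circles in 10% steps; the outer ring
(Fpz-T7-Oz-T8) is the circle at 72 deg polar angle in 10% (18 deg) azimuth
steps; intermediate rows (AF, F, FC, CP, P, PO) subdivide the circle through
their lateral ring electrodes and midline electrode.

Frame: x right, y anterior, z superior.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LANDMARK_DIRECTIONS", "DEFAULT_ELECTRODES", "ideal_1010_positions"]

#: Anatomical landmark directions (unit vectors).
LANDMARK_DIRECTIONS: dict[str, np.ndarray] = {
    "Nz": np.array([0.0, 1.0, 0.0]),
    "Iz": np.array([0.0, -1.0, 0.0]),
    "LPA": np.array([-1.0, 0.0, 0.0]),
    "RPA": np.array([1.0, 0.0, 0.0]),
    "Cz": np.array([0.0, 0.0, 1.0]),
}

#: 39-label candidate set used throughout (frontal-weighted, includes Cz).
DEFAULT_ELECTRODES: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "CP3", "CPz", "CP4",
    "Pz",
)

# Midline chain Nz -> Cz -> Iz, fraction of the half great circle from Nz.
_MIDLINE = {"Fpz": 0.1, "AFz": 0.2, "Fz": 0.3, "FCz": 0.4, "Cz": 0.5,
            "CPz": 0.6, "Pz": 0.7, "POz": 0.8, "Oz": 0.9}
# Coronal chain LPA -> Cz -> RPA, fraction from LPA.
_CORONAL = {"T7": 0.1, "C5": 0.2, "C3": 0.3, "C1": 0.4,
            "C2": 0.6, "C4": 0.7, "C6": 0.8, "T8": 0.9}
# Outer ring at 72 deg polar angle; azimuth in degrees from anterior,
# positive toward the left.
_RING_LEFT = {"Fpz": 0, "Fp1": 18, "AF7": 36, "F7": 54, "FT7": 72, "T7": 90,
              "TP7": 108, "P7": 126, "PO7": 144, "O1": 162, "Oz": 180}
_RING_RIGHT = {"Fp2": 18, "AF8": 36, "F8": 54, "FT8": 72, "T8": 90,
               "TP8": 108, "P8": 126, "PO8": 144, "O2": 162}
# Intermediate rows: (left ring label, midline label, members left of midline
# ordered lateral -> medial). Right-side members are mirror images.
_ROWS = {
    "AF": ("AF7", "AFz", ("AF3",), ("AF4",)),
    "F": ("F7", "Fz", ("F5", "F3", "F1"), ("F6", "F4", "F2")),
    "FC": ("FT7", "FCz", ("FC5", "FC3", "FC1"), ("FC6", "FC4", "FC2")),
    "CP": ("TP7", "CPz", ("CP5", "CP3", "CP1"), ("CP6", "CP4", "CP2")),
    "P": ("P7", "Pz", ("P5", "P3", "P1"), ("P6", "P4", "P2")),
    "PO": ("PO7", "POz", ("PO3",), ("PO4",)),
}


def _midline_point(frac: float) -> np.ndarray:
    a = frac * np.pi
    return np.array([0.0, np.cos(a), np.sin(a)])


def _coronal_point(frac: float) -> np.ndarray:
    a = frac * np.pi
    return np.array([-np.cos(a), 0.0, np.sin(a)])


def _ring_point(azimuth_deg: float, side: str) -> np.ndarray:
    theta = np.deg2rad(72.0)
    alpha = np.deg2rad(azimuth_deg)
    x = -np.sin(theta) * np.sin(alpha)
    if side == "right":
        x = -x
    return np.array([x, np.sin(theta) * np.cos(alpha), np.cos(theta)])


def _circumcenter(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    a, b = p1 - p3, p2 - p3
    axb = np.cross(a, b)
    denom = 2.0 * float(axb @ axb)
    if denom < 1e-30:
        raise ValueError("collinear points have no circumcircle")
    return p3 + np.cross((a @ a) * b - (b @ b) * a, axb) / denom


def _arc_point(start: np.ndarray, end: np.ndarray, third: np.ndarray, frac: float) -> np.ndarray:
    """Point at arc fraction ``frac`` from ``start`` to ``end`` on the circle
    through the three given (unit-sphere) points."""
    c = _circumcenter(start, end, third)
    u, v = start - c, end - c
    axis = np.cross(u, v)
    axis = axis / np.linalg.norm(axis)
    angle = float(np.arctan2(np.linalg.norm(np.cross(u, v)), u @ v))
    t = frac * angle
    rot = (u * np.cos(t) + np.cross(axis, u) * np.sin(t)
           + axis * (axis @ u) * (1.0 - np.cos(t)))
    p = c + rot
    return p / np.linalg.norm(p)


def _build_all() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for lab, f in _MIDLINE.items():
        pos[lab] = _midline_point(f)
    for lab, f in _CORONAL.items():
        pos[lab] = _coronal_point(f)
    for lab, az in _RING_LEFT.items():
        pos.setdefault(lab, _ring_point(az, "left"))
    for lab, az in _RING_RIGHT.items():
        pos[lab] = _ring_point(az, "right")
    for left_lab, mid_lab, members_l, members_r in _ROWS.values():
        left, mid = pos[left_lab], pos[mid_lab]
        right = left * np.array([-1.0, 1.0, 1.0])  # mirror image
        n = len(members_l) + 1
        for i, lab in enumerate(members_l, start=1):
            pos[lab] = _arc_point(left, mid, right, i / n)
        for i, lab in enumerate(members_r, start=1):
            pos[lab] = _arc_point(right, mid, left, i / n)
    return pos


_ALL_POSITIONS = _build_all()


def ideal_1010_positions(labels: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
    """Unit scalp directions for the requested 10-10 labels.

    Defaults to :data:`DEFAULT_ELECTRODES`. Unknown labels raise ``KeyError``.
    """
    if labels is None:
        labels = DEFAULT_ELECTRODES
    out = {}
    for lab in labels:
        if lab not in _ALL_POSITIONS:
            raise KeyError(f"unknown 10-10 label {lab!r}")
        out[lab] = _ALL_POSITIONS[lab].copy()
    return out
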