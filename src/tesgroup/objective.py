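"""Targeting objectives: NERNI, group NERNI and the target-average En.

NERNI (normalised error relative to no intervention) measures how closely the
montage-induced normal E-field matches a weighted target field:

    NERNI = (||w.t||^2 - ||w.(K I) - w.t||^2) / ||w.t||^2

with t the per-node target En, w the node weights (applied element-wise
inside the squared norms, hence effectively squared), K the lead-field and I
the electrode currents (mA, reference implicit). It equals 1 for a perfect
fit, 0 for no stimulation, and is unbounded below for poor fits. The group
objective is the arithmetic mean of per-subject NERNI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Montage, SubjectModel

__all__ = ["FitResult", "nerni", "nerni_group", "mean_en", "evaluate_fit"]


def _weighted_parts(subject: SubjectModel):
    w = subject.target.weights
    wt = w * subject.target.en_trg
    denom = float(wt @ wt)
    if denom == 0.0:
        raise ValueError(
            f"subject {subject.subject_id!r}: weighted target is identically zero "
            "(NERNI denominator undefined)"
        )
    return w, wt, denom


def induced_en(montage: Montage, subject: SubjectModel) -> np.ndarray:
    """Per-node En (V/m) induced by the montage: K @ I."""
    I = montage.current_vector(subject.leadfield)
    return subject.leadfield.matrix @ I


def nerni_from_en(en: np.ndarray, subject: SubjectModel) -> float:
    w, wt, denom = _weighted_parts(subject)
    resid = w * en - wt
    return float((denom - resid @ resid) / denom)


def nerni(montage: Montage, subject: SubjectModel) -> float:
    """NERNI of a montage on one subject (1 = perfect fit, 0 = no intervention)."""
    return nerni_from_en(induced_en(montage, subject), subject)


def nerni_group(montage: Montage, subjects: Sequence[SubjectModel]) -> float:
    """Arithmetic mean of per-subject NERNI over the group."""
    if len(subjects) == 0:
        raise ValueError("empty subject group")
    vals = []
    for s in subjects:
        try:
            vals.append(nerni(montage, s))
        except Exception as exc:
            raise type(exc)(f"subject {s.subject_id!r}: {exc}") from exc
    return float(np.mean(vals))


def mean_en(montage: Montage, subject: SubjectModel) -> float:
    """Area-weighted average induced En (V/m) over the target region.

    The target region is the set of nodes with nonzero target En; node areas
    are one third of the adjacent triangle areas.
    """
    mask = subject.target.target_mask
    if not mask.any():
        raise ValueError(f"subject {subject.subject_id!r} has an empty target region")
    en = induced_en(montage, subject)[mask]
    areas = subject.surface.node_areas[mask]
    return float((en @ areas) / areas.sum())


@dataclass
class FitResult:
    """Evaluation of one montage on one subject."""

    nerni: float
    mean_en_target: float
    induced_en: np.ndarray

    def to_dict(self) -> dict:
        return {"nerni": self.nerni, "mean_en_target_V_per_m": self.mean_en_target}


def evaluate_fit(montage: Montage, subject: SubjectModel) -> FitResult:
    en = induced_en(montage, subject)
    mask = subject.target.target_mask
    areas = subject.surface.node_areas[mask]
    m_en = float((en[mask] @ areas) / areas.sum()) if mask.any() else float("nan")
    return FitResult(nerni=nerni_from_en(en, subject), mean_en_target=m_en, induced_en=en)
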