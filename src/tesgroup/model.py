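"""Core domain containers: lead-fields, target maps, montages, subjects."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .geometry import CorticalSurface, TetMesh

__all__ = [
    "LeadField",
    "TargetMap",
    "Montage",
    "AnatomicalFeatures",
    "SubjectModel",
]


@dataclass
class LeadField:
    """Lead-field matrix K mapping electrode currents (mA) to the normal
    E-field component En (V/m) at every cortical node.

    Each column is the En field of a bipolar montage injecting +1 mA at one
    electrode with the fixed reference (cathode, -1 mA, Cz by default); the
    reference therefore has no column of its own and its current is implicit.
    """

    matrix: np.ndarray  # (n_nodes, n_electrodes - 1)
    electrode_labels: tuple[str, ...]
    reference_label: str = "Cz"

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=float)
        self.electrode_labels = tuple(self.electrode_labels)
        if self.matrix.ndim != 2:
            raise ValueError("lead-field matrix must be 2-D")
        if self.matrix.shape[1] != len(self.electrode_labels):
            raise ValueError(
                f"{self.matrix.shape[1]} columns but {len(self.electrode_labels)} labels"
            )
        if self.reference_label in self.electrode_labels:
            raise ValueError("reference electrode must not appear among the columns")
        if len(set(self.electrode_labels)) != len(self.electrode_labels):
            raise ValueError("duplicate electrode labels")
        if not np.isfinite(self.matrix).all():
            raise ValueError("lead-field matrix contains non-finite entries")
        self._index = {lab: i for i, lab in enumerate(self.electrode_labels)}

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_electrodes(self) -> int:
        """Number of electrode positions including the reference."""
        return self.matrix.shape[1] + 1

    def column_index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"electrode {label!r} not in lead-field") from None


@dataclass
class TargetMap:
    """Per-node target En (V/m) and optimization weights.

    Nodes with nonzero target En form the target region; weights must be
    nonnegative with at least one positive entry.
    """

    en_trg: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.en_trg = np.ascontiguousarray(self.en_trg, dtype=float)
        self.weights = np.ascontiguousarray(self.weights, dtype=float)
        if self.en_trg.shape != self.weights.shape or self.en_trg.ndim != 1:
            raise ValueError("en_trg and weights must be equal-length 1-D arrays")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if not (self.weights > 0).any():
            raise ValueError("at least one node must have positive weight")

    @property
    def target_mask(self) -> np.ndarray:
        return self.en_trg != 0.0


@dataclass
class Montage:
    """Electrode currents in mA, reference excluded.

    The reference current is implicit: minus the sum of the listed currents,
    so every montage is balanced by construction.
    """

    currents: dict[str, float]
    reference_label: str = "Cz"

    def __post_init__(self) -> None:
        self.currents = {str(k): float(v) for k, v in self.currents.items()}
        if any(not np.isfinite(v) for v in self.currents.values()):
            raise ValueError("montage currents must be finite")
        if self.reference_label in self.currents:
            raise ValueError("reference current is implicit; do not list it")

    @property
    def reference_current(self) -> float:
        return -sum(self.currents.values())

    def current_vector(self, leadfield: LeadField) -> np.ndarray:
        """Currents ordered by the lead-field columns (absent electrodes -> 0)."""
        if self.reference_label != leadfield.reference_label:
            raise ValueError(
                f"montage reference {self.reference_label!r} != "
                f"lead-field reference {leadfield.reference_label!r}"
            )
        vec = np.zeros(len(leadfield.electrode_labels))
        for lab, cur in self.currents.items():
            vec[leadfield.column_index(lab)] = cur
        return vec

    def active_electrodes(self, tol: float = 1e-6) -> tuple[str, ...]:
        return tuple(sorted(lab for lab, c in self.currents.items() if abs(c) > tol))

    # -- serialisation -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {"reference": self.reference_label, "currents_mA": self.currents}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        return cls(payload["currents_mA"], reference_label=payload.get("reference", "Cz"))

    def to_csv(self, path: str | Path) -> None:
        lines = ["electrode,current_mA"]
        lines += [f"{lab},{cur:.9g}" for lab, cur in sorted(self.currents.items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, reference_label: str = "Cz") -> "Montage":
        lines = Path(path).read_text().strip().splitlines()
        if lines and lines[0].lower().startswith("electrode"):
            lines = lines[1:]
        currents = {}
        for line in lines:
            lab, cur = line.split(",")
            currents[lab.strip()] = float(cur)
        return cls(currents, reference_label=reference_label)


@dataclass
class AnatomicalFeatures:
    """Scalp geodesic distances (mm) and tissue volumes (mm^3).

    Normalised variants divide each distance by the sum of the three
    distances and each volume by the total tissue volume.
    """

    axial_perimeter: float
    sagittal_perimeter: float
    coronal_distance: float
    volumes: dict[str, float]

    def __post_init__(self) -> None:
        for name in ("axial_perimeter", "sagittal_perimeter", "coronal_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("tissue volumes must be positive")

    @property
    def distances(self) -> dict[str, float]:
        return {
            "axial_perimeter": self.axial_perimeter,
            "sagittal_perimeter": self.sagittal_perimeter,
            "coronal_distance": self.coronal_distance,
        }

    @property
    def normalized_distances(self) -> dict[str, float]:
        total = sum(self.distances.values())
        return {f"{k}_norm": v / total for k, v in self.distances.items()}

    @property
    def normalized_volumes(self) -> dict[str, float]:
        total = sum(self.volumes.values())
        return {f"{k}_vol_norm": v / total for k, v in self.volumes.items()}

    def as_dict(self) -> dict[str, float]:
        out = dict(self.distances)
        out.update({f"{k}_vol": v for k, v in self.volumes.items()})
        out.update(self.normalized_distances)
        out.update(self.normalized_volumes)
        return out


@dataclass
class SubjectModel:
    """One head model: cortical surface, lead-field, target map and features."""

    subject_id: str
    surface: CorticalSurface
    leadfield: LeadField
    target: TargetMap
    features: AnatomicalFeatures | None = None
    scalp_surface: CorticalSurface | None = field(default=None, repr=False)
    tet_mesh: TetMesh | None = field(default=None, repr=False)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.surface.n_nodes
        if self.leadfield.n_nodes != n:
            raise ValueError(
                f"lead-field rows ({self.leadfield.n_nodes}) != surface nodes ({n})"
            )
        if len(self.target.en_trg) != n:
            raise ValueError("target map length != surface node count")
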