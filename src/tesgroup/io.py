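"""File formats: Gmsh MSH v2.2 ASCII meshes and the HDF5 subject container."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import TISSUES, CorticalSurface, TetMesh
from .model import AnatomicalFeatures, LeadField, Montage, SubjectModel, TargetMap

__all__ = ["write_msh", "read_msh", "save_subject", "load_subject"]

_TRIANGLE, _TET = 2, 4


def write_msh(
    path: str | Path,
    surface: CorticalSurface | None = None,
    tetmesh: TetMesh | None = None,
) -> None:
    """Write a surface and/or tetrahedral mesh as Gmsh MSH v2.2 ASCII.

    Tissue labels become volume physical groups; surface triangles go into a
    single physical group named "surface". Node ids are 1-based per dialect.
    """
    if surface is None and tetmesh is None:
        raise ValueError("nothing to write")
    nodes_blocks = []
    offset = 0
    surf_offset = tet_offset = 0
    if surface is not None:
        nodes_blocks.append(surface.nodes)
        surf_offset = offset
        offset += len(surface.nodes)
    if tetmesh is not None:
        nodes_blocks.append(tetmesh.nodes)
        tet_offset = offset
        offset += len(tetmesh.nodes)
    nodes = np.vstack(nodes_blocks)

    physical = []  # (dim, tag, name)
    elements = []  # (etype, physical_tag, node_ids 1-based)
    if surface is not None:
        physical.append((2, 1, "surface"))
        for tri in surface.triangles:
            elements.append((_TRIANGLE, 1, (tri + surf_offset + 1).tolist()))
    if tetmesh is not None:
        present = [t for t in TISSUES if (tetmesh.tissue_labels == t).any()]
        tag_of = {t: 10 + i for i, t in enumerate(present)}
        physical.extend((3, tag_of[t], t) for t in present)
        for tet, lab in zip(tetmesh.tetrahedra, tetmesh.tissue_labels):
            elements.append((_TET, tag_of[lab], (tet + tet_offset + 1).tolist()))

    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(physical))]
    lines += [f'{dim} {tag} "{name}"' for dim, tag, name in physical]
    lines += ["$EndPhysicalNames", "$Nodes", str(len(nodes))]
    lines += [
        f"{i + 1} {x:.17g} {y:.17g} {z:.17g}" for i, (x, y, z) in enumerate(nodes)
    ]
    lines += ["$EndNodes", "$Elements", str(len(elements))]
    for i, (etype, ptag, ids) in enumerate(elements):
        lines.append(f"{i + 1} {etype} 2 {ptag} {ptag} " + " ".join(map(str, ids)))
    lines += ["$EndElements", ""]
    Path(path).write_text("\n".join(lines))


def read_msh(path: str | Path) -> tuple[CorticalSurface | None, TetMesh | None]:
    """Read Gmsh MSH v2.2 ASCII: triangles (type 2) and tetrahedra (type 4).

    Tetrahedron tissue labels come from the volume physical-group names.
    """
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def expect(tag: str) -> None:
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"malformed MSH file: missing {tag}")

    expect("$MeshFormat")
    version = next(it).split()[0]
    if not version.startswith("2."):
        raise ValueError(f"unsupported MSH version {version}; expected 2.2 ASCII")
    expect("$EndMeshFormat")

    names: dict[int, str] = {}
    body = list(it)
    idx = 0
    if "$PhysicalNames" in body:
        idx = body.index("$PhysicalNames")
        count = int(body[idx + 1])
        for k in range(count):
            dim, tag, name = body[idx + 2 + k].split(maxsplit=2)
            names[int(tag)] = name.strip().strip('"')

    n_at = body.index("$Nodes")
    n_nodes = int(body[n_at + 1])
    node_id = np.empty(n_nodes, dtype=np.int64)
    coords = np.empty((n_nodes, 3))
    for k in range(n_nodes):
        parts = body[n_at + 2 + k].split()
        node_id[k] = int(parts[0])
        coords[k] = [float(v) for v in parts[1:4]]
    remap = {nid: k for k, nid in enumerate(node_id)}

    e_at = body.index("$Elements")
    n_elem = int(body[e_at + 1])
    tris, tets, tet_tags = [], [], []
    for k in range(n_elem):
        parts = [int(v) for v in body[e_at + 2 + k].split()]
        etype, ntags = parts[1], parts[2]
        tags = parts[3 : 3 + ntags]
        conn = [remap[v] for v in parts[3 + ntags :]]
        if etype == _TRIANGLE:
            tris.append(conn)
        elif etype == _TET:
            tets.append(conn)
            tet_tags.append(tags[0] if tags else -1)

    surface = None
    if tris:
        used = sorted({i for t in tris for i in t})
        sub = {i: k for k, i in enumerate(used)}
        surface = CorticalSurface(
            coords[used], np.array([[sub[i] for i in t] for t in tris])
        )
    tetmesh = None
    if tets:
        used = sorted({i for t in tets for i in t})
        sub = {i: k for k, i in enumerate(used)}
        labels = []
        for tag in tet_tags:
            lab = names.get(tag)
            if lab not in TISSUES:
                raise ValueError(f"unknown tissue physical group {lab!r} (tag {tag})")
            labels.append(lab)
        tetmesh = TetMesh(
            coords[used],
            np.array([[sub[i] for i in t] for t in tets]),
            np.asarray(labels, dtype=object),
        )
    return surface, tetmesh


# --------------------------------------------------------------------------
# HDF5 subject container
# --------------------------------------------------------------------------

def save_subject(path: str | Path, subject: SubjectModel) -> None:
    """Write a subject to the shared HDF5 layout (mesh, lead-field, target,
    features, metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mesh/nodes", data=subject.surface.nodes)
        f.create_dataset("mesh/triangles", data=subject.surface.triangles)
        f.create_dataset("leadfield/K", data=subject.leadfield.matrix)
        f.create_dataset(
            "leadfield/electrode_labels",
            data=np.array(subject.leadfield.electrode_labels, dtype="S"),
        )
        f["leadfield"].attrs["reference_label"] = subject.leadfield.reference_label
        f.create_dataset("target/en_trg", data=subject.target.en_trg)
        f.create_dataset("target/weights", data=subject.target.weights)
        f.create_group("meta").attrs["subject_id"] = subject.subject_id
        f["meta"].attrs["metadata_json"] = json.dumps(subject.metadata)
        if subject.features is not None:
            g = f.create_group("features")
            for k, v in subject.features.distances.items():
                g.attrs[k] = v
            for k, v in subject.features.volumes.items():
                g.attrs[f"{k}_volume"] = v


def load_subject(path: str | Path) -> SubjectModel:
    with h5py.File(path, "r") as f:
        surface = CorticalSurface(f["mesh/nodes"][()], f["mesh/triangles"][()])
        leadfield = LeadField(
            f["leadfield/K"][()],
            tuple(s.decode() for s in f["leadfield/electrode_labels"][()]),
            reference_label=f["leadfield"].attrs["reference_label"],
        )
        target = TargetMap(f["target/en_trg"][()], f["target/weights"][()])
        subject_id = f["meta"].attrs["subject_id"]
        metadata = json.loads(f["meta"].attrs.get("metadata_json", "{}"))
        features = None
        if "features" in f:
            a = dict(f["features"].attrs)
            features = AnatomicalFeatures(
                axial_perimeter=float(a["axial_perimeter"]),
                sagittal_perimeter=float(a["sagittal_perimeter"]),
                coronal_distance=float(a["coronal_distance"]),
                volumes={
                    k[: -len("_volume")]: float(v)
                    for k, v in a.items()
                    if k.endswith("_volume")
                },
            )
    return SubjectModel(
        subject_id=str(subject_id),
        surface=surface,
        leadfield=leadfield,
        target=target,
        features=features,
        metadata=metadata,
    )
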