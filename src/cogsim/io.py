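"""Readers, writers and configuration for the simulation pipeline.

Formats (all plain text unless noted):

* VTK legacy unstructured grid (ASCII) for quadratic-tet meshes and
  displacement fields (cell type 24, VTK_QUADRATIC_TETRA);
* a solver-input subset in the Abaqus INP dialect (*NODE, *ELEMENT
  TYPE=C3D10, *NSET) for mesh interchange with commercial solvers —
  materials and steps are deliberately not parsed;
* STL (ASCII and binary) for thread surfaces;
* CSV for stress-strain and force-displacement curves;
* JSON/YAML for configs and scenario reports.

The unit system is fixed (mm-N-MPa) and stamped into output headers.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .mesh import TetMesh
from .threads import SurfaceMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_vtk_mesh",
    "write_vtk_mesh",
    "read_inp_mesh",
    "write_inp_mesh",
    "read_stl",
    "write_stl",
    "write_report",
    "load_config",
    "material_from_config",
    "UNIT_STAMP",
]

UNIT_STAMP = "units: mm-N-MPa"

_VTK_QUADRATIC_TETRA = 24


class MeshFormatError(ValueError):
    """Malformed mesh file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# VTK legacy


def write_vtk_mesh(
    mesh: TetMesh, path, point_data: dict[str, np.ndarray] | None = None
) -> None:
    """Write a quadratic-tet mesh (and optional nodal vectors) as legacy VTK."""
    p = Path(path)
    with p.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"cogsim mesh ({UNIT_STAMP})\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {11 * m}\n")
        for row in mesh.elements:
            fh.write("10 " + " ".join(str(int(i)) for i in row) + "\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join([str(_VTK_QUADRATIC_TETRA)] * m) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.shape != (mesh.n_nodes, 3):
                    raise ValueError(f"point data {name!r} must be (n_nodes, 3)")
                fh.write(f"VECTORS {name} double\n")
                for x, y, z in arr:
                    fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
    # node sets are not part of legacy VTK; store them as a sidecar
    if mesh.node_sets or mesh.facet_sets:
        sidecar = {
            "node_sets": {k: v.tolist() for k, v in mesh.node_sets.items()},
            "facet_sets": {k: np.asarray(v).tolist() for k, v in mesh.facet_sets.items()},
        }
        p.with_suffix(p.suffix + ".sets.json").write_text(json.dumps(sidecar))


def read_vtk_mesh(path) -> TetMesh:
    """Read a legacy-VTK quadratic-tet mesh written by :func:`write_vtk_mesh`."""
    p = Path(path)
    lines = p.read_text().splitlines()
    i = 0
    nodes = None
    elements = None
    try:
        while i < len(lines):
            tok = lines[i].split()
            if tok[:1] == ["POINTS"]:
                n = int(tok[1])
                vals = []
                i += 1
                while len(vals) < 3 * n:
                    vals.extend(float(v) for v in lines[i].split())
                    i += 1
                nodes = np.array(vals).reshape(n, 3)
                continue
            if tok[:1] == ["CELLS"]:
                m = int(tok[1])
                elements = np.empty((m, 10), dtype=np.int64)
                for k in range(m):
                    row = lines[i + 1 + k].split()
                    if row[0] != "10":
                        raise MeshFormatError(
                            f"unsupported cell with {row[0]} nodes (need 10)", i + 2 + k
                        )
                    elements[k] = [int(v) for v in row[1:]]
                i += m + 1
                continue
            if tok[:1] == ["CELL_TYPES"]:
                m = int(tok[1])
                for k in range(m):
                    if lines[i + 1 + k].strip() != str(_VTK_QUADRATIC_TETRA):
                        raise MeshFormatError(
                            f"unsupported cell type {lines[i + 1 + k].strip()!r} "
                            f"(only {_VTK_QUADRATIC_TETRA}, quadratic tetra)",
                            i + 2 + k,
                        )
                i += m + 1
                continue
            i += 1
    except (IndexError, ValueError) as err:
        if isinstance(err, MeshFormatError):
            raise
        raise MeshFormatError(f"malformed VTK file: {err}", i + 1) from err
    if nodes is None or elements is None:
        raise MeshFormatError("file lacks POINTS or CELLS sections")
    mesh = TetMesh(nodes, elements)
    sidecar = p.with_suffix(p.suffix + ".sets.json")
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        for k, v in data.get("node_sets", {}).items():
            mesh.node_sets[k] = np.asarray(v, dtype=np.int64)
        for k, v in data.get("facet_sets", {}).items():
            mesh.facet_sets[k] = np.asarray(v, dtype=np.int64).reshape(-1, 2)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Abaqus INP subset (mesh-only interchange)


def write_inp_mesh(mesh: TetMesh, path) -> None:
    """Write nodes, C3D10 connectivity and node sets (1-based ids)."""
    with Path(path).open("w") as fh:
        fh.write(f"** cogsim mesh interchange ({UNIT_STAMP})\n*NODE\n")
        for k, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{k}, {x:.17g}, {y:.17g}, {z:.17g}\n")
        fh.write("*ELEMENT, TYPE=C3D10\n")
        for k, row in enumerate(mesh.elements, start=1):
            fh.write(f"{k}, " + ", ".join(str(int(i) + 1) for i in row) + "\n")
        for name, idx in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name}\n")
            ids = [str(int(i) + 1) for i in idx]
            for s in range(0, len(ids), 12):
                fh.write(", ".join(ids[s : s + 12]) + "\n")


def read_inp_mesh(path) -> TetMesh:
    """Read the *NODE / *ELEMENT (C3D10) / *NSET subset of an INP file."""
    node_ids: list[int] = []
    coords: list[tuple[float, float, float]] = []
    elems: list[list[int]] = []
    nsets: dict[str, list[int]] = {}
    mode = None
    current_set = None
    pending: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            key = line.split(",")[0].strip().upper()
            opts = {
                kv.split("=")[0].strip().upper(): kv.split("=", 1)[1].strip()
                for kv in line.split(",")[1:]
                if "=" in kv
            }
            if key == "*NODE":
                mode = "node"
            elif key == "*ELEMENT":
                etype = opts.get("TYPE", "").upper()
                if etype != "C3D10":
                    raise MeshFormatError(
                        f"unsupported element type {etype or '<missing>'} (only C3D10)",
                        lineno,
                    )
                mode = "element"
                pending = []
            elif key == "*NSET":
                mode = "nset"
                current_set = opts.get("NSET")
                if not current_set:
                    raise MeshFormatError("*NSET without NSET= name", lineno)
                nsets.setdefault(current_set, [])
            else:
                mode = None  # ignore everything else (mesh-only interchange)
            continue
        try:
            if mode == "node":
                parts = line.split(",")
                node_ids.append(int(parts[0]))
                coords.append(tuple(float(v) for v in parts[1:4]))
            elif mode == "element":
                pending.extend(v for v in line.rstrip(",").split(",") if v.strip())
                if len(pending) >= 11:
                    elems.append([int(v) for v in pending[1:11]])
                    pending = []
            elif mode == "nset":
                nsets[current_set].extend(
                    int(v) for v in line.rstrip(",").split(",") if v.strip()
                )
        except ValueError as err:
            raise MeshFormatError(f"cannot parse: {err}", lineno) from err
    if not node_ids or not elems:
        raise MeshFormatError("file lacks *NODE or *ELEMENT data")
    id_map = {nid: k for k, nid in enumerate(node_ids)}
    try:
        elements = np.array([[id_map[i] for i in row] for row in elems], dtype=np.int64)
        node_sets = {
            name: np.array([id_map[i] for i in ids], dtype=np.int64)
            for name, ids in nsets.items()
        }
    except KeyError as err:
        raise MeshFormatError(f"reference to undefined node id {err}") from err
    mesh = TetMesh(np.array(coords), elements, node_sets=node_sets)
    mesh.validate()
    return mesh


def write_mesh(mesh: TetMesh, path, format: str | None = None) -> None:
    fmt = format or ("inp" if str(path).endswith(".inp") else "vtk")
    if fmt == "vtk":
        write_vtk_mesh(mesh, path)
    elif fmt == "inp":
        write_inp_mesh(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def read_mesh(path, format: str | None = None) -> TetMesh:
    fmt = format or ("inp" if str(path).endswith(".inp") else "vtk")
    if fmt == "vtk":
        return read_vtk_mesh(path)
    if fmt == "inp":
        return read_inp_mesh(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# STL


def write_stl(surface: SurfaceMesh, path, binary: bool = False, name: str = "cogsim") -> None:
    tris = surface.vertices[surface.triangles]
    normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.maximum(norm, 1e-30)
    if binary:
        with Path(path).open("wb") as fh:
            fh.write(name.encode().ljust(80, b" "))
            fh.write(struct.pack("<I", len(tris)))
            for nrm, tri in zip(normals, tris):
                fh.write(struct.pack("<3f", *nrm))
                for v in tri:
                    fh.write(struct.pack("<3f", *v))
                fh.write(b"\x00\x00")
    else:
        with Path(path).open("w") as fh:
            fh.write(f"solid {name}\n")
            for nrm, tri in zip(normals, tris):
                fh.write(f"facet normal {nrm[0]:.9g} {nrm[1]:.9g} {nrm[2]:.9g}\n")
                fh.write(" outer loop\n")
                for v in tri:
                    fh.write(f"  vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                fh.write(" endloop\nendfacet\n")
            fh.write(f"endsolid {name}\n")


def read_stl(path) -> SurfaceMesh:
    """Read an ASCII or binary STL into a SurfaceMesh (vertices deduplicated)."""
    p = Path(path)
    raw = p.read_bytes()
    is_ascii = raw[:5] == b"solid" and b"facet" in raw[:2048]
    tris = []
    if is_ascii:
        verts = []
        for line in raw.decode(errors="replace").splitlines():
            line = line.strip()
            if line.startswith("vertex"):
                verts.append([float(v) for v in line.split()[1:4]])
        tris = np.array(verts).reshape(-1, 3, 3)
    else:
        (ntri,) = struct.unpack_from("<I", raw, 80)
        tris = np.empty((ntri, 3, 3), dtype=float)
        off = 84
        for k in range(ntri):
            vals = struct.unpack_from("<12f", raw, off)
            tris[k] = np.array(vals[3:]).reshape(3, 3)
            off += 50
    flat = tris.reshape(-1, 3)
    uniq, inv = np.unique(np.round(flat, 9), axis=0, return_inverse=True)
    return SurfaceMesh(vertices=uniq, triangles=inv.reshape(-1, 3).astype(np.int64))


# ---------------------------------------------------------------------------
# reports and configuration


def _versions() -> dict:
    from importlib.metadata import version

    import numpy
    import pandas
    import scipy
    import yaml

    from . import __version__

    return {
        "cogsim": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "click": version("click"),
        "pyyaml": getattr(yaml, "__version__", "?"),
    }


def write_report(report, out_dir, fields: dict | None = None) -> dict[str, str]:
    """Write a ScenarioReport: JSON + CSV curves + optional VTK + summary.

    ``fields`` maps names to (mesh, displacement array) pairs for VTK
    export.  Returns the mapping of artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    doc = report.to_dict()
    doc["units"] = UNIT_STAMP
    doc["versions"] = _versions()
    jpath = out / "report.json"
    jpath.write_text(json.dumps(doc, indent=2))
    artifacts["report"] = str(jpath)
    for name, curve in getattr(report, "curves", {}).items():
        if hasattr(curve, "to_csv"):
            cpath = out / f"{name}.csv"
            curve.to_csv(cpath)
            artifacts[name] = str(cpath)
    if fields:
        for name, (mesh, disp) in fields.items():
            vpath = out / f"{name}.vtk"
            write_vtk_mesh(mesh, vpath, point_data={"displacement": disp})
            artifacts[name] = str(vpath)
    lines = [f"cogsim scenario report: {doc['scenario']}", UNIT_STAMP, ""]
    for k, v in doc["metrics"].items():
        lines.append(f"  {k}: {v}")
    if doc.get("comparisons"):
        lines.append("")
        lines.append("comparisons:")
        for k, v in doc["comparisons"].items():
            lines.append(f"  {k}: {v}")
    spath = out / "summary.txt"
    spath.write_text("\n".join(lines) + "\n")
    artifacts["summary"] = str(spath)
    return artifacts


_KNOWN_KEYS = {
    "scenario",
    "material",
    "thread",
    "geometry",
    "solver",
    "output",
    "seed",
    "pressure_cmH2O",
    "pressure_MPa",
    "damage",
    "n_threads",
    "sphere_radius_mm",
    "max_travel_mm",
    "angles_deg",
    "max_strain",
    "n_points",
}

_KNOWN_MATERIAL_KEYS = {"type", "convention", "terms", "damage", "youngs_modulus", "poissons_ratio", "units"}


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run configuration.

    Unknown top-level keys are rejected so that typos fail before any
    computation starts.
    """
    import yaml

    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "material" in cfg:
        bad = set(cfg["material"]) - _KNOWN_MATERIAL_KEYS
        if bad:
            raise ValueError(f"unknown material keys: {sorted(bad)}")
    return cfg


def material_from_config(block: dict):
    """Build constitutive parameters from a config material block.

    ``{"type": "ogden", "convention": "solver", "terms": [[mu, alpha], ...],
    "damage": 0.5}`` or ``{"type": "linear", "youngs_modulus": E,
    "poissons_ratio": nu}``.  The mu/E units are MPa (assumption flag
    ``units: MPa`` accepted and checked).
    """
    from .constitutive import LinearElasticParameters, OgdenParameters

    units = block.get("units", "MPa")
    if units != "MPa":
        raise ValueError(f"material units must be MPa, got {units!r}")
    kind = block.get("type")
    if kind == "linear":
        return LinearElasticParameters(
            youngs_modulus=float(block["youngs_modulus"]),
            poissons_ratio=float(block.get("poissons_ratio", 0.3)),
        )
    if kind == "ogden":
        return OgdenParameters(
            terms=tuple((float(m), float(a)) for m, a in block["terms"]),
            convention=block.get("convention", "solver"),
            damage_factor=float(block.get("damage", 0.0)),
        )
    raise ValueError(f"unknown material type {kind!r}")
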