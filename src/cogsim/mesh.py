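"""Quadratic-tetrahedron meshes and structured mesh generation.

The volume discretization used throughout is the 10-node quadratic
tetrahedron (C3D10-style: 4 corner nodes followed by the 6 mid-edge
nodes of edges (0,1), (1,2), (0,2), (0,3), (1,3), (2,3)).

Because no general-purpose tetrahedral mesh generator is available,
volume meshes are built structurally: a 2-D cross-section
triangulation is extruded station by station along the axial (y)
coordinate into prisms, and each prism is split into three tetrahedra
with the minimum-vertex-index rule, which guarantees a conforming
split across neighbouring prisms.  This covers every geometry the
package needs (filaments and cut threads with star-shaped sections,
thick-walled canal tubes, rectangular bars).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TetMesh",
    "TET10_EDGES",
    "TET_FACES",
    "tet10_shape",
    "tet10_shape_grad",
    "disc_section",
    "annulus_section",
    "rect_section",
    "extrude_to_tets",
    "linear_to_quadratic",
    "structured_box",
]

#: local corner pairs of the 6 mid-edge nodes, in connectivity order
TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))

#: outward-oriented corner triples of the 4 faces of a positive tet
TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))

_EDGE_LOOKUP = {tuple(sorted(e)): 4 + i for i, e in enumerate(TET10_EDGES)}


def tet10_face_nodes(face: int) -> tuple[int, ...]:
    """Local connectivity (6 nodes) of a quadratic tet face: 3 corners + 3 mids."""
    a, b, c = TET_FACES[face]
    return (
        a,
        b,
        c,
        _EDGE_LOOKUP[tuple(sorted((a, b)))],
        _EDGE_LOOKUP[tuple(sorted((b, c)))],
        _EDGE_LOOKUP[tuple(sorted((c, a)))],
    )


def tet10_shape(bary: np.ndarray) -> np.ndarray:
    """Shape functions of the 10-node tet at barycentric coords (..., 4)."""
    z = np.asarray(bary, dtype=float)
    N = np.empty(z.shape[:-1] + (10,))
    for i in range(4):
        N[..., i] = z[..., i] * (2.0 * z[..., i] - 1.0)
    for k, (a, b) in enumerate(TET10_EDGES):
        N[..., 4 + k] = 4.0 * z[..., a] * z[..., b]
    return N


def tet10_shape_grad(bary: np.ndarray) -> np.ndarray:
    """Gradients dN/d(zeta_1..3) at barycentric coords; shape (..., 10, 3).

    Uses (z1, z2, z3) as independent coordinates with z0 = 1 - z1 - z2 - z3.
    """
    z = np.asarray(bary, dtype=float)
    dz = np.zeros((4, 3))
    dz[0] = -1.0
    dz[1, 0] = dz[2, 1] = dz[3, 2] = 1.0
    G = np.zeros(z.shape[:-1] + (10, 3))
    for i in range(4):
        G[..., i, :] = (4.0 * z[..., i, None] - 1.0) * dz[i]
    for k, (a, b) in enumerate(TET10_EDGES):
        G[..., 4 + k, :] = 4.0 * (z[..., a, None] * dz[b] + z[..., b, None] * dz[a])
    return G


@dataclass
class TetMesh:
    """10-node tetrahedron mesh with named node and boundary-facet sets.

    nodes : (n, 3) float array, mm
    elements : (m, 10) int array
    node_sets : name -> int array of node indices
    facet_sets : name -> (k, 2) int array of (element, local_face) pairs
    """

    nodes: np.ndarray
    elements: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    facet_sets: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 10:
            raise ValueError("elements must be (m, 10) quadratic tetrahedra")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def corner_volumes(self) -> np.ndarray:
        """Signed volume of each element's corner (straight-edge) tet."""
        v = self.nodes[self.elements[:, :4]]
        d = v[:, 1:] - v[:, :1]
        return np.linalg.det(d) / 6.0

    def volume(self) -> float:
        return float(np.sum(self.corner_volumes()))

    def validate(self) -> None:
        """Check Jacobian positivity and set index validity; raise on failure."""
        vols = self.corner_volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValueError(f"element {bad} has non-positive Jacobian ({vols[bad]:.3e})")
        for name, idx in self.node_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise ValueError(f"node set {name!r} references invalid node indices")
        for name, fs in self.facet_sets.items():
            fs = np.asarray(fs)
            if fs.size and (fs[:, 0].max() >= self.n_elements or fs[:, 1].max() > 3):
                raise ValueError(f"facet set {name!r} references invalid facets")

    # -- boundary -----------------------------------------------------------

    def boundary_facets(self) -> np.ndarray:
        """All boundary facets as (k, 2) array of (element, local_face)."""
        m = self.n_elements
        tris = np.empty((4 * m, 3), dtype=np.int64)
        owner = np.empty(4 * m, dtype=np.int64)
        face = np.empty(4 * m, dtype=np.int64)
        for f, (a, b, c) in enumerate(TET_FACES):
            tris[f * m : (f + 1) * m] = self.elements[:, [a, b, c]]
            owner[f * m : (f + 1) * m] = np.arange(m)
            face[f * m : (f + 1) * m] = f
        key = np.sort(tris, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        sel = counts[inv] == 1
        return np.column_stack([owner[sel], face[sel]])

    def facet_corner_triples(self, facets: np.ndarray) -> np.ndarray:
        out = np.empty((len(facets), 3), dtype=np.int64)
        for f in range(4):
            sel = facets[:, 1] == f
            out[sel] = self.elements[facets[sel, 0]][:, list(TET_FACES[f])]
        return out

    def facet_nodes6(self, facets: np.ndarray) -> np.ndarray:
        """Global 6-node connectivity of quadratic boundary facets."""
        out = np.empty((len(facets), 6), dtype=np.int64)
        for f in range(4):
            sel = facets[:, 1] == f
            out[sel] = self.elements[facets[sel, 0]][:, list(tet10_face_nodes(f))]
        return out

    def boundary_node_indices(self) -> np.ndarray:
        return np.unique(self.facet_nodes6(self.boundary_facets()))

    # -- set helpers --------------------------------------------------------

    def add_node_set(self, name: str, mask_or_indices) -> None:
        arr = np.asarray(mask_or_indices)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        self.node_sets[name] = arr.astype(np.int64)

    def add_facet_set_where(self, name: str, predicate) -> None:
        """Facet set from a predicate on facet centroid coordinates (k,3)->bool."""
        facets = self.boundary_facets()
        tri = self.facet_corner_triples(facets)
        centroids = self.nodes[tri].mean(axis=1)
        sel = predicate(centroids)
        self.facet_sets[name] = facets[sel]

    def nodes_of_facet_set(self, name: str) -> np.ndarray:
        return np.unique(self.facet_nodes6(self.facet_sets[name]))

    # -- point location -----------------------------------------------------

    def locate_points(self, points: np.ndarray, tol: float = 1e-8):
        """Find the containing element and shape values for each point.

        Returns (elems (p,), shape (p, 10)); raises ValueError naming the
        first point that lies outside the mesh.  Assumes straight-edged
        elements (mid nodes at edge midpoints), so the affine corner map
        is exact.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        v = self.nodes[self.elements[:, :4]]
        T = np.swapaxes(v[:, 1:] - v[:, :1], 1, 2)  # (m,3,3) columns = edges
        Tinv = np.linalg.inv(T)
        elems = np.empty(len(pts), dtype=np.int64)
        shape = np.empty((len(pts), 10))
        for i, p in enumerate(pts):
            loc = np.einsum("mij,mj->mi", Tinv, p - v[:, 0])
            bary = np.concatenate([(1.0 - loc.sum(axis=1))[:, None], loc], axis=1)
            worst = bary.min(axis=1)
            e = int(np.argmax(worst))
            if worst[e] < -tol:
                raise ValueError(
                    f"point {p.tolist()} lies outside the mesh (best deficit {worst[e]:.2e})"
                )
            elems[i] = e
            shape[i] = tet10_shape(bary[e])
        return elems, shape


# ---------------------------------------------------------------------------
# 2-D cross-sections (points in the (x, z) plane, triangles CCW)


def disc_section(n_theta: int, n_rings: int = 2):
    """Unit-radius disc: centre node + ``n_rings`` rings of ``n_theta`` nodes.

    Returns (points (p,2), tris (t,3), theta (p,), radial fraction (p,)).
    The actual radius at each angle is applied later by scaling the
    radial fraction, so cut (star-shaped) sections reuse this topology.
    """
    if n_theta < 8:
        raise ValueError("need at least 8 circumferential segments")
    if n_rings < 1:
        raise ValueError("need at least 1 ring")
    theta = [0.0]
    rho = [0.0]
    for k in range(1, n_rings + 1):
        for j in range(n_theta):
            theta.append(2.0 * np.pi * j / n_theta)
            rho.append(k / n_rings)
    tris = []
    # centre fan to ring 1
    for j in range(n_theta):
        a = 1 + j
        b = 1 + (j + 1) % n_theta
        tris.append((0, a, b))
    # ring k-1 to ring k quads
    for k in range(1, n_rings):
        base0 = 1 + (k - 1) * n_theta
        base1 = 1 + k * n_theta
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            a, b = base0 + j, base0 + j1
            c, d = base1 + j, base1 + j1
            tris.append((a, c, d))
            tris.append((a, d, b))
    theta = np.array(theta)
    rho = np.array(rho)
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
    return pts, np.array(tris, dtype=np.int64), theta, rho


def annulus_section(n_theta: int, n_radial: int, r_inner: float, r_outer: float):
    """Annulus cross-section; returns (points (p,2), tris (t,3))."""
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    radii = np.linspace(r_inner, r_outer, n_radial + 1)
    pts = []
    for r in radii:
        for j in range(n_theta):
            th = 2.0 * np.pi * j / n_theta
            pts.append((r * np.cos(th), r * np.sin(th)))
    tris = []
    for k in range(n_radial):
        base0 = k * n_theta
        base1 = (k + 1) * n_theta
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            a, b = base0 + j, base0 + j1
            c, d = base1 + j, base1 + j1
            tris.append((a, c, d))
            tris.append((a, d, b))
    return np.array(pts), np.array(tris, dtype=np.int64)


def rect_section(lx: float, lz: float, nx: int, nz: int):
    """Rectangle [-lx/2, lx/2] x [-lz/2, lz/2]; returns (points, tris)."""
    xs = np.linspace(-lx / 2.0, lx / 2.0, nx + 1)
    zs = np.linspace(-lz / 2.0, lz / 2.0, nz + 1)
    pts = np.array([(x, z) for z in zs for x in xs])
    tris = []
    for k in range(nz):
        for i in range(nx):
            a = k * (nx + 1) + i
            b = a + 1
            c = a + (nx + 1)
            d = c + 1
            tris.append((a, b, d))
            tris.append((a, d, c))
    return pts, np.array(tris, dtype=np.int64)


# ---------------------------------------------------------------------------
# extrusion: stations of 3-D section coordinates -> linear tets -> quadratic


def _split_prisms(bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split prisms (bottom/top triangles of global ids) into 3 tets each.

    Uses the minimum-index indirection rule, which yields a conforming
    tetrahedralization across prisms sharing quadrilateral faces.
    """
    k = np.argmin(bottom, axis=1)
    idx = (k[:, None] + np.arange(3)[None, :]) % 3
    b = np.take_along_axis(bottom, idx, axis=1)
    t = np.take_along_axis(top, idx, axis=1)
    I1, I2, I3 = b[:, 0], b[:, 1], b[:, 2]
    I4, I5, I6 = t[:, 0], t[:, 1], t[:, 2]
    cond = np.minimum(I2, I6) < np.minimum(I3, I5)
    tets = np.empty((len(b), 3, 4), dtype=np.int64)
    A = np.stack(
        [
            np.stack([I1, I2, I3, I6], axis=1),
            np.stack([I1, I2, I6, I5], axis=1),
            np.stack([I1, I5, I6, I4], axis=1),
        ],
        axis=1,
    )
    B = np.stack(
        [
            np.stack([I1, I2, I3, I5], axis=1),
            np.stack([I1, I5, I3, I6], axis=1),
            np.stack([I1, I5, I6, I4], axis=1),
        ],
        axis=1,
    )
    tets[cond] = A[cond]
    tets[~cond] = B[~cond]
    return tets.reshape(-1, 4)


def extrude_to_tets(station_coords: np.ndarray, tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extrude a triangulated section through stations into linear tets.

    station_coords : (n_stations, n_pts, 3) coordinates of the section
        nodes at each axial station (topology identical at every station).
    tris : (t, 3) section triangulation.

    Returns (nodes (N, 3), tets (M, 4)) with positive orientation.
    """
    coords = np.asarray(station_coords, dtype=float)
    n_st, n_pts, _ = coords.shape
    if n_st < 2:
        raise ValueError("need at least 2 stations")
    nodes = coords.reshape(-1, 3)
    all_tets = []
    for s in range(n_st - 1):
        bottom = tris + s * n_pts
        top = tris + (s + 1) * n_pts
        all_tets.append(_split_prisms(bottom, top))
    tets = np.concatenate(all_tets, axis=0)
    # enforce positive orientation (swap two nodes where negative)
    v = nodes[tets]
    vol = np.linalg.det(v[:, 1:] - v[:, :1])
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    if np.any(np.abs(vol) < 1e-15):
        raise ValueError("degenerate (zero-volume) prism encountered during extrusion")
    return nodes, tets


def linear_to_quadratic(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Insert unique mid-edge nodes, turning 4-node tets into 10-node tets."""
    edges = np.concatenate([tets[:, [a, b]] for a, b in TET10_EDGES], axis=0)
    key = np.sort(edges, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    mid = 0.5 * (nodes[uniq[:, 0]] + nodes[uniq[:, 1]])
    all_nodes = np.vstack([nodes, mid])
    m = len(tets)
    elems = np.empty((m, 10), dtype=np.int64)
    elems[:, :4] = tets
    for k in range(6):
        elems[:, 4 + k] = len(nodes) + inv[k * m : (k + 1) * m]
    return all_nodes, elems


def structured_box(
    lx: float, ly: float, lz: float, nx: int = 2, ny: int = 4, nz: int = 2
) -> TetMesh:
    """Quadratic-tet box [-lx/2, lx/2] x [0, ly] x [-lz/2, lz/2].

    Node sets "ymin"/"ymax" (end faces), "xmin"/"xmax"/"zmin"/"zmax",
    and facet sets "ymin"/"ymax" are provided for bar-type tests.
    """
    pts2d, tris = rect_section(lx, lz, nx, nz)
    ys = np.linspace(0.0, ly, ny + 1)
    coords = np.empty((len(ys), len(pts2d), 3))
    for s, y in enumerate(ys):
        coords[s, :, 0] = pts2d[:, 0]
        coords[s, :, 1] = y
        coords[s, :, 2] = pts2d[:, 1]
    nodes, tets = extrude_to_tets(coords, tris)
    nodes, elems = linear_to_quadratic(nodes, tets)
    mesh = TetMesh(nodes, elems)
    tol = 1e-9 * max(lx, ly, lz)
    mesh.add_node_set("ymin", np.abs(nodes[:, 1]) < tol)
    mesh.add_node_set("ymax", np.abs(nodes[:, 1] - ly) < tol)
    mesh.add_node_set("xmin", np.abs(nodes[:, 0] + lx / 2) < tol)
    mesh.add_node_set("xmax", np.abs(nodes[:, 0] - lx / 2) < tol)
    mesh.add_node_set("zmin", np.abs(nodes[:, 2] + lz / 2) < tol)
    mesh.add_node_set("zmax", np.abs(nodes[:, 2] - lz / 2) < tol)
    mesh.add_facet_set_where("ymin", lambda c: np.abs(c[:, 1]) < tol)
    mesh.add_facet_set_where("ymax", lambda c: np.abs(c[:, 1] - ly) < tol)
    mesh.validate()
    return mesh
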