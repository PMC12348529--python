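"""Parametric cog-thread geometry: barbed filaments and their meshes.

A cog thread is a cylindrical monofilament with wedge-shaped barb cuts
arranged along the axis in several radial directions.  Each cut removes
a chord-bounded wedge: its inclined leading face makes ``barb_angle``
with the filament axis and penetrates radially to ``cut_depth``; the
trailing stop face is (nominally) normal to the axis, so every barb
opens toward the same thread end and anchors tissue against one pull
direction.

Because the cut depth is always smaller than the filament radius, every
cross-section of a cut thread is star-shaped about the axis.  The whole
solid can therefore be described by a radius function r(theta, y) and
lofted into a watertight surface or a structured quadratic-tet volume
mesh without boolean operations.  The two exactly axis-normal faces
(trailing stop face, and the leading face at barb_angle = 90 deg) are
approximated by a short axial recovery ramp (``recovery_length``,
default 0.05 mm) so that r stays single-valued in y.

Dimension conventions follow suture practice: lengths in mm, filament
diameter / cut depth / spacing in micrometres.  The thread axis is the
y (supero-inferior) coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import TetMesh, disc_section, extrude_to_tets, linear_to_quadratic

__all__ = [
    "ThreadSpec",
    "SurfaceMesh",
    "ThreadProfile",
    "LinearTetVolume",
    "COMMERCIAL_THREAD",
    "COMPUTATIONAL_THREAD",
    "MEASURED_PRINT_DIAMETER_UM",
    "PRINTING_PARAMETERS",
    "build_filament",
    "cut_barbs",
    "min_cross_section_area",
    "tetrahedralize",
]

#: measured diameter of the printed PCL filament (metadata only)
MEASURED_PRINT_DIAMETER_UM = 598.33

#: melt-electrowriting printing parameters (metadata only; the printing
#: process itself is outside the scope of this package)
PRINTING_PARAMETERS = {
    "bed_voltage_kV": 4.2,
    "nozzle_to_bed_distance_mm": 1.0,
    "nozzle_diameter_um": 600.0,
    "extrusion_speed_mm_per_min": 1000.0,
}


@dataclass(frozen=True)
class ThreadSpec:
    """Parametric description of a cog thread.

    length : mm; diameter, cut_depth, axial_spacing, axial_phase : um;
    barb_angle : degrees in (0, 90]; n_directions >= 1 radial cut
    directions evenly spaced, rotated by direction_offset degrees.
    """

    length: float = 80.0
    diameter: float = 600.0
    barb_angle: float = 45.0
    cut_depth: float = 200.0
    axial_spacing: float = 1600.0
    n_directions: int = 4
    direction_offset: float = 0.0
    axial_phase: float = 0.0
    recovery_length: float = 0.05  # mm, stop-face ramp approximation
    bidirectional: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("length and diameter must be positive")
        if not 0.0 < self.barb_angle <= 90.0:
            raise ValueError("barb_angle must lie in (0, 90] degrees")
        if not self.cut_depth < self.diameter / 2.0:
            raise ValueError(
                f"cut_depth ({self.cut_depth} um) must be smaller than the filament "
                f"radius ({self.diameter / 2:.0f} um); the cut would sever the core"
            )
        if self.cut_depth <= 0:
            raise ValueError("cut_depth must be positive")
        if self.axial_spacing <= 0:
            raise ValueError("axial_spacing must be positive")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        if self.length * 1000.0 <= self.axial_spacing:
            raise ValueError("length must exceed the axial spacing")

    @property
    def radius_mm(self) -> float:
        return self.diameter / 2000.0

    @property
    def cut_depth_mm(self) -> float:
        return self.cut_depth / 1000.0

    @property
    def leading_length_mm(self) -> float:
        """Axial extent of the inclined leading face (depth / tan(angle))."""
        ramp = self.cut_depth_mm / math.tan(math.radians(self.barb_angle))
        return max(ramp, self.recovery_length)

    @property
    def trailing_length_mm(self) -> float:
        return self.recovery_length

    def cut_axial_positions(self) -> np.ndarray:
        """Axial start positions (mm) of the cut sites that fit the length."""
        span = self.leading_length_mm + self.trailing_length_mm
        out = []
        k = 0
        while True:
            y0 = (self.axial_phase + k * self.axial_spacing) / 1000.0
            if y0 + span > self.length + 1e-12:
                break
            out.append(y0)
            k += 1
        return np.array(out)

    @property
    def n_cut_sites_per_direction(self) -> int:
        return len(self.cut_axial_positions())

    def direction_angles_deg(self) -> np.ndarray:
        return self.direction_offset + 360.0 / self.n_directions * np.arange(
            self.n_directions
        )


#: commercial thread (length 160 mm, diameter 630 um, 45 deg barbs)
COMMERCIAL_THREAD = ThreadSpec(length=160.0, diameter=630.0, barb_angle=45.0)

#: computational thread used by the simulations (80 mm x 600 um)
COMPUTATIONAL_THREAD = ThreadSpec(length=80.0, diameter=600.0, barb_angle=45.0)


@dataclass(frozen=True)
class ThreadProfile:
    """Exact radius-function description of a (possibly cut) filament."""

    length: float  # mm
    radius: float  # mm
    cuts: tuple = ()  # tuples (y0_mm, depth_mm, lead_mm, trail_mm, angle_deg)

    def depth_at(self, y: np.ndarray) -> np.ndarray:
        """Per-direction cut depth (mm) at axial positions; (ndir, ny)."""
        y = np.atleast_1d(np.asarray(y, dtype=float))
        angles = sorted({c[4] for c in self.cuts})
        out = np.zeros((len(angles), y.size))
        index = {a: i for i, a in enumerate(angles)}
        for y0, depth, lead, trail, ang in self.cuts:
            i = index[ang]
            up = np.clip((y - y0) / lead, 0.0, 1.0)
            down = np.clip((y0 + lead + trail - y) / trail, 0.0, 1.0)
            out[i] = np.maximum(out[i], depth * np.minimum(up, down))
        return out

    def cut_angles_deg(self) -> np.ndarray:
        return np.array(sorted({c[4] for c in self.cuts}))

    def radius_at(self, theta: np.ndarray, y: float) -> np.ndarray:
        """Radius r(theta) of the cross-section at axial position y (mm)."""
        theta = np.asarray(theta, dtype=float)
        r = np.full(theta.shape, self.radius)
        if not self.cuts:
            return r
        depths = self.depth_at(np.array([y]))[:, 0]
        for phi, delta in zip(np.radians(self.cut_angles_deg()), depths):
            if delta <= 1e-12:
                continue
            h = self.radius - delta
            dth = np.arctan2(np.sin(theta - phi), np.cos(theta - phi))
            half = math.acos(min(h / self.radius, 1.0))
            mask = np.abs(dth) < half
            r[mask] = np.minimum(r[mask], h / np.cos(dth[mask]))
        return r

    def station_breakpoints(self, background_spacing: float) -> np.ndarray:
        """Axial stations: cut-face breakpoints plus a background grid."""
        pts = {0.0, self.length}
        for y0, _, lead, trail, _ in self.cuts:
            pts.update((y0, y0 + lead, y0 + lead + trail))
        n_bg = max(2, int(math.ceil(self.length / background_spacing)))
        pts.update(np.linspace(0.0, self.length, n_bg + 1).tolist())
        ys = np.array(sorted(pts))
        # drop near-duplicates
        keep = np.concatenate([[True], np.diff(ys) > 1e-9])
        return ys[keep]


@dataclass
class SurfaceMesh:
    """Closed triangulated surface (mm) with named facet groups.

    ``profile`` (when present) records the exact radius-function
    geometry the surface was lofted from; structured tetrahedralization
    requires it.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    facet_groups: dict[str, np.ndarray] = field(default_factory=dict)
    profile: ThreadProfile | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)

    def volume(self) -> float:
        """Enclosed volume (mm^3) via the divergence theorem."""
        v = self.vertices[self.triangles]
        return float(np.sum(np.linalg.det(v)) / 6.0)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two triangles, and
        every directed edge used exactly once (consistent orientation)."""
        t = self.triangles
        directed = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        und = np.sort(directed, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        if not np.all(counts == 2):
            return False
        _, dcounts = np.unique(directed, axis=0, return_counts=True)
        return bool(np.all(dcounts == 1))

    def check(self) -> None:
        if not self.is_watertight():
            raise ValueError("surface mesh is not watertight / consistently oriented")
        if self.volume() <= 0:
            raise ValueError("surface mesh is inverted (negative enclosed volume)")
        if np.any(self.triangle_areas() <= 1e-12):
            raise ValueError("surface mesh contains degenerate triangles")


def _loft_profile(profile: ThreadProfile, n_theta: int, background_spacing: float) -> SurfaceMesh:
    """Watertight surface mesh of a radius-function solid along y."""
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    ys = profile.station_breakpoints(background_spacing)
    M = len(ys)
    verts = np.empty((M * n_theta + 2, 3))
    for m, y in enumerate(ys):
        r = profile.radius_at(theta, float(y))
        verts[m * n_theta : (m + 1) * n_theta, 0] = r * np.cos(theta)
        verts[m * n_theta : (m + 1) * n_theta, 1] = y
        verts[m * n_theta : (m + 1) * n_theta, 2] = r * np.sin(theta)
    c_bot = M * n_theta
    c_top = c_bot + 1
    verts[c_bot] = (0.0, ys[0], 0.0)
    verts[c_top] = (0.0, ys[-1], 0.0)
    tris = []
    lateral = []
    for m in range(M - 1):
        b0 = m * n_theta
        b1 = (m + 1) * n_theta
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            a, b = b0 + j, b0 + j1
            c, d = b1 + j, b1 + j1
            lateral.append(len(tris)); tris.append((a, d, c))
            lateral.append(len(tris)); tris.append((a, b, d))
    caps = []
    for j in range(n_theta):
        j1 = (j + 1) % n_theta
        caps.append(len(tris)); tris.append((c_bot, j1, j))            # -y cap
        top0 = (M - 1) * n_theta
        caps.append(len(tris)); tris.append((c_top, top0 + j, top0 + j1))  # +y cap
    mesh = SurfaceMesh(
        verts,
        np.array(tris, dtype=np.int64),
        facet_groups={
            "lateral": np.array(lateral, dtype=np.int64),
            "caps": np.array(caps, dtype=np.int64),
        },
        profile=profile,
    )
    if mesh.volume() < 0:
        mesh.triangles = mesh.triangles[:, [0, 2, 1]]
    mesh.check()
    return mesh


def build_filament(
    length: float, diameter: float, circumferential_segments: int = 64
) -> SurfaceMesh:
    """Closed right circular cylinder along y, base at y = 0.

    length in mm, diameter in micrometres.
    """
    if length <= 0 or diameter <= 0:
        raise ValueError("length and diameter must be positive")
    if circumferential_segments < 8:
        raise ValueError("need at least 8 circumferential segments")
    profile = ThreadProfile(length=length, radius=diameter / 2000.0)
    return _loft_profile(profile, circumferential_segments, background_spacing=length / 8.0)


def cut_barbs(filament: SurfaceMesh, spec: ThreadSpec, n_theta: int | None = None) -> SurfaceMesh:
    """Apply a ThreadSpec's barb cuts to an uncut filament surface.

    Equivalent to boolean subtraction of one wedge per cut site, realized
    through the star-shaped radius-function construction; the result is
    watertight by construction.
    """
    if filament.profile is None or filament.profile.cuts:
        raise ValueError("cut_barbs expects an uncut profile-backed filament surface")
    prof = filament.profile
    if abs(prof.radius - spec.radius_mm) > 1e-9 or abs(prof.length - spec.length) > 1e-9:
        raise ValueError("filament dimensions do not match the ThreadSpec")
    cuts = []
    lead = spec.leading_length_mm
    trail = spec.trailing_length_mm
    for phi in spec.direction_angles_deg():
        for y0 in spec.cut_axial_positions():
            cuts.append((float(y0), spec.cut_depth_mm, lead, trail, float(phi % 360.0)))
            if spec.bidirectional:
                # mirrored barb: leading face toward the other end
                cuts.append((float(y0), spec.cut_depth_mm, trail, lead, float(phi % 360.0)))
    new_prof = replace(prof, cuts=tuple(cuts))
    if n_theta is None:
        n_theta = int(round(len([t for t in filament.facet_groups.get("lateral", [])])))
        # infer ring size from the uncut loft instead
        n_theta = (len(filament.vertices) - 2) // len(
            prof.station_breakpoints(prof.length / 8.0)
        )
    return _loft_profile(new_prof, n_theta, background_spacing=spec.axial_spacing / 1000.0)


# ---------------------------------------------------------------------------
# cross-section analysis


def _section_area(mesh: SurfaceMesh, y: float) -> float:
    """Planar cross-section area at axial station y (plane normal +y)."""
    v = mesh.vertices[mesh.triangles]
    d = v[..., 1] - y
    # nudge exact hits
    if np.any(np.abs(d) < 1e-12):
        return _section_area(mesh, y + 1e-9)
    sign = d > 0
    crossing = ~(np.all(sign, axis=1) | np.all(~sign, axis=1))
    area2 = 0.0
    for tri, dd in zip(v[crossing], d[crossing]):
        pts = []
        for i in range(3):
            j = (i + 1) % 3
            if (dd[i] > 0) != (dd[j] > 0):
                t = dd[i] / (dd[i] - dd[j])
                pts.append(tri[i] + t * (tri[j] - tri[i]))
        if len(pts) != 2:
            continue
        p, q = pts
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        tdir = np.array([n[2], 0.0, -n[0]])  # n x e_y
        if np.dot(q - p, tdir) < 0:
            p, q = q, p
        area2 += p[2] * q[0] - p[0] * q[2]
    return abs(area2) / 2.0


def min_cross_section_area(
    mesh: SurfaceMesh,
    axis_samples: int = 200,
    refine_rounds: int = 3,
    end_margin: float = 0.01,
) -> tuple[float, float]:
    """Minimum planar cross-section area along the thread axis.

    Slices the watertight surface at ``axis_samples`` uniformly spaced
    stations, then refines locally around the minimum.  A profile-backed
    mesh is sliced along its exact (y) axis; otherwise the axis is the
    dominant principal direction of the vertex cloud, which makes the
    result invariant under rigid transformation of the mesh.  A fraction
    ``end_margin`` of the axial span is excluded at each end so that a
    slightly tilted detected axis cannot clip a sliver off an end cap.

    Returns (area_mm2, axial_location_mm) with the location expressed
    along the axis from its lower end.
    """
    mesh.check()
    verts = mesh.vertices
    ctr = verts.mean(axis=0)
    if mesh.profile is not None:
        axis = np.array([0.0, 1.0, 0.0])
    else:
        cov = np.cov((verts - ctr).T)
        w, vecs = np.linalg.eigh(cov)
        axis = vecs[:, np.argmax(w)]
    # rotate axis onto +y
    yhat = np.array([0.0, 1.0, 0.0])
    vcross = np.cross(axis, yhat)
    s = np.linalg.norm(vcross)
    c = float(np.dot(axis, yhat))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        K = np.array(
            [[0, -vcross[2], vcross[1]], [vcross[2], 0, -vcross[0]], [-vcross[1], vcross[0], 0]]
        )
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
    work = SurfaceMesh((verts - ctr) @ R.T, mesh.triangles)
    y = work.vertices[:, 1]
    lo, hi = y.min(), y.max()
    pad = end_margin * (hi - lo)
    samples = np.linspace(lo + pad, hi - pad, axis_samples)
    areas = np.array([_section_area(work, float(s)) for s in samples])
    best = int(np.argmin(areas))
    best_y, best_a = samples[best], areas[best]
    span = samples[1] - samples[0]
    for _ in range(refine_rounds):
        local = np.linspace(best_y - span, best_y + span, 11)
        local = local[(local > lo + pad) & (local < hi - pad)]
        la = np.array([_section_area(work, float(s)) for s in local])
        k = int(np.argmin(la))
        if la[k] < best_a:
            best_a, best_y = la[k], local[k]
        span = (local[1] - local[0]) if len(local) > 1 else span / 10.0
    return float(best_a), float(best_y - lo)


# ---------------------------------------------------------------------------
# structured tetrahedralization


@dataclass
class LinearTetVolume:
    """4-node tetrahedron mesh (only produced when order='linear')."""

    nodes: np.ndarray
    tets: np.ndarray


def tetrahedralize(
    surface: SurfaceMesh,
    target_edge: float = 0.15,
    order: str = "quadratic",
    n_theta: int | None = None,
    n_rings: int | None = None,
    axial_edge: float | None = None,
):
    """Structured volume mesh of a profile-backed thread surface.

    ``target_edge`` (mm) controls the circumferential, radial and axial
    background resolution.  Quadratic order inserts mid-edge nodes
    (straight edges, C3D10-style) and attaches "grip_bottom"/"grip_top"
    node and facet sets at the two end faces.

    Raises ValueError for surfaces without an attached
    :class:`ThreadProfile`: generic tetrahedralization of arbitrary
    watertight surfaces requires an external mesh generator, which this
    package deliberately does not depend on.
    """
    if surface.profile is None:
        raise ValueError(
            "tetrahedralize requires a profile-backed SurfaceMesh "
            "(built by build_filament/cut_barbs); arbitrary surfaces are unsupported"
        )
    surface.check()
    prof = surface.profile
    if order not in ("linear", "quadratic"):
        raise ValueError("order must be 'linear' or 'quadratic'")
    if n_theta is None:
        n_theta = max(12, int(round(2.0 * np.pi * prof.radius / target_edge)))
    if n_rings is None:
        n_rings = max(1, int(round(prof.radius / target_edge)))
    pts2d, tris, theta, rho = disc_section(n_theta, n_rings)
    if axial_edge is None:
        # for a slender filament, axial resolution needs are set by the
        # cut-face breakpoints, not by the cross-section edge target
        axial_edge = max(target_edge, prof.length / 64.0)
    ys = prof.station_breakpoints(background_spacing=axial_edge)
    coords = np.empty((len(ys), len(pts2d), 3))
    for m, y in enumerate(ys):
        r = prof.radius_at(theta, float(y)) * rho
        coords[m, :, 0] = r * np.cos(theta)
        coords[m, :, 1] = y
        coords[m, :, 2] = r * np.sin(theta)
    nodes, tets = extrude_to_tets(coords, tris)
    if order == "linear":
        return LinearTetVolume(nodes, tets)
    nodes, elems = linear_to_quadratic(nodes, tets)
    mesh = TetMesh(nodes, elems)
    tol = 1e-9 * prof.length
    mesh.add_node_set("grip_bottom", np.abs(nodes[:, 1] - ys[0]) < tol)
    mesh.add_node_set("grip_top", np.abs(nodes[:, 1] - ys[-1]) < tol)
    mesh.add_facet_set_where("grip_bottom", lambda c: np.abs(c[:, 1] - ys[0]) < 1e-8)
    mesh.add_facet_set_where("grip_top", lambda c: np.abs(c[:, 1] - ys[-1]) < 1e-8)
    mesh.validate()
    return mesh
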