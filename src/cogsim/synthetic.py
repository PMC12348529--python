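"""Synthetic inputs: idealized canal geometry, noisy curves, thread paths.

The patient-specific pelvic model used in the original simulations is
not publicly distributed, so every pipeline input can be generated
here instead:

* an idealized thick-walled vaginal-canal tube (annular cross-section,
  axis supero-inferior) with the named node/facet sets the load
  scenarios require ("base", "anterior_wall", "posterior", "apex");
* noisy uniaxial stress-strain curves with the exact constitutive
  structure the fitting routines assume;
* longitudinal thread-placement polylines at mid-wall depth across the
  anterior half of the canal.

The default canal dimensions (length 80 mm, inner radius 15 mm, wall
3 mm) are order-of-magnitude anatomical choices, *not* a reconstruction
of any patient geometry; quantitative displacement values computed on
it are therefore only meaningful as orderings and relative comparisons
between runs on the identical mesh.

All generators are pure functions of (spec, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constitutive import (
    LinearElasticParameters,
    OgdenParameters,
    StressStrainCurve,
    linear_uniaxial_stress,
    ogden_uniaxial_nominal,
)
from .mesh import TetMesh, annulus_section, extrude_to_tets, linear_to_quadratic

__all__ = [
    "CanalGeometrySpec",
    "generate_canal_geometry",
    "generate_stress_strain_curve",
    "generate_thread_paths",
]


@dataclass(frozen=True)
class CanalGeometrySpec:
    """Idealized thick-walled canal tube (mm)."""

    length: float = 80.0
    inner_radius: float = 15.0
    wall_thickness: float = 3.0
    curvature_radius: float | None = None  # straight tube if None
    mesh_edge: float = 6.0
    anterior_half_angle: float = 60.0  # deg, extent of the loaded anterior wall
    dome_fraction: float = 0.25  # top fraction tapered into a near-closed dome
    dome_hole_radius: float = 1.0  # mm, residual opening at the apex
    tilt_deg: float = 45.0  # inclination of the canal axis from vertical
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.length, self.inner_radius, self.wall_thickness, self.mesh_edge) <= 0:
            raise ValueError("all dimensions must be positive")
        if not self.wall_thickness < self.inner_radius:
            raise ValueError("wall_thickness must be smaller than inner_radius")
        if self.curvature_radius is not None and self.curvature_radius <= self.length / math.pi:
            raise ValueError("curvature_radius too small for the tube length")

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.wall_thickness

    @property
    def mid_radius(self) -> float:
        return self.inner_radius + 0.5 * self.wall_thickness


def generate_canal_geometry(spec: CanalGeometrySpec) -> TetMesh:
    """Quadratic-tet mesh of the canal with the scenario node/facet sets.

    Sets: "base" (inferior rim, y=0), "apex" (superior rim), "posterior"
    (nodes within the posterior angular sector), and "anterior_wall"
    (outer-surface facets and their nodes within the anterior sector
    around the +x, antero-posterior direction).
    """
    n_theta = max(12, int(round(2.0 * math.pi * spec.mid_radius / spec.mesh_edge)))
    n_axial = max(4, int(round(spec.length / spec.mesh_edge)))
    n_radial = max(1, int(round(spec.wall_thickness / spec.mesh_edge)))
    # unit annulus; per-station scaling shapes the dome taper
    pts2d, tris = annulus_section(n_theta, n_radial, spec.inner_radius, spec.outer_radius)
    rho = np.hypot(pts2d[:, 0], pts2d[:, 1])
    unit = pts2d / rho[:, None]
    frac = (rho - spec.inner_radius) / spec.wall_thickness  # 0 inner .. 1 outer
    ys = np.linspace(0.0, spec.length, n_axial + 1)
    y_dome = spec.length * (1.0 - spec.dome_fraction)
    coords = np.empty((len(ys), len(pts2d), 3))
    for m, y in enumerate(ys):
        if spec.dome_fraction > 0 and y > y_dome:
            # cosine taper of the inner radius toward a small apex hole
            s = (y - y_dome) / (spec.length - y_dome)
            r_in = spec.dome_hole_radius + (spec.inner_radius - spec.dome_hole_radius) * math.cos(
                0.5 * math.pi * s
            )
        else:
            r_in = spec.inner_radius
        r_station = r_in + frac * spec.wall_thickness
        sec = unit * r_station[:, None]
        if spec.curvature_radius is None:
            coords[m, :, 0] = sec[:, 0]
            coords[m, :, 1] = y
            coords[m, :, 2] = sec[:, 1]
        else:
            # sweep the section along a circular arc in the x-y plane
            rc = spec.curvature_radius
            phi = y / rc
            cx, cy = rc * (1.0 - math.cos(phi)), rc * math.sin(phi)
            ex = np.array([math.cos(phi), math.sin(phi), 0.0])  # rotated +x
            coords[m] = (
                np.array([cx, cy, 0.0])
                + sec[:, :1] * ex[None, :]
                + sec[:, 1:] * np.array([0.0, 0.0, 1.0])[None, :]
            )
    nodes, tets = extrude_to_tets(coords, tris)
    nodes, elems = linear_to_quadratic(nodes, tets)
    mesh = TetMesh(nodes, elems)

    tol = 1e-8 * spec.length
    mesh.add_node_set("base", np.abs(nodes[:, 1]) < tol)
    mesh.add_node_set("apex", np.abs(nodes[:, 1] - spec.length) < tol)

    half = math.radians(spec.anterior_half_angle)
    ang = np.arctan2(nodes[:, 2], nodes[:, 0])  # angle from +x (anterior)
    post = np.abs(np.arctan2(np.sin(ang - math.pi), np.cos(ang - math.pi))) < half
    mesh.add_node_set("posterior", post)

    r_out = spec.outer_radius

    y_dome = spec.length * (1.0 - spec.dome_fraction)

    def anterior_outer(c: np.ndarray) -> np.ndarray:
        a = np.arctan2(c[:, 2], c[:, 0])
        r = np.hypot(c[:, 0], c[:, 2])
        return (
            (np.abs(a) < half)
            & (r > r_out - 0.4 * spec.wall_thickness)
            & (c[:, 1] < y_dome + 1e-6 * spec.length)
        )

    mesh.add_facet_set_where("anterior_wall", anterior_outer)
    mesh.add_node_set("anterior_wall", mesh.nodes_of_facet_set("anterior_wall"))

    # tilt the whole canal about the lateral (z) axis: anatomically the
    # canal is inclined, so a supero-inferior (-y) indenter meets the
    # anterior wall transversely rather than end-on
    th = math.radians(spec.tilt_deg)
    c, s = math.cos(th), math.sin(th)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    mesh.nodes = mesh.nodes @ R.T
    mesh.metadata["canal_rotation"] = R
    mesh.validate()
    if any(len(mesh.node_sets[s]) == 0 for s in ("base", "apex", "posterior", "anterior_wall")):
        raise RuntimeError("canal generation produced an empty required set")
    return mesh


def generate_stress_strain_curve(
    material: OgdenParameters | LinearElasticParameters,
    max_strain: float = 0.3,
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> StressStrainCurve:
    """Nominal stress-strain curve from the closed forms plus Gaussian noise.

    The noise is additive, homoscedastic, independent per point
    (``noise_sd`` in MPa), and seeded.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    strain = np.linspace(0.0, max_strain, n_points)
    if isinstance(material, LinearElasticParameters):
        stress = np.asarray(linear_uniaxial_stress(material, strain), dtype=float)
    elif isinstance(material, OgdenParameters):
        stress = np.asarray(ogden_uniaxial_nominal(material, 1.0 + strain), dtype=float)
    else:
        raise TypeError(f"unsupported material: {type(material)!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd, size=stress.shape)
    return StressStrainCurve(strain=strain, stress=stress, label=label)


def generate_thread_paths(
    canal: TetMesh,
    n_threads: int = 4,
    inset: float | None = None,
    span_angle: float = 100.0,
    margin: float = 1.0,
    n_points: int = 15,
) -> list[np.ndarray]:
    """Longitudinal mid-wall polylines across the anterior half of the canal.

    Paths run supero-inferiorly (the clinical insertion direction) at
    mid-wall depth (or ``inset`` mm inward from the outer surface),
    evenly spaced over ``span_angle`` degrees centred on the anterior
    (+x) direction.  Every point is verified to lie strictly inside the
    mesh volume.
    """
    if n_threads < 1:
        raise ValueError("n_threads must be >= 1")
    # work in the canal's own frame (axis = y) if the mesh was tilted
    R = np.asarray(canal.metadata.get("canal_rotation", np.eye(3)))
    # per-station wall radii from the extruded mesh structure: corner
    # stations share exact y values, so the mid-wall depth can follow
    # any apex taper of the wall
    bnodes = canal.nodes[canal.boundary_node_indices()] @ R
    ys_station = np.unique(np.round(bnodes[:, 1], 9))
    r_mid = np.empty(len(ys_station))
    for k, ys_ in enumerate(ys_station):
        at = bnodes[np.abs(bnodes[:, 1] - ys_) < 1e-6]
        r = np.hypot(at[:, 0], at[:, 2])
        r_mid[k] = r.max() - inset if inset is not None else 0.5 * (r.min() + r.max())
    y_lo = ys_station[0] + margin
    y_hi = ys_station[-1] - margin
    if n_threads == 1:
        angles = np.array([0.0])
    else:
        half = math.radians(span_angle) / 2.0
        angles = np.linspace(-half, half, n_threads)
    ys = np.linspace(y_lo, y_hi, n_points)
    r_path = np.interp(ys, ys_station, r_mid)
    # the faceted section is tightest mid-edge between vertices: pull the
    # radius toward the axis by the chord deficit of the coarsest ring
    n_ring = max(12, int(np.sqrt(len(bnodes) / max(len(ys_station), 1))))
    r_path = r_path * math.cos(math.pi / n_ring)
    paths = []
    for a in angles:
        p = np.column_stack([r_path * math.cos(a), ys, r_path * math.sin(a)]) @ R.T
        canal.locate_points(p)  # raises if any point is outside
        paths.append(p)
    return paths
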