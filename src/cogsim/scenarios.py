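"""The three simulation classes as turnkey pipelines.

* :func:`virtual_tensile_test` — displacement-controlled uniaxial
  tension of a (cut or uncut) thread meshed in full 3-D, reporting an
  engineering stress-strain curve (stress = grip reaction / uncut
  nominal area, the standard suture-testing convention, which keeps
  cut and uncut curves directly comparable).
* :func:`cough_pressure_scenario` — cough-pressure loading (default
  160 cmH2O) of the canal in healthy / damaged / thread-reinforced
  states; the reported metric is the antero-posterior (x) displacement
  of the anterior wall.
* :func:`ball_burst_scenario` — a rigid sphere (default radius 10 mm)
  displaced supero-inferiorly against the anterior wall; reaction
  force vs. travel.

Threads inside tissue scenarios are embedded axial-stiffness
(EA) segments tied to the host mesh; the barb cut geometry enters only
through the minimum cross-section area that sets EA.  Full 3-D thread
meshes are reserved for the tensile scenario, where the barb geometry
itself is the object of study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constitutive import (
    LinearElasticParameters,
    OgdenParameters,
    StressStrainCurve,
    apply_damage,
    initial_shear_modulus,
)
from .fem import (
    BoundaryCondition,
    EmbeddedThread,
    ModelAssembly,
    PressureLoad,
    RigidSphere,
    SolutionField,
    assemble_model,
    encastre,
    extract_displacement_metric,
    solve_static,
)
from .mesh import TetMesh
from .threads import ThreadSpec, build_filament, cut_barbs, tetrahedralize

__all__ = [
    "ForceDisplacementCurve",
    "ScenarioReport",
    "pressure_cmh2o_to_mpa",
    "CMH2O_TO_MPA",
    "thread_min_section_area",
    "virtual_tensile_test",
    "cough_pressure_scenario",
    "ball_burst_scenario",
    "reinforcement_gain",
    "angle_sensitivity_study",
]

#: 1 cmH2O = 98.0665 Pa
CMH2O_TO_MPA = 98.0665e-6


def pressure_cmh2o_to_mpa(p: float) -> float:
    """Convert a pressure from cmH2O to MPa (1 cmH2O = 98.0665 Pa)."""
    if p < 0:
        raise ValueError("pressure must be >= 0")
    return p * CMH2O_TO_MPA


@dataclass(frozen=True)
class ForceDisplacementCurve:
    """Reaction force (N) vs. imposed displacement (mm)."""

    displacement: np.ndarray
    force: np.ndarray
    label: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("displacement and force must be 1-D arrays of equal length")
        if d[0] != 0.0:
            raise ValueError("displacement must start at 0")
        if np.any(np.diff(d) < 0):
            raise ValueError("displacement must be nondecreasing")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"displacement_mm": self.displacement, "force_N": self.force}
        ).to_csv(path, index=False)


@dataclass
class ScenarioReport:
    """Metrics, inputs digest and convergence summary of one scenario run."""

    scenario: str
    metrics: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    convergence: list = field(default_factory=list)
    comparisons: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x

        return clean(
            {
                "scenario": self.scenario,
                "metrics": self.metrics,
                "inputs": self.inputs,
                "convergence": self.convergence,
                "comparisons": self.comparisons,
            }
        )


def _convergence_summary(sol: SolutionField) -> list:
    return [
        {
            "t": inc["t"],
            "iterations": len(inc["residuals"]),
            "final_residual": inc["residuals"][-1] if inc["residuals"] else None,
            "converged": inc["converged"],
        }
        for inc in sol.increments
    ]


# ---------------------------------------------------------------------------
# virtual tensile test


def thread_min_section_area(spec: ThreadSpec, n_theta: int = 2048) -> float:
    """Minimum cross-section area (mm^2) of a cut thread, closed form.

    Evaluates the star-shaped section at full cut depth (all directions
    simultaneously engaged, the worst axial station) with the polar
    area formula A = 1/2 int r(theta)^2 dtheta.
    """
    from .threads import ThreadProfile

    cuts = tuple(
        (0.0, spec.cut_depth_mm, spec.leading_length_mm, spec.trailing_length_mm, float(phi % 360))
        for phi in spec.direction_angles_deg()
    )
    prof = ThreadProfile(length=1.0, radius=spec.radius_mm, cuts=cuts)
    theta = 2.0 * np.pi * (np.arange(n_theta) + 0.5) / n_theta
    r = prof.radius_at(theta, spec.leading_length_mm)  # full depth station
    return float(0.5 * np.sum(r**2) * (2.0 * np.pi / n_theta))


def virtual_tensile_test(
    spec: ThreadSpec,
    material: LinearElasticParameters,
    max_strain: float = 0.01,
    n_points: int = 5,
    mesh_edge: float = 0.15,
    uncut: bool = False,
    n_theta: int | None = None,
    n_rings: int | None = None,
    axial_edge: float | None = None,
) -> StressStrainCurve:
    """Simulated uniaxial tensile test of a thread; engineering curve.

    One grip is fully fixed, the other is displaced axially to
    ``max_strain`` of the gauge length over ``n_points`` increments.
    Stress uses the *uncut* nominal area pi d^2/4 regardless of the cut
    state.  On loss of convergence the curve is truncated and flagged.
    """
    if max_strain > 0.05:
        raise ValueError("max_strain beyond the elastic-range assumption (> 0.05)")
    surface = build_filament(spec.length, spec.diameter, circumferential_segments=64)
    if not uncut:
        surface = cut_barbs(surface, spec)
    mesh = tetrahedralize(
        surface, target_edge=mesh_edge, n_theta=n_theta, n_rings=n_rings,
        axial_edge=axial_edge,
    )
    L = spec.length
    area_nom = math.pi * spec.radius_mm**2
    bcs = [
        encastre("grip_bottom"),
        BoundaryCondition("grip_top", ("x", "z")),
        BoundaryCondition("grip_top", ("y",), {"y": max_strain * L}),
    ]
    model = assemble_model(mesh, material, bcs)
    top_dofs = 3 * mesh.node_sets["grip_top"] + 1
    record: list[tuple[float, float]] = []

    def cb(t: float, u: np.ndarray) -> None:
        r, *_ = model.residual_and_tangent(u, t, tangent=False)
        record.append((t, float(r[top_dofs].sum())))

    sol = solve_static(model, n_increments=n_points, callback=cb)
    strain = np.array([0.0] + [t * max_strain for t, _ in record])
    stress = np.array([0.0] + [f / area_nom for _, f in record])
    label = f"{'uncut' if uncut else f'{spec.barb_angle:g}deg cut'} thread"
    curve = StressStrainCurve(strain=strain, stress=stress, label=label)
    if not sol.converged:
        object.__setattr__(curve, "label", label + " [truncated: non-converged]")
    return curve


# ---------------------------------------------------------------------------
# cough-pressure scenario


def _threads_from_paths(
    paths: list[np.ndarray],
    thread_spec: ThreadSpec,
    thread_material: LinearElasticParameters,
) -> list[EmbeddedThread]:
    area = thread_min_section_area(thread_spec)
    ea = thread_material.youngs_modulus * area
    return [EmbeddedThread(path=p, axial_stiffness=ea) for p in paths]


def cough_pressure_scenario(
    canal: TetMesh,
    tissue: OgdenParameters,
    damage: float = 0.0,
    threads: list[EmbeddedThread] | None = None,
    pressure: float = 160.0,
    n_increments: int = 5,
    newton_tol: float = 1e-6,
) -> ScenarioReport:
    """Cough-pressure loading of the canal; returns the wall-displacement report.

    Boundary conditions: encastre at the "base" set, x/z (antero-
    posterior and lateral) restraint on the "posterior" set, uniform
    follower pressure (``pressure`` in cmH2O) on the "anterior_wall"
    facets.  ``damage`` scales the tissue stiffness down before solving.
    The metric is the antero-posterior (x) displacement of the
    "anterior_wall" nodes (max reported, mean alongside).
    """
    for s in ("base", "posterior", "anterior_wall"):
        if s not in canal.node_sets and s not in canal.facet_sets:
            raise KeyError(f"canal mesh lacks required set {s!r}")
    mat = apply_damage(tissue, damage) if damage else tissue
    p_mpa = pressure_cmh2o_to_mpa(pressure)
    bcs = [encastre("base"), BoundaryCondition("posterior", ("x", "z"))]
    loads = [PressureLoad("anterior_wall", p_mpa, follower=True)]
    model = assemble_model(canal, mat, bcs, loads=loads, threads=threads or [])
    sol = solve_static(model, n_increments=n_increments, newton_tol=newton_tol)
    report = ScenarioReport(
        scenario="cough_pressure",
        inputs={
            "pressure_cmH2O": pressure,
            "pressure_MPa": p_mpa,
            "damage": damage,
            "n_threads": len(threads or []),
            "tissue_mu0_MPa": initial_shear_modulus(mat),
            "n_elements": canal.n_elements,
        },
        convergence=_convergence_summary(sol),
    )
    if not sol.converged:
        report.metrics["converged"] = False
        return report
    metric = extract_displacement_metric(sol, canal, "anterior_wall", "x")
    report.metrics.update(
        {
            "converged": True,
            "anterior_ap_displacement_mm": metric["max"],
            "anterior_ap_displacement_mean_mm": metric["mean"],
        }
    )
    return report


# ---------------------------------------------------------------------------
# ball burst


def ball_burst_scenario(
    canal: TetMesh,
    tissue: OgdenParameters,
    threads: list[EmbeddedThread] | None = None,
    sphere_radius: float = 10.0,
    max_travel: float = 5.0,
    n_increments: int = 25,
    contact_penalty: float | None = None,
) -> ForceDisplacementCurve:
    """Rigid-sphere indentation of the anterior wall; force vs. travel.

    The sphere starts in tangent contact above the anterior wall's
    highest point (computed automatically) and moves along -y
    (supero-inferiorly) by ``max_travel`` mm; the canal is fixed at its
    base; contact is frictionless.  On loss of convergence the curve is
    truncated and flagged.
    """
    if "anterior_wall" not in canal.node_sets:
        raise KeyError("canal mesh lacks the 'anterior_wall' node set")
    ant = canal.nodes[canal.node_sets["anterior_wall"]]
    cx, cz = float(np.mean(ant[:, 0])), float(np.mean(ant[:, 2]))
    # tangency against every boundary node the sphere can reach, so the
    # start position never penetrates the apex dome either
    bnd = canal.nodes[canal.boundary_node_indices()]
    horiz2 = (bnd[:, 0] - cx) ** 2 + (bnd[:, 2] - cz) ** 2
    reach = horiz2 < sphere_radius**2
    if not np.any(reach):
        raise ValueError("sphere does not reach any boundary node")
    y0 = float(np.max(bnd[reach, 1] + np.sqrt(sphere_radius**2 - horiz2[reach])))
    if contact_penalty is None:
        # 10 x mu0 x mean element edge: stiff enough that penetration
        # stays well below 1% of the travel, soft enough that Newton
        # remains stable when the active contact set changes
        mu0 = initial_shear_modulus(tissue)
        edges = canal.nodes[canal.elements[:, 1]] - canal.nodes[canal.elements[:, 0]]
        h = float(np.mean(np.linalg.norm(edges, axis=1)))
        contact_penalty = 10.0 * mu0 * h
    sphere = RigidSphere(
        center_start=(cx, y0, cz),
        center_end=(cx, y0 - max_travel, cz),
        radius=sphere_radius,
        contact_penalty=contact_penalty,
    )
    model = assemble_model(
        canal, tissue, [encastre("base")], sphere=sphere, threads=threads or []
    )
    record: list[tuple[float, float]] = []

    def cb(t: float, u: np.ndarray) -> None:
        *_, sphere_reaction = model.residual_and_tangent(u, t, tangent=False)
        record.append((t, float(sphere_reaction[1])))

    sol = solve_static(model, n_increments=n_increments, callback=cb)
    disp = np.array([0.0] + [t * max_travel for t, _ in record])
    force = np.array([0.0] + [f for _, f in record])
    label = f"{len(threads or [])} threads" if threads else "unreinforced"
    return ForceDisplacementCurve(
        displacement=disp, force=force, label=label, truncated=not sol.converged
    )


def reinforcement_gain(
    reinforced: ForceDisplacementCurve, bare: ForceDisplacementCurve
) -> float:
    """Percent force increase of the reinforced run at the final common travel."""
    d_end = min(reinforced.displacement[-1], bare.displacement[-1])
    fr = float(np.interp(d_end, reinforced.displacement, reinforced.force))
    fb = float(np.interp(d_end, bare.displacement, bare.force))
    if fb == 0.0:
        raise ZeroDivisionError("bare curve has zero force at the final common travel")
    return 100.0 * (fr - fb) / fb


# ---------------------------------------------------------------------------
# barb-angle sensitivity


def angle_sensitivity_study(
    canal: TetMesh,
    tissue: OgdenParameters,
    damage: float = 0.5,
    angles: tuple[float, ...] = (90.0, 75.0, 60.0, 45.0),
    pressure: float = 160.0,
    thread_paths: list[np.ndarray] | None = None,
    thread_material: LinearElasticParameters | None = None,
    base_thread_spec: ThreadSpec | None = None,
    n_increments: int = 5,
) -> ScenarioReport:
    """Cough scenario per barb angle; reports the relative metric spread.

    Each angle's threads differ only through the minimum cross-section
    area that sets the embedded axial stiffness EA.  The spread is
    (max - min)/mean over the per-angle displacement metrics.
    """
    from .constitutive import THREAD_LINEAR_ELASTIC
    from .synthetic import generate_thread_paths

    if any(not 0 < a <= 90 for a in angles):
        raise ValueError("angles must lie in (0, 90] degrees")
    thread_material = thread_material or THREAD_LINEAR_ELASTIC
    base = base_thread_spec or ThreadSpec()
    paths = thread_paths if thread_paths is not None else generate_thread_paths(canal)
    report = ScenarioReport(
        scenario="angle_sensitivity",
        inputs={
            "angles_deg": list(angles),
            "damage": damage,
            "pressure_cmH2O": pressure,
            "n_threads": len(paths),
        },
    )
    metrics = {}
    for ang in angles:
        spec = ThreadSpec(
            length=base.length,
            diameter=base.diameter,
            barb_angle=float(ang),
            cut_depth=base.cut_depth,
            axial_spacing=base.axial_spacing,
            n_directions=base.n_directions,
        )
        threads = _threads_from_paths(paths, spec, thread_material)
        rep = cough_pressure_scenario(
            canal, tissue, damage=damage, threads=threads, pressure=pressure,
            n_increments=n_increments,
        )
        if not rep.metrics.get("converged", False):
            raise RuntimeError(f"angle {ang} run did not converge")
        metrics[f"{ang:g}"] = rep.metrics["anterior_ap_displacement_mm"]
        report.curves[f"angle_{ang:g}"] = rep
    vals = np.array(list(metrics.values()))
    spread = float((vals.max() - vals.min()) / vals.mean()) if len(vals) > 1 else 0.0
    report.metrics = {
        "per_angle_mm": metrics,
        "relative_spread": spread,
    }
    return report
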