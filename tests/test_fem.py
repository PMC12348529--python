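"""Finite-element core: kernels, patch tests, oracles and invariants."""

import numpy as np
import pytest

from cogsim.constitutive import (
    LinearElasticParameters,
    TABLE_TISSUE_OGDEN,
    THREAD_LINEAR_ELASTIC,
    ogden_uniaxial_nominal,
)
from cogsim.fem import (
    BoundaryCondition,
    EmbeddedThread,
    OgdenMaterial,
    PressureLoad,
    RigidSphere,
    assemble_model,
    contact_residual,
    encastre,
    extract_displacement_metric,
    follower_pressure_forces,
    solve_static,
)
from cogsim.mesh import structured_box

from conftest import make_pinned_bar


def solve_bar_stretch(mesh, material, stretch, n_increments=4, L=10.0):
    model = assemble_model(
        mesh,
        material,
        [
            BoundaryCondition("ymin", ("y",)),
            BoundaryCondition("ymax", ("y",), {"y": (stretch - 1.0) * L}),
            BoundaryCondition("pin0", ("x", "z")),
            BoundaryCondition("pin1", ("z",)),
        ],
    )
    return model, solve_static(model, n_increments=n_increments)


class TestMaterialKernels:
    @pytest.mark.parametrize(
        "F",
        [
            np.eye(3) + 0.1 * np.random.default_rng(1).standard_normal((3, 3)),
            1.1 * np.eye(3),
            np.diag([1.2, 1.2, 0.9]),
        ],
        ids=["generic", "triple-eigenvalue", "double-eigenvalue"],
    )
    def test_ogden_tangent_matches_finite_differences(self, tissue, F):
        mat = OgdenMaterial(tissue)
        P, A = mat.pk1_and_tangent(F[None])
        P, A = P[0], A[0]
        h = 1e-6
        fd = np.zeros((3, 3, 3, 3))
        for j in range(3):
            for L in range(3):
                dF = np.zeros((3, 3))
                dF[j, L] = h
                fd[:, :, j, L] = (
                    mat.pk1_and_tangent((F + dF)[None])[0][0]
                    - mat.pk1_and_tangent((F - dF)[None])[0][0]
                ) / (2 * h)
        assert np.abs(fd - A).max() / np.abs(A).max() < 1e-6

    def test_ogden_stress_fast_path_matches_full(self, tissue):
        mat = OgdenMaterial(tissue)
        rng = np.random.default_rng(7)
        F = np.eye(3) + 0.15 * rng.standard_normal((12, 3, 3))
        assert np.allclose(mat.pk1(F), mat.pk1_and_tangent(F)[0], atol=1e-12)


class TestPressure:
    def test_flat_square_unit_pressure(self):
        # 1 MPa on a 16 mm^2 flat face -> 16 N against the outward normal
        m = structured_box(4.0, 2.0, 4.0, nx=2, ny=1, nz=2)
        f = follower_pressure_forces(m.facet_nodes6(m.facet_sets["ymax"]), 1.0, m.nodes)
        assert np.allclose(f.sum(axis=0), [0.0, -16.0, 0.0], atol=1e-12)

    def test_closed_surface_has_zero_resultant(self):
        m = structured_box(3.0, 5.0, 2.0, nx=2, ny=2, nz=2)
        f = follower_pressure_forces(m.facet_nodes6(m.boundary_facets()), 1.0, m.nodes)
        assert np.abs(f.sum(axis=0)).max() < 1e-12

    def test_cylindrical_cap_axial_resultant(self):
        # pressure on the curved outer wall of a tube sector integrates to
        # the projected-area resultant p * (projected width x length)
        from cogsim.synthetic import CanalGeometrySpec, generate_canal_geometry

        spec = CanalGeometrySpec(
            length=20.0, inner_radius=10.0, wall_thickness=2.0,
            mesh_edge=5.0, dome_fraction=0.0,
        )
        m = generate_canal_geometry(spec)
        nodes6 = m.facet_nodes6(m.facet_sets["anterior_wall"])
        f = follower_pressure_forces(nodes6, 1.0, m.nodes).sum(axis=0)
        # independent oracle: flat-triangle vector areas from the corner
        # coordinates (plain cross products, no shape functions)
        tri = m.facet_corner_triples(m.facet_sets["anterior_wall"])
        v = m.nodes[tri]
        vec_area = 0.5 * np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]).sum(axis=0)
        assert np.allclose(f, -vec_area, rtol=1e-9)
        assert f[0] < 0  # resultant pushes the anterior wall inward (-x)


class TestContact:
    def test_no_contact_gives_zero_forces(self):
        sph = RigidSphere((0, 10, 0), (0, 5, 0), 1.0, 100.0)
        f, reaction = contact_residual(sph, 0.0, np.array([[0.0, 0.0, 0.0]]), np.zeros((1, 3)))
        assert np.all(f == 0) and np.all(reaction == 0)

    def test_linear_penalty_force(self):
        # node penetrating 0.01 mm with penalty 1000 N/mm -> 10 N radial
        sph = RigidSphere((0, 1.0, 0), (0, 1.0, 0), 1.0, 1000.0)
        x = np.array([[0.0, 0.01, 0.0]])  # distance 0.99, penetration 0.01
        f, reaction = contact_residual(sph, 0.0, x, np.zeros((1, 3)))
        assert np.linalg.norm(f[0]) == pytest.approx(10.0, rel=1e-12)
        assert np.allclose(f[0], [0, -10.0, 0], atol=1e-12)
        assert np.allclose(reaction, [0, 10.0, 0], atol=1e-12)

    def test_block_pressed_by_sphere_global_force_balance(self, tissue):
        m = structured_box(10.0, 5.0, 10.0, nx=2, ny=1, nz=2)
        sph = RigidSphere((0, 13.0, 0), (0, 12.0, 0), 8.0, 50.0)
        model = assemble_model(m, tissue, [encastre("ymin")], sphere=sph)
        sol = solve_static(model, n_increments=4)
        assert sol.converged
        base = sol.reactions.sum(axis=0)
        assert np.abs(base - sol.sphere_reaction).max() < 1e-6 * np.abs(base).max()


class TestAssembly:
    def test_unknown_set_rejected(self, pinned_bar, tissue):
        with pytest.raises(KeyError):
            assemble_model(pinned_bar, tissue, [encastre("nonexistent")])

    def test_thread_point_outside_mesh_rejected(self, pinned_bar, tissue):
        path = np.array([[0.0, 1.0, 0.0], [0.0, 20.0, 0.0]])
        with pytest.raises(ValueError, match="outside"):
            assemble_model(
                pinned_bar, tissue, [encastre("ymin")],
                threads=[EmbeddedThread(path, 10.0)],
            )

    def test_zero_load_gives_zero_solution(self, pinned_bar, tissue):
        model = assemble_model(pinned_bar, tissue, [encastre("ymin")])
        sol = solve_static(model, n_increments=1)
        assert sol.converged
        assert np.abs(sol.displacements).max() == 0.0
        assert np.abs(sol.reactions).max() < 1e-12


class TestPatch:
    def test_linear_patch_reproduces_affine_field(self):
        # affine boundary displacement on every boundary node: interior
        # must follow the same affine map to machine-ish precision
        m = structured_box(2.0, 3.0, 2.0, nx=2, ny=2, nz=2)
        A = np.array([[0.001, 0.0004, 0.0], [0.0002, -0.0005, 0.0003], [0.0, 0.0001, 0.0008]])
        bnd = m.boundary_node_indices()
        m.add_node_set("boundary", bnd)
        u_exact = m.nodes @ A.T
        con_sets = [
            BoundaryCondition("boundary", ("x",)),
            BoundaryCondition("boundary", ("y",)),
            BoundaryCondition("boundary", ("z",)),
        ]
        model = assemble_model(m, THREAD_LINEAR_ELASTIC, con_sets)
        u0 = np.zeros(model.ndof)
        u0.reshape(-1, 3)[bnd] = u_exact[bnd]
        # prescribed values enter through con_vals: set them directly
        model.con_vals = u0[model.con_dofs]
        sol = solve_static(model, n_increments=1)
        assert sol.converged
        err = np.abs(sol.displacements - u_exact).max()
        assert err < 1e-8 * np.abs(u_exact).max()

    def test_ogden_patch_reproduces_affine_field(self, tissue):
        m = structured_box(2.0, 3.0, 2.0, nx=1, ny=2, nz=1)
        # volume-preserving affine map (the penalty term stays small)
        A = np.diag([1.05, 1.0 / 1.05**2, 1.05]) - np.eye(3)
        bnd = m.boundary_node_indices()
        m.add_node_set("boundary", bnd)
        u_exact = m.nodes @ A.T
        model = assemble_model(
            m, tissue,
            [BoundaryCondition("boundary", ("x", "y", "z"))],
        )
        u0 = np.zeros(model.ndof)
        u0.reshape(-1, 3)[bnd] = u_exact[bnd]
        model.con_vals = u0[model.con_dofs]
        sol = solve_static(model, n_increments=2)
        assert sol.converged
        err = np.abs(sol.displacements - u_exact).max()
        assert err < 1e-6 * np.abs(u_exact).max()


class TestBarOracles:
    def test_linear_bar_recovers_hookes_law(self, pinned_bar):
        model, sol = solve_bar_stretch(pinned_bar, THREAD_LINEAR_ELASTIC, 1.001, 1)
        assert sol.converged
        F_top = sol.reactions[pinned_bar.node_sets["ymax"], 1].sum()
        sigma = F_top / 4.0  # 2 x 2 mm section
        assert sigma == pytest.approx(367.69 * 0.001, rel=1e-3)

    @pytest.mark.parametrize("stretch", [1.05, 1.1, 1.2])
    def test_ogden_bar_matches_closed_form_within_penalty_gap(self, pinned_bar, tissue, stretch):
        model, sol = solve_bar_stretch(pinned_bar, tissue, stretch, 6)
        assert sol.converged
        F_top = sol.reactions[pinned_bar.node_sets["ymax"], 1].sum()
        nominal = F_top / 4.0
        assert nominal == pytest.approx(
            ogden_uniaxial_nominal(tissue, stretch), rel=0.02
        )

    def test_newton_quadratic_convergence_tail(self, pinned_bar, tissue):
        model, sol = solve_bar_stretch(pinned_bar, tissue, 1.1, 2)
        assert sol.converged
        res = sol.increments[-1]["residuals"]
        assert len(res) >= 3
        r1, r2, r3 = res[-3], res[-2], res[-1]
        # quadratic tail: the contraction constant from the previous pair
        # bounds the final one within an order of magnitude
        C = r2 / r1**2
        assert r3 <= 10.0 * C * r2**2

    def test_objectivity_under_rigid_rotation(self, tissue):
        # rotating mesh and boundary conditions rotates the solution
        mesh = make_pinned_bar(nx=1, ny=2, nz=1)
        model, sol = solve_bar_stretch(mesh, tissue, 1.1, 2)
        th = 0.7
        R = np.array(
            [
                [np.cos(th), -np.sin(th), 0.0],
                [np.sin(th), np.cos(th), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rot = make_pinned_bar(nx=1, ny=2, nz=1)
        rot.nodes = mesh.nodes @ R.T
        stretch_disp = 0.1 * 10.0
        d = R @ np.array([0.0, stretch_disp, 0.0])
        # constrain every component of the end faces along the rotated axes
        model_r = assemble_model(
            rot, tissue,
            [
                encastre("ymin"),
                BoundaryCondition("ymax", ("x", "y", "z"), {"x": d[0], "y": d[1], "z": d[2]}),
            ],
        )
        sol_r = solve_static(model_r, n_increments=2)
        assert sol_r.converged
        # compare against the unrotated problem with the same encastre grips
        model_s = assemble_model(
            mesh, tissue,
            [
                encastre("ymin"),
                BoundaryCondition("ymax", ("x", "y", "z"), {"y": stretch_disp}),
            ],
        )
        sol_s = solve_static(model_s, n_increments=2)
        assert sol_s.converged
        expected = sol_s.displacements @ R.T
        err = np.abs(sol_r.displacements - expected).max()
        assert err < 1e-6 * np.abs(expected).max()

    def test_mesh_convergence_thick_walled_tube(self):
        # plane-strain Lame tube under internal pressure: displacement
        # error decreases monotonically under uniform refinement
        from cogsim.mesh import TetMesh, annulus_section, extrude_to_tets, linear_to_quadratic

        a, b, p, L = 10.0, 14.0, 0.01, 4.0
        mat = LinearElasticParameters(youngs_modulus=10.0, poissons_ratio=0.3)
        E, nu = mat.youngs_modulus, mat.poissons_ratio
        A_ = p * a**2 / (b**2 - a**2)
        B_ = p * a**2 * b**2 / (b**2 - a**2)
        u_exact_inner = (1 + nu) / E * ((1 - 2 * nu) * A_ * a + B_ / a)
        errors = []
        for n_theta, n_rad, n_ax in [(12, 1, 2), (24, 2, 2), (48, 4, 2)]:
            pts2d, tris = annulus_section(n_theta, n_rad, a, b)
            ys = np.linspace(0, L, n_ax + 1)
            coords = np.stack(
                [np.column_stack([pts2d[:, 0], np.full(len(pts2d), y), pts2d[:, 1]]) for y in ys]
            )
            nodes, tets = extrude_to_tets(coords, tris)
            nodes, elems = linear_to_quadratic(nodes, tets)
            mesh = TetMesh(nodes, elems)
            tol = 1e-9
            mesh.add_node_set("ends", np.abs(nodes[:, 1] * (nodes[:, 1] - L)) < tol)
            r = np.hypot(nodes[:, 0], nodes[:, 2])
            i0 = int(np.argmin(np.abs(r - a) + np.abs(nodes[:, 2]) + np.abs(nodes[:, 1])))
            i1 = int(np.argmin(np.abs(r - a) + np.abs(nodes[:, 0]) + np.abs(nodes[:, 1])))
            mesh.add_node_set("pin0", [i0])
            mesh.add_node_set("pin1", [i1])
            mesh.add_facet_set_where(
                "inner", lambda c: np.hypot(c[:, 0], c[:, 2]) < a + 0.2 * (b - a)
            )
            model = assemble_model(
                mesh, mat,
                [
                    BoundaryCondition("ends", ("y",)),
                    BoundaryCondition("pin0", ("z",)),
                    BoundaryCondition("pin1", ("x",)),
                ],
                loads=[PressureLoad("inner", p, follower=False)],
            )
            sol = solve_static(model, n_increments=1)
            assert sol.converged
            ur = np.hypot(
                nodes[:, 0] + sol.displacements[:, 0], nodes[:, 2] + sol.displacements[:, 2]
            ) - np.hypot(nodes[:, 0], nodes[:, 2])
            inner_nodes = np.hypot(nodes[:, 0], nodes[:, 2]) < a + 1e-6
            errors.append(abs(ur[inner_nodes].mean() - u_exact_inner))
        assert errors[0] > errors[1] > errors[2]


class TestEmbeddedThreads:
    def test_embedding_weights_partition_of_unity(self, pinned_bar, tissue):
        path = np.array([[0.0, 1.0, 0.0], [0.0, 5.0, 0.0], [0.0, 9.0, 0.0]])
        model = assemble_model(
            pinned_bar, tissue, [encastre("ymin")],
            threads=[EmbeddedThread(path, 5.0)],
        )
        _, T, _ = model._threads[0]
        row_sums = np.asarray(T.sum(axis=1)).ravel()
        assert np.allclose(row_sums, 1.0, atol=1e-12)

    def test_thread_stiffens_stretched_bar(self, tissue):
        mesh = make_pinned_bar(nx=1, ny=2, nz=1)
        path = np.array([[0.0, 0.5, 0.0], [0.0, 9.5, 0.0]])
        bcs = lambda: [
            BoundaryCondition("ymin", ("y",)),
            BoundaryCondition("ymax", ("y",), {"y": 1.0}),
            BoundaryCondition("pin0", ("x", "z")),
            BoundaryCondition("pin1", ("z",)),
        ]
        bare = solve_static(assemble_model(mesh, tissue, bcs()), n_increments=4)
        reinforced = solve_static(
            assemble_model(
                mesh, tissue, bcs(), threads=[EmbeddedThread(path, 50.0)]
            ),
            n_increments=4,
        )
        assert bare.converged and reinforced.converged
        f_bare = bare.reactions[mesh.node_sets["ymax"], 1].sum()
        f_reinf = reinforced.reactions[mesh.node_sets["ymax"], 1].sum()
        assert f_reinf > f_bare * 1.02


class TestMetrics:
    def test_metric_requires_convergence(self, pinned_bar, tissue):
        from cogsim.fem import SolutionField

        sol = SolutionField(
            displacements=np.zeros((pinned_bar.n_nodes, 3)),
            reactions=np.zeros((pinned_bar.n_nodes, 3)),
            sphere_reaction=np.zeros(3),
            converged=False,
            increments=[],
        )
        with pytest.raises(RuntimeError):
            extract_displacement_metric(sol, pinned_bar, "ymax", "x")

    def test_metric_on_prescribed_field(self, pinned_bar):
        from cogsim.fem import SolutionField

        disp = np.zeros((pinned_bar.n_nodes, 3))
        disp[pinned_bar.node_sets["ymax"], 0] = -2.5
        sol = SolutionField(
            displacements=disp,
            reactions=np.zeros_like(disp),
            sphere_reaction=np.zeros(3),
            converged=True,
            increments=[],
        )
        out = extract_displacement_metric(sol, pinned_bar, "ymax", "x")
        assert out["max"] == pytest.approx(2.5)
        assert out["mean"] == pytest.approx(2.5)
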