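"""Static nonlinear finite elements on 10-node tetrahedra.

A compact total-Lagrangian solver sufficient for the three simulation
classes of this package: uniaxial thread tension, cough-pressure
loading of the vaginal canal, and rigid-sphere ball-burst indentation.

Formulation
-----------
* 10-node tetrahedra, 4-point Gauss quadrature.
* Ogden hyperelasticity evaluated in principal stretches through an
  eigen-decomposition of the right Cauchy-Green tensor, with an
  isochoric/volumetric split and a quadratic volumetric penalty
  U(J) = kappa/2 (J-1)^2 (near-incompressibility, default
  kappa = 1000 * mu0).  The spectral material tangent uses the
  divided-difference construction with an analytic limit when
  eigenvalues coincide within a 1e-9 relative gap.
* Linear-elastic materials use the small-strain engineering measure
  (geometrically linear), appropriate for the stiff PCL threads whose
  simulations stay below a few percent strain; a displacement-driven
  linear problem then converges in a single Newton iteration.
* Pressure loads integrate p*n dA over the deformed (follower,
  default) or reference surface with quadratic facet quadrature.  The
  follower-load stiffness is omitted from the tangent (the load terms
  are small against the material stiffness at the pressures of
  interest), so convergence on pressure-driven problems is slightly
  sub-quadratic; displacement-driven problems retain full Newton.
* Frictionless rigid-sphere contact by a node-to-analytic-surface
  penalty: a node penetrating by g > 0 feels force penalty*g along the
  outward radial direction.
* Embedded threads are polylines of geometrically nonlinear axial
  (truss) segments tied to the host elements through the element
  interpolation at each path point (no relative motion).

Units are mm-N-MPa throughout; axes: x antero-posterior,
y supero-inferior, z lateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (
    LinearElasticParameters,
    OgdenParameters,
    _term_coeffs,
    initial_shear_modulus,
)
from .mesh import TetMesh, tet10_shape_grad

__all__ = [
    "BoundaryCondition",
    "encastre",
    "PressureLoad",
    "RigidSphere",
    "EmbeddedThread",
    "SolutionField",
    "ModelAssembly",
    "OgdenMaterial",
    "LinearElasticMaterial",
    "assemble_model",
    "solve_static",
    "contact_residual",
    "follower_pressure_forces",
    "extract_displacement_metric",
]

_AXIS = {"x": 0, "y": 1, "z": 2}

# 4-point rule on the reference tetrahedron (degree 2), barycentric
_QA = 0.5854101966249685
_QB = 0.1381966011250105
_QPOINTS = np.array(
    [
        [_QA, _QB, _QB, _QB],
        [_QB, _QA, _QB, _QB],
        [_QB, _QB, _QA, _QB],
        [_QB, _QB, _QB, _QA],
    ]
)
_QWEIGHTS = np.full(4, 1.0 / 24.0)  # reference volume 1/6


# ---------------------------------------------------------------------------
# boundary conditions / loads


@dataclass(frozen=True)
class BoundaryCondition:
    """Dirichlet constraint on a named node set.

    ``prescribed`` maps each constrained axis to its final displacement
    (mm); missing axes of ``constrained_axes`` are held at zero.
    """

    node_set: str
    constrained_axes: tuple[str, ...]
    prescribed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.constrained_axes:
            raise ValueError("constrained_axes must be non-empty")
        for ax in self.constrained_axes:
            if ax not in _AXIS:
                raise ValueError(f"unknown axis {ax!r}")


def encastre(node_set: str) -> BoundaryCondition:
    """Fully fixed support (all displacement components zero)."""
    return BoundaryCondition(node_set=node_set, constrained_axes=("x", "y", "z"))


@dataclass(frozen=True)
class PressureLoad:
    facet_set: str
    magnitude: float  # MPa, positive pushes against the outward normal
    follower: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.magnitude):
            raise ValueError("pressure magnitude must be finite")


@dataclass(frozen=True)
class RigidSphere:
    """Analytic rigid sphere; its centre moves linearly with the load factor."""

    center_start: tuple[float, float, float]
    center_end: tuple[float, float, float]
    radius: float
    contact_penalty: float  # N/mm per node
    node_set: str | None = None  # default: all boundary nodes

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.contact_penalty <= 0:
            raise ValueError("contact penalty must be positive")

    def center(self, load_factor: float) -> np.ndarray:
        a = np.asarray(self.center_start, dtype=float)
        b = np.asarray(self.center_end, dtype=float)
        return a + load_factor * (b - a)


@dataclass(frozen=True)
class EmbeddedThread:
    """Polyline of tied axial-stiffness segments inside the host mesh.

    Segments are tension-only by default (a slender suture sheds
    compressive load by buckling); set ``carries_compression`` to model
    a strut that pushes as well as pulls.
    """

    path: np.ndarray  # (p, 3) mm, all points inside the host volume
    axial_stiffness: float  # EA, N
    coupling: str = "tied"
    carries_compression: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", np.ascontiguousarray(self.path, dtype=float))
        if self.path.ndim != 2 or self.path.shape[1] != 3 or len(self.path) < 2:
            raise ValueError("path must be an (p>=2, 3) array")
        if self.axial_stiffness <= 0:
            raise ValueError("axial_stiffness must be positive")
        if self.coupling != "tied":
            raise ValueError("only tied coupling is implemented")


@dataclass
class SolutionField:
    """Converged (or partially converged) static solution."""

    displacements: np.ndarray  # (n_nodes, 3) mm
    reactions: np.ndarray  # (n_nodes, 3) N, nonzero only at constrained dofs
    sphere_reaction: np.ndarray  # (3,) N, force exerted on the sphere
    converged: bool
    increments: list[dict]  # per-increment {"t", "residuals": [...]}
    load_factor: float = 1.0


# ---------------------------------------------------------------------------
# materials


class OgdenMaterial:
    """Near-incompressible Ogden material for the total-Lagrangian solver."""

    def __init__(self, params: OgdenParameters, kappa: float | None = None):
        self.params = params
        self.mu0 = initial_shear_modulus(params)
        self.kappa = 1000.0 * self.mu0 if kappa is None else float(kappa)
        c, a = _term_coeffs(params)
        self._c = np.asarray(c)
        self._a = np.asarray(a)

    # -- scalar energy derivatives in principal stretches -------------------

    def _w_derivs(self, lam: np.ndarray):
        """First and second derivatives of W(l1,l2,l3); lam is (n, 3)."""
        c, a = self._c, self._a
        J = np.prod(lam, axis=1)  # (n,)
        lb = lam * J[:, None] ** (-1.0 / 3.0)
        e = lb[:, :, None] ** a[None, None, :]  # (n,3,t)
        g = e.sum(axis=1)  # (n,t)
        dev = e - g[:, None, :] / 3.0  # (n,3,t)
        inv_l = 1.0 / lam  # (n,3)
        # dW/dl_j = sum_t c a dev_j / l_j
        W1 = np.einsum("t,njt->nj", c * a, dev) * inv_l
        # d2W/dl_j dl_k
        delta = np.eye(3)
        term_a = np.einsum("t,njt,jk->njk", c * a * a, e, delta - 1.0 / 3.0)
        term_b = -np.einsum("t,nkt->nk", c * a * a, dev)[:, None, :] / 3.0
        W2 = (term_a + term_b) * inv_l[:, :, None] * inv_l[:, None, :]
        W2 -= np.einsum("t,njt->nj", c * a, dev)[:, :, None] * delta * inv_l[:, :, None] ** 2
        # volumetric penalty
        k = self.kappa
        W1 = W1 + k * (J * (J - 1.0))[:, None] * inv_l
        W2 = W2 + k * (J * J + J * (J - 1.0))[:, None, None] * inv_l[:, :, None] * inv_l[:, None, :]
        W2 -= (k * J * (J - 1.0))[:, None, None] * np.eye(3) * inv_l[:, :, None] ** 2
        return W1, W2

    def pk2_and_tangent(self, C: np.ndarray):
        """Second Piola-Kirchhoff stress and C^SE = 2 dS/dC, batched."""
        cval, cvec = np.linalg.eigh(C)
        cval = np.clip(cval, 1e-12, None)
        # spread coincident eigenvalues apart by a tiny relative gap
        gap_tol = 1e-9
        lam = np.sqrt(cval)
        W1, W2 = self._w_derivs(lam)
        S_a = W1 / lam
        dSdl = W2 / lam[:, :, None]
        dSdl -= np.eye(3) * (W1 / lam**2)[:, :, None]
        # stress: S = Q diag(S_a) Q^T
        S = np.einsum("nia,na,nja->nij", cvec, S_a, cvec)
        # tangent assembled as a core tensor in the eigenbasis, then
        # rotated into the reference frame (much cheaper than forming
        # the eigenprojection outer products explicitly)
        n = C.shape[0]
        coef1 = dSdl / lam[:, None, :]
        coef2 = np.zeros((n, 3, 3))
        for a in range(3):
            for b in range(3):
                if a == b:
                    continue
                dc = cval[:, b] - cval[:, a]
                small = np.abs(dc) <= gap_tol * np.maximum(cval[:, a], cval[:, b])
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = (S_a[:, b] - S_a[:, a]) / dc
                lim = (dSdl[:, b, b] - dSdl[:, a, b]) / (2.0 * lam[:, b])
                coef2[:, a, b] = np.where(small, lim, ratio)
        D = np.zeros((n, 3, 3, 3, 3))
        for a in range(3):
            for b in range(3):
                if a == b:
                    D[:, a, a, b, b] = coef1[:, a, b]
                else:
                    D[:, a, a, b, b] = coef1[:, a, b]
                    D[:, a, b, a, b] += coef2[:, a, b]
                    D[:, a, b, b, a] += coef2[:, a, b]
        Q = cvec  # Q[:, i, a]: component i of eigenvector a
        CSE = np.einsum("nia,nabcd->nibcd", Q, D)
        CSE = np.einsum("njb,nibcd->nijcd", Q, CSE)
        CSE = np.einsum("nkc,nijcd->nijkd", Q, CSE)
        CSE = np.einsum("nld,nijkd->nijkl", Q, CSE)
        return S, CSE

    def pk1_and_tangent(self, F: np.ndarray):
        """First Piola-Kirchhoff stress P and A = dP/dF, batched over F (n,3,3)."""
        C = np.einsum("nki,nkj->nij", F, F)
        S, CSE = self.pk2_and_tangent(C)
        P = np.einsum("nik,nkj->nij", F, S)
        delta = np.eye(3)
        A = np.einsum("ij,nKL->niKjL", delta, S)
        A = A + np.einsum("niM,nMKNL,njN->niKjL", F, CSE, F)
        return P, A

    def pk1(self, F: np.ndarray) -> np.ndarray:
        """Stress only (fast path for line-search residual evaluations)."""
        C = np.einsum("nki,nkj->nij", F, F)
        cval, cvec = np.linalg.eigh(C)
        cval = np.clip(cval, 1e-12, None)
        lam = np.sqrt(cval)
        W1 = self._w_first(lam)
        S = np.einsum("nia,na,nja->nij", cvec, W1 / lam, cvec)
        return np.einsum("nik,nkj->nij", F, S)

    def _w_first(self, lam: np.ndarray) -> np.ndarray:
        c, a = self._c, self._a
        J = np.prod(lam, axis=1)
        lb = lam * J[:, None] ** (-1.0 / 3.0)
        e = lb[:, :, None] ** a[None, None, :]
        g = e.sum(axis=1)
        dev = e - g[:, None, :] / 3.0
        inv_l = 1.0 / lam
        W1 = np.einsum("t,njt->nj", c * a, dev) * inv_l
        return W1 + self.kappa * (J * (J - 1.0))[:, None] * inv_l

    def energy_density(self, lam3: np.ndarray) -> np.ndarray:
        """W at principal stretches (n, 3), penalty included."""
        c, a = self._c, self._a
        J = np.prod(lam3, axis=1)
        lb = lam3 * J[:, None] ** (-1.0 / 3.0)
        Wi = np.einsum("t,nt->n", c, np.sum(lb[:, :, None] ** a, axis=1) - 3.0)
        return Wi + 0.5 * self.kappa * (J - 1.0) ** 2


class LinearElasticMaterial:
    """Small-strain isotropic elasticity (geometrically linear)."""

    def __init__(self, params: LinearElasticParameters):
        self.params = params
        self.lam = params.lame_lambda
        self.mu = params.lame_mu
        d = np.eye(3)
        self._A = self.lam * np.einsum("iK,jL->iKjL", d, d) + self.mu * (
            np.einsum("ij,KL->iKjL", d, d) + np.einsum("iL,Kj->iKjL", d, d)
        )

    def pk1_and_tangent(self, F: np.ndarray):
        eps = 0.5 * (F + np.swapaxes(F, 1, 2)) - np.eye(3)
        tr = np.trace(eps, axis1=1, axis2=2)
        sig = self.lam * tr[:, None, None] * np.eye(3) + 2.0 * self.mu * eps
        A = np.broadcast_to(self._A, F.shape[:1] + self._A.shape)
        return sig, A


def material_for(params) -> OgdenMaterial | LinearElasticMaterial:
    if isinstance(params, OgdenParameters):
        return OgdenMaterial(params)
    if isinstance(params, LinearElasticParameters):
        return LinearElasticMaterial(params)
    raise TypeError(f"unsupported material parameters: {type(params)!r}")


# ---------------------------------------------------------------------------
# standalone force kernels (also used inside the assembly)


def contact_residual(
    sphere: RigidSphere,
    load_factor: float,
    coords: np.ndarray,
    displacements: np.ndarray,
):
    """Penalty contact forces of a rigid sphere on a set of nodes.

    Returns (forces (k, 3) N on the nodes, sphere_reaction (3,) N).
    Nodes outside the sphere contribute zero.
    """
    x = np.asarray(coords, dtype=float) + np.asarray(displacements, dtype=float)
    c = sphere.center(load_factor)
    d = x - c
    dist = np.linalg.norm(d, axis=1)
    dist = np.maximum(dist, 1e-12)
    g = sphere.radius - dist
    active = g > 0
    f = np.zeros_like(x)
    f[active] = (sphere.contact_penalty * g[active] / dist[active])[:, None] * d[active]
    return f, -f.sum(axis=0)


_TRI6_Q = np.array([[1.0 / 6, 1.0 / 6], [2.0 / 3, 1.0 / 6], [1.0 / 6, 2.0 / 3]])
_TRI6_W = np.full(3, 1.0 / 6.0)


def _tri6_shape_and_grads(xi: float, eta: float):
    z = np.array([1.0 - xi - eta, xi, eta])
    dz = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # dz_i/d(xi,eta)
    N = np.empty(6)
    dN = np.empty((6, 2))
    for i in range(3):
        N[i] = z[i] * (2 * z[i] - 1)
        dN[i] = (4 * z[i] - 1) * dz[i]
    pairs = ((0, 1), (1, 2), (2, 0))
    for k, (a, b) in enumerate(pairs):
        N[3 + k] = 4 * z[a] * z[b]
        dN[3 + k] = 4 * (z[a] * dz[b] + z[b] * dz[a])
    return N, dN


_TRI6_N = []
_TRI6_DN = []
for _xi, _eta in _TRI6_Q:
    _n, _dn = _tri6_shape_and_grads(_xi, _eta)
    _TRI6_N.append(_n)
    _TRI6_DN.append(_dn)
_TRI6_N = np.array(_TRI6_N)  # (3, 6)
_TRI6_DN = np.array(_TRI6_DN)  # (3, 6, 2)


def follower_pressure_forces(
    facet_nodes6: np.ndarray, magnitude: float, coords: np.ndarray
) -> np.ndarray:
    """Consistent nodal forces of a uniform pressure on quadratic facets.

    facet_nodes6 : (f, 6) global node ids of the facets (outward wound);
    coords : (n, 3) node positions (deformed for a follower load,
    reference otherwise).  Returns (n, 3) global force array; positive
    ``magnitude`` pushes against the outward normal.
    """
    xf = coords[facet_nodes6]  # (f, 6, 3)
    forces = np.zeros_like(coords)
    for q in range(3):
        dN = _TRI6_DN[q]  # (6,2)
        t1 = np.einsum("fak,a->fk", xf, dN[:, 0])
        t2 = np.einsum("fak,a->fk", xf, dN[:, 1])
        nvec = np.cross(t1, t2)  # outward, |n| = 2*area jacobian
        contrib = -magnitude * _TRI6_W[q] * np.einsum("a,fk->fak", _TRI6_N[q], nvec)
        np.add.at(forces, facet_nodes6.ravel(), contrib.reshape(-1, 3))
    return forces


# ---------------------------------------------------------------------------
# model assembly


class ModelAssembly:
    """Immutable assembly: DOF numbering, constraints, loads, embeddings."""

    def __init__(
        self,
        mesh: TetMesh,
        material,
        bcs: list[BoundaryCondition],
        loads: list[PressureLoad] | None = None,
        sphere: RigidSphere | None = None,
        threads: list[EmbeddedThread] | None = None,
    ):
        mesh.validate()
        self.mesh = mesh
        self.material_params = material
        self.material = material_for(material)
        self.bcs = list(bcs)
        self.loads = list(loads or [])
        self.sphere = sphere
        self.threads = list(threads or [])
        self.ndof = 3 * mesh.n_nodes

        # quadrature geometry
        G = tet10_shape_grad(_QPOINTS)  # (4, 10, 3)
        Xe = mesh.nodes[mesh.elements]  # (e, 10, 3)
        J = np.einsum("eai,qaj->eqij", Xe, G)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("non-positive Jacobian at a quadrature point")
        Jinv = np.linalg.inv(J)
        self.dNdX = np.einsum("qaj,eqji->eqai", G, Jinv)  # (e,4,10,3)
        self.wdet = detJ * _QWEIGHTS[None, :]  # (e,4)
        # strain-displacement operator B[e,q,3i+K,3b+j] = delta_ij dN_b/dX_K,
        # so that vec(F)-I = B u_e and K_e = sum_q w B^T A B (A as 9x9)
        e_, q_ = self.dNdX.shape[:2]
        B = np.zeros((e_, q_, 9, 30))
        for i in range(3):
            for K in range(3):
                for b in range(10):
                    B[:, :, 3 * i + K, 3 * b + i] = self.dNdX[:, :, b, K]
        self._B = B

        # physical cap for a single Newton displacement update (mm)
        bbox = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
        self.step_cap = 0.05 * float(np.linalg.norm(bbox))

        # dof maps for sparse assembly
        edofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 30)
        self._edofs = edofs
        self._rows = np.repeat(edofs, 30, axis=1).ravel()
        self._cols = np.tile(edofs, (1, 30)).ravel()

        # constraints
        con: dict[int, float] = {}
        for bc in self.bcs:
            if bc.node_set not in mesh.node_sets:
                raise KeyError(f"unknown node set {bc.node_set!r}")
            idx = mesh.node_sets[bc.node_set]
            for ax in bc.constrained_axes:
                val = float(bc.prescribed.get(ax, 0.0))
                for nid in idx:
                    con[3 * int(nid) + _AXIS[ax]] = val
        self.con_dofs = np.array(sorted(con), dtype=np.int64)
        self.con_vals = np.array([con[d] for d in sorted(con)])
        free = np.ones(self.ndof, dtype=bool)
        free[self.con_dofs] = False
        self.free_dofs = np.flatnonzero(free)

        # pressure facets
        self._pressure = []
        for load in self.loads:
            if load.facet_set not in mesh.facet_sets:
                raise KeyError(f"unknown facet set {load.facet_set!r}")
            nodes6 = mesh.facet_nodes6(mesh.facet_sets[load.facet_set])
            self._pressure.append((load, nodes6))

        # sphere contact nodes
        if sphere is not None:
            if sphere.node_set is not None:
                if sphere.node_set not in mesh.node_sets:
                    raise KeyError(f"unknown node set {sphere.node_set!r}")
                self._contact_nodes = mesh.node_sets[sphere.node_set]
            else:
                self._contact_nodes = mesh.boundary_node_indices()
        else:
            self._contact_nodes = None

        # thread embeddings: sparse tie operator per thread
        self._threads = []
        for th in self.threads:
            try:
                elems, shape = mesh.locate_points(th.path)
            except ValueError as err:
                raise ValueError(f"thread path point outside mesh: {err}") from err
            p = len(th.path)
            rows = np.repeat(np.arange(3 * p).reshape(p, 3)[:, :, None], 10, axis=2)
            cols = (3 * mesh.elements[elems][:, None, :] + np.arange(3)[None, :, None])
            data = np.broadcast_to(shape[:, None, :], (p, 3, 10))
            T = sp.coo_matrix(
                (data.ravel(), (rows.ravel(), cols.ravel())), shape=(3 * p, self.ndof)
            ).tocsr()
            seg_len0 = np.linalg.norm(np.diff(th.path, axis=0), axis=1)
            if np.any(seg_len0 <= 0):
                raise ValueError("thread path has zero-length segments")
            self._threads.append((th, T, seg_len0))

    # -- assembly of residual and tangent -----------------------------------

    def _bulk(self, u: np.ndarray, tangent: bool = True):
        mesh = self.mesh
        Ue = u.reshape(-1, 3)[mesh.elements]  # (e,10,3)
        F = np.einsum("eai,eqaJ->eqiJ", Ue, self.dNdX)
        F = F + np.eye(3)
        shp = F.shape
        if tangent or not hasattr(self.material, "pk1"):
            P, A = self.material.pk1_and_tangent(F.reshape(-1, 3, 3))
        else:
            P, A = self.material.pk1(F.reshape(-1, 3, 3)), None
        P = P.reshape(shp)
        P9 = P.reshape(shp[:2] + (9,))
        fint_e = np.einsum("eq,eqi,eqia->ea", self.wdet, P9, self._B)
        fint = np.zeros(self.ndof)
        np.add.at(fint, self._edofs.ravel(), fint_e.ravel())
        K = None
        if tangent:
            A9 = A.reshape(shp[:2] + (9, 9))
            AB = np.matmul(A9, self._B)  # (e,q,9,30)
            AB *= self.wdet[..., None, None]
            Ke = np.einsum("eqia,eqib->eab", self._B, AB)
            K = sp.coo_matrix(
                (Ke.reshape(-1, 900).ravel(), (self._rows, self._cols)),
                shape=(self.ndof, self.ndof),
            ).tocsr()
        return fint, K

    def _thread_forces(self, u: np.ndarray, tangent: bool = True):
        fint = np.zeros(self.ndof)
        blocks = []
        for th, T, L0 in self._threads:
            up = (T @ u).reshape(-1, 3)
            x = th.path + up
            d = np.diff(x, axis=0)
            l = np.linalg.norm(d, axis=1)
            l = np.maximum(l, 1e-12)
            n = d / l[:, None]
            strain = (l - L0) / L0
            taut = np.ones_like(strain) if th.carries_compression else (strain > 0.0)
            Nf = th.axial_stiffness * strain * taut
            p = len(th.path)
            fp = np.zeros((p, 3))
            seg_f = Nf[:, None] * n
            np.add.at(fp, np.arange(p - 1), -seg_f)
            np.add.at(fp, np.arange(1, p), seg_f)
            fint += T.T @ fp.ravel()
            if tangent:
                EA = th.axial_stiffness * taut
                eye = np.eye(3)
                k_seg = (EA / L0)[:, None, None] * np.einsum("si,sj->sij", n, n)
                k_seg += (Nf / l)[:, None, None] * (eye - np.einsum("si,sj->sij", n, n))
                Kp = np.zeros((3 * p, 3 * p))
                for s in range(p - 1):
                    sl0 = slice(3 * s, 3 * s + 3)
                    sl1 = slice(3 * s + 3, 3 * s + 6)
                    Kp[sl0, sl0] += k_seg[s]
                    Kp[sl1, sl1] += k_seg[s]
                    Kp[sl0, sl1] -= k_seg[s]
                    Kp[sl1, sl0] -= k_seg[s]
                blocks.append(T.T @ sp.csr_matrix(Kp) @ T)
        Ksum = None
        if tangent and blocks:
            Ksum = blocks[0]
            for b in blocks[1:]:
                Ksum = Ksum + b
        return fint, Ksum

    def _contact(self, u: np.ndarray, load_factor: float, tangent: bool = True):
        idx = self._contact_nodes
        sphere = self.sphere
        X = self.mesh.nodes[idx]
        U = u.reshape(-1, 3)[idx]
        f_nodes, sphere_reaction = contact_residual(sphere, load_factor, X, U)
        fext = np.zeros(self.ndof)
        dofs = (3 * idx[:, None] + np.arange(3)).ravel()
        fext[dofs] = f_nodes.ravel()
        K = None
        if tangent:
            x = X + U
            c = sphere.center(load_factor)
            d = x - c
            dist = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
            g = sphere.radius - dist
            active = np.flatnonzero(g > 0)
            if active.size:
                n = d[active] / dist[active][:, None]
                k = sphere.contact_penalty
                nn = np.einsum("si,sj->sij", n, n)
                kb = k * (nn - (g[active] / dist[active])[:, None, None] * (np.eye(3) - nn))
                rows = (3 * idx[active][:, None, None] + np.arange(3)[None, :, None])
                rows = np.broadcast_to(rows, kb.shape)
                cols = (3 * idx[active][:, None, None] + np.arange(3)[None, None, :])
                cols = np.broadcast_to(cols, kb.shape)
                K = sp.coo_matrix(
                    (kb.ravel(), (rows.ravel(), cols.ravel())),
                    shape=(self.ndof, self.ndof),
                ).tocsr()
        return fext, K, sphere_reaction

    def external_forces(self, u: np.ndarray, load_factor: float):
        """Pressure + contact external force vector and sphere reaction."""
        fext = np.zeros(self.ndof)
        coords_def = self.mesh.nodes + u.reshape(-1, 3)
        for load, nodes6 in self._pressure:
            coords = coords_def if load.follower else self.mesh.nodes
            fglob = follower_pressure_forces(nodes6, load.magnitude * load_factor, coords)
            fext += fglob.ravel()
        sphere_reaction = np.zeros(3)
        Kc = None
        if self.sphere is not None:
            fc, Kc, sphere_reaction = self._contact(u, load_factor)
            fext += fc
        return fext, Kc, sphere_reaction

    def residual_and_tangent(self, u: np.ndarray, load_factor: float, tangent: bool = True):
        fint, K = self._bulk(u, tangent)
        if self._threads:
            ft, Kt = self._thread_forces(u, tangent)
            fint += ft
            if tangent and Kt is not None:
                K = K + Kt
        fext, Kc, sphere_reaction = self.external_forces(u, load_factor)
        if tangent and Kc is not None:
            K = K + Kc  # -d fext/du already encoded in sign convention below
        r = fint - fext
        return r, K, fint, fext, sphere_reaction


def assemble_model(
    mesh: TetMesh,
    material,
    bcs: list[BoundaryCondition],
    loads: list[PressureLoad] | None = None,
    sphere: RigidSphere | None = None,
    threads: list[EmbeddedThread] | None = None,
) -> ModelAssembly:
    """Build an immutable model assembly; validates all named sets."""
    return ModelAssembly(mesh, material, bcs, loads, sphere, threads)


# ---------------------------------------------------------------------------
# Newton continuation


def solve_static(
    model: ModelAssembly,
    n_increments: int = 5,
    newton_tol: float = 1e-6,
    max_iters: int = 25,
    u0: np.ndarray | None = None,
    callback=None,
) -> SolutionField:
    """Proportional load stepping with full Newton iterations.

    Loads and prescribed displacements ramp linearly over
    ``n_increments`` steps; a diverging step is bisected automatically
    down to 1/64 of the base increment, after which a non-converged
    result (with history) is returned instead of raising.
    """
    ndof = model.ndof
    u = np.zeros(ndof) if u0 is None else np.asarray(u0, dtype=float).copy()
    base_dt = 1.0 / n_increments
    # ramp in gently: the first increments of a strongly nonlinear problem
    # are the hardest, and a failed attempt is far more expensive than a
    # few extra small ones; dt recovers by doubling after each success
    dt = base_dt / 8.0 if u0 is None else base_dt
    t = 0.0
    increments: list[dict] = []
    converged_all = True
    u_prev = None  # solution at the previous accepted increment
    t_prev = None

    while t < 1.0 - 1e-12:
        t_new = min(t + dt, 1.0)
        u_trial = u.copy()
        if u_prev is not None and t > t_prev:
            # linear extrapolation predictor along the continuation path
            fac = (t_new - t) / (t - t_prev)
            u_trial[model.free_dofs] += fac * (u - u_prev)[model.free_dofs]
        u_trial[model.con_dofs] = t_new * model.con_vals
        residuals = []
        ok = False
        growths = 0
        for _ in range(max_iters):
            r, K, fint, fext, sphere_reaction = model.residual_and_tangent(u_trial, t_new)
            rf = r[model.free_dofs]
            rn = float(np.linalg.norm(rf))
            ref = max(float(np.linalg.norm(fext)), float(np.linalg.norm(fint)), 1e-12)
            residuals.append(rn)
            if not np.isfinite(rn) or not np.isfinite(ref):
                break
            if rn <= newton_tol * ref or rn < 1e-14:
                ok = True
                break
            Kff = K[model.free_dofs][:, model.free_dofs].tocsc()
            try:
                du = spla.spsolve(Kff, -rf)
            except Exception:
                break
            if not np.all(np.isfinite(du)):
                break
            # Newton residual norms are legitimately non-monotone (the
            # full step often overshoots in norm while landing much
            # closer to the solution), so growth is tolerated a limited
            # number of times; only catastrophic growth or a non-finite
            # residual triggers back-tracking.  A physical cap on the
            # displacement update guards against wild first steps.
            alpha = min(1.0, model.step_cap / max(float(np.abs(du).max()), 1e-30))
            accepted = False
            for _ls in range(12):
                u_new = u_trial.copy()
                u_new[model.free_dofs] += alpha * du
                r2, *_ = model.residual_and_tangent(u_new, t_new, tangent=False)
                rn2 = float(np.linalg.norm(r2[model.free_dofs]))
                if np.isfinite(rn2) and (rn2 < rn or growths < 2) and rn2 < 1e3 * rn:
                    growths = growths + 1 if rn2 >= rn else 0
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break
            u_trial = u_new
        increments.append({"t": t_new, "dt": dt, "residuals": residuals, "converged": ok})
        if ok:
            u_prev, t_prev = u, t
            t = t_new
            u = u_trial
            if callback is not None:
                callback(t, u)
            dt = min(base_dt, dt * 2.0)
        else:
            dt *= 0.5
            if dt < base_dt / 64.0 - 1e-15:
                converged_all = False
                break

    r, _, fint, fext, sphere_reaction = model.residual_and_tangent(u, t, tangent=False)
    reactions = np.zeros(ndof)
    reactions[model.con_dofs] = r[model.con_dofs]
    return SolutionField(
        displacements=u.reshape(-1, 3),
        reactions=reactions.reshape(-1, 3),
        sphere_reaction=sphere_reaction,
        converged=converged_all and t >= 1.0 - 1e-12,
        increments=increments,
        load_factor=t,
    )


def extract_displacement_metric(
    solution: SolutionField, mesh: TetMesh, node_set: str, axis: str
) -> dict:
    """Max and mean absolute displacement component over a node set (mm)."""
    if not solution.converged:
        raise RuntimeError("solution did not converge; metric unavailable")
    idx = mesh.node_sets[node_set]
    comp = np.abs(solution.displacements[idx, _AXIS[axis]])
    return {"max": float(comp.max()), "mean": float(comp.mean())}
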