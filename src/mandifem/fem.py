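"""Small-displacement linear-elastic static FEM on labeled tetrahedral meshes.

Region-wise isotropic materials, TET10 (and TET4) elements, vectorized
stiffness assembly, direct or iterative solution, and per-element stress
recovery (tensor at the centroid plus the von Mises effective stress).

Unit system: lengths in micrometres, forces in micronewtons, Young's moduli
supplied in GPa and converted to MPa internally, so stresses come out in MPa
(1 uN / um^2 = 1 MPa).  A 100 000 nN bite load is 100 uN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import REGIONS, TET10_EDGES, LabeledMesh, element_volumes

__all__ = [
    "MaterialMap",
    "BoundaryConditions",
    "ElementField",
    "assemble_stiffness",
    "solve_static",
    "compute_stresses",
    "von_mises",
    "ConstraintError",
]

GPA_TO_MPA = 1.0e3

# direct solver up to this many degrees of freedom, CG above
_DIRECT_DOF_LIMIT = 200_000


class ConstraintError(ValueError):
    """The constrained static system is singular or ill-posed."""


@dataclass(frozen=True)
class MaterialMap:
    """Region -> (Young's modulus E in GPa, Poisson's ratio nu).

    ``heterogeneous`` carries one entry per anatomical region; the homogeneous
    treatment (blade value everywhere) is produced by
    :func:`mandifem.scenarios.apply_E_treatment`.
    """

    properties: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for region, (E, nu) in self.properties.items():
            if E <= 0:
                raise ValueError(f"E must be positive ({region}: {E})")
            if not 0 <= nu < 0.5:
                raise ValueError(f"Poisson's ratio must be in [0, 0.5) ({region}: {nu})")

    def E(self, region: str) -> float:
        return self.properties[region][0]

    def nu(self, region: str) -> float:
        return self.properties[region][1]

    def scaled(self, factor: float) -> "MaterialMap":
        return MaterialMap({r: (E * factor, nu) for r, (E, nu) in self.properties.items()})


@dataclass
class BoundaryConditions:
    """Zero-displacement node set plus nodal point forces (uN).

    ``prescribed`` optionally imposes non-zero displacements (um) on further
    nodes; it is used by verification patch tests, not by the biting
    scenarios.  A node may not be both fixed and loaded.
    """

    fixed_nodes: np.ndarray
    nodal_forces: list[tuple[int, np.ndarray]] = field(default_factory=list)
    prescribed: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=np.int64))
        self.nodal_forces = [
            (int(n), np.asarray(f, dtype=float)) for n, f in self.nodal_forces
        ]
        loaded = {n for n, _ in self.nodal_forces}
        clash = loaded & set(self.fixed_nodes.tolist())
        if clash:
            raise ValueError(
                f"nodes {sorted(clash)[:5]}... are both fixed and loaded; "
                "ambiguous boundary condition"
            )


@dataclass
class ElementField:
    """Per-element stress state of one simulation.

    ``stress`` holds the six independent tensor components in Voigt order
    (xx, yy, zz, xy, yz, zx), MPa; ``sigma_vm`` the von Mises effective
    stress, MPa; ``volume`` the element volume, um^3.
    """

    label: str
    region: np.ndarray
    stress: np.ndarray
    sigma_vm: np.ndarray
    volume: np.ndarray

    @property
    def n_elements(self) -> int:
        return int(self.sigma_vm.shape[0])


# ---------------------------------------------------------------------------
# TET10 shape functions (barycentric; corners then mid-edges per TET10_EDGES)


def _tet10_dshape(xi: np.ndarray) -> np.ndarray:
    """d N / d (xi, eta, zeta) at one reference point; returns (10, 3)."""
    x, y, z = xi
    L = np.array([1.0 - x - y - z, x, y, z])
    dL = np.array([[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    dN = np.zeros((10, 3))
    for i in range(4):
        dN[i] = (4.0 * L[i] - 1.0) * dL[i]
    for k, (a, b) in enumerate(TET10_EDGES):
        dN[4 + k] = 4.0 * (L[a] * dL[b] + L[b] * dL[a])
    return dN


def _tet4_dshape() -> np.ndarray:
    return np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )


# degree-2 Gauss rule on the reference tetrahedron (4 points, weights sum 1/6)
_GA = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_GB = (5.0 - np.sqrt(5.0)) / 20.0
TET_GAUSS4 = (
    np.array(
        [
            [_GA, _GB, _GB],
            [_GB, _GA, _GB],
            [_GB, _GB, _GA],
            [_GB, _GB, _GB],
        ]
    ),
    np.full(4, 1.0 / 24.0),
)

_CENTROID = np.array([0.25, 0.25, 0.25])


def isotropic_elasticity_matrix(E_mpa: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt order (xx,yy,zz,xy,yz,zx)."""
    lam = E_mpa * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E_mpa / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] += 2 * mu
    D[3, 3] = D[4, 4] = D[5, 5] = mu
    return D


def _element_D(mesh: LabeledMesh, materials: MaterialMap) -> np.ndarray:
    """(n_el, 6, 6) elasticity matrices, MPa."""
    present = set(map(str, np.unique(mesh.element_region)))
    missing = present - set(materials.properties)
    if missing:
        raise KeyError(f"no material defined for region(s) {sorted(missing)}")
    D = np.empty((mesh.n_elements, 6, 6))
    for region in present:
        mask = mesh.region_mask(region)
        D[mask] = isotropic_elasticity_matrix(
            materials.E(region) * GPA_TO_MPA, materials.nu(region)
        )
    return D


def _strain_displacement(gradN: np.ndarray) -> np.ndarray:
    """Voigt B matrices from shape-function gradients.

    gradN: (n_el, n_nodes, 3) -> B: (n_el, 6, 3*n_nodes).  Engineering shear
    strains (gamma = 2 eps) in rows 3..5, order xy, yz, zx.
    """
    ne, nn, _ = gradN.shape
    B = np.zeros((ne, 6, 3 * nn))
    gx, gy, gz = gradN[:, :, 0], gradN[:, :, 1], gradN[:, :, 2]
    B[:, 0, 0::3] = gx
    B[:, 1, 1::3] = gy
    B[:, 2, 2::3] = gz
    B[:, 3, 0::3] = gy
    B[:, 3, 1::3] = gx
    B[:, 4, 1::3] = gz
    B[:, 4, 2::3] = gy
    B[:, 5, 0::3] = gz
    B[:, 5, 2::3] = gx
    return B


def _gradients_at(mesh: LabeledMesh, xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients and |J| at one reference point for all elements.

    Returns ``(gradN, detJ)`` with shapes (n_el, n_nodes, 3) and (n_el,).
    """
    dN = _tet10_dshape(xi) if mesh.is_tet10 else _tet4_dshape()
    coords = mesh.node_coords[mesh.elements]  # (ne, nn, 3)
    # J[e, k, j] = d x_j / d xi_k
    J = np.einsum("nk,enj->ekj", dN, coords)
    detJ = np.linalg.det(J)
    invJ = np.linalg.inv(J)
    # dN/dx_j = sum_k dN/dxi_k * dxi_k/dx_j ; inv(J)[j,k] = d xi_k / d x_j
    gradN = np.einsum("nk,ejk->enj", dN, invJ)
    return gradN, detJ


def assemble_stiffness(mesh: LabeledMesh, materials: MaterialMap) -> sp.csr_matrix:
    """Assemble the global (3N x 3N) stiffness matrix, uN/um.

    TET10 elements are integrated with the 4-point degree-2 Gauss rule (exact
    for straight-edged quadratic tets); TET4 with a single centroid point.
    """
    if min(element_volumes(mesh)) <= 0:
        raise ValueError("mesh contains degenerate elements")
    D = _element_D(mesh, materials)
    nn = mesh.nodes_per_element
    ndof_el = 3 * nn
    Ke = np.zeros((mesh.n_elements, ndof_el, ndof_el))
    points, weights = TET_GAUSS4 if mesh.is_tet10 else (np.array([_CENTROID]), np.array([1.0 / 6.0]))
    for xi, w in zip(points, weights):
        gradN, detJ = _gradients_at(mesh, xi)
        B = _strain_displacement(gradN)
        DB = D @ B
        Ke += (w * detJ)[:, None, None] * (B.transpose(0, 2, 1) @ DB)
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(
        mesh.n_elements, ndof_el
    )
    rows = np.repeat(dofs, ndof_el, axis=1).ravel()
    cols = np.tile(dofs, (1, ndof_el)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    return K


def _expand_dofs(node_ids: np.ndarray) -> np.ndarray:
    return (3 * node_ids[:, None] + np.arange(3)[None, :]).ravel()


def solve_static(
    stiffness: sp.spmatrix,
    bcs: BoundaryConditions,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Solve K u = f under the boundary conditions; return (N, 3) displacements.

    Dirichlet constraints are enforced by system reduction.  A sparse direct
    factorization is used up to 200k degrees of freedom, Jacobi-preconditioned
    conjugate gradients above.  Raises :class:`ConstraintError` when the
    constrained system is singular (insufficient constraints).
    """
    n = stiffness.shape[0]
    if bcs.fixed_nodes.size == 0 and not bcs.prescribed:
        raise ConstraintError("no fixed nodes: 6 rigid-body modes unconstrained")
    f = np.zeros(n)
    for node, force in bcs.nodal_forces:
        f[3 * node : 3 * node + 3] += force
    u = np.zeros(n)
    pres_nodes = np.array(sorted(bcs.prescribed), dtype=np.int64)
    for node in pres_nodes:
        u[3 * node : 3 * node + 3] = bcs.prescribed[node]
    constrained_nodes = np.union1d(bcs.fixed_nodes, pres_nodes)
    cdofs = _expand_dofs(constrained_nodes)
    free = np.setdiff1d(np.arange(n), cdofs, assume_unique=True)
    K = stiffness.tocsr()
    rhs = f[free] - K[free][:, cdofs] @ u[cdofs]
    Kff = K[free][:, free]
    u_free = _solve_spd(Kff, rhs, rtol)
    resid = np.linalg.norm(Kff @ u_free - rhs)
    scale = max(np.linalg.norm(rhs), 1e-30)
    if not np.isfinite(u_free).all() or (scale > 1e-20 and resid > 1e-6 * scale):
        raise ConstraintError(
            "constrained system is singular or ill-conditioned "
            f"(relative residual {resid / scale:g}); check that the fixed sets "
            "remove all rigid-body modes"
        )
    u[free] = u_free
    return u.reshape(-1, 3)


def _solve_spd(K: sp.csr_matrix, rhs: np.ndarray, rtol: float) -> np.ndarray:
    if K.shape[0] <= _DIRECT_DOF_LIMIT:
        try:
            # minimum-degree on K^T+K: much less fill than COLAMD for FEM
            lu = spla.splu(K.tocsc(), permc_spec="MMD_AT_PLUS_A")
            return lu.solve(rhs)
        except RuntimeError as exc:  # SuperLU singularity
            raise ConstraintError(f"direct solve failed: {exc}") from exc
    M = sp.diags(1.0 / K.diagonal())
    x, info = spla.cg(K, rhs, rtol=rtol, maxiter=20 * K.shape[0], M=M)
    if info != 0:
        raise ConstraintError(f"CG did not converge (info={info})")
    return x


class FactorizedStiffness:
    """One sparse factorization of K reduced by a base fixed set, reusable
    across load cases that share the set.

    Load cases that fix *additional* nodes (pressure bites also pin the
    engaged tooth tips) are solved from the same factorization by block
    elimination: with Y = K_ff^-1 E_C for the extra constrained columns C,
    the constrained solution is x = y0 - Y (Y_C)^-1 y0_C, which satisfies
    x_C = 0 and the free-row equations exactly.
    """

    def __init__(self, stiffness: sp.spmatrix, base_fixed_nodes: np.ndarray):
        self.K = stiffness.tocsr()
        self.n = self.K.shape[0]
        self.base_fixed = np.unique(np.asarray(base_fixed_nodes, dtype=np.int64))
        cdofs = _expand_dofs(self.base_fixed)
        self.free = np.setdiff1d(np.arange(self.n), cdofs, assume_unique=True)
        if self.free.size == self.n:
            raise ConstraintError("base fixed set is empty")
        Kff = self.K[self.free][:, self.free].tocsc()
        try:
            self.lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A")
        except RuntimeError as exc:
            raise ConstraintError(f"factorization failed: {exc}") from exc
        self._pos = -np.ones(self.n, dtype=np.int64)
        self._pos[self.free] = np.arange(self.free.size)

    def solve(self, bcs: BoundaryConditions) -> np.ndarray:
        """Displacements for boundary conditions whose fixed set contains the
        base fixed set (extra fixed nodes handled by block elimination)."""
        if bcs.prescribed:
            raise ValueError("prescribed displacements require solve_static")
        missing = np.setdiff1d(self.base_fixed, bcs.fixed_nodes)
        if missing.size:
            raise ConstraintError(
                f"load case releases base-fixed nodes {missing[:5].tolist()}..."
            )
        f = np.zeros(self.n)
        for node, force in bcs.nodal_forces:
            f[3 * node : 3 * node + 3] += force
        y0 = self.lu.solve(f[self.free])
        extra = np.setdiff1d(bcs.fixed_nodes, self.base_fixed)
        if extra.size:
            cpos = self._pos[_expand_dofs(extra)]
            if np.any(cpos < 0):
                raise ConstraintError("extra fixed node outside the free set")
            E = np.zeros((self.free.size, cpos.size))
            E[cpos, np.arange(cpos.size)] = 1.0
            Y = self.lu.solve(E)
            lam = np.linalg.solve(Y[cpos], y0[cpos])
            y0 = y0 - Y @ lam
            y0[cpos] = 0.0
        u = np.zeros(self.n)
        u[self.free] = y0
        return u.reshape(-1, 3)


_TET_FACES = ((0, 1, 2), (0, 1, 3), (1, 2, 3), (0, 2, 3))
# mid-edge local index for each corner pair, from TET10_EDGES
_EDGE_MID = {tuple(sorted(e)): 4 + k for k, e in enumerate(TET10_EDGES)}


def uniform_traction_forces(
    mesh: LabeledMesh, surface_nodes: np.ndarray, traction: np.ndarray
) -> list[tuple[int, np.ndarray]]:
    """Work-equivalent nodal forces for a uniform traction (uN/um^2 = MPa)
    on the boundary faces whose nodes all lie in ``surface_nodes``.

    For quadratic (TET10) faces the consistent load of a uniform traction
    puts A/3 on each mid-side node and nothing on the corners; for linear
    faces A/3 on each corner.  Used by verification problems (bars, beams);
    the biting scenarios use the simpler equal-split point loads.
    """
    traction = np.asarray(traction, dtype=float)
    on_surf = np.zeros(mesh.n_nodes, dtype=bool)
    on_surf[np.asarray(surface_nodes, dtype=np.int64)] = True
    forces: dict[int, np.ndarray] = {}
    coords = mesh.node_coords
    for elem in mesh.elements:
        for fa, fb, fc in _TET_FACES:
            corners = (int(elem[fa]), int(elem[fb]), int(elem[fc]))
            if mesh.is_tet10:
                mids = tuple(
                    int(elem[_EDGE_MID[tuple(sorted(pair))]])
                    for pair in ((fa, fb), (fb, fc), (fc, fa))
                )
                face_nodes = corners + mids
            else:
                face_nodes = corners
            if not all(on_surf[n] for n in face_nodes):
                continue
            a, b, c = (coords[n] for n in corners)
            area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
            loaded = mids if mesh.is_tet10 else corners
            for n in loaded:
                forces[n] = forces.get(n, np.zeros(3)) + traction * area / 3.0
    return [(n, f) for n, f in sorted(forces.items())]


def reaction_forces(
    stiffness: sp.spmatrix, displacements: np.ndarray, fixed_nodes: np.ndarray
) -> np.ndarray:
    """(n_fixed, 3) reaction forces (uN) at the fixed nodes."""
    r = (stiffness @ displacements.reshape(-1)).reshape(-1, 3)
    return r[np.asarray(fixed_nodes, dtype=np.int64)]


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises effective stress from Voigt components (xx,yy,zz,xy,yz,zx).

    sigma_vm = sqrt( 0.5[(sxx-syy)^2 + (syy-szz)^2 + (szz-sxx)^2]
                     + 3(txy^2 + tyz^2 + tzx^2) )
    """
    s = np.asarray(stress, dtype=float)
    single = s.ndim == 1
    s = np.atleast_2d(s)
    sxx, syy, szz, txy, tyz, tzx = (s[:, i] for i in range(6))
    vm = np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
    return float(vm[0]) if single else vm


def compute_stresses(
    mesh: LabeledMesh,
    materials: MaterialMap,
    displacements: np.ndarray,
    label: str = "",
) -> ElementField:
    """Centroid stress tensor, von Mises scalar and volume per element."""
    u = np.asarray(displacements, dtype=float)
    if u.shape != (mesh.n_nodes, 3):
        raise ValueError(
            f"displacement shape {u.shape} does not match mesh ({mesh.n_nodes}, 3)"
        )
    D = _element_D(mesh, materials)
    gradN, _ = _gradients_at(mesh, _CENTROID)
    B = _strain_displacement(gradN)
    ue = u[mesh.elements].reshape(mesh.n_elements, -1)
    strain = np.einsum("eij,ej->ei", B, ue)
    stress = np.einsum("eij,ej->ei", D, strain)
    return ElementField(
        label=label,
        region=mesh.element_region.copy(),
        stress=stress,
        sigma_vm=von_mises(stress),
        volume=element_volumes(mesh),
    )
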