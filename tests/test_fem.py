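"""Linear-elastic solver verification: closed forms, patch test, invariants,
and an independent dense assembly oracle at higher quadrature order."""

import numpy as np
import pytest

from mandifem.fem import (
    BoundaryConditions,
    ConstraintError,
    FactorizedStiffness,
    MaterialMap,
    _strain_displacement,
    _tet10_dshape,
    assemble_stiffness,
    compute_stresses,
    isotropic_elasticity_matrix,
    reaction_forces,
    solve_static,
    uniform_traction_forces,
    von_mises,
)
from mandifem.mesh import promote_tet4_to_tet10, tet_box_mesh

# degree-3 quadrature on the reference tet (5 points, one negative weight);
# independent of the assembly's 4-point rule
_Q5_POINTS = np.array(
    [
        [0.25, 0.25, 0.25],
        [0.5, 1 / 6, 1 / 6],
        [1 / 6, 0.5, 1 / 6],
        [1 / 6, 1 / 6, 0.5],
        [1 / 6, 1 / 6, 1 / 6],
    ]
)
_Q5_WEIGHTS = np.array([-4.0 / 5.0, 9.0 / 20.0, 9.0 / 20.0, 9.0 / 20.0, 9.0 / 20.0]) / 6.0


def dense_reference_stiffness(mesh, materials):
    """Slow per-element assembly with the 5-point degree-3 rule."""
    n = 3 * mesh.n_nodes
    K = np.zeros((n, n))
    for eid, elem in enumerate(mesh.elements):
        region = mesh.element_region[eid]
        D = isotropic_elasticity_matrix(materials.E(region) * 1e3, materials.nu(region))
        coords = mesh.node_coords[elem]
        Ke = np.zeros((30, 30))
        for xi, wq in zip(_Q5_POINTS, _Q5_WEIGHTS):
            dN = _tet10_dshape(xi)
            J = dN.T @ coords
            invJ = np.linalg.inv(J)
            gradN = dN @ invJ.T
            B = _strain_displacement(gradN[None])[0]
            Ke += wq * np.linalg.det(J) * B.T @ D @ B
        dofs = (3 * elem[:, None] + np.arange(3)).ravel()
        K[np.ix_(dofs, dofs)] += Ke
    return K


@pytest.fixture
def bar10():
    return promote_tet4_to_tet10(tet_box_mesh((10.0, 1.0, 1.0), (10, 2, 2)))


class TestVonMises:
    def test_uniaxial(self):
        assert von_mises([5.0, 0, 0, 0, 0, 0]) == pytest.approx(5.0)

    def test_hydrostatic_is_zero(self):
        assert von_mises([3.0, 3.0, 3.0, 0, 0, 0]) == pytest.approx(0.0, abs=1e-14)

    def test_pure_shear(self):
        assert von_mises([0, 0, 0, 2.0, 0, 0]) == pytest.approx(2.0 * np.sqrt(3.0))

    def test_nonnegative_on_random_tensors(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(100, 6))
        assert np.all(von_mises(s) >= 0)


class TestAssembly:
    def test_symmetry_single_tet10(self, unit_tet):
        m = promote_tet4_to_tet10(unit_tet)
        K = assemble_stiffness(m, MaterialMap({"MM": (5.0, 0.3)})).toarray()
        assert np.abs(K - K.T).max() < 1e-10 * np.abs(K).max()

    def test_rigid_body_translations_in_null_space(self, box_tet10):
        K = assemble_stiffness(box_tet10, MaterialMap({"BLADE": (2.0, 0.25)}))
        for axis in range(3):
            u = np.zeros((box_tet10.n_nodes, 3))
            u[:, axis] = 1.0
            assert np.abs(K @ u.ravel()).max() < 1e-9 * np.abs(K.data).max()

    def test_missing_material_raises(self, unit_tet):
        m = promote_tet4_to_tet10(unit_tet)
        with pytest.raises(KeyError, match="MM"):
            assemble_stiffness(m, MaterialMap({"BLADE": (2.0, 0.3)}))

    def test_matches_dense_high_order_oracle(self, two_tets, materials):
        mesh = promote_tet4_to_tet10(two_tets)
        K = assemble_stiffness(mesh, materials).toarray()
        K_ref = dense_reference_stiffness(mesh, materials)
        diff = np.linalg.norm(K - K_ref) / np.linalg.norm(K_ref)
        assert diff < 1e-10


class TestSolve:
    def test_zero_load_zero_displacement(self, bar10):
        K = assemble_stiffness(bar10, MaterialMap({"BLADE": (2.0, 0.3)}))
        u = solve_static(K, BoundaryConditions(bar10.node_sets["xmin"]))
        assert np.abs(u).max() == 0.0

    def test_unconstrained_system_raises(self, bar10):
        K = assemble_stiffness(bar10, MaterialMap({"BLADE": (2.0, 0.3)}))
        with pytest.raises(ConstraintError):
            solve_static(K, BoundaryConditions(np.array([], dtype=int)))

    def test_fixed_and_loaded_node_rejected(self):
        with pytest.raises(ValueError, match="fixed and loaded"):
            BoundaryConditions(np.array([0]), [(0, np.array([1.0, 0, 0]))])

    def test_linear_patch_field_reproduced(self):
        """Prescribing a linear displacement field on the boundary must
        reproduce it in the interior to near machine precision (completeness
        of quadratic tets), with constant stress equal to the closed form."""
        mesh = promote_tet4_to_tet10(tet_box_mesh((1.0, 1.0, 1.0), (2, 2, 2)))
        mats = MaterialMap({"BLADE": (2.0, 0.3)})
        K = assemble_stiffness(mesh, mats)
        A = np.array([[1e-3, 2e-4, 0.0], [0.0, -5e-4, 3e-4], [1e-4, 0.0, 8e-4]])
        coords = mesh.node_coords
        u_exact = coords @ A.T
        on_surface = np.any(
            np.isclose(coords, 0.0) | np.isclose(coords, coords.max(axis=0)), axis=1
        )
        boundary = np.flatnonzero(on_surface)
        bcs = BoundaryConditions(
            np.array([], dtype=int),
            prescribed={int(n): u_exact[n] for n in boundary},
        )
        u = solve_static(K, bcs)
        assert np.abs(u - u_exact).max() < 1e-10
        field = compute_stresses(mesh, mats, u)
        strain_v = np.array(
            [A[0, 0], A[1, 1], A[2, 2], A[0, 1] + A[1, 0], A[1, 2] + A[2, 1], A[0, 2] + A[2, 0]]
        )
        sigma_exact = isotropic_elasticity_matrix(2.0e3, 0.3) @ strain_v
        np.testing.assert_allclose(
            field.stress,
            np.broadcast_to(sigma_exact, field.stress.shape),
            rtol=1e-9,
            atol=1e-12,
        )

    def test_axial_bar_closed_form(self, bar10):
        """End traction sigma on a bar: end displacement = FL/(EA)."""
        mats = MaterialMap({"BLADE": (2.0, 0.0)})
        K = assemble_stiffness(bar10, mats)
        forces = uniform_traction_forces(bar10, bar10.node_sets["xmax"], [2.0, 0, 0])
        u = solve_static(K, BoundaryConditions(bar10.node_sets["xmin"], forces))
        end = bar10.node_sets["xmax"]
        expected = 2.0 * 10.0 / (2.0e3 * 1.0)  # FL/EA with F=2, A=1
        assert u[end, 0].mean() == pytest.approx(expected, rel=0.02)

    def test_slender_cantilever_tip_deflection(self):
        """L/h = 10 cantilever, tip shear load: within 5% of FL^3/(3EI)."""
        mesh = promote_tet4_to_tet10(tet_box_mesh((20.0, 2.0, 2.0), (30, 3, 3)))
        mats = MaterialMap({"BLADE": (2.0, 0.3)})
        K = assemble_stiffness(mesh, mats)
        tip = mesh.node_sets["xmax"]
        forces = uniform_traction_forces(mesh, tip, [0, 0, 1.0 / 4.0])  # F=1 over A=4
        u = solve_static(K, BoundaryConditions(mesh.node_sets["xmin"], forces))
        I = 2.0 * 2.0**3 / 12.0
        expected = 1.0 * 20.0**3 / (3.0 * 2.0e3 * I)
        assert u[tip, 2].mean() == pytest.approx(expected, rel=0.05)

    def test_global_force_balance(self, bar10):
        mats = MaterialMap({"BLADE": (2.0, 0.3)})
        K = assemble_stiffness(bar10, mats)
        load = np.array([1.0, -2.0, 0.5])
        end = bar10.node_sets["xmax"]
        forces = [(int(n), load / end.size) for n in end]
        u = solve_static(K, BoundaryConditions(bar10.node_sets["xmin"], forces))
        reactions = reaction_forces(K, u, bar10.node_sets["xmin"]).sum(axis=0)
        np.testing.assert_allclose(reactions, -load, rtol=1e-8, atol=1e-10)


class TestStress:
    def test_uniform_extension_uniform_stress(self, bar10):
        """Imposed strain 0.001 with E = 2 GPa, nu = 0 -> sigma_xx = 2 MPa."""
        mats = MaterialMap({"BLADE": (2.0, 0.0)})
        u = np.zeros((bar10.n_nodes, 3))
        u[:, 0] = 1e-3 * bar10.node_coords[:, 0]
        field = compute_stresses(bar10, mats, u)
        np.testing.assert_allclose(field.stress[:, 0], 2.0, rtol=1e-12)
        np.testing.assert_allclose(field.stress[:, 1:], 0.0, atol=1e-12)
        np.testing.assert_allclose(field.sigma_vm, 2.0, rtol=1e-12)

    def test_rigid_body_motion_zero_stress(self, bar10, materials):
        u = np.tile([0.3, -0.2, 0.7], (bar10.n_nodes, 1))
        field = compute_stresses(bar10, materials, u)
        assert np.abs(field.stress).max() < 1e-12

    def test_shape_mismatch_raises(self, bar10, materials):
        with pytest.raises(ValueError, match="shape"):
            compute_stresses(bar10, materials, np.zeros((3, 3)))


class TestScalingInvariances:
    def test_E_scaling_leaves_stress_invariant(self, bar10):
        """Force loading + zero-displacement constraints: scaling every E by c
        leaves stresses unchanged and scales displacements by 1/c."""
        base = MaterialMap({"BLADE": (2.0, 0.3)})
        forces = uniform_traction_forces(bar10, bar10.node_sets["xmax"], [1.0, 0.5, 0])
        results = {}
        for c in (1.0, 7.5):
            mats = base.scaled(c)
            K = assemble_stiffness(bar10, mats)
            u = solve_static(K, BoundaryConditions(bar10.node_sets["xmin"], forces))
            results[c] = (u, compute_stresses(bar10, mats, u))
        u1, f1 = results[1.0]
        u2, f2 = results[7.5]
        assert np.linalg.norm(f2.stress - f1.stress) < 1e-10 * np.linalg.norm(f1.stress)
        assert np.linalg.norm(u2 - u1 / 7.5) < 1e-10 * np.linalg.norm(u1)

    def test_load_linearity(self, bar10, materials_bar=None):
        mats = MaterialMap({"BLADE": (3.0, 0.3)})
        K = assemble_stiffness(bar10, mats)
        forces1 = uniform_traction_forces(bar10, bar10.node_sets["xmax"], [1.0, 0, 0])
        forces2 = [(n, 2.0 * f) for n, f in forces1]
        u1 = solve_static(K, BoundaryConditions(bar10.node_sets["xmin"], forces1))
        u2 = solve_static(K, BoundaryConditions(bar10.node_sets["xmin"], forces2))
        np.testing.assert_allclose(u2, 2.0 * u1, rtol=1e-10, atol=1e-18)


class TestFactorizedStiffness:
    def test_matches_direct_solve_with_extra_constraints(self, bar10):
        mats = MaterialMap({"BLADE": (2.0, 0.3)})
        K = assemble_stiffness(bar10, mats)
        base_fixed = bar10.node_sets["xmin"]
        extra = bar10.node_sets["xmax"][:4]
        mid = [int(n) for n in range(bar10.n_nodes) if n not in set(np.r_[base_fixed, extra])][:5]
        forces = [(n, np.array([0.0, 1.0, 0.0])) for n in mid]
        bcs = BoundaryConditions(np.union1d(base_fixed, extra), forces)
        u_direct = solve_static(K, bcs)
        u_fact = FactorizedStiffness(K, base_fixed).solve(bcs)
        np.testing.assert_allclose(u_fact, u_direct, rtol=1e-9, atol=1e-14)

    def test_released_base_nodes_rejected(self, bar10):
        mats = MaterialMap({"BLADE": (2.0, 0.3)})
        K = assemble_stiffness(bar10, mats)
        solver = FactorizedStiffness(K, bar10.node_sets["xmin"])
        with pytest.raises(ConstraintError, match="releases"):
            solver.solve(BoundaryConditions(bar10.node_sets["xmin"][:2]))
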