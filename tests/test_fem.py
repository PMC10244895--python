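"""Plane-stress solver: constitutive model, element matrices, loads, solves
and stress recovery, each against an independent closed-form or brute-force
oracle."""

import numpy as np
import pytest

import antfea as af
from antfea.fem import (FemError, assemble_stiffness, build_load_case,
                        solve_constrained)
from conftest import consistent_edge_loads, solve_with_bc

REF_COORDS = np.array([[0, 0], [1, 0], [0, 1],
                       [0.5, 0], [0.5, 0.5], [0, 0.5]], float)


class TestConstitutive:
    def test_nu_zero(self):
        d = af.constitutive_matrix(af.Material(1.0, 0.0))
        np.testing.assert_allclose(d, np.diag([1.0, 1.0, 0.5]))

    def test_cuticle_entry(self):
        d = af.constitutive_matrix(af.CUTICLE)
        assert d[0, 0] == pytest.approx(2750.0 / 0.91, rel=1e-9)
        assert d[0, 1] == pytest.approx(0.3 * 2750.0 / 0.91, rel=1e-9)

    @pytest.mark.parametrize("e,nu", [(1.0, 0.0), (2750.0, 0.3), (10.0, 0.49)])
    def test_symmetric_positive_definite(self, e, nu):
        d = af.constitutive_matrix(af.Material(e, nu))
        np.testing.assert_allclose(d, d.T)
        assert (np.linalg.eigvalsh(d) > 0).all()

    def test_incompressible_rejected(self):
        with pytest.raises(FemError):
            af.Material(1.0, 0.5)


class TestElementStiffness:
    def setup_method(self):
        self.d = af.constitutive_matrix(af.Material(1000.0, 0.3))
        self.k = af.element_stiffness(REF_COORDS, self.d)

    def test_symmetry(self):
        assert np.abs(self.k - self.k.T).max() < 1e-12 * np.abs(self.k).max()

    def test_rigid_translation_in_nullspace(self):
        for u in (np.tile([1.0, 0.0], 6), np.tile([0.0, 1.0], 6)):
            assert np.abs(self.k @ u).max() < 1e-10 * np.abs(self.k).max()

    def test_nullspace_dimension_exactly_three(self):
        w = np.linalg.eigvalsh(self.k)
        assert int((np.abs(w) < 1e-9 * w.max()).sum()) == 3

    def test_constant_strain_reproduces_d_times_eps(self):
        # impose u = [eps_x * x, eps_y * y + gamma * x] -> sigma = D eps exactly
        eps = np.array([1e-3, -2e-3, 5e-4])
        u = np.empty(12)
        u[0::2] = eps[0] * REF_COORDS[:, 0]
        u[1::2] = eps[1] * REF_COORDS[:, 1] + eps[2] * REF_COORDS[:, 0]
        from antfea.fem import _b_matrix
        b, _ = _b_matrix(REF_COORDS, 1 / 3, 1 / 3)
        np.testing.assert_allclose(self.d @ (b @ u), self.d @ eps, rtol=1e-12)

    def test_inverted_element_rejected(self):
        bad = REF_COORDS[[0, 2, 1, 5, 4, 3]]  # clockwise corners
        with pytest.raises(FemError, match="[Ii]nverted"):
            af.element_stiffness(bad, self.d)


class TestAssembly:
    def test_matches_dense_bruteforce_on_small_mesh(self, unit_square):
        """COO-based sparse assembly equals an independent dense loop."""
        mesh = af.triangulate(unit_square, 0.5)
        assert mesh.n_elements <= 20
        mat = af.Material(1000.0, 0.3)
        k_sparse = assemble_stiffness(mesh, mat).toarray()
        d = af.constitutive_matrix(mat)
        k_dense = np.zeros_like(k_sparse)
        for conn in mesh.elements:
            ke = af.element_stiffness(mesh.nodes[conn], d, mat.thickness)
            for a in range(6):
                for b in range(6):
                    for ca in range(2):
                        for cb in range(2):
                            k_dense[2 * conn[a] + ca, 2 * conn[b] + cb] += \
                                ke[2 * a + ca, 2 * b + cb]
        np.testing.assert_allclose(k_sparse, k_dense, atol=1e-10 * np.abs(k_dense).max())


class TestLoadCase:
    def test_equal_division_and_magnitude_sum(self, head_mesh):
        lc = build_load_case(head_mesh, 1.0, 45.0)
        f = lc.forces.reshape(-1, 2)
        for name in ("left_load", "right_load"):
            nodes = lc.loaded_sets[name]
            mags = np.linalg.norm(f[nodes], axis=1)
            np.testing.assert_allclose(mags, 1.0 / len(nodes), rtol=1e-12)
            assert mags.sum() == pytest.approx(1.0, rel=1e-12)

    def test_components_at_45_degrees(self, head_mesh):
        lc = build_load_case(head_mesh, 1.0, 45.0)
        f = lc.forces.reshape(-1, 2)
        left = lc.loaded_sets["left_load"]
        mag = 1.0 / len(left)
        np.testing.assert_allclose(f[left, 0], mag / np.sqrt(2), rtol=1e-12)
        np.testing.assert_allclose(f[left, 1], -mag / np.sqrt(2), rtol=1e-12)

    def test_left_right_mirror(self, head_mesh):
        lc = build_load_case(head_mesh, 1.0, 45.0)
        f = lc.forces.reshape(-1, 2)
        left, right = lc.loaded_sets["left_load"], lc.loaded_sets["right_load"]
        assert f[left, 0].sum() == pytest.approx(-f[right, 0].sum(), rel=1e-12)
        assert f[left, 1].sum() == pytest.approx(f[right, 1].sum(), rel=1e-12)

    def test_missing_sets_error(self, unit_square):
        bare = af.triangulate(unit_square, 0.5)  # no landmarks -> no sets
        with pytest.raises(FemError, match="node set"):
            build_load_case(bare, 1.0)


class TestNormalizeLoad:
    def test_identity(self):
        assert af.normalize_load(3.510, 3.510, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("area,expected", [(1.710, 0.70), (0.141, 0.20)])
    def test_printed_loads(self, area, expected):
        assert round(af.normalize_load(area, 3.510, 1.0), 2) == expected

    def test_square_root_rule(self):
        assert af.normalize_load(1.0, 4.0, 1.0) == pytest.approx(0.5)

    def test_nonpositive_rejected(self):
        for args in ((0.0, 1.0, 1.0), (1.0, -1.0, 1.0), (1.0, 1.0, 0.0)):
            with pytest.raises(FemError):
                af.normalize_load(*args)


class TestSolve:
    def test_zero_load_zero_displacement(self, head_mesh):
        lc = build_load_case(head_mesh, 1.0, 45.0)
        lc.forces[:] = 0.0
        disp = af.solve_linear_static(head_mesh, af.CUTICLE, lc)
        assert np.abs(disp.displacements).max() == 0.0

    def test_unconstrained_system_rejected(self, head_mesh):
        k = assemble_stiffness(head_mesh, af.CUTICLE)
        with pytest.raises(FemError, match="rigid"):
            solve_constrained(k, np.zeros(k.shape[0]), np.empty(0, int))

    def test_fixed_nodes_have_zero_displacement(self, head_solution):
        mesh, lc, disp, _ = head_solution
        fixed = np.concatenate(list(lc.fixed_sets.values()))
        assert np.abs(disp.displacements[fixed]).max() == 0.0

    def test_residual_within_contract(self, head_solution):
        assert head_solution[2].residual <= 1e-8

    def test_global_equilibrium(self, head_solution):
        _, lc, disp, _ = head_solution
        total = lc.forces.reshape(-1, 2).sum(axis=0) \
            + disp.reactions.reshape(-1, 2).sum(axis=0)
        assert np.abs(total).max() <= 1e-8 * np.linalg.norm(lc.forces)

    def test_uniaxial_patch_exact(self, unit_square):
        """Uniform tension on a coarse square mesh is reproduced exactly."""
        mesh = af.triangulate(unit_square, 0.5)
        mat = af.Material(1000.0, 0.3)
        sigma = 7.0
        forces = consistent_edge_loads(mesh, 0, 1.0, (sigma, 0.0))
        fixed = [2 * n for n, (x, _) in enumerate(mesh.nodes) if np.isclose(x, 0)]
        fixed += [2 * n + 1 for n, (_, y) in enumerate(mesh.nodes) if np.isclose(y, 0)]
        u, fld = solve_with_bc(mesh, mat, forces, fixed)
        np.testing.assert_allclose(fld.sigma[:, 0], sigma, rtol=1e-8)
        np.testing.assert_allclose(fld.sigma[:, 1], 0.0, atol=1e-8 * sigma)
        np.testing.assert_allclose(fld.sigma[:, 2], 0.0, atol=1e-8 * sigma)
        # analytic displacement at the loaded edge: u_x = sigma/E
        tip = np.isclose(mesh.nodes[:, 0], 1.0)
        np.testing.assert_allclose(u[tip, 0], sigma / 1000.0, rtol=1e-8)

    def test_cantilever_matches_beam_theory(self):
        """Tip deflection of a 10:1 strip within 5% of P L^3 / 3 E I."""
        rect = af.Outline(np.array([[0, 0], [10, 0], [10, 1], [0, 1]], float))
        mat = af.Material(1000.0, 0.0)
        exact = 1.0 * 10.0**3 / (3.0 * 1000.0 * (1.0 / 12.0))
        errors = []
        for h in (0.7, 0.35):
            mesh = af.triangulate(rect, h)
            forces = consistent_edge_loads(mesh, 0, 10.0, (0.0, -1.0))
            fixed = []
            for n, (x, _) in enumerate(mesh.nodes):
                if np.isclose(x, 0.0):
                    fixed += [2 * n, 2 * n + 1]
            u, _ = solve_with_bc(mesh, mat, forces, fixed)
            tip = np.isclose(mesh.nodes[:, 0], 10.0)
            delta = -u[tip, 1].mean()
            errors.append(abs(delta - exact) / exact)
        assert max(errors) < 0.05


class TestStressRecovery:
    def test_hydrostatic_in_plane(self):
        s1, s2, _ = af.principal_stresses(5.0, 5.0, 0.0)
        assert (s1, s2) == (5.0, 5.0)
        assert af.tresca_equivalent(s1, s2) == 5.0

    def test_pure_shear(self):
        s1, s2, _ = af.principal_stresses(0.0, 0.0, 3.0)
        assert s1 == pytest.approx(3.0)
        assert s2 == pytest.approx(-3.0)
        assert af.tresca_equivalent(s1, s2) == pytest.approx(6.0)

    def test_mohr_circle_example(self):
        s1, s2, _ = af.principal_stresses(80.0, 20.0, 30.0)
        assert s1 == pytest.approx(92.4264, abs=1e-3)
        assert s2 == pytest.approx(7.5736, abs=1e-3)
        assert af.tresca_equivalent(s1, s2) == pytest.approx(92.4264, abs=1e-3)

    def test_field_invariants(self, head_solution):
        fld = head_solution[3]
        assert (fld.sigma1 >= fld.sigma2 - 1e-12).all()
        assert (fld.tresca >= 0).all()
        assert (fld.tresca >= np.abs(fld.sigma1 - fld.sigma2) - 1e-12).all()
        assert (fld.nodal_tresca >= 0).all()


class TestFieldProperties:
    def test_scaling_invariance(self, head_solution):
        """Geometry x k with load x k leaves centroid stresses unchanged."""
        mesh, lc, _, fld = head_solution
        k = 3.0
        scaled = af.Mesh(nodes=mesh.nodes * k, elements=mesh.elements,
                         density=mesh.density * k,
                         boundary_nodes=mesh.boundary_nodes,
                         boundary_s=mesh.boundary_s * k,
                         boundary_node_sets=mesh.boundary_node_sets)
        lc2 = build_load_case(scaled, lc.side_load * k, lc.load_angle)
        disp2 = af.solve_linear_static(scaled, af.CUTICLE, lc2)
        fld2 = af.recover_stress(scaled, af.CUTICLE, disp2)
        assert np.abs(fld2.tresca - fld.tresca).max() <= 1e-6 * fld.tresca.max()

    def test_mirror_symmetry_within_one_percent(self, head_outline, head_solution):
        """Symmetric shape + load: Tresca at (x, y) vs (-x, y) within 1%."""
        import matplotlib.tri as mtri
        import shapely
        mesh, _, _, fld = head_solution
        tri = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1],
                                 mesh.elements[:, :3])
        interp = mtri.LinearTriInterpolator(tri, fld.nodal_tresca)
        rng = np.random.default_rng(0)
        inner = head_outline.polygon.buffer(-0.05)
        pts = rng.uniform([-1.0, -1.0], [1.0, 1.0], (3000, 2))
        keep = shapely.contains_xy(inner, pts[:, 0], pts[:, 1])
        pts = pts[keep][:400]
        a = np.asarray(interp(pts[:, 0], pts[:, 1]))
        b = np.asarray(interp(-pts[:, 0], pts[:, 1]))
        ok = np.isfinite(a) & np.isfinite(b)
        assert ok.sum() > 200
        assert np.abs(a[ok] - b[ok]).max() <= 0.01 * fld.tresca.max()


class TestResultWriters:
    def test_element_table_schema(self, head_solution):
        _, _, _, fld = head_solution
        tab = af.element_table(fld, "head")
        assert list(tab.columns) == ["model", "element_id", "tresca", "area_mm2"]
        assert tab["element_id"].is_unique

    def test_stress_csv(self, head_solution, tmp_path):
        from antfea.fem import write_stress_csv
        import pandas as pd
        _, _, _, fld = head_solution
        p = tmp_path / "stress.csv"
        write_stress_csv(fld, "head", str(p))
        back = pd.read_csv(p)
        assert {"sigma_xx", "sigma_yy", "tau_xy", "sigma_1", "sigma_2",
                "tresca", "area_mm2"} <= set(back.columns)
        np.testing.assert_allclose(back["tresca"], fld.tresca)
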