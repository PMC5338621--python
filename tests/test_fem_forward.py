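"""CEM/PEM assembly, forward solves and lead-field computation."""

import numpy as np
import pytest
import scipy.sparse as sp

from cemfwd import (
    ConductivityModel,
    assemble_cem_system,
    assemble_pem_system,
    assemble_stiffness,
    average_reference_matrix,
    compute_lead_field,
    net_electrode_currents,
    solve_forward,
    subelectrode_variation,
)
from cemfwd.exceptions import UnsupportedModelError, ValidationError
from cemfwd.head_geometry import BRAIN


class TestStiffness:
    def test_row_sums_vanish(self, small_head, sigma_i, small_stiffness):
        # constants lie in the null space of the pure stiffness matrix
        rs = np.abs(np.asarray(small_stiffness.sum(axis=1))).max()
        assert rs < 1e-12 * np.abs(small_stiffness.data).max() * 100

    def test_symmetric(self, small_stiffness):
        diff = np.abs((small_stiffness - small_stiffness.T).data)
        assert (diff.max() if diff.size else 0.0) < 1e-14

    def test_reference_tet_closed_form(self, single_tet_mesh):
        """Unit-sigma stiffness of the reference tet from the gradient formula
        grad(psi_i) = -n_i A_i / (3V): hand-computed entries."""
        sigma = ConductivityModel("unit", {BRAIN: 1.0})
        K = assemble_stiffness(single_tet_mesh, sigma).toarray()
        # reference tet: grad(psi_0) = (-1,-1,-1), grad(psi_i) = e_i, V = 1/6
        grads = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        expected = grads @ grads.T / 6.0
        np.testing.assert_allclose(K, expected, atol=1e-15)

    def test_linear_in_sigma(self, single_tet_mesh):
        k1 = assemble_stiffness(
            single_tet_mesh, ConductivityModel("a", {BRAIN: 0.5})
        ).toarray()
        k2 = assemble_stiffness(
            single_tet_mesh, ConductivityModel("b", {BRAIN: 1.0})
        ).toarray()
        np.testing.assert_allclose(2.0 * k1, k2, rtol=1e-14)


class TestCemAssembly:
    def test_b_column_sums_equal_c(self, small_cem):
        """Partition of unity on each patch: sum_i b_il = 1/Z_l = c_ll."""
        colsums = np.asarray(small_cem.B.sum(axis=0)).ravel()
        np.testing.assert_allclose(colsums, small_cem.C, rtol=1e-12)

    def test_block_matrix_symmetric(self, small_cem):
        M = small_cem.block_matrix()
        diff = np.abs((M - M.T).data)
        assert (diff.max() if diff.size else 0.0) < 1e-12 * np.abs(M.data).max()

    def test_a_symmetric(self, small_cem):
        diff = np.abs((small_cem.A - small_cem.A.T).data)
        assert (diff.max() if diff.size else 0.0) < 1e-12 * np.abs(small_cem.A.data).max()

    def test_infinite_impedance_limit(self, small_head, sigma_i, small_cap, small_stiffness):
        """Z -> inf: electrode terms vanish, A tends to grounded stiffness."""
        big = assemble_cem_system(
            small_head, sigma_i, small_cap.with_impedance(1e12), stiffness=small_stiffness
        )
        assert np.abs(big.B.data).max() < 1e-9
        assert np.abs(big.C).max() < 1e-9
        ref = assemble_cem_system(
            small_head, sigma_i, small_cap, stiffness=small_stiffness
        )
        diff = big.A - _reground_stiffness(small_stiffness, ref.ground_node)
        if diff.data.size:
            assert np.abs(diff.data).max() < 1e-9

    def test_b_rows_only_under_electrodes(self, small_head, small_cem, small_cap):
        rows = np.unique(small_cem.B.nonzero()[0])
        patch_nodes = np.unique(
            small_head.boundary_tris[np.concatenate(small_cap.triangles)]
        )
        assert np.all(np.isin(rows, patch_nodes))


def _reground_stiffness(K, node):
    from cemfwd.fem_forward import _ground

    return _ground(K, node)


class TestForwardSolve:
    def test_zero_source_gives_zero_solution(self, small_cem, small_space):
        sol = solve_forward(small_cem, np.zeros(len(small_space)), small_space.G)
        assert np.all(sol.z == 0) and np.all(sol.v == 0)

    def test_linearity(self, small_cem, small_space):
        m = len(small_space)
        x1 = np.zeros(m)
        x1[10] = 1.0
        x2 = np.zeros(m)
        x2[m // 2] = -0.5
        s1 = solve_forward(small_cem, x1, small_space.G)
        s2 = solve_forward(small_cem, x2, small_space.G)
        s12 = solve_forward(small_cem, x1 + x2, small_space.G)
        np.testing.assert_allclose(s12.v, s1.v + s2.v, atol=1e-12 * np.abs(s1.v).max())

    def test_voltage_is_patch_integral_mean(self, small_head, small_cem, small_cap, small_space):
        """Second block row: U_l = (1/A_l) int_{e_l} u dS."""
        x = np.zeros(len(small_space))
        x[0] = 1.0
        sol = solve_forward(small_cem, x, small_space.G)
        areas = small_head.boundary_areas()
        for l in (0, 5, 40):
            tris = small_head.boundary_tris[small_cap.triangles[l]]
            a = areas[small_cap.triangles[l]]
            integral = (sol.z[tris].mean(axis=1) * a).sum()  # P1: mean = centroid value
            assert sol.v[l] == pytest.approx(integral / a.sum(), abs=1e-10 * np.abs(sol.v).max())

    def test_zero_net_electrode_current(self, small_cem, small_space):
        x = np.zeros(len(small_space))
        x[3] = 1.0
        sol = solve_forward(small_cem, x, small_space.G)
        cur = net_electrode_currents(small_cem, sol)
        scale = np.abs(small_cem.C * sol.v).max()
        assert np.abs(cur).max() < 1e-10 * scale


class TestSubelectrodeVariation:
    def test_area_weighted_mean_vanishes(self, small_head, small_cem, small_cap, small_space):
        x = np.zeros(len(small_space))
        x[7] = 1.0
        sol = solve_forward(small_cem, x, small_space.G)
        areas = small_head.boundary_areas()
        for l in (1, 20, 60):
            var = subelectrode_variation(sol, small_head, small_cap, l)
            a = areas[small_cap.triangles[l]]
            mean = (var * a).sum() / a.sum()
            assert abs(mean) < 1e-10 * max(np.abs(var).max(), 1e-30)

    def test_pem_solution_rejected(self, small_head, sigma_i, small_cap, small_space, small_stiffness):
        pem = assemble_pem_system(
            small_head, sigma_i, small_cap, stiffness=small_stiffness
        )
        sol = solve_forward(pem, np.zeros(len(small_space)), small_space.G)
        with pytest.raises(UnsupportedModelError):
            subelectrode_variation(sol, small_head, small_cap, 0)

    def test_low_impedance_suppresses_variation(
        self, small_head, sigma_i, small_cap, small_space, small_stiffness
    ):
        """Shunting at 0.1 Ohm flattens the subelectrode potential relative
        to 2 kOhm (max-abs ratio < 0.1)."""
        x = np.zeros(len(small_space))
        x[len(small_space) // 2] = 1.0

        def max_var(z):
            sys_z = assemble_cem_system(
                small_head, sigma_i, small_cap.with_impedance(z), stiffness=small_stiffness
            )
            sol = solve_forward(sys_z, x, small_space.G)
            return max(
                np.abs(subelectrode_variation(sol, small_head, small_cap, l)).max()
                for l in range(len(small_cap))
            )

        assert max_var(0.1) < 0.1 * max_var(2000.0)


class TestPem:
    def test_snapped_b_is_selection_matrix(self, small_head, sigma_i, small_cap, small_stiffness):
        pem = assemble_pem_system(small_head, sigma_i, small_cap, stiffness=small_stiffness)
        colsums = np.asarray(pem.B.sum(axis=0)).ravel()
        np.testing.assert_allclose(colsums, 1.0, rtol=1e-15)
        assert pem.B.nnz == len(small_cap)
        assert np.all(pem.B.data == 1.0)

    def test_voltages_are_nodal_potentials(self, small_head, sigma_i, small_cap, small_space, small_stiffness):
        pem = assemble_pem_system(small_head, sigma_i, small_cap, stiffness=small_stiffness)
        x = np.zeros(len(small_space))
        x[11] = 1.0
        sol = solve_forward(pem, x, small_space.G)
        np.testing.assert_allclose(sol.v, sol.z[pem.electrode_nodes], rtol=0, atol=0)

    def test_barycentric_columns_sum_to_one(self, small_head, sigma_i, small_cap, small_stiffness):
        pem = assemble_pem_system(
            small_head, sigma_i, small_cap.centers, snap=False, stiffness=small_stiffness
        )
        colsums = np.asarray(pem.B.sum(axis=0)).ravel()
        np.testing.assert_allclose(colsums, 1.0, rtol=1e-12)


class TestLeadField:
    def test_average_reference_matrix_idempotent(self):
        R = average_reference_matrix(74)
        np.testing.assert_allclose(R @ R, R, atol=1e-14)

    def test_columns_sum_to_zero(self, small_lead_field):
        scale = np.abs(small_lead_field.matrix).max()
        assert np.abs(small_lead_field.matrix.sum(axis=0)).max() < 1e-10 * scale

    def test_methods_agree(self, small_cem, small_space, small_lead_field):
        for method in ("block", "transfer"):
            lf = compute_lead_field(small_cem, small_space.G, method=method, rtol=1e-12)
            num = np.abs(lf.matrix - small_lead_field.matrix).max()
            assert num < 1e-8 * np.abs(small_lead_field.matrix).max()

    def test_unknown_method_rejected(self, small_cem, small_space):
        with pytest.raises(ValidationError):
            compute_lead_field(small_cem, small_space.G, method="magic")

    def test_matches_forward_solve(self, small_cem, small_space, small_lead_field):
        x = np.zeros(len(small_space))
        x[42] = 2.5
        sol = solve_forward(small_cem, x, small_space.G)
        R = average_reference_matrix(small_cem.n_electrodes)
        np.testing.assert_allclose(
            small_lead_field.matrix @ x,
            R @ sol.v,
            atol=1e-9 * np.abs(sol.v).max(),
        )

    def test_corrupted_b_breaks_net_current(self, small_head, sigma_i, small_cap, small_space, small_stiffness):
        """Fault injection: one sign flip in B must violate the discrete
        zero-net-current identity."""
        cem = assemble_cem_system(
            small_head, sigma_i, small_cap, stiffness=small_stiffness
        )
        bad = cem.B.tolil(copy=True)
        row = cem.B[:, 0].nonzero()[0][0]
        bad[row, 0] = -bad[row, 0]
        cem_bad = type(cem)(
            cem.A, sp.csr_matrix(bad), cem.C, cem.ground_node, cem.mesh, cem.cap, cem.sigma_tag
        )
        x = np.zeros(len(small_space))
        x[5] = 1.0
        sol = solve_forward(cem_bad, x, small_space.G)
        cur = net_electrode_currents(cem, sol)  # checked against the true B
        scale = np.abs(cem.C * sol.v).max()
        assert np.abs(cur).max() > 1e-10 * scale
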