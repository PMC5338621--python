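"""Whitney dipole source space: geometry, divergence matrix, sampling.

The divergence matrix is validated against an independent quadrature oracle
that evaluates the scaled face basis function w geometrically (piecewise
linear vector field with unit flux through the shared face, scaled by
4/||r_Pj - r_Pi||), takes its divergence by finite differences and
integrates psi (div w) with a second-order rule on each adjacent tet.
"""

import numpy as np
import pytest

from cemfwd import (
    TetMesh,
    build_source_space,
    locate_test_sources,
    sample_sources_by_eccentricity,
)
from cemfwd.exceptions import ConfigurationError, SamplingError
from cemfwd.head_geometry import BRAIN, DEFAULT_FONTANELS

# second-order quadrature on the reference tet (4 points, weights 1/4)
_QA, _QB = 0.5854101966249685, 0.1381966011250105
_QPTS = np.array(
    [
        [_QA, _QB, _QB],
        [_QB, _QA, _QB],
        [_QB, _QB, _QA],
        [_QB, _QB, _QB],
    ]
)


def _whitney_field(point, apex, vol, scale, sign):
    """w(x) = sign * scale * (x - apex) / (3V) on one adjacent tet."""
    return sign * scale * (point - apex) / (3.0 * vol)


def _divergence_fd(point, apex, vol, scale, sign, h=1e-7):
    div = 0.0
    for k in range(3):
        e = np.zeros(3)
        e[k] = h
        div += (
            _whitney_field(point + e, apex, vol, scale, sign)[k]
            - _whitney_field(point - e, apex, vol, scale, sign)[k]
        ) / (2 * h)
    return div


def _adjacent_tets(mesh, space, k):
    face = set(space.faces[k].tolist())
    p_i, p_j = space.node_pairs[k]
    out = {}
    for t, tet in enumerate(mesh.tets):
        s = set(tet.tolist())
        if face <= s:
            if p_i in s:
                out["i"] = t
            elif p_j in s:
                out["j"] = t
    return out


def _quadrature_column_and_moment(mesh, space, k):
    """Independent oracle: G column by quadrature and int w dV."""
    p_i, p_j = space.node_pairs[k]
    d = np.linalg.norm(mesh.nodes[p_j] - mesh.nodes[p_i])
    scale = 4.0 / d
    adj = _adjacent_tets(mesh, space, k)
    vols = mesh.tet_volumes()
    col = np.zeros(len(mesh.nodes))
    moment = np.zeros(3)
    for side, sign, apex in (("i", 1.0, p_i), ("j", -1.0, p_j)):
        t = adj[side]
        verts = mesh.nodes[mesh.tets[t]]
        apex_pos = mesh.nodes[apex]
        # map reference quadrature points into the tet
        lam0 = 1.0 - _QPTS.sum(axis=1)
        bary = np.column_stack([lam0, _QPTS])
        pts = bary @ verts
        w_quad = vols[t] / 4.0
        for q, point in enumerate(pts):
            div = _divergence_fd(point, apex_pos, vols[t], scale, sign)
            moment += w_quad * _whitney_field(point, apex_pos, vols[t], scale, sign)
            for local, node in enumerate(mesh.tets[t]):
                col[node] += w_quad * bary[q, local] * div
    return col, moment


class TestTwoTetExample:
    def test_dipole_geometry_and_column(self):
        """Two tets sharing a face; the dipole connects the opposite nodes
        with a unit moment and a two-entry divergence column."""
        nodes = np.array(
            [
                [0.0, 0.0, 0.0],  # P_i
                [1.0, 0.0, 0.0],  # P_j (opposite sides of face 2,3,4)
                [0.5, 1.0, 0.0],
                [0.5, 0.0, 1.0],
                [0.5, -1.0, 0.2],
            ]
        )
        tets = np.array([[0, 2, 3, 4], [1, 2, 3, 4]])
        mesh = TetMesh(nodes, tets, np.array([BRAIN, BRAIN]))
        space = build_source_space(mesh, exclude_surface_layers=0)
        assert len(space) == 1
        np.testing.assert_allclose(space.moments[0], [1.0, 0.0, 0.0], atol=1e-15)
        np.testing.assert_allclose(space.positions[0], [0.5, 0.0, 0.0], atol=1e-15)
        col = space.G[:, 0].toarray().ravel()
        np.testing.assert_allclose(col[[0, 1]], [1.0, -1.0], atol=1e-15)
        np.testing.assert_allclose(col[2:], 0.0, atol=1e-15)

    def test_column_and_moment_match_quadrature(self):
        nodes = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.1, 0.2, -0.1],
                [0.5, 1.0, 0.0],
                [0.4, 0.1, 1.0],
                [0.5, -0.9, 0.3],
            ]
        )
        tets = np.array([[0, 2, 3, 4], [1, 2, 3, 4]])
        mesh = TetMesh(nodes, tets, np.array([BRAIN, BRAIN]))
        space = build_source_space(mesh, exclude_surface_layers=0)
        col_ref, moment_ref = _quadrature_column_and_moment(mesh, space, 0)
        col = space.G[:, 0].toarray().ravel()
        d = space.pole_separations[0]
        np.testing.assert_allclose(col, col_ref, atol=1e-7 / d)
        np.testing.assert_allclose(moment_ref, space.moments[0], atol=1e-7)


class TestSourceSpaceOnHead:
    def test_columns_match_quadrature_oracle(self, small_head, small_space):
        rng = np.random.default_rng(0)
        for k in rng.choice(len(small_space), 5, replace=False):
            col_ref, moment_ref = _quadrature_column_and_moment(
                small_head, small_space, int(k)
            )
            col = small_space.G[:, int(k)].toarray().ravel()
            d = small_space.pole_separations[int(k)]
            # FD divergence limits agreement to ~sqrt(eps) relative
            np.testing.assert_allclose(col * d, col_ref * d, atol=2e-6)
            np.testing.assert_allclose(moment_ref, small_space.moments[int(k)], atol=1e-6)

    def test_column_sums_vanish(self, small_space):
        colsums = np.abs(np.asarray(small_space.G.sum(axis=0))).ravel()
        assert colsums.max() < 1e-12 * np.abs(small_space.G.data).max()

    def test_columns_have_two_entries(self, small_space):
        nnz = np.diff(small_space.G.tocsc().indptr)
        assert np.all(nnz == 2)

    def test_unit_moments(self, small_space):
        np.testing.assert_allclose(
            np.linalg.norm(small_space.moments, axis=1), 1.0, rtol=1e-12
        )

    def test_surface_exclusion_removes_interface_dipoles(self, small_head):
        s0 = build_source_space(small_head, exclude_surface_layers=0)
        s1 = build_source_space(small_head, exclude_surface_layers=1)
        pairs0 = set(map(tuple, s0.node_pairs))
        pairs1 = set(map(tuple, s1.node_pairs))
        assert pairs1 < pairs0
        # the removed dipoles are exactly those touching an interface node
        interface = set(s1.excluded_nodes.tolist())
        removed = pairs0 - pairs1
        assert all(pi in interface or pj in interface for pi, pj in removed)
        assert not any(
            pi in interface or pj in interface for pi, pj in pairs1
        )

    def test_positions_inside_brain(self, small_space):
        assert np.linalg.norm(small_space.positions, axis=1).max() < 0.037

    def test_deterministic_count(self, small_head, small_space):
        again = build_source_space(small_head)
        assert len(again) == len(small_space)
        np.testing.assert_array_equal(again.node_pairs, small_space.node_pairs)


class TestEccentricitySampling:
    def test_default_design_five_levels_of_100(self, fine_space):
        """The default design: 5 eccentricity levels x 100 random sources,
        on a source space fine enough to populate the deepest band."""
        samples = sample_sources_by_eccentricity(fine_space, seed=4)
        assert set(samples) == {0.2, 0.4, 0.6, 0.8, 0.98}
        assert all(len(v) == 100 for v in samples.values())

    def test_same_seed_reproduces(self, fine_space):
        a = sample_sources_by_eccentricity(fine_space, seed=9)
        b = sample_sources_by_eccentricity(fine_space, seed=9)
        for e in a:
            np.testing.assert_array_equal(a[e], b[e])

    def test_band_membership(self, fine_space):
        samples = sample_sources_by_eccentricity(fine_space, seed=4)
        rad = np.linalg.norm(fine_space.positions, axis=1)
        rel = rad / rad.max()
        for e, idx in samples.items():
            assert np.all(np.abs(rel[idx] - e) <= 0.02 + 1e-12)

    def test_insufficient_band_raises(self, small_space):
        with pytest.raises(SamplingError):
            sample_sources_by_eccentricity(
                small_space, eccentricities=(0.2,), n_per_level=10**6
            )


class TestFixedTestSources:
    def test_amplitudes_are_ten_nanoamperemeters(self, small_space, small_cap):
        idx, amp = locate_test_sources(
            small_space, small_cap, "A", DEFAULT_FONTANELS
        )
        assert amp == 1e-8

    def test_source_a_adjacent_to_c6_electrode(self, small_space, small_cap):
        """Source A sits within one mesh cell of the admissible dipole
        nearest the C6-like electrode (ties broken toward radial moments)."""
        idx, _ = locate_test_sources(small_space, small_cap, "A", DEFAULT_FONTANELS)
        c6 = small_cap.centers[small_cap.c6_index]
        d = np.linalg.norm(small_space.positions - c6, axis=1)
        assert d[idx] <= d.min() + 0.003 + 1e-12

    def test_source_b_inside_frontal_fontanel_cone(self, small_space, small_cap):
        idx, _ = locate_test_sources(small_space, small_cap, "B", DEFAULT_FONTANELS)
        frontal = DEFAULT_FONTANELS[0]
        assert frontal.contains(small_space.positions[idx])

    def test_source_b_without_fontanel_raises(self, small_space, small_cap):
        with pytest.raises(ConfigurationError):
            locate_test_sources(small_space, small_cap, "B", ())
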