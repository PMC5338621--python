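"""Finite-element forward solvers for the complete and point electrode models.

Piecewise-linear (P1) nodal elements on a labelled tetrahedral mesh.  The
complete electrode model (CEM) couples the interior Poisson problem to the
electrode voltages through the contact impedances: with stiffness-plus-
electrode-mass matrix A, electrode coupling B, impedance diagonal C and the
source vector G x, the discrete system is the symmetric block form

    [[A, -B], [-B^T, C]] [z; v] = [-G x; 0].

The electrode voltage v_l is then the area mean of the potential under the
contact patch, and the second block row enforces zero net current per
electrode.  The point electrode model (PEM) drops the boundary terms and
samples the potential at one scalp location per electrode.

Lead fields map unit-amplitude source columns of G to average-referenced
electrode voltages; three algebraically equivalent computation routes
(`schur`, `block`, `transfer`) are provided and must agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import (
    AssemblyError,
    GroundingError,
    SolverError,
    UnsupportedModelError,
    ValidationError,
)
from .head_geometry import ConductivityModel, ElectrodeCap, TetMesh

_DEGENERATE_REL_VOL = 1e-14


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_stiffness(mesh: TetMesh, sigma: ConductivityModel) -> sp.csr_matrix:
    """Stiffness matrix a_ij = int sigma grad(psi_i) . grad(psi_j) dV.

    Symmetric positive semidefinite with the constant vector in its null
    space; sigma is piecewise constant per tet.
    """
    p = mesh.nodes[mesh.tets]  # (T, 4, 3)
    d = p[:, 1:] - p[:, :1]  # edge matrix rows v1-v0, v2-v0, v3-v0
    vol6 = np.einsum("ti,ti->t", d[:, 0], np.cross(d[:, 1], d[:, 2]))
    if np.any(np.abs(vol6) <= 6 * _DEGENERATE_REL_VOL * np.abs(vol6).max()):
        t = int(np.argmin(np.abs(vol6)))
        raise AssemblyError(f"degenerate tetrahedron {t} (volume ~ 0)")
    # gradients of barycentric coordinates: rows of inv(d), grad(lambda_0) = -sum
    inv = np.linalg.inv(d)  # (T, 3, 3); columns are grads of lambda_1..3
    g = np.empty((len(p), 4, 3))
    g[:, 1:] = np.transpose(inv, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)

    st = sigma.per_tet(mesh) * np.abs(vol6) / 6.0
    ke = np.einsum("t,tid,tjd->tij", st, g, g)  # (T, 4, 4)

    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix((ke.reshape(-1), (rows, cols)), shape=(len(mesh.nodes),) * 2)
    return K.tocsr()


def _patch_boundary_terms(mesh: TetMesh, cap: ElectrodeCap):
    """Per-electrode surface mass matrices and int psi_i dS vectors.

    Exact P1 integrals on each contact triangle: the 3x3 triangle mass matrix
    is area * (1 + delta_ij) / 12 and int psi_i dS = area / 3 per vertex.
    """
    n = len(mesh.nodes)
    areas = mesh.boundary_areas()
    mass_rows, mass_cols, mass_vals = [], [], []
    b_cols = []
    for l, tri_idx in enumerate(cap.triangles):
        tris = mesh.boundary_tris[tri_idx]
        a = areas[tri_idx]
        w = 1.0 / (cap.impedances[l] * cap.areas[l])
        # mass term
        rows = np.repeat(tris, 3, axis=1).reshape(-1)
        cols = np.tile(tris, (1, 3)).reshape(-1)
        tmpl = (np.ones((3, 3)) + np.eye(3)) / 12.0
        vals = (w * a)[:, None, None] * tmpl
        mass_rows.append(rows)
        mass_cols.append(cols)
        mass_vals.append(vals.reshape(-1))
        # b column
        bl = np.zeros(n)
        np.add.at(bl, tris.reshape(-1), np.repeat(w * a / 3.0, 3))
        b_cols.append(bl)
    M = sp.coo_matrix(
        (np.concatenate(mass_vals), (np.concatenate(mass_rows), np.concatenate(mass_cols))),
        shape=(n, n),
    ).tocsr()
    B = sp.csr_matrix(np.stack(b_cols, axis=1))
    return M, B


def choose_ground_node(mesh: TetMesh, cap: ElectrodeCap) -> int:
    """Deterministic boundary node maximally distant from all electrode centers."""
    bnodes = mesh.boundary_nodes()
    under = np.unique(mesh.boundary_tris[cap.all_triangles()])
    free = np.setdiff1d(bnodes, under)
    if len(free) == 0:
        raise GroundingError("no boundary node outside all electrode patches")
    d = np.linalg.norm(mesh.nodes[free][:, None, :] - cap.centers[None], axis=2)
    return int(free[np.argmax(d.min(axis=1))])


def _ground(A: sp.csr_matrix, node: int) -> sp.csr_matrix:
    """Symmetric grounding: zero row and column of ``node``, unit diagonal.

    Equivalent to the Kronecker-delta ground row whenever the right-hand side
    vanishes at the ground node, but keeps the matrix symmetric.
    """
    A = A.tolil(copy=True)
    A[node, :] = 0.0
    A[:, node] = 0.0
    A[node, node] = 1.0
    return A.tocsr()


@dataclass
class CemSystem:
    """Assembled CEM block system (A, B, C) with grounding metadata."""

    A: sp.csr_matrix
    B: sp.csr_matrix
    C: np.ndarray  # diagonal entries c_ll = 1 / Z_l
    ground_node: int
    mesh: TetMesh
    cap: ElectrodeCap
    sigma_tag: str
    _block_factor: object = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.B.shape[1]

    def block_matrix(self) -> sp.csr_matrix:
        return sp.bmat(
            [[self.A, -self.B], [-self.B.T, sp.diags(self.C)]], format="csr"
        )

    def block_factorization(self):
        if self._block_factor is None:
            self._block_factor = spla.splu(self.block_matrix().tocsc())
        return self._block_factor


@dataclass
class PemSystem:
    """Grounded stiffness A' with point-evaluation matrix B'."""

    A: sp.csr_matrix
    B: sp.csr_matrix  # N x L nodal interpolation weights at electrode points
    electrode_nodes: np.ndarray  # snapped node index per electrode (-1 if barycentric)
    ground_node: int
    mesh: TetMesh
    sigma_tag: str
    _factor: object = field(default=None, repr=False)

    @property
    def n_electrodes(self) -> int:
        return self.B.shape[1]

    def factorization(self):
        if self._factor is None:
            self._factor = spla.splu(self.A.tocsc())
        return self._factor


def assemble_cem_system(
    mesh: TetMesh,
    sigma: ConductivityModel,
    cap: ElectrodeCap,
    stiffness: sp.csr_matrix | None = None,
    ground_node: int | None = None,
) -> CemSystem:
    """Assemble the CEM matrices for a given cap and conductivity model.

    The electrode boundary mass enters A with the 1/(Z_l A_l) weight of the
    weak form, matching c_ll = 1/Z_l so that the block system is symmetric.
    Pass a precomputed ``stiffness`` to amortize assembly over impedance
    sweeps (the stiffness does not depend on the cap).
    """
    K = assemble_stiffness(mesh, sigma) if stiffness is None else stiffness
    M, B = _patch_boundary_terms(mesh, cap)
    if ground_node is None:
        ground_node = choose_ground_node(mesh, cap)
    if B[ground_node].count_nonzero():
        raise GroundingError("ground node lies under an electrode patch")
    A = _ground(K + M, ground_node)
    C = 1.0 / cap.impedances
    return CemSystem(A, B.tocsr(), C, ground_node, mesh, cap, sigma.tag)


def assemble_pem_system(
    mesh: TetMesh,
    sigma: ConductivityModel,
    cap_or_points,
    snap: bool = True,
    stiffness: sp.csr_matrix | None = None,
    ground_node: int | None = None,
    snap_tolerance: float = 0.01,
) -> PemSystem:
    """Assemble the PEM system.

    By default each electrode is snapped to its nearest scalp surface node
    (B' is then a 0/1 selection matrix); with ``snap=False`` the potential is
    interpolated barycentrically on the boundary triangle nearest each point.
    """
    if isinstance(cap_or_points, ElectrodeCap):
        points = cap_or_points.centers
        cap = cap_or_points
    else:
        points = np.asarray(cap_or_points, dtype=float)
        cap = None
    K = assemble_stiffness(mesh, sigma) if stiffness is None else stiffness
    n = len(mesh.nodes)

    bnodes = mesh.boundary_nodes()
    if snap:
        d = np.linalg.norm(mesh.nodes[bnodes][:, None] - points[None], axis=2)
        worst = d.min(axis=0).max()
        if worst > snap_tolerance:
            raise ValidationError(
                f"electrode point {worst:.4g} m from nearest surface node"
            )
        enodes = bnodes[np.argmin(d, axis=0)]
        B = sp.csr_matrix(
            (np.ones(len(points)), (enodes, np.arange(len(points)))),
            shape=(n, len(points)),
        )
    else:
        cents = mesh.boundary_centroids()
        d = np.linalg.norm(cents[:, None] - points[None], axis=2)
        tri = np.argmin(d, axis=0)
        if d[tri, np.arange(len(points))].max() > snap_tolerance:
            raise ValidationError("electrode point too far from the surface")
        rows, cols, vals = [], [], []
        for l, t in enumerate(tri):
            verts = mesh.boundary_tris[t]
            w = _barycentric_on_triangle(mesh.nodes[verts], points[l])
            rows.extend(verts)
            cols.extend([l] * 3)
            vals.extend(w)
        B = sp.csr_matrix((vals, (rows, cols)), shape=(n, len(points)))
        enodes = np.full(len(points), -1)

    if ground_node is None:
        if cap is not None:
            ground_node = choose_ground_node(mesh, cap)
        else:
            used = np.unique(B.nonzero()[0])
            free = np.setdiff1d(bnodes, used)
            if len(free) == 0:
                raise GroundingError("no boundary node free of electrodes")
            d = np.linalg.norm(mesh.nodes[free][:, None] - points[None], axis=2)
            ground_node = int(free[np.argmax(d.min(axis=1))])
    A = _ground(K, ground_node)
    return PemSystem(A, B, enodes, ground_node, mesh, sigma.tag)


def _barycentric_on_triangle(verts: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Barycentric weights of the in-plane projection of ``point``, clipped to
    the triangle and renormalized (weights sum to one)."""
    v0, v1, v2 = verts
    e1, e2 = v1 - v0, v2 - v0
    g = np.array([[e1 @ e1, e1 @ e2], [e1 @ e2, e2 @ e2]])
    rhs = np.array([e1 @ (point - v0), e2 @ (point - v0)])
    s, t = np.linalg.solve(g, rhs)
    w = np.clip([1.0 - s - t, s, t], 0.0, None)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Solves
# ---------------------------------------------------------------------------


@dataclass
class PotentialSolution:
    """Nodal potential coefficients z and electrode voltages v (volts)."""

    z: np.ndarray
    v: np.ndarray
    model: str  # "cem" | "pem"


def solve_forward(system, x, G, rtol: float = 1e-10) -> PotentialSolution:
    """Solve the forward problem for source amplitudes x (A*m).

    CEM: direct factorization of the symmetric block system with right-hand
    side [-G x; 0].  PEM: A' z = -G x and v = B'^T z.  The residual of the
    solved system is checked against ``rtol`` times the right-hand side norm.
    """
    x = np.asarray(x, dtype=float)
    f = -(G @ x)
    if not np.all(np.isfinite(f)):
        raise ValidationError("non-finite source right-hand side")
    if isinstance(system, CemSystem):
        rhs = np.concatenate([f, np.zeros(system.n_electrodes)])
        sol = system.block_factorization().solve(rhs)
        res = np.linalg.norm(system.block_matrix() @ sol - rhs)
        scale = np.linalg.norm(rhs)
        if scale > 0 and res > rtol * scale:
            raise SolverError("block solve residual above tolerance", residual=res)
        n = system.n_nodes
        return PotentialSolution(sol[:n], sol[n:], "cem")
    if isinstance(system, PemSystem):
        z = system.factorization().solve(f)
        res = np.linalg.norm(system.A @ z - f)
        scale = np.linalg.norm(f)
        if scale > 0 and res > rtol * scale:
            raise SolverError("PEM solve residual above tolerance", residual=res)
        return PotentialSolution(z, system.B.T @ z, "pem")
    raise UnsupportedModelError(f"unknown system type {type(system)!r}")


def net_electrode_currents(system: CemSystem, solution: PotentialSolution) -> np.ndarray:
    """Discrete per-electrode net current (amperes).

    I_l = (1/(Z_l A_l)) int_{e_l} (u - U_l) dS, which the second block row of
    the CEM system forces to zero.
    """
    if solution.model != "cem":
        raise UnsupportedModelError("net electrode currents are a CEM quantity")
    return np.asarray(system.B.T @ solution.z - system.C * solution.v)


def subelectrode_variation(
    solution: PotentialSolution, mesh: TetMesh, cap: ElectrodeCap, electrode: int
) -> np.ndarray:
    """Potential variation u - U_l at the contact-triangle centroids.

    The area-weighted mean vanishes because U_l is the area mean of u over
    the patch.
    """
    if solution.model != "cem":
        raise UnsupportedModelError("subelectrode variation requires a CEM solution")
    tris = mesh.boundary_tris[cap.triangles[electrode]]
    u_cent = solution.z[tris].mean(axis=1)
    return u_cent - solution.v[electrode]


# ---------------------------------------------------------------------------
# Lead fields
# ---------------------------------------------------------------------------


def average_reference_matrix(n: int) -> np.ndarray:
    """Centering matrix R (r_ll = 1 - 1/n, off-diagonal -1/n); idempotent."""
    return np.eye(n) - np.full((n, n), 1.0 / n)


@dataclass
class LeadField:
    """Average-referenced lead field: volts at L electrodes per unit (A*m)
    amplitude of each of M source-space dipoles."""

    matrix: np.ndarray
    model: str  # "cem" | "pem"
    impedances: np.ndarray | None
    referenced: bool = True
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.matrix.shape


def _dense_cols(lu, B: sp.csr_matrix) -> np.ndarray:
    return lu.solve(np.asarray(B.todense()))


def _transfer_solve(A: sp.csr_matrix, B: sp.csr_matrix, rtol: float) -> np.ndarray:
    """Iterative route of the transfer-matrix equation A H^T = B: one
    Jacobi-preconditioned CG solve per electrode (A is SPD after grounding)."""
    n, L = B.shape
    d = A.diagonal()
    M = spla.LinearOperator((n, n), lambda x: x / d)
    Bd = np.asarray(B.todense())
    H = np.empty((n, L))
    maxiter = int(10 * np.sqrt(n)) + 100
    for l in range(L):
        sol, info = spla.cg(A, Bd[:, l], rtol=rtol, atol=0.0, M=M, maxiter=maxiter)
        if info != 0:
            res = float(np.linalg.norm(A @ sol - Bd[:, l]))
            raise SolverError(f"CG failed for transfer column {l}", residual=res)
        H[:, l] = sol
    return H


def compute_lead_field(system, G, method: str = "schur", rtol: float = 1e-10) -> LeadField:
    """Lead field L = R (B^T A^-1 B - C)^-1 B^T A^-1 G (CEM) or the PEM
    analogue, with the average-reference matrix R applied last.

    Methods (CEM): ``schur`` factorizes A directly; ``block`` factorizes the
    condensed matrix A - B C^-1 B^T and uses v = -C^-1 B^T (.)^-1 G;
    ``transfer`` computes H = B^T A^-1 by iterative solves.  All routes agree
    to solver accuracy.
    """
    if isinstance(system, PemSystem):
        lu = system.factorization()
        W = _dense_cols(lu, system.B)  # A'^-1 B'
        pre = -(W.T @ G)  # v = -B'^T A'^-1 G x
        R = average_reference_matrix(system.n_electrodes)
        return LeadField(
            np.asarray(R @ pre), "pem", None, True, {"sigma": system.sigma_tag}
        )
    if not isinstance(system, CemSystem):
        raise UnsupportedModelError(f"unknown system type {type(system)!r}")

    L = system.n_electrodes
    Cd = system.C
    if method == "schur":
        lu = spla.splu(system.A.tocsc())
        X = _dense_cols(lu, system.B)  # A^-1 B
        S = system.B.T @ X - np.diag(Cd)
        T = X.T @ G
        pre = _solve_schur(S, np.asarray(T))
    elif method == "block":
        K = (system.A - system.B.multiply(1.0 / Cd) @ system.B.T).tocsc()
        lu = spla.splu(K)
        Y = _dense_cols(lu, system.B)
        pre = -(Y.T @ G) / Cd[:, None]
    elif method == "transfer":
        H = _transfer_solve(system.A, system.B, rtol).T  # B^T A^-1
        S = H @ system.B - np.diag(Cd)
        pre = _solve_schur(S, np.asarray(H @ G))
    else:
        raise ValidationError(f"unknown lead-field method {method!r}")
    R = average_reference_matrix(L)
    return LeadField(
        np.asarray(R @ pre),
        "cem",
        system.cap.impedances.copy(),
        True,
        {"sigma": system.sigma_tag, "method": method},
    )


def _solve_schur(S: np.ndarray, T: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(S, T)
    except np.linalg.LinAlgError:
        raise SolverError(
            "singular Schur complement (degenerate impedances or patches)"
        ) from None
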