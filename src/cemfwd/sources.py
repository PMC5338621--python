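"""Whitney (Raviart-Thomas) synthetic-dipole source space.

Each interior face F of the source compartment shared by two tetrahedra
defines one synthetic dipole: with P_i and P_j the two vertices opposite F,
the dipole sits at the midpoint r_w = (r_Pi + r_Pj)/2 with unit moment
q_w = (r_Pj - r_Pi)/||r_Pj - r_Pi||.  The face-based vector basis function w
scaled to have that moment (int w dV = q_w) pairs with the nodal basis as

    int psi (div w) dV = (S_{psi,Pi} - S_{psi,Pj}) / ||r_Pj - r_Pi||,

so each column of the divergence matrix G has exactly two nonzeros,
+1/d at row P_i and -1/d at row P_j.  Physically the right-hand side -G x
injects current +x/d at the positive pole P_j and removes it at P_i, the
two-monopole representation of a dipole pointing from P_i to P_j.

Dipoles touching the compartment surface are excluded (conductivity jumps at
the brain boundary otherwise produce outlier potentials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .exceptions import ConfigurationError, SamplingError
from .head_geometry import BRAIN, ElectrodeCap, Fontanel, TetMesh

_FACE_OF_VERTEX = [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]


@dataclass
class WhitneySourceSpace:
    """Admissible face dipoles with positions, unit moments and the sparse
    divergence matrix G (N nodes x M dipoles)."""

    positions: np.ndarray  # (M, 3), meters
    moments: np.ndarray  # (M, 3), unit vectors P_i -> P_j
    node_pairs: np.ndarray  # (M, 2) = (P_i, P_j)
    faces: np.ndarray  # (M, 3) shared-face node triples
    G: sp.csr_matrix
    compartment: int
    excluded_nodes: np.ndarray  # node indices removed by the surface exclusion
    pole_separations: np.ndarray = None  # type: ignore[assignment]  # (M,) ||r_Pj - r_Pi||

    def __len__(self) -> int:
        return self.positions.shape[0]

    def mean_spacing(self) -> float:
        """Mean inter-dipole spacing (V/M)^(1/3) in meters, with V the convex
        hull volume of the dipole cloud: the resolution scale of the source
        space.  (Nearest-neighbor distances are not used here; on structured
        meshes face midpoints can lie much closer than the mesh resolution.)
        """
        from scipy.spatial import ConvexHull

        vol = ConvexHull(self.positions).volume
        return float((vol / len(self)) ** (1.0 / 3.0))

    def nearest_neighbor_spacing(self) -> float:
        """Mean nearest-neighbor distance between dipole positions (meters)."""
        from scipy.spatial import cKDTree

        d, _ = cKDTree(self.positions).query(self.positions, k=2)
        return float(d[:, 1].mean())

    def to_dataframe(self):
        """One row per dipole: index, position, unit moment, node pair and
        pole separation; suitable for delimited-text export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "dipole": np.arange(len(self)),
                "x_m": self.positions[:, 0],
                "y_m": self.positions[:, 1],
                "z_m": self.positions[:, 2],
                "qx": self.moments[:, 0],
                "qy": self.moments[:, 1],
                "qz": self.moments[:, 2],
                "node_i": self.node_pairs[:, 0],
                "node_j": self.node_pairs[:, 1],
                "separation_m": self.pole_separations,
                "compartment": self.compartment,
            }
        )


def build_source_space(
    mesh: TetMesh,
    compartment: int = BRAIN,
    exclude_surface_layers: int = 1,
) -> WhitneySourceSpace:
    """Build the synthetic-dipole space of a compartment.

    One dipole per interior face whose two adjacent tets both carry
    ``compartment``'s label and whose opposite vertices are at least
    ``exclude_surface_layers`` node layers away from the compartment boundary
    (layer 1 = the boundary nodes themselves).
    """
    in_comp = mesh.labels == compartment
    if not np.any(in_comp):
        raise ConfigurationError(f"compartment {compartment} not present in mesh")
    tets = mesh.tets[in_comp]

    faces = tets[:, _FACE_OF_VERTEX].reshape(-1, 3)
    opp = tets[:, [0, 1, 2, 3]].reshape(-1)
    key = np.sort(faces, axis=1)
    uniq, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)

    # nodes on the compartment boundary: nodes of faces not shared by two
    # compartment tets
    surf_nodes = np.unique(uniq[counts == 1])
    excluded = _expand_layers(tets, surf_nodes, exclude_surface_layers)

    shared = counts == 2
    order = np.argsort(inverse, kind="stable")
    inv_sorted = inverse[order]
    # for each unique face, the (up to 2) incident half-faces in sorted order
    starts = np.searchsorted(inv_sorted, np.arange(len(uniq)))
    f1 = order[starts[shared]]
    f2 = order[starts[shared] + 1]
    pa, pb = opp[f1], opp[f2]
    p_i = np.minimum(pa, pb)
    p_j = np.maximum(pa, pb)

    keep = ~(np.isin(p_i, excluded) | np.isin(p_j, excluded))
    p_i, p_j = p_i[keep], p_j[keep]
    face_nodes = uniq[shared][keep]
    # distinct faces can share an opposite-node pair on structured meshes;
    # such dipoles are identical (same position, moment and G column)
    _, first = np.unique(p_i * np.int64(len(mesh.nodes)) + p_j, return_index=True)
    p_i, p_j, face_nodes = p_i[first], p_j[first], face_nodes[first]
    if len(p_i) == 0:
        raise ConfigurationError("source space empty after surface exclusion")

    ri, rj = mesh.nodes[p_i], mesh.nodes[p_j]
    d = np.linalg.norm(rj - ri, axis=1)
    positions = 0.5 * (ri + rj)
    moments = (rj - ri) / d[:, None]

    m = len(p_i)
    rows = np.concatenate([p_i, p_j])
    cols = np.tile(np.arange(m), 2)
    vals = np.concatenate([1.0 / d, -1.0 / d])
    G = sp.csr_matrix((vals, (rows, cols)), shape=(len(mesh.nodes), m))

    return WhitneySourceSpace(
        positions,
        moments,
        np.stack([p_i, p_j], axis=1),
        face_nodes,
        G,
        compartment,
        excluded,
        d,
    )


def _expand_layers(tets: np.ndarray, seed_nodes: np.ndarray, layers: int) -> np.ndarray:
    """Nodes within ``layers`` node-layers of the seed set, via tet-edge
    adjacency restricted to the compartment (layer 1 = the seeds)."""
    if layers <= 0:
        return np.array([], dtype=np.int64)
    current = set(seed_nodes.tolist())
    if layers > 1:
        adj: dict[int, set] = {}
        for tet in tets:
            s = tet.tolist()
            for a in s:
                adj.setdefault(a, set()).update(s)
        frontier = set(current)
        for _ in range(layers - 1):
            nxt = set()
            for a in frontier:
                nxt.update(adj.get(a, ()))
            nxt -= current
            current |= nxt
            frontier = nxt
    return np.array(sorted(current), dtype=np.int64)


def sample_sources_by_eccentricity(
    space: WhitneySourceSpace,
    eccentricities=(0.2, 0.4, 0.6, 0.8, 0.98),
    n_per_level: int = 100,
    tolerance: float = 0.02,
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """Uniform random dipole samples in eccentricity bands.

    Eccentricity is the relative norm ||r_w|| / R_ref with R_ref the largest
    admissible dipole radius, so the most superficial sources sit near 1.
    """
    radii = np.linalg.norm(space.positions, axis=1)
    r_ref = radii.max()
    rel = radii / r_ref
    rng = np.random.default_rng(seed)
    out: dict[float, np.ndarray] = {}
    for ecc in eccentricities:
        if not 0.0 < ecc < 1.0 + tolerance:
            raise ConfigurationError(f"eccentricity {ecc} outside (0, 1)")
        band = np.nonzero(np.abs(rel - ecc) <= tolerance)[0]
        if len(band) < n_per_level:
            raise SamplingError(
                f"only {len(band)} admissible dipoles within {tolerance} of "
                f"eccentricity {ecc}; enlarge the tolerance or refine the mesh"
            )
        out[ecc] = np.sort(rng.choice(band, size=n_per_level, replace=False))
    return out


#: Amplitude of the two fixed test sources: 10 nAm.
TEST_SOURCE_AMPLITUDE = 1e-8


def locate_test_sources(
    space: WhitneySourceSpace,
    cap: ElectrodeCap,
    mode: str,
    fontanels: tuple[Fontanel, ...] = (),
) -> tuple[int, float]:
    """The two fixed 10-nAm test sources.

    Mode ``A``: the admissible dipole nearest the C6-like electrode center.
    Mode ``B``: the admissible dipole beneath the frontal fontanel cone
    nearest the ray from the head center through the Fz-like electrode.
    Returns (dipole index, amplitude in A*m).
    """
    mode = mode.upper()
    window = 0.003  # candidate window (m): dipoles within one mesh cell of the best
    if mode == "A":
        c = cap.centers[cap.c6_index]
        dist = np.linalg.norm(space.positions - c, axis=1)
        cand = np.nonzero(dist <= dist.min() + window)[0]
        to_elec = c - space.positions[cand]
        to_elec /= np.linalg.norm(to_elec, axis=1, keepdims=True)
        radiality = np.abs(np.einsum("kd,kd->k", space.moments[cand], to_elec))
        idx = int(cand[np.argmax(radiality)])
        return idx, TEST_SOURCE_AMPLITUDE
    if mode == "B":
        if not fontanels:
            raise ConfigurationError("source B requires a configured fontanel cone")
        fz_dir = cap.centers[cap.fz_index]
        fz_dir = fz_dir / np.linalg.norm(fz_dir)
        frontal = max(fontanels, key=lambda fo: float(fo.unit() @ fz_dir))
        inside = np.nonzero(frontal.contains(space.positions))[0]
        if len(inside) == 0:
            raise ConfigurationError("no admissible dipole under the frontal fontanel")
        pos = space.positions[inside]
        along = pos @ fz_dir
        off_axis = np.linalg.norm(pos - along[:, None] * fz_dir, axis=1)
        cand = inside[off_axis <= off_axis.min() + window]
        radiality = np.abs(space.moments[cand] @ fz_dir)
        idx = int(cand[np.argmax(radiality)])
        return idx, TEST_SOURCE_AMPLITUDE
    raise ConfigurationError(f"unknown test source mode {mode!r}")
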