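"""Tetrahedral head-mesh data model and the synthetic layered-sphere neonatal head.

The computational domain is a four-compartment ball (brain, CSF, skull, scalp)
with optional circular low-ossification openings in the skull standing in for
the fontanels and sutures of a neonatal head.  The mesh generator is fully
deterministic: a cube grid is split into six Kuhn tetrahedra per cell and
mapped onto the ball by a piecewise-linear radial warp that places every
compartment interface exactly on a grid shell, so no tetrahedron straddles a
tissue boundary.

Units are meters throughout; the head center sits at the origin.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import (
    EmptyElectrodeError,
    LabelDataError,
    MeshError,
    OverlapError,
    ResolutionError,
    UnsupportedCellError,
    ValidationError,
)

# Compartment identifiers used in per-tet labels.
BRAIN = 1
CSF = 2
SKULL = 3
SCALP = 4
FONTANEL = 5

COMPARTMENT_NAMES = {
    BRAIN: "brain",
    CSF: "csf",
    SKULL: "skull",
    SCALP: "scalp",
    FONTANEL: "fontanel",
}

#: Default shell outer radii in meters (brain, CSF, skull, scalp) sized for a
#: 3-day-old neonate with a ~10.4 cm head diameter.
DEFAULT_RADII = (0.037, 0.042, 0.047, 0.052)

# Outward-oriented faces of a positively oriented tet (v0, v1, v2, v3).
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


# ---------------------------------------------------------------------------
# Core mesh type
# ---------------------------------------------------------------------------


@dataclass
class TetMesh:
    """Labelled tetrahedral volume mesh with an oriented surface triangulation.

    Attributes
    ----------
    nodes : (N, 3) float array
        Node coordinates in meters.
    tets : (T, 4) int array
        Node indices per tetrahedron, ordered for positive signed volume.
    labels : (T,) int array
        Compartment identifier per tetrahedron.
    boundary_tris : (Tb, 3) int array
        Triangles belonging to exactly one tet, oriented so the normal
        ``cross(b - a, c - a)`` points out of the domain.
    """

    nodes: np.ndarray
    tets: np.ndarray
    labels: np.ndarray
    boundary_tris: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be a (T, 4) index array")
        if self.labels.shape[0] != self.tets.shape[0]:
            raise MeshError("one label per tetrahedron required")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise MeshError("tet node index out of range")
        self._fix_orientation()
        if self.boundary_tris is None:
            self.boundary_tris = self.extract_boundary()
        else:
            self.boundary_tris = np.ascontiguousarray(self.boundary_tris, dtype=np.int64)

    # -- geometry helpers ---------------------------------------------------

    def _fix_orientation(self) -> None:
        vol = self.tet_volumes(signed=True)
        neg = vol < 0
        if np.any(neg):
            self.tets[neg] = self.tets[neg][:, [0, 1, 3, 2]]
        if np.any(self.tet_volumes(signed=True) <= 0):
            raise MeshError("mesh contains a degenerate (zero-volume) tetrahedron")

    def tet_volumes(self, signed: bool = False) -> np.ndarray:
        p = self.nodes[self.tets]
        d = p[:, 1:] - p[:, :1]
        vol = np.einsum("ti,ti->t", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0
        return vol if signed else np.abs(vol)

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def extract_boundary(self) -> np.ndarray:
        """Faces belonging to exactly one tet, outward-oriented."""
        faces = self.tets[:, _TET_FACES].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inverse] == 1]

    def face_counts(self) -> tuple[int, int]:
        """(number of interior faces, number of boundary faces)."""
        key = np.sort(self.tets[:, _TET_FACES].reshape(-1, 3), axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        return int(np.sum(counts == 2)), int(np.sum(counts == 1))

    def boundary_areas(self) -> np.ndarray:
        p = self.nodes[self.boundary_tris]
        return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    def boundary_centroids(self) -> np.ndarray:
        return self.nodes[self.boundary_tris].mean(axis=1)

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_tris)

    def validate(self) -> None:
        """Raise MeshError if any structural invariant is violated."""
        if np.any(self.tet_volumes(signed=True) <= 0):
            raise MeshError("non-positive tet volume")
        if not np.array_equal(
            np.unique(np.sort(self.boundary_tris, axis=1), axis=0),
            np.unique(np.sort(self.extract_boundary(), axis=1), axis=0),
        ):
            raise MeshError("boundary_tris is not the set of single-tet faces")
        # outward orientation: normal dot (face centroid - adjacent tet centroid) > 0
        p = self.nodes[self.boundary_tris]
        normals = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        fc = p.mean(axis=1)
        owner = self._boundary_owner_tets()
        out = np.einsum("fi,fi->f", normals, fc - self.tet_centroids()[owner])
        if np.any(out <= 0):
            raise MeshError("boundary triangle oriented inward")

    def _boundary_owner_tets(self) -> np.ndarray:
        faces = np.sort(self.tets[:, _TET_FACES].reshape(-1, 3), axis=1)
        order = np.lexsort(faces.T)
        lookup = {tuple(f): i // 4 for i, f in zip(order, faces[order])}
        return np.array([lookup[tuple(f)] for f in np.sort(self.boundary_tris, axis=1)])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.nodes, self.tets, self.labels):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Conductivity models (per-compartment isotropic sigma, S/m)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConductivityModel:
    """Isotropic conductivity per compartment, S/m.

    Tags I-III are the three neonatal variants: I is the open-skull reference
    (conductive fontanels), II closes the skull by giving the fontanel
    compartment bone conductivity, III raises bone conductivity to 0.1 S/m.
    """

    tag: str
    values: dict[int, float]

    def __post_init__(self):
        if any(v <= 0 for v in self.values.values()):
            raise ValidationError("conductivities must be strictly positive")

    def per_tet(self, mesh: TetMesh) -> np.ndarray:
        try:
            table = np.zeros(max(self.values) + 1)
            for k, v in self.values.items():
                table[k] = v
            sigma = table[mesh.labels]
        except IndexError:
            raise ValidationError("mesh label without conductivity value") from None
        if np.any(sigma <= 0):
            raise ValidationError("mesh label without conductivity value")
        return sigma

    @classmethod
    def model(cls, tag: str) -> "ConductivityModel":
        tag = tag.upper()
        base = {SCALP: 0.33, SKULL: 0.04, FONTANEL: 0.3, CSF: 1.79, BRAIN: 0.33}
        if tag == "I":
            return cls("I", base)
        if tag == "II":
            return cls("II", {**base, FONTANEL: 0.04})
        if tag == "III":
            return cls("III", {**base, SKULL: 0.1})
        raise ValidationError(f"unknown conductivity model tag {tag!r}")

    @classmethod
    def homogeneous(cls, sigma: float = 0.33) -> "ConductivityModel":
        return cls("homogeneous", {k: sigma for k in (BRAIN, CSF, SKULL, SCALP, FONTANEL)})


# ---------------------------------------------------------------------------
# Mesh I/O: legacy ASCII VTK unstructured grid with integer cell data
# ---------------------------------------------------------------------------

_VTK_TET = 10


def write_mesh(mesh: TetMesh, path, label_name: str = "compartment") -> None:
    """Write a labelled tet mesh as legacy ASCII VTK (loadable by ParaView etc.)."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncemfwd head mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(mesh.nodes)} double\n")
        for p in mesh.nodes:
            f.write("%.17g %.17g %.17g\n" % tuple(p))
        t = len(mesh.tets)
        f.write(f"CELLS {t} {5 * t}\n")
        for tet in mesh.tets:
            f.write("4 %d %d %d %d\n" % tuple(tet))
        f.write(f"CELL_TYPES {t}\n")
        f.write("\n".join(["10"] * t) + "\n")
        f.write(f"CELL_DATA {t}\nSCALARS {label_name} int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(v)) for v in mesh.labels) + "\n")


def read_mesh(path, label_name: str = "compartment") -> TetMesh:
    """Read a legacy ASCII VTK tet mesh with an integer cell-data label field."""
    with open(path) as f:
        tokens = f.read().split()
    it = iter(range(len(tokens)))

    def find(word):
        for i, tok in enumerate(tokens):
            if tok == word:
                return i
        return None

    i = find("POINTS")
    if i is None:
        raise MeshError("not a legacy VTK unstructured grid (no POINTS)")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=np.float64).reshape(n, 3)

    i = find("CELLS")
    if i is None:
        raise MeshError("no CELLS section")
    t = int(tokens[i + 1])

    j = find("CELL_TYPES")
    types = np.array(tokens[j + 2 : j + 2 + t], dtype=np.int64)
    if np.any(types != _VTK_TET):
        raise UnsupportedCellError("mesh contains non-tetrahedral cells")
    raw = np.array(tokens[i + 3 : i + 3 + 5 * t], dtype=np.int64).reshape(t, 5)
    if np.any(raw[:, 0] != 4):
        raise UnsupportedCellError("tetrahedral cells must list exactly 4 nodes")

    i = find("SCALARS")
    if i is None or find("CELL_DATA") is None:
        raise LabelDataError(f"missing integer cell-data field {label_name!r}")
    if tokens[i + 1] != label_name:
        raise LabelDataError(
            f"cell-data field {tokens[i + 1]!r} found, expected {label_name!r}"
        )
    j = find("LOOKUP_TABLE")
    labels = np.array(tokens[j + 2 : j + 2 + t], dtype=np.int64)
    return TetMesh(pts, raw[:, 1:], labels)


# ---------------------------------------------------------------------------
# Synthetic layered-sphere head
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fontanel:
    """Conical skull opening: tets whose centroid direction lies within
    ``angular_radius`` of ``direction`` are relabelled FONTANEL."""

    direction: tuple[float, float, float]
    angular_radius: float  # radians, in (0, pi/2)

    def unit(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        return d / np.linalg.norm(d)

    def contains(self, points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(points, axis=-1)
        cosang = points @ self.unit() / np.where(r > 0, r, 1.0)
        return np.arccos(np.clip(cosang, -1.0, 1.0)) <= self.angular_radius


#: One large anterior opening at the vertex and two smaller lateral ones.
DEFAULT_FONTANELS = (
    Fontanel((0.0, 0.0, 1.0), 0.35),
    Fontanel((0.94, 0.0, 0.34), 0.15),
    Fontanel((-0.94, 0.0, 0.34), 0.15),
)

# Kuhn subdivision: 6 tets per cube cell sharing the main diagonal.
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _shell_layers(radii, target_edge_length):
    thick = np.diff(np.concatenate([[0.0], radii]))
    if target_edge_length > 2.0 * thick[1:].min() * (1.0 + 1e-9):
        raise ResolutionError(
            "target edge length %.4g m cannot resolve the thinnest shell (%.4g m)"
            % (target_edge_length, thick[1:].min())
        )
    layers = [max(2, round(thick[0] / target_edge_length))]
    layers += [max(1, round(t / target_edge_length)) for t in thick[1:]]
    return layers


def build_sphere_head(
    radii=DEFAULT_RADII,
    fontanels=DEFAULT_FONTANELS,
    target_edge_length: float = 0.005,
    seed: int = 0,
) -> TetMesh:
    """Deterministic quasi-uniform tetrahedral mesh of a four-shell ball.

    Parameters
    ----------
    radii
        Strictly increasing outer radii of brain, CSF, skull and scalp shells
        (meters).
    fontanels
        Conical skull openings; skull tets inside any cone are relabelled to
        the fontanel/suture compartment.  Pass ``()`` for a closed skull.
    target_edge_length
        Approximate radial layer thickness (meters); sets the resolution.
    seed
        Accepted for interface uniformity; the construction is deterministic
        and does not consume randomness.
    """
    radii = tuple(float(r) for r in radii)
    if len(radii) != 4 or np.any(np.diff(radii) <= 0) or radii[0] <= 0:
        raise ValidationError("radii must be 4 strictly increasing positive values")
    for fo in fontanels:
        if not (0.0 < fo.angular_radius < math.pi / 2):
            raise ValidationError("fontanel angular radius must be in (0, pi/2)")

    layers = _shell_layers(radii, target_edge_length)
    n = sum(layers)

    # grid nodes on [-n, n]^3
    axis = np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3).astype(np.float64)

    # cube -> ball: direction from the point, radius from the inf-norm shell,
    # warped so shell k_i maps exactly onto radius r_i
    rho_inf = np.max(np.abs(grid), axis=1) / n
    r2 = np.linalg.norm(grid, axis=1)
    direction = np.divide(grid, r2[:, None], out=np.zeros_like(grid), where=r2[:, None] > 0)
    knots = np.concatenate([[0.0], np.cumsum(layers)]) / n
    radius = np.interp(rho_inf, knots, np.concatenate([[0.0], radii]))
    nodes = direction * radius[:, None]

    # cells and their 8 corner node ids
    m = 2 * n + 1
    caxis = np.arange(2 * n)
    cx, cy, cz = np.meshgrid(caxis, caxis, caxis, indexing="ij")
    base = np.stack([cx, cy, cz], axis=-1).reshape(-1, 3)

    def nid(offset):
        q = base + offset
        return (q[:, 0] * m + q[:, 1]) * m + q[:, 2]

    corner = {  # corner index by (dx, dy, dz)
        (dx, dy, dz): nid(np.array([dx, dy, dz]))
        for dx in (0, 1)
        for dy in (0, 1)
        for dz in (0, 1)
    }
    e = np.eye(3, dtype=int)
    tet_blocks = []
    for p in _KUHN_PERMS:
        s1 = tuple(e[p[0]])
        s2 = tuple(e[p[0]] + e[p[1]])
        tet_blocks.append(
            np.stack([corner[0, 0, 0], corner[s1], corner[s2], corner[1, 1, 1]], axis=1)
        )
    tets = np.concatenate(tet_blocks, axis=0)

    # labels by centroid radius; interfaces sit exactly on grid shells so no
    # tet straddles two compartments
    centroids = nodes[tets].mean(axis=1)
    cr = np.linalg.norm(centroids, axis=1)
    labels = np.searchsorted(np.asarray(radii[:-1]), cr) + 1

    skull = labels == SKULL
    for fo in fontanels:
        labels[skull & fo.contains(centroids)] = FONTANEL

    return TetMesh(nodes, tets, labels)


# ---------------------------------------------------------------------------
# Electrode cap
# ---------------------------------------------------------------------------


@dataclass
class ElectrodeCap:
    """Finite-size scalp electrodes as disjoint sets of boundary triangles.

    ``triangles[l]`` indexes into ``mesh.boundary_tris``; ``areas[l]`` is the
    summed triangle area (m^2) and ``impedances[l]`` the average contact
    impedance Z_l (Ohm).  ``c6_index``/``fz_index`` nominate the electrodes
    used by the two fixed test sources.
    """

    centers: np.ndarray
    contact_radius: float
    triangles: list
    areas: np.ndarray
    impedances: np.ndarray
    labels: list
    c6_index: int = 5
    fz_index: int = 0

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.areas = np.asarray(self.areas, dtype=np.float64)
        self.impedances = np.asarray(self.impedances, dtype=np.float64)
        if np.any(self.impedances <= 0):
            raise ValidationError("contact impedances must be strictly positive")

    def __len__(self) -> int:
        return len(self.triangles)

    def with_impedance(self, impedance) -> "ElectrodeCap":
        z = np.broadcast_to(np.asarray(impedance, dtype=float), (len(self),)).copy()
        return replace(self, impedances=z)

    def all_triangles(self) -> np.ndarray:
        return np.concatenate(self.triangles) if self.triangles else np.array([], dtype=int)


def build_electrode_cap(
    mesh: TetMesh,
    centers,
    contact_radius: float = 0.005,
    impedance=1000.0,
    labels=None,
    single_triangle: bool = False,
    c6_index: int = 5,
    fz_index: int | None = None,
) -> ElectrodeCap:
    """Assign boundary triangles to electrodes by centroid distance.

    A triangle belongs to electrode l if its centroid lies within
    ``contact_radius`` of the electrode center; a triangle within reach of two
    centers is an overlap error, not a tie-break.  With ``single_triangle``
    each electrode is the one nearest boundary triangle (used for the
    point-electrode limit experiments).
    """
    centers = np.asarray(centers, dtype=np.float64)
    cents = mesh.boundary_centroids()
    tri_areas = mesh.boundary_areas()
    dist = cdist(centers, cents)

    nearest = dist.min(axis=1)
    if np.any(nearest > contact_radius):
        bad = int(np.argmax(nearest))
        raise ValidationError(
            f"electrode center {bad} is {nearest[bad]:.4g} m from the scalp surface "
            f"(> contact radius {contact_radius:.4g} m)"
        )

    if single_triangle:
        picks = np.argmin(dist, axis=1)
        if len(np.unique(picks)) != len(picks):
            raise OverlapError("two electrodes snap to the same boundary triangle")
        tri_sets = [np.array([p]) for p in picks]
    else:
        capture = dist <= contact_radius
        claimed = capture.sum(axis=0)
        if np.any(claimed > 1):
            tri = int(np.argmax(claimed > 1))
            pair = np.nonzero(capture[:, tri])[0][:2]
            raise OverlapError(
                f"electrodes {pair[0]} and {pair[1]} overlap on boundary triangle {tri}"
            )
        tri_sets = [np.nonzero(capture[l])[0] for l in range(len(centers))]
        for l, s in enumerate(tri_sets):
            if len(s) == 0:
                raise EmptyElectrodeError(f"electrode {l} captured no boundary triangle")

    areas = np.array([tri_areas[s].sum() for s in tri_sets])
    z = np.broadcast_to(np.asarray(impedance, dtype=float), (len(centers),)).copy()
    if labels is None:
        labels = [f"E{l:02d}" for l in range(len(centers))]
    if fz_index is None:
        fz_index = int(np.argmax(centers[:, 2]))
    return ElectrodeCap(
        centers, contact_radius, tri_sets, areas, z, list(labels), c6_index, fz_index
    )


def fibonacci_cap_centers(radius: float, n: int = 74, z_min: float = -0.3) -> np.ndarray:
    """Deterministic quasi-uniform spiral layout over the upper part of the
    sphere (fraction ``(1 - z_min) / 2`` of the total area).

    The first point is the vertex-most electrode; with the anterior fontanel
    cone on top it doubles as the Fz-like electrode of the test-source layout.
    """
    k = np.arange(n)
    z = 1.0 - (k + 0.5) * (1.0 - z_min) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    return radius * np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def default_cap(
    mesh: TetMesh,
    impedance=1000.0,
    contact_radius: float = 0.005,
    n_electrodes: int = 74,
) -> ElectrodeCap:
    """The default 74-electrode, 10-mm-diameter cap on the scalp surface."""
    r_scalp = np.linalg.norm(mesh.nodes[mesh.boundary_nodes()], axis=1).mean()
    centers = fibonacci_cap_centers(r_scalp, n_electrodes)
    cap = build_electrode_cap(mesh, centers, contact_radius, impedance)
    cap.labels[cap.c6_index] = "C6-like"
    cap.labels[cap.fz_index] = "Fz-like"
    return cap


def write_cap(cap: ElectrodeCap, path) -> None:
    data = {
        "contact_radius": cap.contact_radius,
        "c6_index": cap.c6_index,
        "fz_index": cap.fz_index,
        "electrodes": [
            {
                "label": cap.labels[l],
                "center": [float(c) for c in cap.centers[l]],
                "impedance": float(cap.impedances[l]),
            }
            for l in range(len(cap))
        ],
    }
    with open(path, "w") as f:
        json.dump(data, f, indent=1)


def read_cap(path, mesh: TetMesh) -> ElectrodeCap:
    with open(path) as f:
        data = json.load(f)
    centers = [e["center"] for e in data["electrodes"]]
    z = [e["impedance"] for e in data["electrodes"]]
    labels = [e["label"] for e in data["electrodes"]]
    return build_electrode_cap(
        mesh,
        centers,
        contact_radius=data["contact_radius"],
        impedance=np.array(z),
        labels=labels,
        c6_index=data.get("c6_index", 5),
        fz_index=data.get("fz_index"),
    )
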