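"""Seeded desk-scale reproductions of the electrode/skull-model experiments.

Four entry points mirror the study design on the synthetic layered-sphere
head:

* :func:`run_comparison_sweep` -- RDM/MAG between two electrode/head models
  (1: CEM-I vs PEM-I, 2: CEM-I vs CEM-II, 3: CEM-III vs PEM-III) across the
  14-value contact-impedance sweep 0.1 Ohm .. 12 kOhm.
* :func:`run_eccentricity_analysis` -- forward differences and IAS source
  localization differences (PD/AD/ND) for random dipole samples at fixed
  eccentricities; data are simulated with the CEM and reconstructed through
  the PEM, with the generating dipole removed from the inversion space.
* :func:`run_source_ab` -- voltage patterns and subelectrode potential
  variation for the two fixed 10-nAm test sources.
* :func:`run_validation_suite` -- the oracle/invariant harness.

All tables are plain DataFrames; a manifest (config hash, mesh hash, seeds,
library versions) accompanies anything written to disk.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .fem_forward import (
    assemble_cem_system,
    assemble_pem_system,
    assemble_stiffness,
    average_reference_matrix,
    choose_ground_node,
    compute_lead_field,
    net_electrode_currents,
    solve_forward,
    subelectrode_variation,
)
from .head_geometry import (
    DEFAULT_FONTANELS,
    DEFAULT_RADII,
    ConductivityModel,
    TetMesh,
    build_electrode_cap,
    build_sphere_head,
    default_cap,
    fibonacci_cap_centers,
)
from .inverse_mce import IASConfig, ias_solve
from .metrics import ad as _ad
from .metrics import boxplot_summary, mag, nd as _nd, pd as _pd, rdm
from .oracle import dipole_potential_insulated_sphere
from .sources import build_source_space, locate_test_sources, sample_sources_by_eccentricity


def impedance_sweep(low: float = 0.1, high: float = 12000.0, n: int = 14) -> np.ndarray:
    """The default contact-impedance sweep: n log-uniform values (Ohm)."""
    return np.logspace(np.log10(low), np.log10(high), n)


#: The four model/impedance combinations of the fixed-source experiment.
SOURCE_AB_COMBOS = (
    ("pem", "I", None),
    ("cem", "I", 2000.0),
    ("cem", "I", 0.1),
    ("cem", "II", 2000.0),
)


@dataclass
class ExperimentConfig:
    """Study conditions for the desk-scale experiment suite.

    Defaults follow the study design: a four-shell neonatal sphere head with
    fontanel openings, 74 electrodes of 10 mm diameter, a 14-value
    log-uniform impedance sweep between 0.1 Ohm and 12 kOhm, eccentricity
    levels {0.2, 0.4, 0.6, 0.8, 0.98} with 100 random sources each, and 50
    IAS iterations at gamma = nu^2 sqrt(2)/theta0 = 1.4142e-6.
    """

    radii: tuple = DEFAULT_RADII
    fontanels: tuple = DEFAULT_FONTANELS
    target_edge_length: float = 0.005
    mesh_seed: int = 0
    n_electrodes: int = 74
    contact_radius: float = 0.005
    impedances: tuple = tuple(impedance_sweep())
    sweep_n_sources: int = 200
    sweep_seed: int = 1
    eccentricities: tuple = (0.2, 0.4, 0.6, 0.8, 0.98)
    n_per_level: int = 100
    ecc_tolerance: float = 0.02
    ecc_impedance: float = 2000.0
    sample_seed: int = 2
    exclude_surface_layers: int = 1
    ias: IASConfig = field(default_factory=lambda: IASConfig(nu=0.001, theta0=1.0))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class HeadBundle:
    """Mesh, cap, source space and cached stiffness matrices for a config."""

    mesh: TetMesh
    cap: object
    space: object
    ground_node: int
    stiffness: dict  # sigma tag -> csr matrix
    config: ExperimentConfig

    def K(self, tag: str):
        if tag not in self.stiffness:
            self.stiffness[tag] = assemble_stiffness(self.mesh, ConductivityModel.model(tag))
        return self.stiffness[tag]


def build_head(config: ExperimentConfig) -> HeadBundle:
    """Build the synthetic head, electrode cap and admissible source space."""
    mesh = build_sphere_head(
        radii=config.radii,
        fontanels=config.fontanels,
        target_edge_length=config.target_edge_length,
        seed=config.mesh_seed,
    )
    cap = default_cap(
        mesh, contact_radius=config.contact_radius, n_electrodes=config.n_electrodes
    )
    space = build_source_space(mesh, exclude_surface_layers=config.exclude_surface_layers)
    return HeadBundle(mesh, cap, space, choose_ground_node(mesh, cap), {}, config)


def _cem_lead_field(head: HeadBundle, tag: str, impedance: float):
    sigma = ConductivityModel.model(tag)
    system = assemble_cem_system(
        head.mesh,
        sigma,
        head.cap.with_impedance(impedance),
        stiffness=head.K(tag),
        ground_node=head.ground_node,
    )
    return compute_lead_field(system, head.space.G, method="schur")


def _pem_lead_field(head: HeadBundle, tag: str):
    sigma = ConductivityModel.model(tag)
    system = assemble_pem_system(
        head.mesh, sigma, head.cap, stiffness=head.K(tag), ground_node=head.ground_node
    )
    return compute_lead_field(system, head.space.G)


_COMPARISONS = {
    1: (("cem", "I"), ("pem", "I")),
    2: (("cem", "I"), ("cem", "II")),
    3: (("cem", "III"), ("pem", "III")),
}


def run_comparison_sweep(
    config: ExperimentConfig, comparison: int, head: HeadBundle | None = None
) -> pd.DataFrame:
    """RDM/MAG between the two sides of one of the three electrode/head
    model comparisons, per impedance and per sampled source."""
    if comparison not in _COMPARISONS:
        raise ValidationError(f"comparison must be 1, 2 or 3, got {comparison}")
    (m1, t1), (m2, t2) = _COMPARISONS[comparison]
    head = head or build_head(config)
    rng = np.random.default_rng(config.sweep_seed)
    n_src = min(config.sweep_n_sources, len(head.space))
    picks = np.sort(rng.choice(len(head.space), n_src, replace=False))

    pem_cache: dict[str, np.ndarray] = {}

    def side(model, tag, z):
        if model == "pem":
            if tag not in pem_cache:
                pem_cache[tag] = _pem_lead_field(head, tag).matrix
            return pem_cache[tag]
        return _cem_lead_field(head, tag, z).matrix

    records = []
    for z in config.impedances:
        L1 = side(m1, t1, z)[:, picks]
        L2 = side(m2, t2, z)[:, picks]
        n1 = np.linalg.norm(L1, axis=0)
        n2 = np.linalg.norm(L2, axis=0)
        rdms = 100.0 * np.linalg.norm(L1 / n1 - L2 / n2, axis=0)
        mags = 100.0 * n2 / n1 - 100.0
        for j, k in enumerate(picks):
            records.append(
                {
                    "comparison": comparison,
                    "impedance_ohm": z,
                    "source": int(k),
                    "rdm_pct": rdms[j],
                    "mag_pct": mags[j],
                }
            )
    return pd.DataFrame.from_records(records)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-impedance five-number box-plot summaries of RDM and MAG."""
    rows = []
    for (comp, z), grp in table.groupby(["comparison", "impedance_ohm"]):
        row = {"comparison": comp, "impedance_ohm": z}
        for col, name in (("rdm_pct", "rdm"), ("mag_pct", "mag")):
            s = boxplot_summary(grp[col])
            row.update(
                {
                    f"{name}_median": s.median,
                    f"{name}_q1": s.iqr_low,
                    f"{name}_q3": s.iqr_high,
                    f"{name}_min": s.minimum,
                    f"{name}_max": s.maximum,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["comparison", "impedance_ohm"], ignore_index=True)


def run_eccentricity_analysis(
    config: ExperimentConfig, head: HeadBundle | None = None
) -> pd.DataFrame:
    """Forward differences and PEM-based IAS localization per eccentricity.

    For each sampled dipole, exact data are computed with the CEM (model I,
    ``ecc_impedance``), normalized to unit 2-norm, and reconstructed with
    the PEM lead field from which the generating dipole column has been
    removed.  Reported: RDM/MAG of the two forward columns and PD (mm),
    AD (degrees), ND (mm, truth-minus-estimate) plus the depth bias -ND.
    """
    head = head or build_head(config)
    space = head.space
    L_cem = _cem_lead_field(head, "I", config.ecc_impedance).matrix
    L_pem = _pem_lead_field(head, "I").matrix
    samples = sample_sources_by_eccentricity(
        space,
        config.eccentricities,
        config.n_per_level,
        config.ecc_tolerance,
        config.sample_seed,
    )
    records = []
    for ecc, idxs in samples.items():
        for k in idxs:
            y = L_cem[:, k]
            y = y / np.linalg.norm(y)
            keep = np.ones(len(space), dtype=bool)
            keep[k] = False
            est = ias_solve(L_pem[:, keep], y, config.ias)
            w = np.abs(est.x)
            r_est = (w / w.sum()) @ space.positions[keep]
            q_est = (w / w.sum()) @ space.moments[keep]
            nd_val = _nd(space.positions[k], r_est)
            records.append(
                {
                    "eccentricity": ecc,
                    "source": int(k),
                    "rdm_pct": rdm(L_cem[:, k], L_pem[:, k]),
                    "mag_pct": mag(L_cem[:, k], L_pem[:, k]),
                    "pd_mm": _pd(space.positions[k], r_est),
                    "ad_deg": _ad(space.moments[k], q_est),
                    "nd_mm": nd_val,
                    "depth_bias_mm": -nd_val,
                }
            )
    return pd.DataFrame.from_records(records)


def run_source_ab(
    config: ExperimentConfig, head: HeadBundle | None = None
) -> dict[str, pd.DataFrame]:
    """Voltages and subelectrode variation for the fixed sources A and B.

    Four model combinations are evaluated: PEM (I), CEM (I) at 2.0 kOhm,
    CEM (I) at 0.1 Ohm and CEM (II) at 2.0 kOhm; both sources carry 10 nAm.
    """
    head = head or build_head(config)
    R = average_reference_matrix(len(head.cap))
    volt_rows, var_rows = [], []
    for mode in ("A", "B"):
        k, amp = locate_test_sources(head.space, head.cap, mode, config.fontanels)
        x = np.zeros(len(head.space))
        x[k] = amp
        for model, tag, z in SOURCE_AB_COMBOS:
            combo = f"{model.upper()} ({tag})" + (f" {z:g} Ohm" if z is not None else "")
            sigma = ConductivityModel.model(tag)
            if model == "cem":
                system = assemble_cem_system(
                    head.mesh,
                    sigma,
                    head.cap.with_impedance(z),
                    stiffness=head.K(tag),
                    ground_node=head.ground_node,
                )
            else:
                system = assemble_pem_system(
                    head.mesh, sigma, head.cap, stiffness=head.K(tag),
                    ground_node=head.ground_node,
                )
            sol = solve_forward(system, x, head.space.G)
            y = R @ sol.v
            for l in range(len(head.cap)):
                volt_rows.append(
                    {
                        "source": mode,
                        "combo": combo,
                        "electrode": l,
                        "label": head.cap.labels[l],
                        "voltage_v": y[l],
                    }
                )
            if model == "cem":
                for l in range(len(head.cap)):
                    var = subelectrode_variation(sol, head.mesh, head.cap, l)
                    var_rows.append(
                        {
                            "source": mode,
                            "combo": combo,
                            "electrode": l,
                            "max_abs_variation_v": float(np.abs(var).max()),
                            "min_variation_v": float(var.min()),
                            "max_variation_v": float(var.max()),
                        }
                    )
    return {
        "voltages": pd.DataFrame.from_records(volt_rows),
        "variation": pd.DataFrame.from_records(var_rows),
    }


# ---------------------------------------------------------------------------
# Validation harness
# ---------------------------------------------------------------------------


def _quadrature_g_column(mesh: TetMesh, space, k: int) -> np.ndarray:
    """int psi (div w) dV for dipole k by per-tet integration of the scaled
    face basis (div w = +-4/(d V) on the two adjacent tets)."""
    p_i, p_j = space.node_pairs[k]
    face = set(space.faces[k].tolist())
    col = np.zeros(len(mesh.nodes))
    d = np.linalg.norm(mesh.nodes[p_j] - mesh.nodes[p_i])
    vols = mesh.tet_volumes()
    for t, tet in enumerate(mesh.tets):
        s = set(tet.tolist())
        if face <= s and (p_i in s or p_j in s):
            sign = 1.0 if p_i in s else -1.0
            div = sign * 4.0 / (d * vols[t])
            for node in tet:
                col[node] += div * vols[t] / 4.0  # int psi dV = V/4 per vertex
    return col


def run_validation_suite(
    config: ExperimentConfig | None = None,
    limit_edges=(0.0095, 0.0065, 0.0045),
) -> dict:
    """Oracle and invariant harness; returns a pass/fail report.

    Checks: average reference, zero net electrode current, lead-field route
    equivalence, shunting monotonicity across the impedance sweep, the
    CEM-to-PEM small-patch limit under mesh refinement, the homogeneous
    sphere analytic oracle, the divergence-matrix quadrature identity and
    IAS matched-model recovery.
    """
    config = config or ExperimentConfig(
        target_edge_length=0.0065, sweep_n_sources=50, n_per_level=10, ecc_tolerance=0.05
    )
    head = build_head(config)
    mesh, space, cap = head.mesh, head.space, head.cap
    checks: dict[str, dict] = {}

    def record(name, value, tol, passed=None):
        checks[name] = {
            "value": float(value),
            "tolerance": float(tol),
            "passed": bool(value <= tol if passed is None else passed),
        }

    lf = _cem_lead_field(head, "I", 2000.0)
    scale = np.abs(lf.matrix).max()
    record("average_reference_colsum", np.abs(lf.matrix.sum(axis=0)).max() / scale, 1e-10)

    sigma1 = ConductivityModel.model("I")
    cem = assemble_cem_system(
        mesh, sigma1, cap.with_impedance(2000.0), stiffness=head.K("I"),
        ground_node=head.ground_node,
    )
    k_mid = len(space) // 2
    x = np.zeros(len(space))
    x[k_mid] = 1.0
    sol = solve_forward(cem, x, space.G)
    cur_scale = np.abs(cem.C * sol.v).max()
    record(
        "net_electrode_current",
        np.abs(net_electrode_currents(cem, sol)).max() / cur_scale,
        1e-10,
    )

    lf_b = compute_lead_field(cem, space.G, "block")
    lf_s = compute_lead_field(cem, space.G, "schur")
    lf_t = compute_lead_field(cem, space.G, "transfer", rtol=1e-12)
    den = np.abs(lf_s.matrix).max()
    route_err = max(
        np.abs(lf_s.matrix - lf_b.matrix).max(), np.abs(lf_s.matrix - lf_t.matrix).max()
    )
    record("lead_field_route_agreement", route_err / den, 1e-8)

    # shunting monotonicity for the mid source
    variations = []
    for z in config.impedances:
        sys_z = assemble_cem_system(
            mesh, sigma1, cap.with_impedance(z), stiffness=head.K("I"),
            ground_node=head.ground_node,
        )
        sol_z = solve_forward(sys_z, x, space.G)
        variations.append(
            max(
                np.abs(subelectrode_variation(sol_z, mesh, cap, l)).max()
                for l in range(len(cap))
            )
        )
    variations = np.array(variations)
    record(
        "shunting_monotone",
        0.0 if np.all(np.diff(variations) >= 0) else 1.0,
        0.0,
        passed=bool(np.all(np.diff(variations) >= 0)),
    )
    record("shunting_low_over_high", variations[0] / variations[-1], 0.1)

    record("cem_pem_limit_rdm", cem_pem_limit_rdms(limit_edges)[-1], 1.0)

    record("sphere_oracle_rdm", sphere_oracle_rdm(head), 5.0)

    qerr = 0.0
    for k in np.linspace(0, len(space) - 1, 5).astype(int):
        ref = _quadrature_g_column(mesh, space, int(k))
        diff = np.abs(space.G[:, int(k)].toarray().ravel() - ref).max()
        qerr = max(qerr, diff * space.pole_separations[int(k)])  # relative to 1/d
    record("g_quadrature", qerr, 1e-10)

    rec = ias_recovery_fractions(head, n_sources=10, seed=config.sample_seed)
    record("ias_recovery_fraction", rec, 1.0, passed=bool(rec >= 0.9))

    return {"passed": all(c["passed"] for c in checks.values()), "checks": checks}


def cem_pem_limit_rdms(
    edges=(0.0095, 0.0065, 0.0045),
    z_tilde: float = 2000.0 * np.pi * 0.005**2,
    target_point=(0.0, 0.021, 0.021),
) -> list[float]:
    """RDM between single-triangle-patch CEM and point-matched PEM voltages
    across mesh refinement levels.

    Each electrode is a single boundary triangle with fixed effective
    impedance Z~ (so Z = Z~/A grows as the patch shrinks) and the PEM
    evaluates the potential barycentrically at the same patch point, making
    the difference a pure electrode-model effect that vanishes in the
    point-electrode limit.
    """
    sigma = ConductivityModel.model("I")
    target = np.asarray(target_point)
    out = []
    for edge in edges:
        mesh = build_sphere_head(target_edge_length=edge)
        centers = fibonacci_cap_centers(DEFAULT_RADII[-1])
        cap1 = build_electrode_cap(mesh, centers, 0.005, 1.0, single_triangle=True)
        cap1 = cap1.with_impedance(z_tilde / cap1.areas)
        K = assemble_stiffness(mesh, sigma)
        space = build_source_space(mesh)
        k = int(np.argmin(np.linalg.norm(space.positions - target, axis=1)))
        x = np.zeros(len(space))
        x[k] = 1.0
        cem = assemble_cem_system(mesh, sigma, cap1, stiffness=K)
        sol_c = solve_forward(cem, x, space.G)
        pts = mesh.boundary_centroids()[[s[0] for s in cap1.triangles]]
        pem = assemble_pem_system(
            mesh, sigma, pts, snap=False, stiffness=K, ground_node=cem.ground_node
        )
        sol_p = solve_forward(pem, x, space.G)
        R = average_reference_matrix(len(cap1))
        out.append(rdm(R @ sol_c.v, R @ sol_p.v))
    return out


def sphere_oracle_rdm(head: HeadBundle, eccentricity: float = 0.45) -> float:
    """RDM between the PEM forward solution on a homogenized head and the
    closed-form dipole-in-insulated-sphere surface potential."""
    hom = ConductivityModel.homogeneous()
    mesh, space = head.mesh, head.space
    K = assemble_stiffness(mesh, hom)
    pem = assemble_pem_system(
        mesh, hom, head.cap, stiffness=K, ground_node=head.ground_node
    )
    rad = np.linalg.norm(space.positions, axis=1)
    rel = rad / rad.max()
    k = int(np.nonzero(np.abs(rel - eccentricity) < 0.05)[0][0])
    x = np.zeros(len(space))
    x[k] = 1.0
    sol = solve_forward(pem, x, space.G)
    obs = mesh.nodes[pem.electrode_nodes]
    ua = dipole_potential_insulated_sphere(
        obs, space.positions[k], space.moments[k], 0.33, head.config.radii[-1]
    )
    R = average_reference_matrix(len(head.cap))
    return rdm(R @ sol.v, R @ ua)


def ias_recovery_fractions(
    head: HeadBundle,
    n_sources: int = 50,
    eccentricity: float = 0.8,
    band: float = 0.05,
    seed: int = 3,
    impedance: float = 2000.0,
) -> float:
    """Fraction of matched-lead-field IAS reconstructions (generating dipole
    excluded) with PD below the source space's mean inter-dipole spacing."""
    space = head.space
    lf = _cem_lead_field(head, "I", impedance)
    rng = np.random.default_rng(seed)
    rad = np.linalg.norm(space.positions, axis=1)
    rel = rad / rad.max()
    cand = np.nonzero(np.abs(rel - eccentricity) <= band)[0]
    ks = rng.choice(cand, min(n_sources, len(cand)), replace=False)
    bound = space.mean_spacing() * 1e3
    cfg = head.config.ias
    hits = 0
    for k in ks:
        y = lf.matrix[:, k] / np.linalg.norm(lf.matrix[:, k])
        keep = np.ones(len(space), dtype=bool)
        keep[k] = False
        est = ias_solve(lf.matrix[:, keep], y, cfg)
        w = np.abs(est.x) / np.abs(est.x).sum()
        if _pd(space.positions[k], w @ space.positions[keep]) < bound:
            hits += 1
    return hits / len(ks)


# ---------------------------------------------------------------------------
# Manifests, persistence, plotting
# ---------------------------------------------------------------------------


def manifest(config: ExperimentConfig, head: HeadBundle | None = None) -> dict:
    import scipy

    info = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "versions": {
            "cemfwd": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    if head is not None:
        info["mesh_hash"] = head.mesh.content_hash()
        info["n_tets"] = int(len(head.mesh.tets))
        info["n_dipoles"] = int(len(head.space))
    return info


def save_table(table: pd.DataFrame, path, config: ExperimentConfig, head=None) -> None:
    """CSV table plus a sibling .manifest.json provenance file."""
    table.to_csv(path, index=False)
    with open(str(path) + ".manifest.json", "w") as f:
        json.dump(manifest(config, head), f, indent=1, default=str)


def plot_sweep_summary(summary: pd.DataFrame, path) -> None:
    """Box-plot style figure of RDM/MAG medians, IQRs and extremes against
    impedance (log axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax, name, title in zip(axes, ("rdm", "mag"), ("RDM (%)", "MAG (%)")):
        z = summary["impedance_ohm"]
        ax.fill_between(z, summary[f"{name}_min"], summary[f"{name}_max"], alpha=0.15)
        ax.fill_between(z, summary[f"{name}_q1"], summary[f"{name}_q3"], alpha=0.35)
        ax.plot(z, summary[f"{name}_median"], "o-")
        ax.set_xscale("log")
        ax.set_xlabel("contact impedance (Ohm)")
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
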