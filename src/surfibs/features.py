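"""Per-vertex surface features: shape index, distance-dependent curvature,
hydropathy, electrostatic potential, hydrogen-bond potential.

All five features are dimensionless and clipped to [-1, 1], with the fixed
column order [shape_index, ddc, hydropathy, electrostatics, hbond].  The ddc
column is patch-relative: the assembled vertex table stores 0 there and
patch extraction fills it per member.

Electrostatics uses a screened-Coulomb (Debye-Hueckel) potential over a
coarse formal-charge table, and the hydrogen-bond potential is a signed
Gaussian in the distance to the nearest polar atom.  Both are self-contained
stand-ins with the same range and sign semantics as solver-based potentials;
externally computed per-vertex values can be supplied instead through
``assemble_features(..., electrostatics_override=...)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from surfibs.structures_io import ProteinStructure, SurfaceMesh

FEATURE_NAMES = ("shape_index", "ddc", "hydropathy", "electrostatics", "hbond")

# Kyte-Doolittle hydropathy scale; divided by 4.5 on use so ILE -> +1, ARG -> -1
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# formal charges on charged-sidechain heavy atoms at pH 7; HIS neutral
FORMAL_CHARGES = {
    ("LYS", "NZ"): +1.0,
    ("ARG", "CZ"): +1.0,
    ("ASP", "CG"): -1.0,
    ("GLU", "CD"): -1.0,
}

# hydrogen-bond roles of polar heavy atoms: +1 donor, -1 acceptor.
# backbone N donates, backbone O accepts; sidechain roles by atom name.
HBOND_ROLES = {
    ("*", "N"): +1.0,
    ("*", "O"): -1.0,
    ("*", "OXT"): -1.0,
    ("LYS", "NZ"): +1.0,
    ("ARG", "NE"): +1.0, ("ARG", "NH1"): +1.0, ("ARG", "NH2"): +1.0,
    ("ASP", "OD1"): -1.0, ("ASP", "OD2"): -1.0,
    ("GLU", "OE1"): -1.0, ("GLU", "OE2"): -1.0,
    ("ASN", "OD1"): -1.0, ("ASN", "ND2"): +1.0,
    ("GLN", "OE1"): -1.0, ("GLN", "NE2"): +1.0,
    ("HIS", "ND1"): -1.0, ("HIS", "NE2"): +1.0,
    ("SER", "OG"): +1.0,
    ("THR", "OG1"): +1.0,
    ("TYR", "OH"): +1.0,
    ("TRP", "NE1"): +1.0,
}

PATCH_RADIUS = 9.0  # Angstrom, geodesic patch radius used to scale ddc


def _vertex_rings(mesh: SurfaceMesh, depth: int = 2) -> list[np.ndarray]:
    """k-ring neighborhoods (excluding the vertex itself)."""
    adj: list[set] = [set() for _ in range(mesh.n_vertices)]
    for tri in mesh.faces:
        a, b, c = int(tri[0]), int(tri[1]), int(tri[2])
        adj[a].update((b, c)); adj[b].update((a, c)); adj[c].update((a, b))
    rings = []
    for v in range(mesh.n_vertices):
        ring = set(adj[v])
        frontier = ring
        for _ in range(depth - 1):
            frontier = set().union(*(adj[u] for u in frontier)) - ring - {v} if frontier else set()
            ring |= frontier
        rings.append(np.fromiter(ring, dtype=np.int64))
    return rings


def principal_curvatures(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex principal curvatures (kappa1 >= kappa2), sign convention
    positive for convex regions with respect to the outward normal.

    Quadric height fit h(u, w) = du + ew + au^2 + buw + cw^2 over the 2-ring
    in the local normal frame; curvatures are the negated eigenvalues of the
    height Hessian (outward normal means a convex cap has negative heights).
    """
    v = mesh.vertices
    n = mesh.normals
    rings = _vertex_rings(mesh, depth=2)
    k1 = np.zeros(mesh.n_vertices)
    k2 = np.zeros(mesh.n_vertices)
    for i in range(mesh.n_vertices):
        nb = rings[i]
        if len(nb) < 5:
            if len(nb) == 0:
                warnings.warn(f"isolated vertex {i}: curvature set to 0")
            continue
        ni = n[i]
        # local tangent frame
        t1 = np.cross(ni, [1.0, 0.0, 0.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(ni, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(ni, t1)
        d = v[nb] - v[i]
        u = d @ t1
        w = d @ t2
        h = d @ ni
        A = np.column_stack([u, w, u * u, u * w, w * w])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        hess = np.array([[2 * coef[2], coef[3]], [coef[3], 2 * coef[4]]])
        eig = np.linalg.eigvalsh(-hess)
        k2[i], k1[i] = eig[0], eig[1]
    return k1, k2


def shape_index(mesh: SurfaceMesh) -> np.ndarray:
    """s = (2/pi) arctan((k1+k2)/(k1-k2)) in [-1, 1]; umbilic -> sign(k1)."""
    k1, k2 = principal_curvatures(mesh)
    s = np.zeros_like(k1)
    diff = k1 - k2
    umbilic = diff < 1e-9
    reg = ~umbilic
    s[reg] = (2.0 / np.pi) * np.arctan2(k1[reg] + k2[reg], diff[reg])
    s[umbilic] = np.sign(k1[umbilic])
    return np.clip(s, -1.0, 1.0)


def distance_dependent_curvature(
    member_xyz: np.ndarray, center_xyz: np.ndarray, center_normal: np.ndarray,
    patch_radius: float = PATCH_RADIUS,
) -> np.ndarray:
    """Patch-relative bending: chord-normal ratio scaled by the patch radius.

    ddc_i = clip(2 <p_i - p_c, n_c> / |p_i - p_c|^2 * r_patch, -1, 1); the
    center itself is 0 by convention.  A member on a sphere of radius R gives
    -r_patch / R independent of where it sits on the sphere.
    """
    d = member_xyz - center_xyz[None, :]
    dist2 = (d * d).sum(axis=1)
    out = np.zeros(len(member_xyz))
    ok = dist2 > 1e-12
    out[ok] = 2.0 * (d[ok] @ center_normal) / dist2[ok] * patch_radius
    return np.clip(out, -1.0, 1.0)


def hydropathy(mesh: SurfaceMesh, structure: ProteinStructure) -> np.ndarray:
    """Kyte-Doolittle index of the nearest residue, scaled to [-1, 1]."""
    if mesh.nearest_residue is None:
        raise ValueError("mesh.nearest_residue must be assigned first")
    table = np.array(
        [KYTE_DOOLITTLE.get(r.name, 0.0) / 4.5 for r in structure.residues]
    )
    return np.clip(table[mesh.nearest_residue], -1.0, 1.0)


def _debye_kappa(ionic_strength: float) -> float:
    # inverse Debye length in 1/Angstrom for water at 298 K
    return np.sqrt(ionic_strength) / 3.04


def electrostatics(
    mesh: SurfaceMesh, structure: ProteinStructure, ionic_strength: float = 0.15
) -> np.ndarray:
    """Screened-Coulomb potential of the coarse formal charges, robust-scaled.

    phi(v) = sum_i q_i exp(-kappa d_iv) / d_iv with d clamped at 0.1 A, then
    divided by the 97.5th percentile of |phi| over the surface and clipped.
    """
    charges, coords = [], []
    for a in structure.atoms:
        q = FORMAL_CHARGES.get((a.residue_name, a.name))
        if q:
            charges.append(q)
            coords.append(a.xyz)
    if not charges:
        return np.zeros(mesh.n_vertices)
    q = np.array(charges)
    c = np.array(coords)
    kappa = _debye_kappa(ionic_strength)
    d = np.linalg.norm(mesh.vertices[:, None, :] - c[None, :, :], axis=2)
    d = np.maximum(d, 0.1)
    phi = (q[None, :] * np.exp(-kappa * d) / d).sum(axis=1)
    scale = np.percentile(np.abs(phi), 97.5)
    if scale < 1e-12:
        return np.zeros(mesh.n_vertices)
    return np.clip(phi / scale, -1.0, 1.0)


def hbond_potential(
    mesh: SurfaceMesh, structure: ProteinStructure,
    cutoff: float = 3.5, d0: float = 1.5, sigma: float = 1.0,
) -> np.ndarray:
    """Signed Gaussian proximity to the nearest polar (N/O) heavy atom.

    role(a*) * exp(-(d - d0)^2 / 2 sigma^2), +1 for donors, -1 for acceptors,
    0 when no polar atom lies within the cutoff.
    """
    roles, coords = [], []
    for a in structure.atoms:
        if a.element.upper() not in ("N", "O"):
            continue
        role = HBOND_ROLES.get((a.residue_name, a.name), HBOND_ROLES.get(("*", a.name), 0.0))
        roles.append(role)
        coords.append(a.xyz)
    if not coords:
        return np.zeros(mesh.n_vertices)
    roles = np.array(roles)
    tree = cKDTree(np.array(coords))
    d, idx = tree.query(mesh.vertices)
    val = roles[idx] * np.exp(-((d - d0) ** 2) / (2 * sigma**2))
    val[d > cutoff] = 0.0
    return np.clip(val, -1.0, 1.0)


@dataclass
class FeatureConfig:
    ionic_strength: float = 0.15  # mol/L
    patch_radius: float = PATCH_RADIUS


def assemble_features(
    mesh: SurfaceMesh,
    structure: ProteinStructure,
    config: FeatureConfig | None = None,
    electrostatics_override: np.ndarray | None = None,
) -> np.ndarray:
    """V x 5 feature table in the fixed column order.

    The ddc column holds 0 here; patch extraction recomputes it per member
    relative to each patch center.
    """
    config = config or FeatureConfig()
    si = shape_index(mesh)
    hp = hydropathy(mesh, structure)
    if electrostatics_override is not None:
        el = np.clip(np.asarray(electrostatics_override, dtype=float), -1.0, 1.0)
        if len(el) != mesh.n_vertices:
            raise ValueError("electrostatics override length mismatch")
    else:
        el = electrostatics(mesh, structure, config.ionic_strength)
    hb = hbond_potential(mesh, structure)
    feats = np.column_stack([si, np.zeros(mesh.n_vertices), hp, el, hb])
    return np.clip(feats, -1.0, 1.0)
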