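"""Synthetic fixtures: analytic meshes, toy helical proteins, planted-IBS
datasets, and toy membrane-approach trajectories.

The planted dataset carries the statistical structure the model is meant to
learn from real peripheral membrane proteins: a minority geodesic cap of
"binding" surface whose hydropathy and shape-index features are shifted
upward (a hydrophobic protrusion), against a noisy background, with
pseudo-superfamily group tags for grouped cross-validation.  Every generator
is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from surfibs.features import FEATURE_NAMES
from surfibs.labels import LabelSet
from surfibs.structures_io import (
    AtomRecord,
    ProteinStructure,
    SurfaceMesh,
    format_atom_line,
)

HYDROPHOBIC = ("ILE", "LEU", "VAL", "PHE", "ALA")
POLAR = ("SER", "THR", "ASN", "GLN")
CHARGED = ("LYS", "ARG", "ASP", "GLU")

# representative sidechain heavy atoms placed radially outward from CA
SIDECHAIN_ATOMS = {
    "ALA": [("CB", "C", 1.5)],
    "VAL": [("CB", "C", 1.5), ("CG1", "C", 2.6)],
    "LEU": [("CB", "C", 1.5), ("CD1", "C", 3.3)],
    "ILE": [("CB", "C", 1.5), ("CD1", "C", 3.4)],
    "PHE": [("CB", "C", 1.5), ("CZ", "C", 4.0)],
    "SER": [("CB", "C", 1.5), ("OG", "O", 2.6)],
    "THR": [("CB", "C", 1.5), ("OG1", "O", 2.6)],
    "ASN": [("CB", "C", 1.5), ("OD1", "O", 3.2), ("ND2", "N", 3.4)],
    "GLN": [("CB", "C", 1.5), ("OE1", "O", 4.0), ("NE2", "N", 4.2)],
    "LYS": [("CB", "C", 1.5), ("NZ", "N", 5.0)],
    "ARG": [("CB", "C", 1.5), ("CZ", "C", 4.8), ("NH1", "N", 5.6)],
    "ASP": [("CB", "C", 1.5), ("CG", "C", 2.6), ("OD1", "O", 3.4)],
    "GLU": [("CB", "C", 1.5), ("CD", "C", 3.8), ("OE1", "O", 4.5)],
}


def make_icosphere(subdivisions: int = 2, radius: float = 10.0) -> SurfaceMesh:
    """Subdivided icosahedron projected to the sphere; V = 10*4^s + 2."""
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(tm.vertices)
    normals = v / np.linalg.norm(v, axis=1, keepdims=True)
    return SurfaceMesh(vertices=v, faces=np.asarray(tm.faces), normals=normals)


# ---------------------------------------------------------------------------
# toy proteins
# ---------------------------------------------------------------------------

def make_toy_protein(n_residues: int = 10, seed: int = 0, chain_id: str = "A"):
    """Ideal-helix toy protein (rise 1.5 A, twist 100 deg) with pseudo
    sidechains; composition 50% hydrophobic / 30% polar / 20% charged.

    Returns (ProteinStructure, pdb_text); the text is byte-stable per seed.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    kinds = rng.choice(3, size=n_residues, p=[0.5, 0.3, 0.2])
    pools = (HYDROPHOBIC, POLAR, CHARGED)
    names = [pools[k][rng.integers(len(pools[k]))] for k in kinds]

    helix_radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    atoms: list[AtomRecord] = []
    serial = 1
    for i, resname in enumerate(names):
        ang = i * twist
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        ca = helix_radius * radial + np.array([0.0, 0.0, i * rise])
        backbone = [
            ("N", "N", ca + np.array([-0.5, 0.0, -0.9])),
            ("CA", "C", ca),
            ("C", "C", ca + np.array([0.5, 0.0, 0.9])),
            ("O", "O", ca + np.array([1.4, 0.5, 0.9])),
        ]
        for name, element, xyz in backbone:
            atoms.append(AtomRecord(serial, name, element, resname, i + 1, chain_id, xyz))
            serial += 1
        for name, element, dist in SIDECHAIN_ATOMS.get(resname, []):
            xyz = ca + dist * radial
            atoms.append(AtomRecord(serial, name, element, resname, i + 1, chain_id, xyz))
            serial += 1
    structure = ProteinStructure(atoms)
    text = "".join(format_atom_line(a) + "\n" for a in atoms) + "END\n"
    return structure, text


# ---------------------------------------------------------------------------
# planted-IBS dataset
# ---------------------------------------------------------------------------

@dataclass
class PlantConfig:
    n_proteins: int = 20
    subdivisions: int = 3  # icosphere level; 3 -> 642 vertices per protein
    sphere_radius: float = 12.0  # Angstrom
    bump_amplitude: float = 0.03  # radial noise, fraction of radius
    cap_fraction: float = 0.15  # fraction of surface labeled IBS
    feature_shift: float = 0.6  # added to hydropathy and shape index in the cap
    noise_sd: float = 0.3  # Gaussian feature noise
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.cap_fraction < 0.5):
            raise ValueError("cap_fraction must be in (0, 0.5)")


@dataclass
class PlantedProtein:
    protein_id: str
    mesh: SurfaceMesh
    features: np.ndarray  # (V, 5)
    labels: LabelSet  # surface level
    group: str  # pseudo-superfamily tag (cap-direction octant)


def _bumpy_sphere(config: PlantConfig, rng: np.random.Generator) -> SurfaceMesh:
    base = make_icosphere(config.subdivisions, config.sphere_radius)
    u = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    bump = np.zeros(len(u))
    for _ in range(6):  # smooth low-frequency radial field
        k = rng.normal(size=3)
        phase = rng.uniform(0, 2 * np.pi)
        bump += np.sin(u @ k * 2.0 + phase)
    r = config.sphere_radius * (1.0 + config.bump_amplitude * bump / 6.0)
    verts = u * r[:, None]
    return SurfaceMesh(vertices=verts, faces=base.faces)


def make_planted_dataset(config: PlantConfig | None = None) -> list[PlantedProtein]:
    """Bumpy spheres with a hydrophobic, protruding geodesic cap planted as
    the IBS: hydropathy and shape-index columns are shifted by
    ``feature_shift`` inside the cap, all columns carry Gaussian noise, and
    everything is clipped to [-1, 1].  Group = octant of the cap direction.
    """
    config = config or PlantConfig()
    rng = np.random.default_rng(config.seed)
    cos_cap = 1.0 - 2.0 * config.cap_fraction  # cap area fraction on the sphere
    shift_cols = [FEATURE_NAMES.index("hydropathy"), FEATURE_NAMES.index("shape_index")]
    out = []
    for i in range(config.n_proteins):
        mesh = _bumpy_sphere(config, rng)
        u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        cap_dir = rng.normal(size=3)
        cap_dir /= np.linalg.norm(cap_dir)
        labels = (u @ cap_dir >= cos_cap).astype(int)
        feats = rng.normal(0.0, config.noise_sd, size=(mesh.n_vertices, 5))
        for c in shift_cols:
            feats[labels == 1, c] += config.feature_shift
        feats = np.clip(feats, -1.0, 1.0)
        octant = (cap_dir > 0) @ np.array([1, 2, 4])
        out.append(
            PlantedProtein(
                protein_id=f"planted{i:03d}",
                mesh=mesh,
                features=feats,
                labels=LabelSet("surface", list(range(mesh.n_vertices)), labels),
                group=f"oct{int(octant)}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# toy membrane-approach trajectories
# ---------------------------------------------------------------------------

MEMBRANE_RESNAME = "MLI"  # toy truncated lipid


def _make_membrane(extent: float, spacing: float = 1.0, atoms_per_residue: int = 25):
    xs = np.arange(-extent, extent + spacing / 2, spacing)
    pts = np.array([[x, y, 0.0] for x in xs for y in xs])
    atoms = []
    for j, p in enumerate(pts):
        atoms.append(
            AtomRecord(
                serial=10000 + j, name="P", element="P",
                residue_name=MEMBRANE_RESNAME,
                residue_index=1000 + j // atoms_per_residue,
                chain_id="M", xyz=p,
            )
        )
    return atoms


def make_toy_trajectory(
    protein: ProteinStructure,
    contact_residues: set,
    n_frames: int = 5,
    seed: int = 0,
    bound_frame: int | None = None,
    contact_distance: float = 4.9,
    clearance: float = 6.0,
) -> list[ProteinStructure]:
    """Multi-frame approach of a rigid protein to a planar pseudo-membrane.

    In the bound frame (default: the last) exactly ``contact_residues`` have
    a heavy atom within ``contact_distance`` of membrane heavy atoms while
    every other residue stays at least ``clearance`` away; other frames keep
    the whole protein clear.  Raises if the requested contact set cannot be
    realized by any rigid translation along the membrane normal.
    ``contact_residues`` may contain Residue triples or resid strings.
    """
    del seed  # geometry is deterministic; kept for interface uniformity
    contact_ids = {r[1] if isinstance(r, tuple) else str(r) for r in contact_residues}
    known = {r.resid for r in protein.residues}
    missing = contact_ids - known
    if missing:
        raise ValueError(f"contact residues not in protein: {sorted(missing)}")

    coords = protein.coords()
    heavy = np.array([a.is_heavy for a in protein.atoms])
    in_contact = np.array([a.resid in contact_ids for a in protein.atoms])

    if contact_ids:
        # search orientations for the one best separating contact residues
        # (low) from all others (high) along the membrane normal
        resid_arr = np.array([a.resid for a in protein.atoms])
        dirs = _fibonacci_sphere(600)
        H = coords[heavy] @ dirs.T  # heavy-atom heights per candidate "up"
        res_min = []
        is_contact_res = []
        for r in protein.residues:
            sel = resid_arr[heavy] == r.resid
            res_min.append(H[sel].min(axis=0))
            is_contact_res.append(r.resid in contact_ids)
        res_min = np.array(res_min)
        is_contact_res = np.array(is_contact_res)
        margin = res_min[~is_contact_res].min(axis=0) - res_min[is_contact_res].max(axis=0) \
            if (~is_contact_res).any() else np.full(len(dirs), np.inf)
        best = int(np.argmax(margin))
        rot = _rotation_between(dirs[best], np.array([0.0, 0.0, 1.0]))
        coords = (coords - coords.mean(axis=0)) @ rot.T

    # feasibility along z: every contact residue must reach within
    # contact_distance while all other residues stay >= clearance
    z = coords[:, 2]
    resid_of_atom = np.array([a.resid for a in protein.atoms])
    contact_req, other_min = [], []
    for r in protein.residues:
        sel = (resid_of_atom == r.resid) & heavy
        if r.resid in contact_ids:
            contact_req.append(z[sel].min())
        else:
            other_min.append(z[sel].min())
    # place the highest contact residue exactly at contact_distance above the
    # membrane plane (xy grid discretization adds at most ~0.03 A)
    hi_shift = (min(other_min) - clearance) if other_min else np.inf
    lo_shift = (max(contact_req) - contact_distance) if contact_req else np.inf
    if contact_ids and lo_shift > hi_shift:
        raise ValueError(
            "infeasible geometry: requested contact residues do not all face the membrane"
        )
    final_shift = lo_shift if contact_ids else -(clearance + 10.0 - z.min())
    base = coords.copy()
    base[:, 2] -= final_shift

    extent = np.abs(base[:, :2]).max() + 8.0
    membrane = _make_membrane(extent)
    bound = n_frames if bound_frame is None else bound_frame
    if not (1 <= bound <= n_frames):
        raise ValueError("bound_frame out of range")

    minh = float(base[heavy, 2].min())
    clear_lift = clearance + 2.0 - min(minh, 0.0)  # whole protein well clear
    frames = []
    for f in range(1, n_frames + 1):
        if f == bound:
            lift = 0.0
        elif f < bound:
            lift = clear_lift + 3.0 * (bound - 1 - f)
        else:
            lift = clear_lift + 8.0 * (f - bound)
        atoms = []
        for a, p in zip(protein.atoms, base):
            atoms.append(
                AtomRecord(a.serial, a.name, a.element, a.residue_name,
                           a.residue_index, a.chain_id,
                           p + np.array([0.0, 0.0, lift]), a.icode)
            )
        frames.append(ProteinStructure(atoms + membrane))
    return frames


def _fibonacci_sphere(k: int) -> np.ndarray:
    i = np.arange(k) + 0.5
    phi = np.arccos(1 - 2 * i / k)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)
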