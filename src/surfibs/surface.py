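"""Molecular surface construction and regularization.

The default surface generator extracts an isosurface of a smooth union of
atom spheres inflated by the probe radius (a solvent-accessible-style
envelope).  Users with MSMS output can bypass it entirely through
``read_msms_surface``; the downstream contract (closed, outward-oriented,
regularized triangle mesh) is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from surfibs.structures_io import ProteinStructure, SurfaceMesh, vertex_normals

# van der Waals radii (Angstrom) for the elements that occur in proteins;
# anything unlisted falls back to carbon.
DEFAULT_ATOM_RADII = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


@dataclass
class SurfaceConfig:
    probe_radius: float = 1.5  # Angstrom, water probe
    target_edge_length: float = 1.0  # Angstrom, mesh resolution after regularization
    grid_spacing: float = 0.6  # Angstrom, isosurface sampling grid
    atom_radii: dict = field(default_factory=lambda: dict(DEFAULT_ATOM_RADII))
    smoothing: float = 0.3  # Angstrom, soft-min blending width of the sphere union
    keep_all_components: bool = False
    regularize: bool = True

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.target_edge_length <= 0:
            raise ValueError("target_edge_length must be positive")


def _collinear(coords: np.ndarray, tol: float) -> bool:
    if len(coords) < 3:
        return False
    c = coords - coords.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[1] < tol)


def build_surface(structure: ProteinStructure, config: SurfaceConfig | None = None) -> SurfaceMesh:
    """Triangulated envelope enclosing all heavy atoms.

    The implicit function is a soft-min over per-atom signed sphere
    distances, phi(x) = -s * log sum_i exp(-(|x - x_i| - r_i - probe)/s),
    extracted at phi = 0 by marching cubes and regularized to the target
    edge length.  For a single atom this is exactly the sphere of radius
    r_atom + probe.
    """
    config = config or SurfaceConfig()
    heavy = structure.heavy_atoms()
    if not heavy:
        raise ValueError("structure has no heavy atoms")
    coords = np.array([a.xyz for a in heavy])
    if _collinear(coords, config.grid_spacing):
        raise ValueError("degenerate structure: heavy atoms collinear within grid spacing")
    radii = np.array(
        [config.atom_radii.get(a.element.upper(), 1.70) for a in heavy]
    ) + config.probe_radius

    h = config.grid_spacing
    margin = radii.max() + 3 * config.smoothing + 2 * h
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    ns = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 8)
    axes = [lo[d] + h * np.arange(ns[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tree = cKDTree(coords)
    k = min(len(coords), 16)
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    signed = dist - radii[idx]  # per-neighbor signed sphere distance
    s = config.smoothing
    m = signed.min(axis=1, keepdims=True)
    phi = (m.ravel() - s * np.log(np.exp(-(signed - m) / s).sum(axis=1))).reshape(gx.shape)

    verts, faces, _, _ = marching_cubes(phi, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = SurfaceMesh(vertices=verts, faces=np.asarray(faces, dtype=np.int64))
    if not config.keep_all_components:
        mesh = largest_component(mesh)
    mesh = _orient(mesh)
    if config.regularize:
        mesh = regularize(mesh, config.target_edge_length)
    return mesh


def largest_component(mesh: SurfaceMesh) -> SurfaceMesh:
    import trimesh

    tm = mesh.as_trimesh()
    parts = tm.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    best = max(parts, key=lambda p: len(p.faces))
    return SurfaceMesh(vertices=np.asarray(best.vertices), faces=np.asarray(best.faces))


def _orient(mesh: SurfaceMesh) -> SurfaceMesh:
    import trimesh

    tm = mesh.as_trimesh()
    trimesh.repair.fix_normals(tm)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# isotropic remeshing
# ---------------------------------------------------------------------------

def _edge_lengths(v: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)


def _unique_edges(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.unique(np.sort(e, axis=1), axis=0)


def _split_pass(verts: list, faces: np.ndarray, threshold: float) -> np.ndarray:
    """Split every edge longer than threshold at its midpoint (one pass)."""
    v = np.asarray(verts)
    edge_faces: dict[tuple, list[int]] = {}
    for fi, tri in enumerate(faces):
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            edge_faces.setdefault((min(a, b), max(a, b)), []).append(fi)
    lengths = {e: np.linalg.norm(v[e[0]] - v[e[1]]) for e in edge_faces}
    long_edges = sorted((e for e, L in lengths.items() if L > threshold),
                        key=lambda e: -lengths[e])
    faces = faces.tolist()
    dirty: set[int] = set()
    for (a, b) in long_edges:
        fis = edge_faces[(a, b)]
        if any(fi in dirty for fi in fis):
            continue
        mid = len(verts)
        verts.append(0.5 * (np.asarray(verts[a]) + np.asarray(verts[b])))
        for fi in fis:
            tri = faces[fi]
            # preserve winding: replace b with mid in one copy, a in the other
            t1 = [mid if x == b else x for x in tri]
            t2 = [mid if x == a else x for x in tri]
            faces[fi] = t1
            faces.append(t2)
            dirty.add(fi)
            dirty.add(len(faces) - 1)
    return np.asarray(faces, dtype=np.int64)


def _collapse_pass(verts: np.ndarray, faces: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Collapse edges shorter than threshold to their midpoint (one pass)."""
    neighbors: dict[int, set] = {}
    for tri in faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            neighbors.setdefault(int(a), set()).add(int(b))
            neighbors.setdefault(int(b), set()).add(int(a))
    edges = _unique_edges(faces)
    lengths = _edge_lengths(verts, edges)
    order = np.argsort(lengths)
    verts = verts.copy()
    remap = np.arange(len(verts))
    touched: set[int] = set()
    for ei in order:
        if lengths[ei] >= threshold:
            break
        a, b = int(edges[ei, 0]), int(edges[ei, 1])
        if a in touched or b in touched:
            continue
        # link condition: shared neighbors must be exactly the two wing vertices
        shared = neighbors[a] & neighbors[b]
        if len(shared) != 2:
            continue
        verts[a] = 0.5 * (verts[a] + verts[b])
        remap[b] = a
        touched.update({a, b} | neighbors[a] | neighbors[b])
    faces = remap[faces]
    keep = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    faces = faces[keep]
    used = np.unique(faces)
    new_index = -np.ones(len(verts), dtype=np.int64)
    new_index[used] = np.arange(len(used))
    return verts[used], new_index[faces]


def _tangential_smooth(mesh_verts: np.ndarray, faces: np.ndarray, lam: float = 0.3) -> np.ndarray:
    n = vertex_normals(mesh_verts, faces)
    adj = {}
    for tri in faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            adj.setdefault(int(a), set()).add(int(b))
            adj.setdefault(int(b), set()).add(int(a))
    out = mesh_verts.copy()
    centroid = np.array([mesh_verts[list(adj[i])].mean(axis=0) if i in adj else mesh_verts[i]
                         for i in range(len(mesh_verts))])
    d = centroid - mesh_verts
    d -= (d * n).sum(axis=1, keepdims=True) * n  # project onto tangent plane
    return out + lam * d


def regularize(mesh: SurfaceMesh, target_edge_length: float = 1.0, n_iter: int = 5) -> SurfaceMesh:
    """Isotropic remeshing: iterated long-edge split, short-edge collapse and
    tangential smoothing until the median edge length sits near the target."""
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be positive")
    v = np.asarray(mesh.vertices, dtype=float)
    diameter = np.linalg.norm(v.max(axis=0) - v.min(axis=0))
    if target_edge_length > diameter:
        raise ValueError(
            f"target edge length {target_edge_length} exceeds mesh diameter {diameter:.3g}"
        )
    f = np.asarray(mesh.faces, dtype=np.int64)
    for _ in range(n_iter):
        vl = [p for p in v]
        f = _split_pass(vl, f, threshold=4.0 / 3.0 * target_edge_length)
        v = np.asarray(vl)
        v, f = _collapse_pass(v, f, threshold=0.8 * target_edge_length)
        if len(v) < 16:
            raise ValueError("mesh collapsed below 16 vertices during regularization")
        v = _tangential_smooth(v, f)
    return SurfaceMesh(vertices=v, faces=f, nearest_residue=None)


def assign_nearest_residue(mesh: SurfaceMesh, structure: ProteinStructure) -> SurfaceMesh:
    """Assign each vertex the residue of its nearest heavy atom.

    Exact ties are broken by the lower atom serial, which is also the order
    heavy atoms appear in the structure, making the result deterministic and
    invariant to vertex reordering.
    """
    heavy = structure.heavy_atoms()
    if not heavy or mesh.n_vertices == 0:
        raise ValueError("mesh and structure must both be nonempty")
    order = np.argsort([a.serial for a in heavy], kind="stable")
    heavy = [heavy[i] for i in order]
    coords = np.array([a.xyz for a in heavy])
    res_of_atom = np.array([structure.residue_of(a) for a in heavy])
    d = np.linalg.norm(mesh.vertices[:, None, :] - coords[None, :, :], axis=2) \
        if len(coords) * mesh.n_vertices <= 2_000_000 else None
    if d is not None:
        # argmin returns the first (lowest-serial) atom on exact ties
        nearest_atom = d.argmin(axis=1)
    else:
        tree = cKDTree(coords)
        _, nearest_atom = tree.query(mesh.vertices)
    mesh.nearest_residue = res_of_atom[nearest_atom]
    return mesh
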