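"""Structure and mesh IO: PDB atoms, MSMS surfaces, PLY/OFF meshes.

The atomic data model is deliberately minimal: ordered atom records plus the
ordered unique residue list they induce.  Coordinates are Angstrom
everywhere.  Hydrogens are kept in the structure (hydrogen-bond donor logic
needs them when present) but carry ``is_heavy=False`` so contact and
nearest-residue machinery can exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import trimesh


class ParseError(ValueError):
    """Raised when a structure or mesh file cannot be parsed."""


class Residue(NamedTuple):
    """Unique residue key: chain, author index (insertion code appended), name."""

    chain_id: str
    resid: str
    name: str


# elements treated as hydrogen for the heavy-atom flag
_HYDROGEN = {"H", "D", "T"}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    xyz: np.ndarray  # (3,) Angstrom
    icode: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN

    @property
    def resid(self) -> str:
        """Author residue number with insertion code appended, e.g. '42A'."""
        return f"{self.residue_index}{self.icode}"

    @property
    def residue(self) -> Residue:
        return Residue(self.chain_id, self.resid, self.residue_name)


class ProteinStructure:
    """Ordered atoms plus the ordered unique residues they induce."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        if not atoms:
            raise ValueError("structure must contain at least one atom")
        self.atoms: list[AtomRecord] = list(atoms)
        seen: dict[Residue, int] = {}
        for a in self.atoms:
            r = a.residue
            if r not in seen:
                seen[r] = len(seen)
        self.residues: list[Residue] = list(seen.keys())
        self._residue_index = seen

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_of(self, atom: AtomRecord) -> int:
        """Position of the atom's residue in ``self.residues``."""
        return self._residue_index[atom.residue]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return np.array([a.xyz for a in atoms], dtype=float)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class SurfaceMesh:
    """Triangulated molecular surface.

    faces are 0-based with counter-clockwise outward winding; normals are
    per-vertex unit vectors; ``nearest_residue`` (when set) indexes into the
    owning ProteinStructure's residue list.
    """

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int
    normals: np.ndarray | None = None
    nearest_residue: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if self.normals is None:
            self.normals = vertex_normals(self.vertices, self.faces)
        else:
            self.normals = np.asarray(self.normals, dtype=float)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2) with e[0] < e[1]."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted accumulation of face normals, normalized per vertex."""
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area-weighted
    n = np.zeros_like(v)
    for k in range(3):
        np.add.at(n, f[:, k], fn)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def orient_outward(mesh: SurfaceMesh) -> SurfaceMesh:
    """Normalize winding to consistent counter-clockwise outward orientation."""
    tm = mesh.as_trimesh()
    trimesh.repair.fix_normals(tm)
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces),
        nearest_residue=mesh.nearest_residue,
    )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        icode = line[26].strip()
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"unparseable ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the atom-name convention: first alphabetic character,
        # respecting the column-13 element alignment for 4-char names
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else "X"
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_index=resseq, chain_id=chain, xyz=xyz, icode=icode,
    )


def _read_pdb_models(path, chain, include_hetatm):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model and current:
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                if current:
                    models.append(current)
                current = []
                in_model = False
            elif rec == "ATOM  " or (include_hetatm and rec == "HETATM"):
                altloc = line[16].strip() if len(line) > 16 else ""
                if altloc not in ("", "A"):
                    continue
                atom = _parse_atom_line(line, lineno)
                if chain is not None and atom.chain_id != chain:
                    continue
                current.append(atom)
    if current:
        models.append(current)
    return models


def read_pdb(path, chain: str | None = None, include_hetatm: bool = False) -> ProteinStructure:
    """Read ATOM records of one chain (first MODEL if several).

    HETATM records and altlocs other than blank/'A' are dropped by default;
    waters never carry ATOM records so no separate filter is needed.
    """
    models = _read_pdb_models(path, chain, include_hetatm)
    if not models or not models[0]:
        raise ParseError(
            f"no ATOM records{' for chain ' + chain if chain else ''} in {path}"
        )
    return ProteinStructure(models[0])


def read_trajectory(path, chain: str | None = None, include_hetatm: bool = True) -> list[ProteinStructure]:
    """Read a multi-MODEL PDB as a list of frames."""
    models = _read_pdb_models(path, chain, include_hetatm)
    if not models:
        raise ParseError(f"no ATOM records in {path}")
    return [ProteinStructure(m) for m in models]


def format_atom_line(a: AtomRecord) -> str:
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {a.serial:5d} {name}{'':1s}{a.residue_name:>3s} {a.chain_id:1s}"
        f"{a.residue_index:4d}{a.icode:<1s}   "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb(structure: ProteinStructure, path) -> None:
    with open(path, "w") as fh:
        for a in structure.atoms:
            fh.write(format_atom_line(a) + "\n")
        fh.write("END\n")


def write_trajectory(frames: Sequence[ProteinStructure], path) -> None:
    with open(path, "w") as fh:
        for i, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            for a in frame.atoms:
                fh.write(format_atom_line(a) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# MSMS .vert / .face
# ---------------------------------------------------------------------------

def _msms_body(path) -> tuple[int, list[str]]:
    """Skip comment lines, read the count header, return (count, body lines)."""
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"empty MSMS file {path}")
    try:
        count = int(lines[0].split()[0])
    except ValueError as exc:
        raise ParseError(f"bad MSMS header in {path}: {lines[0].rstrip()!r}") from exc
    body = lines[1:]
    if len(body) != count:
        raise ParseError(
            f"MSMS header of {path} declares {count} records but body has {len(body)}"
        )
    return count, body


def read_msms_surface(vert_path, face_path) -> SurfaceMesh:
    """Read a paired MSMS ``.vert``/``.face`` surface (1-based faces -> 0-based)."""
    nv, vlines = _msms_body(vert_path)
    verts = np.empty((nv, 3))
    norms = np.empty((nv, 3))
    for i, ln in enumerate(vlines):
        fields = ln.split()
        if len(fields) < 6:
            raise ParseError(f"vertex line {i + 1} of {vert_path} has {len(fields)} fields, expected >= 6")
        verts[i] = [float(x) for x in fields[:3]]
        norms[i] = [float(x) for x in fields[3:6]]
    nf, flines = _msms_body(face_path)
    faces = np.empty((nf, 3), dtype=np.int64)
    for i, ln in enumerate(flines):
        fields = ln.split()
        faces[i] = [int(x) for x in fields[:3]]
    faces -= 1
    bad = np.flatnonzero((faces < 0) | (faces >= nv))
    if bad.size:
        j = bad[0] // 3
        raise ParseError(
            f"face {j} of {face_path} references vertex {faces.flat[bad[0]] + 1} "
            f"outside the {nv}-vertex file"
        )
    lengths = np.linalg.norm(norms, axis=1)
    if np.any(lengths < 1e-8):
        norms = vertex_normals(verts, faces)
    else:
        norms = norms / lengths[:, None]
    return SurfaceMesh(vertices=verts, faces=faces, normals=norms)


# ---------------------------------------------------------------------------
# PLY / OFF
# ---------------------------------------------------------------------------

def write_mesh(path, mesh: SurfaceMesh) -> None:
    """Write ascii PLY or OFF (by extension) with full decimal precision."""
    path = Path(path)
    v, f = mesh.vertices, mesh.faces
    if path.suffix.lower() == ".ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(v)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {len(f)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for p in v:
                fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
    elif path.suffix.lower() == ".off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{len(v)} {len(f)} 0\n")
            for p in v:
                fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
    else:
        raise ValueError(f"unsupported mesh extension {path.suffix!r} (use .ply or .off)")


def read_mesh(path) -> SurfaceMesh:
    """Read a PLY or OFF mesh."""
    path = Path(path)
    if path.suffix.lower() not in (".ply", ".off"):
        raise ValueError(f"unsupported mesh extension {path.suffix!r} (use .ply or .off)")
    try:
        tm = trimesh.load(path, process=False, force="mesh")
    except Exception as exc:
        raise ParseError(f"cannot parse mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ParseError(f"no triangulated mesh found in {path}")
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
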