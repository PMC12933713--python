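"""Ground-truth label machinery.

Residue-level IBS annotations map to surface vertices through the
nearest-residue assignment; predictions map back by per-residue max (or
mean) aggregation over owned vertices.  MD-derived labels mark residues
whose heavy atoms come within the contact cutoff (5 Angstrom, i.e. 0.5 nm)
of membrane heavy atoms in the last membrane-bound trajectory frame, and
replica label sets combine into union and consensus sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from surfibs.structures_io import ProteinStructure, Residue, SurfaceMesh

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class LabelSet:
    """Binary labels at surface (vertex index) or residue (triple) level."""

    level: str  # "surface" | "residue"
    ids: list  # vertex indices or Residue triples
    labels: np.ndarray  # binary, aligned with ids

    def __post_init__(self):
        self.labels = np.asarray(self.labels).astype(int)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels length mismatch")
        if len(set(map(tuple, self.ids)) if self.level == "residue" else set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")

    @property
    def positives(self) -> set:
        if self.level == "residue":
            return {tuple(i) for i, l in zip(self.ids, self.labels) if l == 1}
        return {i for i, l in zip(self.ids, self.labels) if l == 1}


def write_label_tsv(label_set: LabelSet, path) -> None:
    if label_set.level != "residue":
        raise ValueError("TSV label tables are residue-level")
    with open(path, "w") as fh:
        fh.write("chain\tresidue_index\tresidue_name\tlabel\n")
        for r, l in zip(label_set.ids, label_set.labels):
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\t{int(l)}\n")


def read_label_tsv(path) -> LabelSet:
    ids, labels = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("chain"):
            raise ValueError(f"label table {path} must start with a header line")
        for ln in fh:
            if not ln.strip():
                continue
            chain, resid, resname, label = ln.rstrip("\n").split("\t")
            ids.append(Residue(chain, resid, resname))
            labels.append(int(label))
    return LabelSet(level="residue", ids=ids, labels=np.array(labels))


@dataclass
class ContactConfig:
    cutoff: float = 5.0  # Angstrom (0.5 nm)
    consensus_min_fraction: float = 0.5
    sidechain_only: bool = False

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not (0 < self.consensus_min_fraction <= 1):
            raise ValueError("consensus_min_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# surface <-> residue mapping
# ---------------------------------------------------------------------------

def residue_to_surface(
    mesh: SurfaceMesh, residue_labels: LabelSet, structure: ProteinStructure
) -> LabelSet:
    """Vertex label = label of its nearest residue; unlisted residues -> 0."""
    if mesh.nearest_residue is None:
        raise ValueError("mesh.nearest_residue must be assigned first")
    per_residue = np.zeros(structure.n_residues, dtype=int)
    index = {r: i for i, r in enumerate(structure.residues)}
    for rid, lab in zip(residue_labels.ids, residue_labels.labels):
        key = Residue(*rid)
        if key not in index:
            warnings.warn(f"labeled residue {key} not found in structure; skipped")
            continue
        per_residue[index[key]] = lab
    vertex_labels = per_residue[mesh.nearest_residue]
    return LabelSet(level="surface", ids=list(range(mesh.n_vertices)), labels=vertex_labels)


def surface_to_residue(
    values: np.ndarray, mesh: SurfaceMesh, structure: ProteinStructure,
    aggregation: str = "max",
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate per-vertex values to residues owning them.

    Returns (per-residue values, exposed mask).  Buried residues (owning no
    vertex) carry NaN and exposed=False; they are excluded from
    residue-level evaluation.
    """
    if mesh.nearest_residue is None:
        raise ValueError("mesh.nearest_residue must be assigned first")
    if aggregation not in ("max", "mean"):
        raise ValueError("aggregation must be 'max' or 'mean'")
    values = np.asarray(values, dtype=float)
    n = structure.n_residues
    out = np.full(n, np.nan)
    exposed = np.zeros(n, dtype=bool)
    for r in range(n):
        owned = values[mesh.nearest_residue == r]
        if owned.size:
            exposed[r] = True
            out[r] = owned.max() if aggregation == "max" else owned.mean()
    return out, exposed


# ---------------------------------------------------------------------------
# MD contact labels
# ---------------------------------------------------------------------------

def _membrane_predicate(selector):
    if callable(selector):
        return selector
    names = set(selector)
    return lambda atom: atom.residue_name in names


def md_contact_labels(
    frames: list[ProteinStructure],
    membrane_selector,
    config: ContactConfig | None = None,
) -> LabelSet:
    """Residue-level IBS labels from a membrane-approach trajectory.

    Uses the last frame in which any protein-membrane heavy-atom pair lies
    within the cutoff; a residue is labeled 1 iff its minimum heavy-atom
    distance to the membrane is <= cutoff.  Raises if no frame is bound.
    """
    config = config or ContactConfig()
    is_membrane = _membrane_predicate(membrane_selector)
    for frame in reversed(frames):
        mem = [a for a in frame.atoms if is_membrane(a) and a.is_heavy]
        prot = [a for a in frame.atoms if not is_membrane(a) and a.is_heavy]
        if config.sidechain_only:
            prot = [a for a in prot if a.name not in BACKBONE_ATOMS]
        if not mem or not prot:
            continue
        tree = cKDTree(np.array([a.xyz for a in mem]))
        d, _ = tree.query(np.array([a.xyz for a in prot]))
        if d.min() > config.cutoff:
            continue
        # this is the last bound frame: label per residue
        residues: dict[Residue, int] = {}
        for atom, dist in zip(prot, d):
            key = atom.residue
            residues[key] = max(residues.get(key, 0), int(dist <= config.cutoff))
        ids = list(residues)
        return LabelSet(level="residue", ids=ids,
                        labels=np.array([residues[r] for r in ids]))
    raise ValueError("no bound frame: protein and membrane never within cutoff")


def combine_replicas(
    label_sets: list[LabelSet], config: ContactConfig | None = None
) -> dict[str, LabelSet]:
    """Union and consensus IBS over replica simulations.

    union: residues labeled in >= 1 replica; consensus: residues labeled in
    >= ceil(consensus_min_fraction * n_replicas) replicas.
    """
    if not label_sets:
        raise ValueError("need at least one replica")
    config = config or ContactConfig()
    counts: dict[tuple, int] = {}
    universe: dict[tuple, None] = {}
    for ls in label_sets:
        if ls.level != "residue":
            raise ValueError("combine_replicas expects residue-level label sets")
        for rid in ls.ids:
            universe.setdefault(tuple(rid), None)
        for rid in ls.positives:
            counts[rid] = counts.get(rid, 0) + 1
    need = ceil(config.consensus_min_fraction * len(label_sets))
    ids = [Residue(*r) for r in universe]
    union = np.array([int(counts.get(tuple(r), 0) >= 1) for r in ids])
    consensus = np.array([int(counts.get(tuple(r), 0) >= need) for r in ids])
    return {
        "union": LabelSet(level="residue", ids=ids, labels=union),
        "consensus": LabelSet(level="residue", ids=ids, labels=consensus),
    }
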