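import numpy as np
import pytest

from surfibs.labels import (
    ContactConfig,
    LabelSet,
    combine_replicas,
    md_contact_labels,
    read_label_tsv,
    residue_to_surface,
    surface_to_residue,
    write_label_tsv,
)
from surfibs.structures_io import AtomRecord, ProteinStructure, Residue
from surfibs.surface import SurfaceConfig, assign_nearest_residue, build_surface
from surfibs.synthetic import MEMBRANE_RESNAME, make_toy_protein, make_toy_trajectory


def _rls(pairs):
    """Residue LabelSet from (chain, resid, name, label) tuples."""
    return LabelSet(
        level="residue",
        ids=[Residue(c, r, n) for c, r, n, _ in pairs],
        labels=np.array([l for *_, l in pairs]),
    )


@pytest.fixture(scope="module")
def helix_with_mesh():
    structure, _ = make_toy_protein(8, seed=3)
    mesh = build_surface(structure, SurfaceConfig())
    assign_nearest_residue(mesh, structure)
    return structure, mesh


class TestResidueSurfaceMapping:
    def test_all_ones_and_unlisted_zero(self, helix_with_mesh):
        structure, mesh = helix_with_mesh
        ls = _rls([(r.chain_id, r.resid, r.name, 1) for r in structure.residues])
        out = residue_to_surface(mesh, ls, structure)
        assert out.level == "surface"
        np.testing.assert_array_equal(out.labels, 1)

    def test_single_residue_owns_exactly_its_vertices(self, helix_with_mesh):
        structure, mesh = helix_with_mesh
        target = structure.residues[4]
        ls = _rls([(target.chain_id, target.resid, target.name, 1)])
        out = residue_to_surface(mesh, ls, structure)
        expected = set(np.flatnonzero(mesh.nearest_residue == 4))
        assert set(np.flatnonzero(out.labels)) == expected

    def test_unknown_residue_warns_and_skips(self, helix_with_mesh):
        structure, mesh = helix_with_mesh
        ls = _rls([("Z", "999", "LYS", 1)])
        with pytest.warns(UserWarning, match="not found"):
            out = residue_to_surface(mesh, ls, structure)
        np.testing.assert_array_equal(out.labels, 0)

    def test_round_trip_max_is_identity_for_exposed(self, helix_with_mesh):
        structure, mesh = helix_with_mesh
        rng = np.random.default_rng(0)
        res_labels = rng.integers(0, 2, size=structure.n_residues)
        ls = _rls([
            (r.chain_id, r.resid, r.name, int(l))
            for r, l in zip(structure.residues, res_labels)
        ])
        surf = residue_to_surface(mesh, ls, structure)
        back, exposed = surface_to_residue(surf.labels.astype(float), mesh, structure)
        assert exposed.all()  # every helix residue owns >= 1 vertex here
        np.testing.assert_array_equal(back.astype(int), res_labels)

    def test_aggregation_max_mean_and_buried(self, helix_with_mesh):
        structure, mesh = helix_with_mesh
        scores = np.full(mesh.n_vertices, 0.2)
        owned = np.flatnonzero(mesh.nearest_residue == 0)
        scores[owned[0]] = 0.9
        vmax, _ = surface_to_residue(scores, mesh, structure, "max")
        vmean, _ = surface_to_residue(scores, mesh, structure, "mean")
        assert vmax[0] == pytest.approx(0.9)
        assert 0.2 < vmean[0] < 0.9
        # constant field maps to the constant for every exposed residue
        const, exposed = surface_to_residue(np.full(mesh.n_vertices, 0.7), mesh, structure)
        np.testing.assert_allclose(const[exposed], 0.7)

    def test_buried_residue_flagged(self):
        # two-residue structure where residue 2 is fully enclosed by the mesh
        atoms = [
            AtomRecord(1, "CA", "C", "ALA", 1, "A", np.zeros(3)),
            AtomRecord(2, "CA", "C", "GLY", 2, "A", np.array([0.0, 0.0, 40.0])),
        ]
        s = ProteinStructure(atoms)
        from surfibs.synthetic import make_icosphere

        mesh = make_icosphere(1, 3.0)  # everything nearest to residue 1
        assign_nearest_residue(mesh, s)
        vals, exposed = surface_to_residue(np.ones(mesh.n_vertices), mesh, s)
        assert exposed[0] and not exposed[1]
        assert np.isnan(vals[1])


class TestMDContactLabels:
    def test_planted_contact_set_recovered(self):
        protein, _ = make_toy_protein(10, seed=1)
        target = {protein.residues[6].resid}
        frames = make_toy_trajectory(protein, target, n_frames=5, seed=0)
        ls = md_contact_labels(frames, [MEMBRANE_RESNAME])
        assert {r.resid for r in ls.ids if True} >= target
        assert {r.resid for r, l in zip(ls.ids, ls.labels) if l == 1} == target

    def test_near_miss_is_no_bound_frame(self):
        protein, _ = make_toy_protein(10, seed=1)
        frames = make_toy_trajectory(
            protein, {protein.residues[6].resid}, n_frames=3, seed=0,
            contact_distance=5.1,
        )
        with pytest.raises(ValueError, match="no bound frame"):
            md_contact_labels(frames, [MEMBRANE_RESNAME])

    def test_last_bound_frame_rule(self):
        protein, _ = make_toy_protein(10, seed=1)
        target = {protein.residues[2].resid}
        frames = make_toy_trajectory(protein, target, n_frames=5, seed=0, bound_frame=3)
        # only frame 3 is bound; labels must match the planted set
        ls = md_contact_labels(frames, [MEMBRANE_RESNAME])
        assert {r.resid for r, l in zip(ls.ids, ls.labels) if l == 1} == target

    def test_empty_contact_set_never_binds(self):
        protein, _ = make_toy_protein(6, seed=2)
        frames = make_toy_trajectory(protein, set(), n_frames=4, seed=0)
        with pytest.raises(ValueError, match="no bound frame"):
            md_contact_labels(frames, [MEMBRANE_RESNAME])

    def test_invariant_to_atom_order_and_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        protein, _ = make_toy_protein(8, seed=4)
        target = {protein.residues[3].resid}
        frames = make_toy_trajectory(protein, target, n_frames=2, seed=0)
        ref = md_contact_labels(frames, [MEMBRANE_RESNAME]).positives

        R = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        t = np.array([3.0, -8.0, 11.0])
        moved = []
        for frame in frames:
            atoms = [
                AtomRecord(a.serial, a.name, a.element, a.residue_name,
                           a.residue_index, a.chain_id, R @ a.xyz + t, a.icode)
                for a in frame.atoms
            ]
            moved.append(ProteinStructure(list(reversed(atoms))))
        out = md_contact_labels(moved, [MEMBRANE_RESNAME]).positives
        assert out == ref


class TestCombineReplicas:
    def _ls(self, positive, universe):
        return LabelSet(
            "residue",
            [Residue("A", str(i), "ALA") for i in universe],
            np.array([int(i in positive) for i in universe]),
        )

    def test_union_and_consensus_fractions(self):
        universe = [1, 2, 3]
        reps = [self._ls({1, 2}, universe), self._ls({2, 3}, universe)]
        half = combine_replicas(reps, ContactConfig(consensus_min_fraction=0.5))
        assert {r.resid for r in half["union"].ids
                if half["union"].labels[half["union"].ids.index(r)]} == {"1", "2", "3"}
        assert half["consensus"].positives == {("A", "1", "ALA"), ("A", "2", "ALA"),
                                               ("A", "3", "ALA")}
        full = combine_replicas(reps, ContactConfig(consensus_min_fraction=1.0))
        assert full["consensus"].positives == {("A", "2", "ALA")}
        assert full["union"].positives == {("A", "1", "ALA"), ("A", "2", "ALA"),
                                            ("A", "3", "ALA")}

    def test_single_replica_identity(self):
        ls = self._ls({1}, [1, 2])
        out = combine_replicas([ls])
        assert out["union"].positives == out["consensus"].positives == ls.positives

    def test_disjoint_full_fraction_empty_consensus(self):
        reps = [self._ls({1}, [1, 2]), self._ls({2}, [1, 2])]
        out = combine_replicas(reps, ContactConfig(consensus_min_fraction=1.0))
        assert out["consensus"].positives == set()
        assert out["union"].positives == {("A", "1", "ALA"), ("A", "2", "ALA")}

    def test_consensus_subset_of_union_property(self):
        rng = np.random.default_rng(0)
        universe = list(range(12))
        for frac in (0.3, 0.5, 0.8, 1.0):
            reps = [
                self._ls(set(rng.choice(12, size=rng.integers(1, 8), replace=False)),
                         universe)
                for _ in range(4)
            ]
            out = combine_replicas(reps, ContactConfig(consensus_min_fraction=frac))
            assert out["consensus"].positives <= out["union"].positives


class TestLabelTSV:
    def test_round_trip(self, tmp_path):
        ls = _rls([("A", "5", "LYS", 1), ("A", "6A", "GLU", 0)])
        path = tmp_path / "labels.tsv"
        write_label_tsv(ls, path)
        back = read_label_tsv(path)
        assert back.ids == ls.ids
        np.testing.assert_array_equal(back.labels, ls.labels)
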