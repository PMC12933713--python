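# surfibs

Prediction of membrane **interfacial binding sites (IBS)** on protein
molecular surfaces with geometric deep learning.

Peripheral membrane proteins (PMPs) bind reversibly to one face of the lipid
bilayer without spanning it. The surface region that touches the membrane —
the IBS — is determined by local geometry (hydrophobic protrusions, convex
patches) and chemistry (hydropathy, charge, hydrogen-bonding capacity).
`surfibs` scores **every vertex of a triangulated molecular surface** with an
IBS probability in (0, 1), and provides the full machinery around that task:
surface construction, per-vertex features, geodesic patch decomposition, the
learned soft-polar-grid network, residue/surface label mapping, MD-derived
contact labels, and per-protein evaluation.

## Method

1. **Surface.** A protein structure (PDB) becomes a closed triangle mesh:
   either an MSMS `.vert`/`.face` surface read directly, or the built-in
   isosurface of a smooth union of probe-inflated atom spheres
   (probe 1.5 Å), regularized to ~1 Å edge length.
2. **Features.** Each vertex carries five features in [−1, 1]:
   shape index *s* = (2/π)·arctan((κ₁+κ₂)/(κ₁−κ₂)), distance-dependent
   curvature (patch-relative bending), Kyte–Doolittle hydropathy of the
   nearest residue (scaled by 4.5), a screened-Coulomb electrostatic
   potential, and a signed hydrogen-bond donor/acceptor potential.
3. **Patches.** Every vertex is the center of a geodesic patch: all mesh
   points within 9 Å geodesic radius (Dijkstra along the mesh), capped at
   the 100 nearest. Geodesic polar coordinates (ρ, θ) come from Dijkstra
   radii plus a 2-D classical MDS embedding of intra-patch geodesics, with a
   random 0° reference axis per patch.
4. **Network.** Each patch is mapped onto a learned *soft polar grid* — 12
   Gaussian kernels on 3 radial × 4 angular bins acting as soft, overlapping
   pixels. Three such convolution layers (linear filter + **angular max
   pooling** over evenly spaced rotations + ReLU) feed a small MLP head with
   a sigmoid output. Angular max pooling makes the score invariant to each
   patch's arbitrary reference axis.
5. **Training.** Adam on a sigmoid cross-entropy loss; one protein per
   batch; negatives randomly subsampled each epoch to balance the classes;
   10 % of proteins held out for validation; checkpoint kept whenever the
   mean per-protein validation ROC AUC improves.
6. **Labels & evaluation.** Residue-level IBS annotations map to vertices
   through the nearest-residue assignment and back by per-residue max
   aggregation (buried residues excluded). Labels can also be derived from
   membrane-approach MD trajectories: residues with heavy atoms within
   0.5 nm of membrane heavy atoms in the last bound frame, with union and
   consensus combination across replicas. Metrics are per-protein ROC AUC
   and MCC.

Transfer-learning surgery is included: freeze the conv layers and replace
the head with an FC128/FC64/FC4/FC2 stack (*opt1*), or freeze them and
append three fresh conv layers (*opt2*).

## Worked example

```bash
# generate a synthetic planted-IBS dataset of 8 toy proteins
surfibs synth --kind planted --n-proteins 8 --seed 0 --out-dir data/
# -> wrote 8 patch archives to data

# train (one protein per batch, balanced subsampling, Adam)
surfibs train data/ --epochs 20 --seed 0 \
    --checkpoint model.npz --history history.csv
# -> trained 12 epochs; best validation mean ROC AUC 0.9996

# score one protein
surfibs predict --checkpoint model.npz --patches data/planted000.npz --out scores.tsv
# -> wrote scores.tsv (642 scores)
```

The training log reports, per epoch, the mean training loss and the mean
per-protein validation ROC AUC; a value near 1.0 on the planted dataset
means the network has recovered the planted hydrophobic-protrusion signal,
while ~0.5 indicates chance level. A library-level pipeline (PDB → surface →
features → patches → scores) is shown in the module docstrings;
`surfibs mdlabel` derives residue labels from a multi-MODEL PDB trajectory
and `surfibs crossval --features geom|chem|all` runs the grouped k-fold
feature-ablation harness.

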