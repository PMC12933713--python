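# Methods

This note documents the models, numerical choices, and limitations behind
`surfibs`. It is the package's own account of its science; every number it
mentions is computed by the test suite or `scripts/acceptance.py` at run
time.

## Surfaces

The canonical input is a solvent-excluded surface from MSMS (`.vert`/`.face`
reader, 1-based faces converted to 0-based, zero normals recomputed by
area-weighted face-normal accumulation). When MSMS output is unavailable the
built-in generator extracts the zero isosurface of a smooth union of atom
spheres,

φ(x) = −s · log Σᵢ exp(−(‖x−xᵢ‖ − rᵢ − r_probe)/s),

on a regular grid (default spacing 0.6 Å, blending width s = 0.3 Å, probe
1.5 Å, van der Waals radii per element) via marching cubes. This is a
solvent-accessible-style envelope: it lacks the reentrant patches of a true
reduced surface but is closed, outward-oriented, and has the same downstream
contract. Only the largest connected component is kept by default, since
disconnected fragments usually indicate missing density rather than real
topology. Degenerate inputs (≥3 heavy atoms collinear within one grid
spacing) are rejected.

Meshes are regularized to a target edge length (default 1.0 Å) by iterated
isotropic remeshing: edges longer than 4/3·L are split at their midpoint,
edges shorter than 4/5·L are collapsed (guarded by the link condition so the
mesh stays manifold and the Euler characteristic is preserved), followed by
tangential Laplacian smoothing (λ = 0.3). Edge flips are omitted; the
median-edge, aspect-ratio, and topology contracts are met without them and
omitting them removes a class of connectivity bugs. The contract is a median
edge within ±25 % of the target and no face with aspect ratio above 20.

Every vertex is assigned the residue of its **nearest heavy atom**
(hydrogens are absent from most crystal structures); exact ties break to the
lower atom serial, which makes the assignment deterministic and invariant to
vertex reordering.

## Per-vertex features

Fixed column order: `[shape_index, ddc, hydropathy, electrostatics, hbond]`,
all clipped to [−1, 1].

- **Shape index**: principal curvatures from a quadric height fit
  h(u,w) = du + ew + au² + buw + cw² over the 2-ring in the local normal
  frame; κ = eigenvalues of −Hess(h) so that convex regions (w.r.t. the
  outward normal) are positive; s = (2/π)·arctan((κ₁+κ₂)/(κ₁−κ₂)), with
  s = sign(κ₁) at umbilic points. Spheres give +1, saddles 0, cylinders +0.5.
- **Distance-dependent curvature (ddc)** is patch-relative:
  ddc = clip(2⟨p−p_c, n_c⟩/‖p−p_c‖² · r_patch, −1, 1), zero at the center.
  On a sphere of radius R every member evaluates to −r_patch/R exactly.
  The vertex-level feature table stores 0 in this column; patch extraction
  overwrites it per member.
- **Hydropathy**: Kyte–Doolittle value of the nearest residue divided by
  4.5 (ILE → +1, ARG → −1); unknown residues → 0.
- **Electrostatics**: screened Coulomb (Debye–Hückel) potential
  φ(v) = Σ qᵢ exp(−κ_D d)/d over a coarse formal-charge table (LYS NZ +1,
  ARG CZ +1, ASP CG −1, GLU CD −1, HIS neutral), Debye length from the ionic
  strength (default 0.15 M), distances clamped at 0.1 Å. The potential is
  robust-scaled by the 97.5th percentile of |φ| over the protein and
  clipped; percentile scaling bounds the feature without letting isolated
  charge clusters dominate. A per-vertex override hook accepts values from
  an external Poisson–Boltzmann solver for users who want full fidelity.
- **Hydrogen-bond potential**: role(a*)·exp(−(d−d₀)²/2σ²) with the nearest
  polar (N/O) heavy atom a* within 3.5 Å, d₀ = 1.5 Å (probe contact),
  σ = 1.0 Å; roles from a bundled per-residue table (+1 donor, −1 acceptor,
  backbone N/O included). Vertices with no polar atom within 3.5 Å get 0.

The two geometric features are intrinsic and all chemical features depend
only on distances, so the full feature table is invariant under rigid
motions of structure and mesh together.

## Geodesic patches and polar coordinates

Geodesic distances are Dijkstra shortest paths on the mesh graph. The graph
contains the mesh edges **plus all 2-hop vertex pairs weighted by their
Euclidean chord**: pure edge-walk distances systematically overshoot surface
geodesics by roughly 10 % on a sphere independent of resolution (the lattice
admits only a few path directions), and the chordal shortcuts cancel most of
that bias (mean error under 5 % against great-circle arcs up to 60°).

A patch collects the vertices within 9 Å geodesic radius of its center,
keeping at most the 100 nearest (ties by vertex index). Shorter patches are
padded to 100 with mask = 0, ρ = 9 Å, θ = 0 and zero features; the Gaussian
grid gives padded slots near-zero weight and the mask removes them from
every sum exactly (the training-loss gradient with respect to padded
features is identically zero). The angular coordinate comes from a classical
(Torgerson) metric MDS of the pairwise intra-patch geodesic distance matrix,
computed on the patch-induced submesh — distances inside a 9 Å disc rarely
shortcut outside it and the restriction bounds cost. ρ is kept from Dijkstra
(not from the embedding). Each patch measures θ from a uniformly random
reference direction; the chirality of the 2-D embedding is deliberately left
unresolved, because the network removes both ambiguities by angular max
pooling. Patches with fewer than 3 real members get θ = 0.

## Network

Each conv layer owns a **soft polar grid** of 12 Gaussian kernels (3 radial
× 4 angular bins) with learnable centers and widths; widths stay positive
through a softplus reparameterization. Kernels are initialized on a regular
polar lattice over [0, 9] Å × [0, 2π), widths at half the bin spacing. The
grid maps a patch to 12 normalized bin activations per input channel,

bin(b, f) = Σₘ mask·w_b(ρ, θ+offset)·x_f / (Σₘ mask·w_b + 1e−8),

with the angular difference wrap-aware. A linear filter maps the flattened
bins to 16 channels; the responses at 4 evenly spaced angular offsets are
max-pooled (rotational augmentation realized as pooling rather than dataset
duplication) and passed through ReLU. Layers 2 and 3 reuse the same patch
geometry and gather the previous layer's per-vertex outputs over the patch
members. The head is a small MLP (default one hidden layer of 8) ending in
one sigmoid unit. Channel width 16, learning rate 1e−3, and ReLU are desk-
scale defaults exposed in the configs.

With 4 rotations and 4 angular bins, re-randomizing every patch's reference
axis moves scores by well under 0.05, and 8- vs 16-rotation forward passes
agree within 0.02 — the empirical form of the rotation-invariance design
goal.

**Training**: Adam, sigmoid cross-entropy, one protein per optimization
step. Because non-IBS vertices greatly outnumber IBS vertices, each step
uses all positives plus an equal-size random negative subsample, redrawn
every epoch. 10 % of proteins form the validation set; the checkpoint is
saved whenever the mean per-protein validation ROC AUC improves, and
training stops early after `patience` epochs (default 10) without an
improvement larger than `min_delta` (default 1e−3). Proteins whose labels
are single-class are excluded with a warning. Everything is seeded and
bit-reproducible.

**Transfer surgery**: `opt1` freezes the three conv layers and replaces the
head with an FC128/FC64/FC4/FC2 stack before the sigmoid output; `opt2`
freezes them and appends three fresh conv layers plus a fresh head. Frozen
parameters are excluded from the optimizer and remain bit-identical through
training.

The network and Adam are implemented over numpy with a compact reverse-mode
autodiff engine (`surfibs/_autodiff.py`) covering exactly the operator set
the model needs; its gradients are verified against central finite
differences in the test suite. Model arithmetic runs in float32.

## Labels

Residue→surface: each vertex inherits its nearest residue's label; unlisted
residues count as 0. Surface→residue: per-residue max (or mean) over owned
vertices; residues owning no vertex are flagged buried and excluded from
residue-level evaluation — "surface-exposed" is defined as owning at least
one mesh vertex, matching the nearest-residue machinery.

MD contact labels use the **last frame in which any protein–membrane
heavy-atom pair is within the cutoff** (5.0 Å, i.e. 0.5 nm); a residue is
labeled 1 iff its minimum heavy-atom distance to membrane heavy atoms is
within the cutoff. "Membrane" atoms are all heavy atoms of the configured
lipid residue names, not only head groups. Contacts use side-chain and
backbone heavy atoms by default, with a side-chain-only switch. Replica
combination: union = labeled in ≥1 replica; consensus = labeled in
≥ ceil(fraction × n_replicas) replicas (default fraction 0.5) — an explicit,
monotone reading of time-averaged consensus that reduces to the union as the
fraction approaches 0. Consensus ⊆ union always.

## Evaluation

ROC AUC is the Mann–Whitney probability that a random positive outscores a
random negative (ties ½; undefined and raising for single-class inputs).
MCC uses the standard confusion-matrix formula with the zero-denominator →
0 convention so degenerate proteins stay in summaries. Binarization is
score ≥ threshold (threshold an explicit argument, default 0.5). Reports are
per-protein with median/mean summaries. Cross-validation assigns whole
groups (superfamilies; cap-direction octants in the synthetic data) to folds
greedily, largest group first into the currently smallest fold, so related
proteins never straddle a train/test boundary.

## Synthetic data

The planted-IBS generator emulates the statistical structure of the real
task: 20 proteins per study set, each a bumpy sphere (icosphere subdivision
3 → 642 vertices, radius 12 Å, low-frequency radial noise of 3 %) with a
geodesic cap covering 15 % of the surface labeled IBS — the minority-class
regime that motivates balanced negative subsampling. Inside the cap the
hydropathy and shape-index features are shifted by +0.6 (a hydrophobic
protrusion, the signal the ablation harness should rank as dominant);
all five features carry Gaussian noise of σ = 0.3 and are clipped to
[−1, 1]. Group tags are the octant of the cap direction, giving 8
pseudo-superfamilies for grouped splits. Protein size (642 vertices) and
count (20) were chosen as the smallest set on which per-protein batching,
validation splitting, and grouped k-fold are all non-trivial.

What the generator does **not** emulate: real side-chain geometry, correlated
features, electrostatic signal in the IBS, superfamily-specific binding
modes, or conformational change on binding. Passing the planted-recovery
test therefore shows the architecture and training loop can learn a
localized, feature-coupled surface signal — not that the defaults reach any
particular accuracy on real PMPs.

Toy proteins are ideal helices (rise 1.5 Å, twist 100°, 50 % hydrophobic /
30 % polar / 20 % charged residues) with representative side-chain heavy
atoms, written as byte-stable PDB text. Toy trajectories rigidly translate
a protein toward a planar grid of pseudo-lipid residues so that, in the
bound frame, exactly the requested residues sit within 4.9 Å of membrane
atoms and all others stay ≥ 6 Å away; the orientation is chosen by searching
~600 candidate directions for the one that best separates contact from
non-contact residues, and geometrically unrealizable requests raise an
error.

## Known limitations

- The internal surface is solvent-accessible-like, not a true reduced
  surface; deep reentrant pockets are smoothed over.
- Electrostatics and hydrogen-bond potentials are self-contained surrogates
  with the right sign, range and distance behaviour, not solver outputs;
  the override hook restores fidelity where APBS-style values exist.
- Dijkstra-plus-chords is an approximation to exact polyhedral geodesics
  (no MMP/heat method); accuracy is bounded by mesh resolution.
- Patch pairwise distances ignore shortcuts leaving the 9 Å disc.
- Training is CPU-bound numpy; desk-scale datasets (hundreds of proteins at
  ~10³ vertices) are practical, proteome-scale runs are not the target.
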