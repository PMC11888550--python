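# Methods

This note documents the model, the protocols, the numerical choices, and
what the synthetic test bed does and does not establish.

## Problem setting

A degrader-induced ternary complex has three rigid bodies: protein1 (the E3
ligase; its input coordinates define the output frame and pass through
unchanged), a small molecule, and protein2 (the protein of interest). The
task is to predict the ligand conformation and the rigid placements of the
ligand and protein2 relative to protein1. Two regimes are supported:

* **PROTAC mode** — the anchor–E3 and warhead–POI binary poses are known
  ("unbound pockets", standard in PROTAC design). The network predicts the
  PROTAC conformation and a confidence (PAE); geometry is assembled from the
  unbound pockets. 40 conformer seeds are sampled and ranked by PAE.
* **Molecular-glue (MGD) mode** — blind: the decoder predicts the interface
  pocket points itself; a single seed is used because glue molecules have
  little conformational freedom.

## Featurization

Ligand atoms carry atomic number, chirality, total degree, formal charge,
implicit/total hydrogen counts, radical electrons, hybridization,
aromaticity and ring membership (categoricals one-hot with an explicit
"unknown" bucket); hydrogens are excluded. Ligand edges connect atom pairs
strictly closer than 4 Å in the construction conformation. Protein residues
are Cα nodes typed by amino acid (20 + unknown); protein graphs use
k-nearest neighbours, default k = 10, ties broken by ascending index. Edge
features are the Euclidean distance plus an 8-centre Gaussian radial basis;
an optional angular descriptor (cosine between the edge vector and the
direction to the molecular centroid) can be enabled for ligand graphs —
distance is the only unambiguous relative-geometry feature, so the angular
term is off by default. Conformer pools are generated with RDKit ETKDGv3,
one conformer per seed (bitwise-reproducible per seed), 50 per ligand for
training.

Pocket embeddings: nodes belonging to a known binding pocket are flagged; a
learnable per-entity-type vector is added to their latent features by
summation. At inference the flagged nodes' coordinates are pinned to the
unbound binary pose; during training flags sit on the ground-truth
(post-augmentation) pocket members.

## Encoder

M layers (default 8, hidden dimension 64; the small test model uses 4/32)
alternate intra-graph messages, ternary inter-graph attention, an
equivariant coordinate update along unit neighbour directions, and a convex
latent update with trade-off β (default 0.5). The two protein parameter
groups are one shared store, making the network symmetric under exchanging
the proteins; training additionally swaps the protein labels with
probability 1/2. Only squared distances and invariant features enter the
messages, so latents are E(3)-invariant and coordinates exactly equivariant
under independent rigid motions of each input graph (verified to < 1e-4 by
the test suite with active, randomly weighted coordinate heads).

Numerical choices, all of which the cited model family uses but the
equations do not spell out:

* non-affine layer normalization on latents wherever they feed an MLP or an
  attention projection — without it the latent recursion diverges at
  learning rates above ~1e-3;
* the coordinate-update head φ_x has a zero-initialized output layer, so an
  untrained network is the identity on coordinates and displacement fields
  grow from zero;
* attention logits are scaled by 1/sqrt(hidden_dim) (absorbed into φ_q);
* empty neighbourhoods produce the zero message; coincident node pairs are
  skipped in the coordinate update (removable singularity);
* the distance-geometry projection Ψ defaults to the identity; optionally it
  restores the ligand's reference 1-2 (< 1.8 Å) and 1-3 distances with 20
  Gauss–Seidel sweeps.

Training-time regularization adds zero-mean Gaussian noise to input
coordinates and initial latents. The noise level is expressed in Å (default
2, the value the ablation literature favours over 1 and 3) and applied as
noise_level/scale in the normalized frame, i.e. 0.2 latent/coordinate units
at the default scale — a literal σ = 2 in normalized units would displace
entities by ~20 Å and destroy the signal.

## Decoder and pocket points

Four learnable query blocks (default 10 rows each; 8 in the small test
model) plus one PAE query are refined against the role-embedded encoder
latents by N layers (default 4) of self-attention, query→graph
cross-attention and graph→query feedback, all single-head (multi-head is a
config flag kept only for the ablation that shows it hurts coordinate
extraction). The blocks are wrapped in residual (pre-norm) connections;
without the skips, near-uniform early attention collapses every query row
onto the same vector and all pocket points coincide — we observed exactly
this failure before adding them. In PROTAC mode the same decoder runs with
only the PAE query.

Pocket coordinates are attention-weighted sums of the source graph's
(encoder-updated) coordinates, hence always inside that graph's convex hull
and equivariant with it. The PAE head is an MLP with a softplus output
(non-negative by construction), trained against the unaligned coordinate
RMSD of protein2 in protein1's frame and reported in Å after
un-normalization.

## Assembly

`kabsch(P, Q)` returns the proper rigid transform mapping the first
argument onto the second (so the update equations read literally);
reflections are corrected by flipping the smallest singular vector, and
collinear or undersized point sets raise unless explicitly tolerated (the
inference path tolerates them, since an undertrained model can emit nearly
flat pocket sets). MGD assembly aligns the ligand by kabsch(P_lig,
P_p1→lig) and protein2 by kabsch(P_p2, P_p1→p2). PROTAC assembly aligns the
predicted PROTAC onto the anchor pocket, re-expresses the warhead in
protein1's frame with that same transform, and aligns protein2's unbound
pose onto the placed warhead. Protein1 is never touched; ligand and
protein2 internal geometry is preserved to 1e-6 Å. Complexes are written as
multi-chain PDB/mmCIF (A = p1, B = p2, ligand as HETATM residue LIG) with a
JSON transform log.

## Objective

The six terms are summed unweighted (per-term weights exist in config,
default 1):

* ligand MSE and Kabsch-aligned ligand MSE (the latter isolates
  conformational from placement error and never exceeds the former);
* one optimal-transport term per interface. Each interface has a single
  native target point set — the contact-pair midpoints (4 Å rule for
  ligand–protein contacts, 10 Å for protein–protein, matching the DockQ
  interface convention), subsampled to at most 8 points by farthest-point
  selection. Both predicted sides of an interface are transported to that
  set under one shared plan, cost(k, j) = ‖a_k − t_j‖² + ‖b_k − t_j‖², so
  that row k of both sides converges to the same physical point — exactly
  the index correspondence the Kabsch alignment requires. Per-side targets
  (ligand atoms vs. protein Cα) would leave that correspondence
  unconstrained and make the assembly transform meaningless at convergence;
  the per-side 4 Å membership rule is still used for the pocket-embedding
  flags. Transport is solved exactly: linear assignment for equal
  cardinalities, a uniform-marginal LP otherwise (no entropic smoothing —
  the sets are small). The target-set cap matters because uniform-marginal
  transport onto a much larger cloud has an irreducible quantization floor
  unrelated to prediction quality.
* an intersection penalty: per entity pair, the mean over atoms of
  relu(Σ_b exp(−d²/σ²) − γ) with σ = 1.5 Å (scaled into the normalized
  frame) and clash onset γ = 1. σ is chosen so the penalty is exactly zero
  for any geometry respecting the 2 Å clash rule — a larger width would
  penalize native contact geometry and break the "all terms vanish at
  ground truth" property;
* an L1 PAE loss against protein2's RMSD.

Combinatorial sub-solves (transport plans, Kabsch rotations) are computed on
detached values and treated as constants under the autograd trace; for the
Kabsch-aligned MSE this yields the exact gradient (envelope argument), for
the transport plan it is the standard fixed-plan gradient.

## Training and inference protocols

Cluster-balanced sampling draws a sequence cluster uniformly, then its
representative with probability 0.2, else a uniform member. Per instance
one protein is fixed (fair coin); the other protein and a random pool
conformer receive uniform random rotations and ball-uniform translations
(radius 10 normalized units); when protein1 is the moved one, the targets
are re-expressed in its new frame. Coordinates are normalized to protein1's
centroid at 10 Å per unit; un-normalizing restores protein1 exactly.
Optimization is Adam (default lr 1e-4; the overfit harness uses 1e-2) with
global-norm gradient clipping at 1.0. Gradients come from HIPS autograd
over pure-numpy forward passes; parameters live in a flat named-array dict,
checkpointed as .npz plus a JSON config manifest.

Failed conformer seeds at PROTAC inference are skipped with a warning; the
ranking is ascending PAE with ties broken by seed index, ranks 1-based.

## Synthetic test bed

`ternadock.synthetic` fabricates toy ternary complexes with full ground
truth: a zig-zag "ligand" chain (C/N/O atoms, 1.5 Å spacing, anchor block
dipping toward protein1 and warhead block toward protein2) sandwiched
between two flattened self-avoiding-walk Cα "proteins" slid to a 2.35–2.7 Å
closest approach, plus a few deliberate protein–protein contact bridges at
the DockQ-relevant separation. Default sizes (10+10 residues, 9 ligand
atoms) keep every stage fast on one CPU. By construction each fixture
passes the contact (≥3 at 4 Å) and clash (none under 2 Å) filters, has ≥2
native protein–protein contacts under 5 Å, non-collinear anchor/warhead
triples and interface point sets, an exact PROTAC unbound-pocket bundle
(a rigidly displaced protein2 with its warhead pose and index maps), a
rigid-copy conformer pool, and synthetic sequences grouped into
mutated-copy clusters for the split machinery.

What the toys do not emulate: real chemistry (bond orders, torsional
energetics, rotamers), full-backbone proteins, crystallographic noise, and
PDB-scale diversity. Passing the suite therefore demonstrates correctness
of the machinery — symmetries, geometry, losses, protocols, metrics — not
benchmark-level accuracy on real PROTAC/MGD complexes, which would require
training on a PDB-scale corpus.

## Parameter-recovery (tiny-overfit) check

Three fixtures, the small model (hidden 32, 4 encoder layers, 2 decoder
layers, 8 queries), identity augmentation and zero noise so each fixture is
a fixed regression target, full-batch Adam (lr 1e-2) on the mean six-term
loss, at most 2000 updates with early stop once the running-mean loss falls
below 2% of its initial value. Measured at seed 0: convergence in 217
steps (~2 minutes on one CPU), final/initial loss ratio 0.017, re-predicted
DockQ 0.997–0.998 against each fabricated native, ligand RMSD ≤ 0.24
normalized units; seeds 1 and 2 behave the same (ratios 0.014–0.021, DockQ
≥ 0.93). The full stochastic protocol (cluster sampling, augmentation,
noise, p1/p2 swap) is exercised separately by the training-loop tests.

## Metrics

DockQ is computed on the protein1–protein2 interface with the standard
constants: 5 Å contacts for Fnat, 10 Å for interface residues, 1.5/8.5 Å
scales, receptor = protein1 in this package's frame convention. With
Cα-only toy proteins, "backbone" and "heavy atom" reduce to Cα. CAPRI
classes are assigned from DockQ bands (≥0.80/>0.49/>0.23) rather than the
original decision tree — an approximation consistent with how the bands are
reported. SASA is Shrake–Rupley with golden-spiral sphere points (default
960; doubling changes totals < 1%), probe 1.4 Å, standard van-der-Waals
radii with a warned default of 1.7 Å for unknown elements; buried area per
pair is SASA(A) + SASA(B) − SASA(A∪B), summed over the three pairs without
dividing by two.

## Curation

Filters are pure functions over parsed metadata/coordinates with an audit
trail on the record; the verdict is order-independent. Boundary semantics:
resolution ≤ 3.5 and R-free ≤ 0.26 are inclusive; the 2 Å clash rule is
strict (exactly 2.00 Å passes); the contact rule counts ligand atoms within
4 Å of any protein atom, jointly across both proteins. The whitelist ships
with the two canonical borderline entries (an R-free of 0.268 and a 1.97 Å
contact) and is user-extendable; "heavy atom" means atomic number > 1.
Production-scale sequence clustering is imported from an external tool's
cluster table (cluster-id TAB member-id); the built-in greedy clusterer
(global-alignment identity via Bio.Align, threshold 0.5) exists for
fixtures. Offline, the parsers and distance measurements for the borderline
checks are exercised on fabricated stand-ins with those values planted;
verifying them against the actual archive entries requires downloads.

## Known limitations

* The published parameter scale (~16.7 M) and trained weights are not
  reproduced; hidden sizes are defaults, and benchmark DockQ levels are out
  of reach without PDB-scale training.
* The absolute-coordinate ligand MSE is frame-sensitive: under SE(3)
  augmentation an equivariant network cannot drive it to zero in general;
  it is meaningful in the identity regime and as a soft anchor otherwise
  (the Kabsch-aligned term carries the conformational signal).
* The intersection penalty's gradient flows through the ligand path only;
  protein2's placement enters it via a detached rigid transform.
* Exact transport via LP is suitable for tens of points per set, not
  thousands.
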