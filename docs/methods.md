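# Methods

## Model overview

`shellscore` scores a docked protein–ligand pose by predicting its heavy-atom
RMSD to the native ligand placement, computed in the common coordinate frame
(no re-superposition, as is standard for re-docking evaluation).  Lower
predicted RMSD ranks better.  The model has three stages: shell-graph
construction, per-shell graph-transformer encoding, and an MLP regression
head over the concatenated shell embeddings.

### Shell partition

The whole ligand is the center of the shell stack.  A protein atom's radial
coordinate is its distance to the *nearest* ligand atom, which makes the
shells ligand-shaped rather than spherical and assigns each atom to exactly
one shell.  Shell k covers the half-open band (d0+(k−2)·d, d0+(k−1)·d], with
the first shell starting at 0.  Defaults: d0 = 3.0 Å, d = 1.0 Å, n = 10
shells, i.e. an outer boundary of 12 Å — the range that covers ordinary
non-covalent interactions (hydrogen bonds ~3 Å, van der Waals contacts
3.5–4.5 Å, longer-range electrostatics out to ~12 Å).  The boundary
convention is (lower, upper]: a distance exactly on a boundary belongs to the
inner shell.  All three values are configurable.

### Per-shell graphs

Graph k holds every ligand atom plus shell k's protein atoms.  Edges:

* ligand–ligand: the covalent bonds, category single/double/triple/aromatic,
  distance feature fixed to 1.  The covalent skeleton (not a clique) is used
  so the shortest-path structure of the ligand survives for the attention
  biases.
* protein–ligand: every pair within the shell's (DistMin, DistMax] band,
  category "non-covalent", distance feature DistMax — the band's outer
  boundary, deliberately *not* the true pairwise distance.  Using the same
  band for membership and for edge creation guarantees each protein node has
  at least one ligand edge.
* protein–protein: never.

Node features are 171-dim one-hot stacks: protein atoms populate the first
97 dims (element category ×7, degree ×10, implicit valence ×6, attached
hydrogens ×6, hybridization ×9, amino-acid type ×22, PDB atom name ×37),
ligand atoms the last 74 (element ×7, degree ×10, valence ×6, hydrogens ×6,
hybridization ×9, formal charge ×22, ring size ×12, aromaticity ×2).  The
element block lists 6 named elements plus metal (protein) or halogen
(ligand); anything else encodes as all-zeros in that block, which is what
makes the printed 7-wide block consistent with the 97/74/171 totals.  The
vocabularies behind the block widths (charge range −10…+10, 36 common PDB
atom names, ring sizes 3–10 with >10 as "other", etc.) live in one
`FeatureSchema` constant and are exported as JSON next to cached features.
Protein atoms read from PDB files carry no bond graph, so their
degree/valence/hydrogen/hybridization blocks are unknown and stay all-zero;
the informative protein blocks are element, residue type and atom name.

### Encoder

Each shell graph is processed by its own graph-transformer stack (weights
are not shared across shells).  Attention scores are

    A_ij = (h_i W_Q)(h_j W_K)^T / sqrt(d_head) + b_φ(i,j) + c_ij

* Spatial bias b: shortest-path hop counts φ between all node pairs come
  from Floyd–Warshall on the unweighted graph, capped at hop_max (default 5)
  with −1 for unreachable pairs.  Every φ value, including the −1 sentinel
  and the diagonal 0, has its own learnable scalar per attention head.
* Edge bias c: one shortest edge path per pair is reconstructed
  deterministically (pivots tried in ascending node order, strict
  improvement only, so the smallest pivot wins ties) and truncated to
  hop_max edges; c_ij is the mean of dot-products between the edge feature
  vectors along the path and position-indexed learnable weight vectors.
  Pairs with φ ∈ {0, −1} get c = 0.  The raw distance entry (1…DistMax Å)
  enters unscaled; it is bounded by the outer shell radius.
* No centrality (degree) encoding anywhere — in ablations it does not help
  this task and can hurt.

Readout uses a virtual token prepended to the node list; its pairs use a
dedicated learnable bias slot.  Pre-norm residual blocks (LayerNorm →
attention, LayerNorm → 2× ReLU MLP) keep small models stable without a
warmup schedule.  The final virtual-token representation is projected to the
128-dim shell embedding.  Note a structural property of this readout: in a
single-layer stack the virtual row of the bias matrix is constant, so the
spatial/edge biases affect the embedding only from two layers on; one-layer
models still learn through content-based attention over node features.

Defaults: 4 layers, 4 heads, d_hidden = 128, embedding 128 — only the
embedding width is architecturally pinned (it fixes the 1280-dim input of
the head at n = 10); the rest are configurable.

### Head and the dissociated rule

The n shell embeddings are concatenated (10 × 128 = 1280 by default) and
passed through an MLP (1280 → 256 → 64 → 1, ReLU) whose scalar output goes
through a softplus so predicted RMSD is nonnegative.  If *no* shell contains
a protein atom the pose has left the modeled interaction range entirely and
its prediction is +infinity without running the network.  Infinite
predictions are excluded from losses and regression metrics and rank last in
ordering metrics.

## Training recipe

MSE loss, AdamW (betas 0.9/0.999, weight decay 0.01) with initial learning
rate 0.001 halved every STEP = 25 epochs; early stopping when the
*validation* loss fails to improve by at least 1e-4 for STEP consecutive
epochs; hard cap 150 epochs; the checkpoint with the lowest validation loss
is returned.  Early stopping monitors validation rather than training loss
because checkpoint selection is validation-based; monitoring training loss
would make the two criteria disagree.

`fit_ensemble()` splits the complexes (never the poses of one complex) into
four disjoint parts; each part trains one model and validates on another
randomly chosen part; metrics are reported as mean ± std across the four
models.  Datasets replicate each complex's native pose four times so natives
survive any split.

All numerics are float64 throughout — with NumPy as the computational
backend this is the native dtype, and it keeps the finite-difference
gradient checks of the autodiff core tight.  The reverse-mode engine in
`shellscore/_autodiff.py` implements exactly the operations the encoder and
head need (batched matmul, softmax, layer norm, table gather, the edge-path
contraction) with hand-written backward passes, each verified against
central differences in the test suite.

## RMSD computation

Plain RMSD uses the identity atom mapping over heavy atoms.
Symmetry-corrected RMSD minimizes over graph automorphisms of the ligand
(element- and bond-order-preserving permutations, enumerated with VF2), so
chemically equivalent atoms — e.g. a flipped phenyl ring — do not inflate
the deviation.  The automorphism minimum is cross-checked in the tests
against brute-force permutation enumeration and against RDKit's substructure
self-matches.  The symmetric value can never exceed the plain one, and a
whole-molecule translation by t gives plain RMSD exactly |t|.

## Curation predicates

Applied before training/scoring, each independently reportable: resolution
≤ 3.0 Å (skipped when unknown), 5–60 ligand atoms, rotatable bonds ≤ 20
(single acyclic bonds between non-terminal heavy atoms; the cap is
configurable since published practice varies), and no ligand–protein
covalent contact (any heavy non-metal inter-molecular pair < 1.8 Å — just
above the longest common covalent bonds and well below van der Waals
contact distances).

## Synthetic data

The fixture generator emulates a re-docking study at desk scale.  Each toy
complex is a rigid template ligand (benzene by default) inside a spherical
pocket of protein-like atoms placed at controlled nearest-ligand distances:
default 3.5 ± 0.4 Å, i.e. straddling the first two shell boundaries, with
48 pocket atoms.  Decoy poses are rigid whole-ligand translations, chosen
because a translation by t has in-place RMSD exactly |t| — every label is
analytic, which is the fixture's entire point.  Displacement magnitudes are
drawn uniformly from (0, 2.5] Å so the label range brackets the 2 Å
near-native threshold, and four exact native copies per complex mirror the
replication used in ensemble training.

Displacing the ligand moves pocket atoms between shells, so shell-occupancy
patterns carry a smooth, monotone signal about the displacement magnitude;
the radial jitter blurs the occupancy thresholds into a learnable gradient.
What these fixtures do *not* contain: torsional decoys, chemistry diversity,
clashes, solvent, or any pose-quality signal beyond geometry.  Tests passing
on them demonstrate that the architecture can extract distance-band
occupancy signals and that every contract (shapes, invariances, recipes)
holds — not that the model reaches publication-level accuracy on real
docking data, which would require GPU-scale training on a curated corpus.

## Problem sizes used in the checks

The conformance suite trains the reduced model (2 shells, 1 layer, 2 heads,
d_hidden 32, embedding 32, head 32→16) on 10 complexes × 24 poses with seed
7; it reaches train MSE ≈ 0.02 and held-out Pearson r ≈ 0.94 in about 75
epochs, comfortably clearing the acceptance bars (MSE < 0.25, r > 0.8).
Shortest-path checks run 200 random graphs of ≤ 30 nodes against a BFS
oracle; permutation invariance uses 50 node shuffles; the random-ranking
enrichment-factor expectation uses 1000 shuffles.

## Known limitations

* Protein-side chemistry blocks are empty for PDB-derived structures (no
  bond perception is attempted).
* DistMax-as-distance deliberately discards intra-band geometry; the model
  sees band membership, not exact contact distances — by design.
* The edge/spatial biases are inert in 1-layer stacks (see above).
* Hydrogens are used only if present in the input files; no protonation.
* Automorphism enumeration is capped at 10 000 mappings; pathological
  highly symmetric ligands would fall back to a partial minimum.
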