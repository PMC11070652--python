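# shellscore

Scoring protein–ligand docking poses by predicting each pose's RMSD to the
native binding mode with a shell-graph graph transformer.

## The problem

Docking samplers emit dozens of candidate placements ("poses") of a ligand in
a protein binding site; a scoring function must rank the near-native poses
(RMSD < 2 Å to the crystallographic ligand) above the rest.  `shellscore`
treats this as regression: predict the pose's heavy-atom, in-place RMSD and
rank ascending.

## The model

The binding-site environment is partitioned into *n* concentric shells
centered on the whole ligand molecule: a protein atom with nearest-ligand
distance *r* belongs to shell *k* when
`d0 + (k−2)·d < r ≤ d0 + (k−1)·d` (the first shell starts at 0; defaults
d0 = 3 Å, d = 1 Å, n = 10).  Each shell yields a graph containing all ligand
atoms (connected by the covalent skeleton, distance feature fixed to 1) and
the shell's protein atoms, each linked to the ligand atoms inside the shell's
distance band by non-covalent edges whose distance feature is the band's
outer boundary, DistMax.  Protein–protein edges never exist.  Nodes are
171-dimensional one-hot stacks (protein block: first 97 dims; ligand block:
last 74); edges are 8-dimensional (7-way category + distance).

Each shell graph is embedded by a graph transformer whose attention score is

    A_ij = (h_i W_Q)(h_j W_K)^T / √d  +  b_φ(i,j)  +  c_ij

with `φ(i,j)` the Floyd–Warshall shortest-path hop count (capped at hop_max,
−1 when unreachable, each value mapped to a learnable scalar per head) and
`c_ij = (1/N) Σ_p x_{e_p}·w_p^E` the mean dot-product of edge features along
one shortest path with position-indexed learnable weights.  Centrality
(degree) encoding is deliberately omitted.  A virtual readout token pools
each graph into a 128-dim embedding; the *n* embeddings are concatenated
(1280 dims at n = 10) and an MLP head predicts RMSD.  A pose whose shells
contain no protein atom at all scores +infinity.

Training minimizes MSE with AdamW (lr 0.001 halved every 25 epochs), early
stopping after 25 non-improving validation epochs, a hard cap of 150 epochs,
and a 4-part complex-disjoint ensemble whose metrics are reported as
mean ± std; native poses are replicated four times per complex so every part
retains natives.

## Worked example

Everything below runs from synthetic fixtures — no downloads.  A reduced
model (2 shells, 1 layer, 32 hidden units) is trained on 10 synthetic
complexes × 24 poses whose RMSD labels are exact by construction (rigid
translations):

```python
from shellscore import (ShellLayout, ScoringConfig, ShellScoreModel,
                        make_learnable_dataset)
from shellscore.graphormer import GraphormerConfig

data = make_learnable_dataset(n_complexes=10, poses_per_complex=20, seed=7)
config = ScoringConfig(
    layout=ShellLayout(3.0, 1.0, 2),
    encoder=GraphormerConfig(d_hidden=32, n_heads=2, n_layers=1, out_dim=32),
    mlp_hidden=(32, 16), seed=7)
results = ShellScoreModel(data, config).fit()
print(results.summary())
```

```
Shell-graph RMSD regression results
===================================================
shells (n, d0, d)                       2, 3.0, 1.0
encoder (layers/heads/d)                     1/2/32
embedding per shell                              32
epochs run                                       74
best epoch                                       48
best val MSE                                 0.0923
final train MSE                              0.0171
train complexes                                   8
val complexes                                     2
===================================================
```

Training stopped at epoch 74 (25 validation epochs without improvement after
the best checkpoint at epoch 48); the best held-out MSE of 0.09 Å² means the
model recovers the displacement magnitude to about ±0.3 Å.  Evaluating the
ranking on the two held-out complexes:

```python
test = [p for p in data if p.complex_id in set(results.val_complex_ids)]
print(results.evaluate(test, k_dock=1, k_hit=10).text())
```

```
rmse               0.30374652266980773
pearson_r          0.9374914056978303
spearman_rho       0.925942153619331
docking_power      1.0
hit_rate           0.5409356725146199
enrichment_factor  1.2982456140350878
```

Docking power 1.0 says the top-scored pose of every held-out complex is
near-native; hit rate 0.54 says the top 10 recover 54% of each complex's
near-native poses, 1.3× more than the random-ranking expectation (EF ≈ 1).

The same pipeline is scriptable from the shell:

```
shellscore make-fixtures --out fixtures --seed 5 --n-complexes 4
shellscore train --fixtures fixtures --out model.npz
shellscore score --model model.npz --protein fixtures/cplx000/protein.pdb \
                 --poses fixtures/cplx000/poses.sdf --out scores.tsv
shellscore evaluate --scores rankings.tsv --out metrics.json
```

## Scope

Pose *generation* (docking), PDBQT conversion, protonation and dataset
download/curation at scale are out of scope; the curation predicates
(resolution ≤ 3 Å, 5–60 ligand atoms, no covalent ligand–protein contact,
rotatable-bond cap) are implemented in `shellscore.structures`.  See
`docs/methods.md` for the full model description, parameter defaults and
limitations.
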