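# Methods

## Problem and model

`torsionlink` predicts circRNA–drug (sensitivity) associations — CDAs — by link
prediction on a bipartite graph G = (V_C, V_D, E) with N circRNAs, M drugs and
biadjacency A ∈ {0,1}^{N×M}. The distinguishing ingredient is a geometric edge
weight: for every association (a, b) a local subgraph is extracted, its clique
complex built, and the **log analytic torsion** of that complex used to weight
message propagation in a graph neural network.

### Analytic torsion of a local complex

For a subgraph around an edge we form the clique complex up to dimension Q:
0-simplices are nodes, 1-simplices edges, and (for Q = 2) 2-simplices the
3-cliques. Simplices are stored as strictly ascending tuples of global node
indices; the boundary matrix B_g carries (−1)^j at the face obtained by deleting
vertex j, which makes B_{g−1} B_g = 0 an exact integer identity. The Hodge
Laplacians are

    Z_0 = B_1 B_1ᵀ,   Z_g = B_gᵀ B_g + B_{g+1} B_{g+1}ᵀ,   Z_m = B_mᵀ B_m,

and with |Z_g| the pseudo-determinant (product of non-zero eigenvalues, empty
product = 1), the torsion in log form is

    Q = 1:  log T(S) = ½ log |Z_1|
    Q = 2:  log T(S) = ½ log |Z_1| + log |Z_2|.

The general alternating-sign torsion sum and these closed forms differ in the
sign of the exponent; we implement the closed forms with positive exponents,
because the propagation rule consumes log T and positive log-weights keep
message passing well behaved. Torsion is a spectral invariant, so it does not
depend on the orientation convention or node labelling (tested by random
relabelling).

Because a purely bipartite graph has no odd cycles, Q = 2 complexes contain no
triangles and reduce exactly to Q = 1; the default is Q = 1, P = 1. For
triangle-free complexes the non-zero spectrum of Z_1 = B_1ᵀB_1 equals that of
Z_0 = B_1B_1ᵀ — the ordinary graph Laplacian over the (usually far fewer)
subgraph nodes — and `torsion_weights` evaluates log |Z_1| through that smaller
matrix. Tests assert the equality against the full boundary-matrix route, and
against the matrix-tree theorem (|Z_1| = n · #spanning-trees for connected
subgraphs).

### Subgraphs, degrees, propagation

The edge-centred subgraph of (u, v) at order P contains every node within P BFS
hops of u or v and all induced circRNA–drug edges; the node-centred subgraph
(used for the self-loop weight) is the ≤P-hop ball around one node. Degrees use
d = (bipartite degree) + 1 so the self term of the propagation rule is defined
for isolated nodes. The GCN-style layer is

    h_a = σ( Σ_{b ∈ N(a) ∪ {a}}  w(a,b) / √(d_a d_b) · W h_b ),

with w(a,b) the edge log-torsion, w(a,a) the node log-torsion, and σ the
logistic function (kept as the layer activation for fidelity to the published
propagation rule, although ReLU is the more common choice). With torsion
disabled, w ≡ 1 and the layer is exactly symmetric-normalised self-loop
propagation D̃^{-1/2}(A+I)D̃^{-1/2} — the ablation arm and a reduction oracle in
the tests. The GAT variant adds log-torsion to each attention logit before the
neighbourhood softmax; the GIN variant uses it as a multiplicative neighbour
weight inside MLP((1+ε)h_a + Σ_b w(a,b) h_b). Both collapse to their standard
forms when torsion is off. An edgeless (isolated-node) complex gets log-torsion
0, i.e. neutral weight.

### Decoder, loss, training

A pair (u, v) is scored by an MLP over the concatenation of (h_u + h_v,
h_u ⊙ h_v, h_u ‖ h_v) — input width 4d, hidden widths d and d/2, ReLU hidden
activations, sigmoid output — trained with mean binary cross-entropy.
Prediction always uses (circRNA, drug) order, since the concatenation block is
order-sensitive.

The model is implemented in pure numpy on a small reverse-mode automatic
differentiation module (`torsionlink.autodiff`), gradient-checked against
central finite differences. Training is full-batch Adam (lr 1e-3, up to 500
epochs) with early stopping on a 10 % validation split of the training pairs
(patience 50, best-validation weights restored); with too few pairs for a
split, the full epoch budget is used. Parameters are Glorot-uniform under the
run seed; one top-level seed derives per-fold seeds as seed + fold_id, and all
randomness flows through `numpy.random.default_rng`, so single-threaded runs
are bit-reproducible.

## Defaults and the parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| encoder | gcn | best balanced operating point among gcn/gat/gin |
| layers | 2 | shallow stack avoids oversmoothing |
| hidden_dim / out_dim | 128 / 128 | embedding widths |
| feature_init | position | rows of the symmetric training adjacency (best performer) |
| P (subgraph_order) | 1 | direct-neighbour subgraphs |
| Q (complex_dim) | 1 | bipartite graphs have no triangles, so Q=2 is inert |
| torsion_enabled | true | false = ablation arm, all weights 1 |
| folds | 5 | cross-validation |
| lr / epochs | 1e-3 / 500 | Adam, early stopping patience 50 |
| kmer_k | 4 | 256-dim circular k-mer space |
| zero-eigenvalue cutoff | 1e-8 · max(1, λ_max) | scale-aware zero-mode threshold |

Feature schemes: `position` (adjacency rows), `onehot`, `uniform`/`normal`
random, and `sim` — block-diagonal similarity features where circRNA similarity
fuses the Gaussian interaction profile (GIP) kernel of training-adjacency rows
with cosine similarity of circular k-mer frequencies, and drug similarity fuses
the GIP kernel of columns with Tanimoto similarity of Morgan fingerprints
(radius 2, 2048 bits). The GIP bandwidth is γ = 1 / mean‖x_i‖² (γ = 1 for
all-zero profiles). The sequence-similarity metric and the fusion rule
(elementwise mean) are deliberate package conventions — both are simple,
standard choices and are isolated behind `features` so they can be swapped.
circRNAs are covalently closed, so k-mer counting wraps around the sequence
end and every frequency row sums to 1 (ambiguous `N` positions carry no count).

## Cross-validation protocol

Negatives are drawn once per run, uniformly without replacement from
zero-entry pairs, matched in count to the positives. Positives and negatives
are shuffled and partitioned into k folds independently. Each fold's graph —
and therefore its torsion cache and its adjacency-derived features (position,
GIP) — is rebuilt from the training positives only, while the node universe
comes from the full table so held-out nodes keep embeddings. No held-out edge
influences training; a test asserts this. Thresholded metrics (accuracy,
recall, precision, F1) use 0.5; AUC is the tie-corrected rank statistic and
AUPR stepwise average precision (scikit-learn, cross-checked against
exhaustive-definition oracles).

## Synthetic data

The generator emulates the shape of the public circRNA–drug screen this method
targets: 271 circRNAs × 218 drugs with 4,314 curated positive pairs. Structure
is planted as a bipartite block model — nodes assigned to blocks round-robin,
pair positive with probability p_in within a block and p_out across (defaults
4 blocks, p_in 0.3, p_out 0.02); `n_positives` subsamples to an exact count.
Sequences are i.i.d. uniform nucleotides, optionally with block-shared motifs
so sequence similarity correlates with the planted structure.

What the generator does **not** emulate: real circRNA sequence composition,
real drug chemistry, degree heterogeneity beyond the block pattern, and any
correlation between chemistry and interaction profile. Passing tests therefore
demonstrate that the machinery is correct and that the pipeline recovers
recoverable planted structure — not that the headline numbers on the real
screen are reproduced, which requires the external dataset.

A relevant ceiling: under the block model, conditional on block membership all
unobserved pairs are exchangeable, so no predictor can beat the block-posterior
scorer. At the 100×80 / 4-block / p_in 0.3 / p_out 0.02 operating point used in
the recovery tests, that ceiling is mean held-out AUC ≈ 0.82 (positives are
~83 % within-block while balanced negatives are ~19 % within-block); the
trained model reaches ≈ 0.80, i.e. close to the information-theoretic limit of
the simulation, and the chance control (labels permuted) sits at 0.5.

## Numerical choices and degenerate inputs

- Initial feature matrices are column-wise z-scored inside the estimator before
  encoding. Sparse 0/1 rows (position, one-hot) otherwise shrink to near-zero
  pre-activations after degree-normalised propagation and park the sigmoid
  layers on a flat plateau; standardisation keeps the encoder responsive for
  every initialisation scheme and both torsion arms. Constant columns centre
  at zero.
- Eigenvalues are computed with `eigvalsh` on the symmetrised matrix; a value
  below −1e-8·max(1, λ_max) raises rather than being silently clipped.
- log-pseudo-determinants are accumulated as sums of logs to avoid overflow on
  large complexes.
- Ties in rankings break lexicographically by (circ_id, drug_id); score ties in
  AUC get half-credit via the rank statistic.
- Duplicate pairs, labels outside {0,1}, unknown ids, empty positive sets,
  same-side subgraph centres, unparsable SMILES and too-short sequences all
  raise with the offending item named; an empty association file reads as an
  empty table with a warning.
- Problem sizes in the test suite are chosen so the full suite and the
  acceptance script each run in minutes on one CPU: recovery experiments use a
  100×80 block model over 3 seeds, and full-scale checks one 271×218 instance.

## Known limitations

- Torsion weights are recomputed per training fold (no cross-fold reuse); at
  the target scale this is ~1–2 s, but very dense graphs would make
  edge-centred subgraphs large and the Laplacian eigendecompositions dominant.
- The sigmoid layer activation saturates for large hidden sums; Glorot
  initialisation and 2-layer defaults keep this benign at the supported scale.
- Only circRNA–drug edges propagate messages; similarity information enters
  through node features, never as extra edges, so Q = 2 torsion is inert unless
  a user supplies a non-bipartite graph.
- The GAT/GIN torsion injections are package conventions (additive logit bias,
  multiplicative neighbour weight); the published rule specifies torsion
  weighting only for the GCN form.
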