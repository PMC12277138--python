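# torsionlink

Torsion-weighted graph neural networks for circRNA–drug association (CDA)
prediction.

Circular RNAs modulate drug response and resistance, and screening every
circRNA–drug pair experimentally is infeasible, so computational ranking of
candidate associations matters for biomarker and therapeutic-target discovery.
`torsionlink` frames the task as link prediction on the bipartite circRNA–drug
graph G = (V_C, V_D, E) with biadjacency A ∈ {0,1}^{N×M}, and enriches message
passing with a geometric signal: for every association (a, b) it extracts the
local P-hop subgraph, builds its clique complex, and computes the **log
analytic torsion**

    log T(S) = ½ log |Z₁|            (Q = 1)
    log T(S) = ½ log |Z₁| + log |Z₂| (Q = 2)

where Z_g = B_gᵀB_g + B_{g+1}B_{g+1}ᵀ is the g-th Hodge Laplacian of the
complex, B_g the signed boundary matrix, and |·| the pseudo-determinant
(product of non-zero eigenvalues). The log-torsion becomes the edge weight of
graph-convolutional propagation,

    h_a = σ( Σ_{b ∈ N(a) ∪ {a}}  log T(S_{a,b}) / √(d_a d_b) · W h_b ),

and pairs are scored by an MLP over (h_u + h_v, h_u ⊙ h_v, h_u ‖ h_v) trained
with binary cross-entropy. GAT and GIN encoder variants, five node-feature
initialisations (position, one-hot, uniform, normal, similarity-based with GIP
kernel / k-mer / Morgan-fingerprint components), and a torsion on/off ablation
switch are all exposed. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from torsionlink import (
    TorsionGNNClassifier, BlockModelSpec, generate_block_model,
    build_graph, sample_negatives, torsion_weights,
)

# synthetic screen: 30 circRNAs x 24 drugs with 2 planted interaction blocks
table = generate_block_model(
    BlockModelSpec(n_circ=30, n_drug=24, n_blocks=2, p_in=0.6, p_out=0.05, seed=7)
)
graph = build_graph(table)
pos = table.positives()
neg = sample_negatives(graph, len(pos), seed=7)
X = pos + neg
y = np.array([1] * len(pos) + [0] * len(neg))

est = TorsionGNNClassifier(hidden_dim=32, out_dim=16, random_state=7).fit(X, y)
scores = est.predict_proba(X)[:, 1]
print(f"mean score | positives: {scores[y == 1].mean():.3f}")
print(f"mean score | negatives: {scores[y == 0].mean():.3f}")

cache = torsion_weights(graph, P=1, Q=1)
u, v = graph.global_index(pos[0][0]), graph.global_index(pos[0][1])
print(f"log-torsion of edge {pos[0]}: {cache.edge(u, v):.3f}")
```

prints

```
mean score | positives: 0.710
mean score | negatives: 0.301
log-torsion of edge ('circ0000', 'drug0004'): 12.252
```

Positives score well above negatives (the planted blocks are recovered). The
first positive edge's local subgraph — 18 nodes around circ0000–drug0004 —
carries log-torsion ≈ 12.3, i.e. a pseudo-determinant |Z₁| = e^{24.5} = n ·
(#spanning trees), reflecting the dense within-block neighbourhood of that
association. A single isolated edge would give the minimum, ½ ln 2 ≈ 0.347.

The same workflow is available from the shell:

```bash
torsionlink simulate --n-circ 271 --n-drug 218 --n-pos 4314 --seed 1 --out assoc.tsv
torsionlink torsion  --associations assoc.tsv --out torsion.tsv
torsionlink cv       --associations assoc.tsv --folds 5 --seed 1 --out metrics.json
torsionlink train    --associations assoc.tsv --seed 1 --out model
torsionlink predict  --checkpoint model --query circ0000 --top-k 20 --out ranked.tsv
```

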