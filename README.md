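# hetprop

Disease-gene and disease-disease prioritization by **random walk with
restart on a heterogeneous gene–disease network** (RWRH).

Given a disease of interest, which other genes — and which other
diseases — are most likely associated with it?  `hetprop` answers this by
joining three networks into one:

* a weighted, undirected **gene/protein network** (adjacency `W_G`),
* a **phenotypic disease-similarity network** (`W_D`), sparsified so each
  disease keeps only its `k_top` strongest similarities,
* the bipartite network of **known disease–gene associations** (`W_GD`)
  that connects the two layers.

A random walker starts from the disease of interest `d₁` and its known
associated genes, and at every step either moves to a neighbour or
restarts at the seeds with back-probability γ.  When a node has bipartite
links, the walker jumps between the gene and disease layers with
probability λ; the seed mass is split between the layers by η.  The
steady-state visiting probability of each node measures its association
with `d₁`, and candidate genes and diseases are ranked by it.  Because
the disease layer is ranked too, the method also predicts disease–disease
associations, and it works for diseases without any known genes (the seed
is then the disease alone).

## Model

With row-stochastic transition matrix

```
W' = [[W'_G,  W'_GD],
      [W'_DG, W'_D ]]
```

where for a gene `i` with bipartite links `(W'_GD)_ij = λ·(W_GD)_ij / Σ_j (W_GD)_ij`
and `(W'_G)_ij = (1−λ)·(W_G)_ij / Σ_j (W_G)_ij` (plain normalization when
gene `i` has no bipartite links; symmetric definitions for disease rows),
the walk iterates

```
P^{t+1} = (1−γ) · W'ᵀ P^t + γ P⁰
```

to its unique fixed point `P^∞`.  The initial vector `P⁰` gives each seed
gene `(1−η)/|S|` and each seed disease `η/|D|`.  The map is a contraction
with factor `1−γ` in L1, so the fixed point exists, is unique, and every
iterate remains a probability distribution.  Defaults: γ = 0.5, λ = 0.6,
η = 0.7.

## Worked example

A five-node network: genes `g1–g2–g3` in a path, diseases `d1–d2`, and one
known association `d1–g1`.  Seeding with `S = {g1}` and `d1`:

```python
from hetprop import (GeneNetwork, DiseaseNetwork, BipartiteAssociations,
                     assemble_heterogeneous, build_transition, SeedSet,
                     build_seed_vector, rwrh_steady_state, rank_candidates)
from hetprop.hetnet_io import _symmetric_csr

genes, diseases = ("g1", "g2", "g3"), ("d1", "d2")
gene_net = GeneNetwork(genes, _symmetric_csr(genes, {("g1","g2"): 1.0, ("g2","g3"): 1.0}))
disease_net = DiseaseNetwork(diseases, _symmetric_csr(diseases, {("d1","d2"): 1.0}))
net = assemble_heterogeneous(gene_net, disease_net,
                             BipartiteAssociations({("d1","g1"): 1.0}))

t = build_transition(net, lambda_=0.5)
seeds = SeedSet(frozenset({"g1"}), frozenset({"d1"}))
p0 = build_seed_vector(net, seeds, eta=0.7)
p = rwrh_steady_state(t, p0, gamma=0.5)
r = rank_candidates(net, p, {"g2", "g3"}, {"d2"}, seeds=seeds)
```

This prints (via the loop in the example script):

```
gene    1  g2  0.083333
gene    2  g3  0.020833
disease 1  d2  0.120833
iterations: 33
```

`g2`, adjacent to the seed gene, collects four times the probability of
`g3`, which is two steps away; the candidate disease `d2` scores 0.120833
(= 29/240 exactly — this tiny system can be solved by hand).  The seed
nodes themselves hold the rest of the mass (`g1` ≈ 0.2917, `d1` ≈ 0.4833).

The same pipeline runs from the shell on generated data:

```sh
hetprop simulate --out-dir demo            # synthetic network with planted modules
hetprop rank     --gene-network demo/gene_network.tsv \
                 --disease-similarity demo/disease_similarity.tsv \
                 --bipartite demo/bipartite.tsv \
                 --disease d000 --out-dir demo/rank
hetprop evaluate --gene-network demo/gene_network.tsv \
                 --disease-similarity demo/disease_similarity.tsv \
                 --bipartite demo/bipartite.tsv --out-dir demo/cv
```

`rank` writes `gene_ranking.tsv`, `disease_ranking.tsv` and a manifest
with parameters and input checksums; `evaluate` writes the
leave-one-out cross-validation report with its AUC summary line.

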