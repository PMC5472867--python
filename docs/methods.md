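# Methods

## The model

`hetprop` scores every node of a heterogeneous gene–disease network by
the steady state of a random walk with restart.  The network
`G(V, E)` has `N = n_G + n_D` nodes: genes indexed `[0, n_G)` and
diseases `[n_G, N)`.  Three adjacency blocks define it — the gene/protein
network `W_G`, the disease-similarity network `W_D`, and the bipartite
known-association matrix `W_GD` (gene rows, disease columns).

The row-stochastic transition matrix is assembled from four piecewise
blocks.  For gene `i`:

* if `Σ_j (W_GD)_ij ≠ 0` (the gene has bipartite links), the walker jumps
  to the disease layer with probability λ: the bipartite row is
  `λ·(W_GD)_ij / Σ_j (W_GD)_ij` and the gene-gene row is
  `(1−λ)·(W_G)_ij / Σ_j (W_G)_ij`;
* otherwise the gene-gene row is plainly normalized and independent of λ.

Disease rows are defined symmetrically on `W_D` and the *columns* of
`W_GD`.  The walk then iterates

    P^{t+1} = (1−γ)·W'ᵀ·P^t + γ·P⁰

The transpose matters: `W'` is stored row-stochastic with
`W'[i,j] = P(i→j)`, so its transpose acts column-stochastically on
probability vectors and every iterate keeps total mass 1.  The update
without the transpose would not conserve probability.

The restart vector `P⁰` places `(1−η)/|S|` on each seed gene and `η/|D|`
on each seed disease (`η` itself when a single disease is of interest).
The seed-gene share is divided over the seed *genes* only; this is the
only split for which `P⁰` sums to 1.  When a disease has no known genes,
`S = ∅` and the disease layer takes all the initial mass — the method
still ranks candidates for diseases without known molecular basis.

### Degenerate rows

The piecewise formulas leave a node whose only links are bipartite with
outgoing mass λ < 1.  Such rows are rescued by renormalizing the
bipartite block to sum 1: the walker has nowhere else to go, so it must
jump.  This mirrors the structure of the no-bipartite branch (all mass to
the only available block) and is the package's own completion of the
formulas; assembly has already rejected nodes with no links at all, so
after the rescue every row is stochastic to 1e−12 by construction (the
builder verifies and refuses otherwise).

## Parameters

| parameter | meaning | default | domain |
|---|---|---|---|
| γ (`gamma`) | restart (back) probability per step | 0.5 | (0, 1) |
| λ (`lambda_`) | layer-jump probability where bipartite links exist | 0.6 | (0, 1) |
| η (`eta`) | share of initial mass on the disease layer | 0.7 | (0, 1) |
| `k_top` | similarities kept per disease when sparsifying `W_D` | 5 | ≥ 1 |
| `tol` | L1 convergence threshold of the power iteration | 1e−10 | > 0 |
| `max_iter` | iteration cap (error, not silent stop, when hit) | 1000 | ≥ 1 |

γ, λ and η defaults are the settings reported to perform best for this
family of methods; `k_top = 5` matches the conventional sparsification of
dense phenotypic-similarity matrices.  `tol` and `max_iter` are this
package's choices: the iteration contracts with factor 1−γ in L1, so with
γ = 0.5 the default tolerance is reached in ≈ 35 iterations and the cap
is far from binding.  Non-convergence raises an error carrying the last
iterate rather than returning it silently.

## Input handling

Readers accept TSV edge lists (genes, similarities, associations), SIF
(genes, including the one-to-many form), and a dense similarity matrix
with an id header row and column.  Rules applied on read: self-loops are
dropped; duplicate edges keep the maximum weight (order-independent);
missing weights default to 1; matrix asymmetries are averaged before
filtering (phenotypic similarity is symmetric by construction); blank
lines and `#` comments are skipped; malformed lines report their line
number.

The top-k similarity filter selects, for each disease, its `k_top`
largest-weight neighbours (ties broken lexicographically by neighbour id
for reproducibility) and keeps the union of selections: an edge survives
if either endpoint chose it, with its original continuous weight.  The
filter is idempotent — re-filtering a filtered network changes nothing —
which makes write/read round trips safe.

Assembly drops bipartite pairs whose ids do not resolve (logging the
count), rejects nodes with total degree 0 across all three blocks, and
rejects ids used as both a gene and a disease.  Full connectivity is
*not* required: the restart term makes the walk well defined on any
degree-positive graph, and unreachable components simply keep near-zero
scores.

## Ranking and evaluation

Candidates (never overlapping the seeds) are ranked by steady-state
probability, descending, ties broken lexicographically, dense 1-based
ranks.  Candidate genes can be: all non-training genes, direct network
neighbours of the training genes, those neighbours restricted to
chromosomes carrying a training gene, all genes on an exact
`chromosome:band` label, or a user list.  Candidate diseases are always
the non-training diseases.

Leave-one-out cross-validation removes each known association `(d, g)` of
every disease with ≥ 2 known genes, reseeds with `d` and its remaining
genes, ranks **all** genes outside the remaining seed set, and records
the rank of `g` using average ranks over score ties (order-independent).
The summary statistic

    AUC = mean over trials of (n_candidates − rank)/(n_candidates − 1)

equals, trial by trial, the area under the ROC curve for one positive
against `n_candidates − 1` negatives (Mann–Whitney identity, ties counted
half); the test suite verifies this against explicit ROC integration.
Trials are pooled with equal weight rather than averaged per disease.

## Synthetic data

The generator emulates the structural premise the method exploits: that
phenotypically similar diseases share causal genes, and that causal genes
cluster in network modules.

* Gene network: planted-partition graph, `n_genes = 200` in
  `n_modules = 10` equal blocks, within-module edge probability
  `p_in = 0.3`, between-module `p_out = 0.01`, unit weights.  Genes the
  edge draw leaves isolated are re-wired with one uniform random edge so
  counts stay exact.
* Diseases: `n_diseases = 30`, assigned to modules round-robin; each
  draws `genes_per_disease = 8` causal genes from its module.
* Disease similarity: Jaccard index of causal gene sets plus uniform
  noise in [0, 0.05] (the noise breaks ties in the top-k filter), then
  the `k_top = 5` filter.
* Bipartite: a per-disease random half (`known_fraction = 0.5`, i.e. 4 of
  8) of the causal genes is revealed; the rest is held-out ground truth.

All draws come from one `numpy` Generator seeded by `rng_seed`; equal
specs give bit-identical networks.  A degree-preserving null is obtained
by permuting the disease labels of the bipartite pairs.

What the synthetic networks do **not** emulate: the heavy-tailed degree
distributions of real protein-interaction networks, the scale
(10⁴ genes, 5·10³ diseases), weighted interaction confidences, and the
text-mining noise structure of real phenotype similarities.  Passing
recovery tests therefore demonstrates that the implementation ranks
planted signal correctly under the model's own assumptions, not that any
particular AUC will be attained on real data.

Under these default conditions the leave-one-out AUC is ≈ 0.94–0.96
(recomputed, not pinned, by `scripts/acceptance.py`), against ≈ 0.5 for
the shuffled null.  The problem sizes used throughout the tests (≤ 230
nodes; 120 cross-validation trials) keep the whole suite in seconds while
exercising every code path; the method itself is a sparse matrix-vector
iteration and scales to the sizes real gene networks have.

## Numerical choices

* Sparse CSR throughout; the transition builder scales rows with a
  diagonal product and verifies stochasticity to 1e−12.
* Row sums are computed by matrix–vector product with a ones vector
  (sequential accumulation over stored entries), which makes the builder
  bit-for-bit reproducible against elementwise evaluation of the
  formulas.
* Power iteration rather than a direct solve: the system is sparse, the
  contraction is fast, and iteration matches the method's definition; the
  dense linear solve `γ(I − (1−γ)W'ᵀ)⁻¹P⁰` serves as the independent
  oracle in tests, never as the implementation.
* Deterministic tie-breaks everywhere (lexicographic ids in rankings and
  the top-k filter; average ranks inside the AUC), so identical inputs
  give byte-identical outputs.

## Known limitations

* No id mapping between gene naming systems; identifiers are opaque
  strings and must already match across files.
* Evidence counts for pathways/complexes use dual membership (a term
  containing ≥ 1 gene of each disease); disease-level pathway annotations
  are not consulted.
* No alternative propagation kernels (symmetric Laplacian, PRINCE-style);
  the four-block RWRH normalization is the only one offered.
* The chromosome-band candidate strategy matches band labels exactly; no
  genomic-interval arithmetic.
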