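"""Synthetic heterogeneous networks with planted disease modules.

The generator emulates the structure the method exploits in real data:
genes form modules (a planted-partition graph, dense within a module and
sparse between), each disease draws its causal genes from one module,
phenotypic similarity between diseases is the Jaccard index of their
causal gene sets (plus a little uniform noise so the top-k filter has no
degenerate ties), and only a fraction of the causal genes is revealed as
the known bipartite associations.  The held-back associations are the
ground truth that cross-validation and recovery tests measure against.
All randomness is driven by a single seed; equal specs give bit-identical
networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .hetnet_io import (
    BipartiteAssociations,
    DiseaseNetwork,
    GeneNetwork,
    HetNet,
    _symmetric_csr,
    _topk_sparsify,
    assemble_heterogeneous,
    write_bipartite,
    write_disease_similarity,
    write_gene_network,
)

__all__ = ["SyntheticSpec", "SyntheticHetNet", "generate", "shuffle_bipartite", "write_synthetic"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; the defaults define the standard test-bed
    conditions used throughout the package's own evaluation."""

    n_genes: int = 200
    n_diseases: int = 30
    n_modules: int = 10
    p_in: float = 0.3
    p_out: float = 0.01
    genes_per_disease: int = 8
    known_fraction: float = 0.5
    k_top: int = 5
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_modules > self.n_genes:
            raise ValidationError("n_modules cannot exceed n_genes")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValidationError("need 0 <= p_out <= p_in <= 1")
        if not 0.0 < self.known_fraction < 1.0:
            raise ValidationError("known_fraction must be in (0, 1)")
        if self.genes_per_disease > self.n_genes // self.n_modules:
            raise ValidationError(
                f"genes_per_disease={self.genes_per_disease} exceeds the module size "
                f"{self.n_genes // self.n_modules}"
            )
        if self.k_top < 1:
            raise ValidationError("k_top must be >= 1")


@dataclass(frozen=True)
class SyntheticHetNet:
    """Generated network plus the full and revealed disease-gene truth."""

    net: HetNet
    truth: dict[str, frozenset[str]]     # disease -> all causal genes
    revealed: dict[str, frozenset[str]]  # disease -> installed subset
    spec: SyntheticSpec

    def held_out(self, disease_id: str) -> frozenset[str]:
        return self.truth[disease_id] - self.revealed[disease_id]


def _gene_id(i: int) -> str:
    return f"g{i:04d}"


def _disease_id(j: int) -> str:
    return f"d{j:03d}"


def generate(spec: SyntheticSpec) -> SyntheticHetNet:
    """Draw one synthetic heterogeneous network from the spec."""
    rng = np.random.default_rng(spec.rng_seed)
    gene_ids = tuple(_gene_id(i) for i in range(spec.n_genes))
    disease_ids = tuple(_disease_id(j) for j in range(spec.n_diseases))

    # planted-partition gene graph: module labels are contiguous blocks
    labels = np.arange(spec.n_genes) * spec.n_modules // spec.n_genes
    iu, ju = np.triu_indices(spec.n_genes, k=1)
    probs = np.where(labels[iu] == labels[ju], spec.p_in, spec.p_out)
    mask = rng.random(probs.size) < probs
    weights = {
        (gene_ids[i], gene_ids[j]): 1.0 for i, j in zip(iu[mask], ju[mask])
    }

    # each disease draws its causal genes from one module (round-robin)
    truth: dict[str, frozenset[str]] = {}
    for j, d in enumerate(disease_ids):
        module = j % spec.n_modules
        members = np.flatnonzero(labels == module)
        chosen = rng.choice(members, size=spec.genes_per_disease, replace=False)
        truth[d] = frozenset(gene_ids[i] for i in sorted(chosen))

    # phenotypic similarity: Jaccard of causal sets plus uniform noise
    sim: dict[tuple[str, str], float] = {}
    for a_idx in range(spec.n_diseases):
        for b_idx in range(a_idx + 1, spec.n_diseases):
            a, b = disease_ids[a_idx], disease_ids[b_idx]
            inter = len(truth[a] & truth[b])
            union = len(truth[a] | truth[b])
            jac = inter / union if union else 0.0
            sim[(a, b)] = jac + rng.uniform(0.0, 0.05)
    disease_net = _topk_sparsify(disease_ids, sim, spec.k_top)

    # reveal a per-disease subset as the known bipartite associations
    n_reveal = math.ceil(spec.known_fraction * spec.genes_per_disease)
    revealed: dict[str, frozenset[str]] = {}
    pairs: dict[tuple[str, str], float] = {}
    for d in disease_ids:
        causal = sorted(truth[d])
        chosen = rng.choice(len(causal), size=n_reveal, replace=False)
        revealed[d] = frozenset(causal[i] for i in sorted(chosen))
        for g in sorted(revealed[d]):
            pairs[(d, g)] = 1.0

    # re-wire genes the edge draw left isolated so assembly cannot reject
    # them (and so held-out genes stay reachable through the gene layer)
    degree: dict[str, int] = {g: 0 for g in gene_ids}
    for a, b in weights:
        degree[a] += 1
        degree[b] += 1
    for i, g in enumerate(gene_ids):
        if degree[g] == 0:
            partner = int(rng.integers(spec.n_genes - 1))
            if partner >= i:
                partner += 1
            key = (g, gene_ids[partner]) if g < gene_ids[partner] else (gene_ids[partner], g)
            weights[key] = 1.0
            degree[g] += 1
            degree[gene_ids[partner]] += 1

    gene_net = GeneNetwork(gene_ids, _symmetric_csr(gene_ids, weights))
    net = assemble_heterogeneous(gene_net, disease_net, BipartiteAssociations(pairs))
    return SyntheticHetNet(net, truth, revealed, spec)


def shuffle_bipartite(syn: SyntheticHetNet, rng_seed: int) -> SyntheticHetNet:
    """Degree-preserving null model: permute the disease labels of the
    bipartite pairs (each gene keeps its association count); the truth map
    is untouched."""
    pairs = sorted(syn.net.bipartite.pairs.items())
    if not pairs:
        raise ValidationError("cannot shuffle an empty bipartite network")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(pairs))
    shuffled: dict[tuple[str, str], float] = {}
    for k, ((d, g), w) in enumerate(pairs):
        new_d = pairs[perm[k]][0][0]
        key = (new_d, g)
        shuffled[key] = max(w, shuffled.get(key, 0.0))
    net = assemble_heterogeneous(
        syn.net.gene_net, syn.net.disease_net, BipartiteAssociations(shuffled)
    )
    return SyntheticHetNet(net, syn.truth, syn.revealed, syn.spec)


def write_synthetic(syn: SyntheticHetNet, out_dir: str | Path) -> dict[str, Path]:
    """Write the three network files plus the truth table in the package's
    text formats, so the CLI pipeline runs end-to-end on generated data."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_network": out / "gene_network.tsv",
        "disease_similarity": out / "disease_similarity.tsv",
        "bipartite": out / "bipartite.tsv",
        "truth": out / "truth.tsv",
    }
    write_gene_network(syn.net.gene_net, paths["gene_network"])
    write_disease_similarity(syn.net.disease_net, paths["disease_similarity"])
    write_bipartite(syn.net.bipartite, paths["bipartite"])
    with open(paths["truth"], "w") as fh:
        fh.write("# disease_id\tgene_id\trevealed\n")
        for d in syn.net.disease_net.disease_ids:
            for g in sorted(syn.truth[d]):
                fh.write(f"{d}\t{g}\t{int(g in syn.revealed[d])}\n")
    return paths
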