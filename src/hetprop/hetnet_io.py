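"""Read, filter and assemble the gene-disease heterogeneous network.

The heterogeneous network has three parts: a weighted undirected
gene/protein network (adjacency ``W_G``), a phenotypic disease-similarity
network (``W_D``, sparsified so each disease keeps only its ``k_top``
strongest similarities), and the bipartite disease-gene association
network (``W_GD``) that ties the two layers together.  This module owns
the text formats for all three and the assembly step that aligns them
into one indexed node universe (genes first, then diseases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy import sparse

from .errors import AssemblyError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "DiseaseNetwork",
    "BipartiteAssociations",
    "HetNet",
    "read_gene_network",
    "read_disease_similarity",
    "read_bipartite",
    "assemble_heterogeneous",
    "write_gene_network",
    "write_disease_similarity",
    "write_bipartite",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def _symmetric_csr(ids: tuple[str, ...], weights: dict[tuple[str, str], float]) -> sparse.csr_array:
    """Build a symmetric CSR adjacency from an a<b keyed weight dict."""
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    if not weights:
        return sparse.csr_array((n, n))
    rows, cols, vals = [], [], []
    for (a, b), w in weights.items():
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    m = sparse.coo_array((vals, (rows, cols)), shape=(n, n)).tocsr()
    m.sum_duplicates()
    return m


@dataclass(frozen=True)
class GeneNetwork:
    """Weighted undirected gene/protein network.

    ``w`` is symmetric with a zero diagonal; absent pairs are 0 and all
    stored edge weights are positive.
    """

    gene_ids: tuple[str, ...]
    w: sparse.csr_array

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield each undirected edge once as (a, b, weight) with a < b."""
        coo = sparse.coo_array(self.w)
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if i < j:
                yield self.gene_ids[i], self.gene_ids[j], float(v)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "GeneNetwork":
        """Build from (a, b, weight) triples; duplicates keep the max weight,
        self-loops are dropped, node order follows first appearance."""
        ids: list[str] = []
        seen: set[str] = set()
        weights: dict[tuple[str, str], float] = {}
        for a, b, w in edges:
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    ids.append(g)
            if a == b:
                continue
            if w < 0:
                raise ValidationError(f"negative edge weight {w} on ({a}, {b})")
            key = (a, b) if a < b else (b, a)
            weights[key] = max(w, weights.get(key, 0.0))
        ids_t = tuple(ids)
        return cls(ids_t, _symmetric_csr(ids_t, weights))


@dataclass(frozen=True)
class DiseaseNetwork:
    """Phenotypic disease-similarity network after top-k sparsification."""

    disease_ids: tuple[str, ...]
    w: sparse.csr_array

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        coo = sparse.coo_array(self.w)
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if i < j:
                yield self.disease_ids[i], self.disease_ids[j], float(v)


@dataclass(frozen=True)
class BipartiteAssociations:
    """Known disease-gene associations, keyed (disease_id, gene_id)."""

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def without(self, disease_id: str, gene_id: str) -> "BipartiteAssociations":
        """A copy with one association removed (used by cross-validation)."""
        out = dict(self.pairs)
        out.pop((disease_id, gene_id), None)
        return BipartiteAssociations(out)

    def genes_of(self, disease_id: str) -> set[str]:
        return {g for (d, g) in self.pairs if d == disease_id}


@dataclass(frozen=True)
class HetNet:
    """Aligned heterogeneous network: genes occupy global indices
    ``[0, n_genes)``, diseases ``[n_genes, n_genes + n_diseases)``."""

    gene_net: GeneNetwork
    disease_net: DiseaseNetwork
    bipartite: BipartiteAssociations
    w_gd: sparse.csr_array  # gene rows x disease columns
    index_map: dict[str, int]

    @property
    def n_genes(self) -> int:
        return self.gene_net.n_genes

    @property
    def n_diseases(self) -> int:
        return self.disease_net.n_diseases

    @property
    def n_nodes(self) -> int:
        return self.n_genes + self.n_diseases

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.gene_net.gene_ids + self.disease_net.disease_ids

    def is_gene(self, node_id: str) -> bool:
        return self.index_map[node_id] < self.n_genes

    def known_genes(self, disease_id: str) -> set[str]:
        return self.bipartite.genes_of(disease_id)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (lineno, whitespace-split fields), skipping blanks and '#' lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def _parse_weight(token: str, path: str | Path, lineno: int) -> float:
    try:
        w = float(token)
    except ValueError:
        raise ParseError(path, lineno, f"weight {token!r} is not a number") from None
    if not np.isfinite(w):
        raise ParseError(path, lineno, f"weight {token!r} is not finite")
    return w


def read_gene_network(path: str | Path, dialect: str = "tsv") -> GeneNetwork:
    """Read a weighted undirected gene network from a TSV edge list or SIF.

    TSV lines are ``gene_a gene_b [weight]`` (weight defaults to 1.0); SIF
    lines are ``a relation b [c ...]`` with every (a, x) pair an edge of
    weight 1.0.  Self-loops are dropped; duplicate edges keep the maximum
    weight; negative weights are rejected.
    """
    if dialect not in ("tsv", "sif"):
        raise ValidationError(f"unknown gene-network dialect {dialect!r}")
    edges: list[tuple[str, str, float]] = []
    for lineno, fields in _data_lines(path):
        if dialect == "tsv":
            if len(fields) not in (2, 3):
                raise ParseError(path, lineno, f"expected 2-3 fields, got {len(fields)}")
            w = _parse_weight(fields[2], path, lineno) if len(fields) == 3 else 1.0
            if w < 0:
                raise ValidationError(f"{path}:{lineno}: negative weight {w}")
            edges.append((fields[0], fields[1], w))
        else:  # sif
            if len(fields) < 3:
                raise ParseError(path, lineno, f"SIF line needs >= 3 fields, got {len(fields)}")
            a = fields[0]
            for b in fields[2:]:
                edges.append((a, b, 1.0))
    return GeneNetwork.from_edges(edges)


def _topk_sparsify(
    ids: tuple[str, ...], sim: dict[tuple[str, str], float], k_top: int
) -> DiseaseNetwork:
    """Keep, for each disease, its k_top largest-weight neighbours (ties
    broken lexicographically by neighbour id), then symmetrize by union."""
    sim = {((a, b) if a < b else (b, a)): w for (a, b), w in sim.items()}
    neighbours: dict[str, list[tuple[str, float]]] = {d: [] for d in ids}
    for (a, b), w in sim.items():
        if w <= 0:
            continue
        neighbours[a].append((b, w))
        neighbours[b].append((a, w))
    selected: set[tuple[str, str]] = set()
    for d, nbrs in neighbours.items():
        nbrs.sort(key=lambda t: (-t[1], t[0]))
        for b, _ in nbrs[:k_top]:
            key = (d, b) if d < b else (b, d)
            selected.add(key)
    kept = {key: sim[key] for key in selected}
    return DiseaseNetwork(ids, _symmetric_csr(ids, kept))


def read_disease_similarity(
    path: str | Path, format: str = "edgelist", k_top: int = 5
) -> DiseaseNetwork:
    """Read disease similarities and keep each disease's k_top strongest.

    ``matrix`` expects a dense TSV with a disease-id header row and column
    (entries in [0, 1]; asymmetries are averaged before filtering);
    ``edgelist`` expects ``a b weight`` lines.  An edge survives the filter
    if it is a top-k choice of at least one endpoint.
    """
    if k_top < 1:
        raise ValidationError(f"k_top must be >= 1, got {k_top}")
    if format not in ("edgelist", "matrix"):
        raise ValidationError(f"unknown similarity format {format!r}")

    if format == "edgelist":
        ids: list[str] = []
        seen: set[str] = set()
        sim: dict[tuple[str, str], float] = {}
        for lineno, fields in _data_lines(path):
            if len(fields) not in (2, 3):
                raise ParseError(path, lineno, f"expected 2-3 fields, got {len(fields)}")
            a, b = fields[0], fields[1]
            w = _parse_weight(fields[2], path, lineno) if len(fields) == 3 else 1.0
            if w < 0:
                raise ValidationError(f"{path}:{lineno}: negative similarity {w}")
            for d in (a, b):
                if d not in seen:
                    seen.add(d)
                    ids.append(d)
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            sim[key] = max(w, sim.get(key, 0.0))
        return _topk_sparsify(tuple(ids), sim, k_top)

    # dense matrix with id header row and column
    rows = list(_data_lines(path))
    if not rows:
        raise ValidationError(f"{path}: empty similarity matrix")
    header = rows[0][1]
    body = rows[1:]
    n = len(body)
    if len(header) == n + 1:
        header = header[1:]  # corner cell
    if len(header) != n:
        raise ValidationError(
            f"{path}: matrix is not square ({len(header)} header ids, {n} rows)"
        )
    m = np.zeros((n, n))
    for i, (lineno, fields) in enumerate(body):
        if len(fields) != n + 1:
            raise ParseError(path, lineno, f"expected {n + 1} fields, got {len(fields)}")
        if fields[0] != header[i]:
            raise ValidationError(
                f"{path}:{lineno}: row id {fields[0]!r} does not match header id {header[i]!r}"
            )
        for j, tok in enumerate(fields[1:]):
            v = _parse_weight(tok, path, lineno)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{path}:{lineno}: similarity {v} outside [0, 1]")
            m[i, j] = v
    m = (m + m.T) / 2.0  # phenotypic similarity is symmetric by construction
    np.fill_diagonal(m, 0.0)
    ids_t = tuple(header)
    sim = {
        (ids_t[i], ids_t[j]): float(m[i, j])
        for i in range(n)
        for j in range(i + 1, n)
        if m[i, j] > 0
    }
    return _topk_sparsify(ids_t, sim, k_top)


def read_bipartite(path: str | Path) -> BipartiteAssociations:
    """Read disease-gene associations: ``disease_id gene_id [weight]``.

    Missing weight defaults to 1.0; duplicate pairs keep the maximum weight;
    non-positive weights are rejected.
    """
    pairs: dict[tuple[str, str], float] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) not in (2, 3):
            raise ParseError(path, lineno, f"expected 2-3 fields, got {len(fields)}")
        w = _parse_weight(fields[2], path, lineno) if len(fields) == 3 else 1.0
        if w <= 0:
            raise ValidationError(f"{path}:{lineno}: association weight must be > 0, got {w}")
        key = (fields[0], fields[1])
        pairs[key] = max(w, pairs.get(key, 0.0))
    return BipartiteAssociations(pairs)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble_heterogeneous(
    gene_net: GeneNetwork,
    disease_net: DiseaseNetwork,
    bipartite: BipartiteAssociations,
) -> HetNet:
    """Align the three networks into one indexed heterogeneous network.

    Bipartite pairs referencing unknown gene or disease ids are dropped
    (with a logged count).  Every retained node must have total degree >= 1
    across the three blocks; gene and disease id namespaces must not
    collide.  The restart term of the walk makes the process well defined
    on any degree-positive graph, so full connectivity is not required.
    """
    if gene_net.n_genes == 0 or disease_net.n_diseases == 0:
        raise AssemblyError("gene and disease networks must both be non-empty")
    gene_set = set(gene_net.gene_ids)
    disease_set = set(disease_net.disease_ids)
    collision = gene_set & disease_set
    if collision:
        raise AssemblyError(f"ids used as both gene and disease: {sorted(collision)[:5]}")

    gi = {g: i for i, g in enumerate(gene_net.gene_ids)}
    di = {d: j for j, d in enumerate(disease_net.disease_ids)}

    kept: dict[tuple[str, str], float] = {}
    dropped = 0
    for (d, g), w in bipartite.pairs.items():
        if d in di and g in gi:
            kept[(d, g)] = w
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d bipartite pairs with unresolvable ids", dropped)

    n_g, n_d = gene_net.n_genes, disease_net.n_diseases
    if kept:
        rows = [gi[g] for (d, g) in kept]
        cols = [di[d] for (d, g) in kept]
        vals = list(kept.values())
        w_gd = sparse.coo_array((vals, (rows, cols)), shape=(n_g, n_d)).tocsr()
    else:
        w_gd = sparse.csr_array((n_g, n_d))

    gene_deg = gene_net.w.sum(axis=1) + w_gd.sum(axis=1)
    disease_deg = disease_net.w.sum(axis=1) + w_gd.sum(axis=0)
    for i in np.flatnonzero(gene_deg == 0):
        raise AssemblyError(f"node {gene_net.gene_ids[i]!r} has total degree 0")
    for j in np.flatnonzero(disease_deg == 0):
        raise AssemblyError(f"node {disease_net.disease_ids[j]!r} has total degree 0")

    index_map = {g: i for g, i in gi.items()}
    index_map.update({d: n_g + j for d, j in di.items()})
    return HetNet(gene_net, disease_net, BipartiteAssociations(kept), w_gd, index_map)


# ---------------------------------------------------------------------------
# writers (round-trip counterparts of the readers)
# ---------------------------------------------------------------------------


def write_gene_network(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tweight\n")
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_disease_similarity(net: DiseaseNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# disease_a\tdisease_b\tsimilarity\n")
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_bipartite(bip: BipartiteAssociations, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# disease_id\tgene_id\tweight\n")
        for (d, g), w in sorted(bip.pairs.items()):
            fh.write(f"{d}\t{g}\t{w:.10g}\n")
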