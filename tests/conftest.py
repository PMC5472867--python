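"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's sparse code paths: the
transition oracle evaluates the four piecewise block formulas elementwise
on dense arrays, and the steady-state oracle solves the fixed-point
system directly.  Both serve as ground truth for the implementation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from hetprop.hetnet_io import (
    BipartiteAssociations,
    DiseaseNetwork,
    GeneNetwork,
    HetNet,
    _symmetric_csr,
    assemble_heterogeneous,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def dense_transition_oracle(net: HetNet, lam: float) -> np.ndarray:
    """Elementwise evaluation of the four piecewise transition formulas
    (plus the bipartite-only rescue) on dense arrays."""
    wg = net.gene_net.w.toarray()
    wd = net.disease_net.w.toarray()
    wgd = net.w_gd.toarray()
    n_g, n_d = wgd.shape
    m = np.zeros((n_g + n_d, n_g + n_d))

    def seqsum(vec):
        # left-to-right accumulation, as when normalizing a row by hand
        s = 0.0
        for x in vec:
            s += x
        return s

    for i in range(n_g):
        gg, gd = seqsum(wg[i]), seqsum(wgd[i])
        if gd != 0:
            share = lam if gg != 0 else 1.0  # rescue: no intra links
            m[i, n_g:] = wgd[i] * (share / gd)
        if gg != 0:
            share = 1.0 if gd == 0 else 1.0 - lam
            m[i, :n_g] = wg[i] * (share / gg)
    for j in range(n_d):
        i = n_g + j
        dd, dg = seqsum(wd[j]), seqsum(wgd[:, j])
        if dg != 0:
            share = lam if dd != 0 else 1.0
            m[i, :n_g] = wgd[:, j] * (share / dg)
        if dd != 0:
            share = 1.0 if dg == 0 else 1.0 - lam
            m[i, n_g:] = wd[j] * (share / dd)
    return m


def steady_state_direct(m: np.ndarray | sparse.sparray, p0: np.ndarray, gamma: float) -> np.ndarray:
    """Closed-form fixed point: p = gamma * (I - (1-gamma) M^T)^-1 p0."""
    md = m.toarray() if sparse.issparse(m) else np.asarray(m)
    n = md.shape[0]
    return gamma * np.linalg.solve(np.eye(n) - (1.0 - gamma) * md.T, p0)


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------


def make_hetnet(
    gene_edges: list[tuple[str, str, float]],
    disease_ids: list[str],
    disease_edges: list[tuple[str, str, float]],
    pairs: list[tuple[str, str]],
    gene_ids: list[str] | None = None,
) -> HetNet:
    """Assemble a small heterogeneous network from explicit edge lists."""
    if gene_ids is None:
        seen: list[str] = []
        for a, b, _ in gene_edges:
            for g in (a, b):
                if g not in seen:
                    seen.append(g)
        for _, g in pairs:
            if g not in seen:
                seen.append(g)
        gene_ids = seen
    g_w = {( (a, b) if a < b else (b, a) ): w for a, b, w in gene_edges}
    d_w = {( (a, b) if a < b else (b, a) ): w for a, b, w in disease_edges}
    gene_net = GeneNetwork(tuple(gene_ids), _symmetric_csr(tuple(gene_ids), g_w))
    disease_net = DiseaseNetwork(tuple(disease_ids), _symmetric_csr(tuple(disease_ids), d_w))
    bip = BipartiteAssociations({(d, g): 1.0 for d, g in pairs})
    return assemble_heterogeneous(gene_net, disease_net, bip)


def random_hetnet(rng: np.random.Generator, max_genes: int = 12, max_diseases: int = 8) -> HetNet:
    """Random degree-positive heterogeneous net with random positive weights.

    Occasionally produces bipartite-only nodes, exercising the rescue rule.
    """
    n_g = int(rng.integers(2, max_genes + 1))
    n_d = int(rng.integers(2, max_diseases + 1))
    gene_ids = [f"g{i}" for i in range(n_g)]
    disease_ids = [f"d{j}" for j in range(n_d)]
    g_w = {}
    for i in range(n_g):
        for j in range(i + 1, n_g):
            if rng.random() < 0.35:
                g_w[(gene_ids[i], gene_ids[j])] = float(rng.uniform(0.1, 2.0))
    d_w = {}
    for i in range(n_d):
        for j in range(i + 1, n_d):
            if rng.random() < 0.35:
                d_w[(disease_ids[i], disease_ids[j])] = float(rng.uniform(0.1, 2.0))
    pairs = {}
    for g in gene_ids:
        for d in disease_ids:
            if rng.random() < 0.25:
                pairs[(d, g)] = float(rng.uniform(0.5, 1.5))
    # guarantee total degree >= 1 everywhere
    linked_genes = {g for e in g_w for g in e} | {g for (_, g) in pairs}
    for g in set(gene_ids) - linked_genes:
        pairs[(disease_ids[int(rng.integers(n_d))], g)] = 1.0
    linked_diseases = {d for e in d_w for d in e} | {d for (d, _) in pairs}
    for d in set(disease_ids) - linked_diseases:
        pairs[(d, gene_ids[int(rng.integers(n_g))])] = 1.0
    gene_net = GeneNetwork(tuple(gene_ids), _symmetric_csr(tuple(gene_ids), g_w))
    disease_net = DiseaseNetwork(tuple(disease_ids), _symmetric_csr(tuple(disease_ids), d_w))
    return assemble_heterogeneous(gene_net, disease_net, BipartiteAssociations(pairs))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def micro_net() -> HetNet:
    """The 5-node worked example: genes g1-g2-g3 in a path, diseases d1-d2,
    one known association d1-g1."""
    return make_hetnet(
        gene_edges=[("g1", "g2", 1.0), ("g2", "g3", 1.0)],
        disease_ids=["d1", "d2"],
        disease_edges=[("d1", "d2", 1.0)],
        pairs=[("d1", "g1")],
    )
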