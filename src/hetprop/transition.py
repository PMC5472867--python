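"""Block transition matrix of the heterogeneous random walk.

The walk moves over genes and diseases with a jumping probability
``lambda_`` of crossing between the two layers wherever bipartite links
exist.  Writing ``W_G``, ``W_D``, ``W_GD`` for the three adjacency blocks,
the row-stochastic transition matrix is

    W' = [[W'_G,  W'_GD],
          [W'_DG, W'_D ]]

where, for a gene i with bipartite links, the gene-gene block row is the
row-normalized ``W_G`` row scaled by ``1 - lambda_`` and the gene-disease
block row is the row-normalized ``W_GD`` row scaled by ``lambda_``; a gene
without bipartite links keeps its plain row-normalized ``W_G`` row.  The
disease rows are defined symmetrically on ``W_D`` and the columns of
``W_GD``.  A node whose only links are bipartite would be left with
outgoing mass ``lambda_ < 1`` by those formulas, so its bipartite block
row is renormalized to sum 1 (the walker must jump); this rescue is the
only deviation from plain piecewise normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

from .errors import ValidationError
from .hetnet_io import HetNet

__all__ = ["TransitionMatrix", "build_transition", "write_transition_tsv"]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic N x N transition matrix; ``m[i, j] = P(i -> j)``."""

    m: sparse.csr_array
    lambda_: float
    n_genes: int
    n_diseases: int

    @property
    def n_nodes(self) -> int:
        return self.n_genes + self.n_diseases


def _row_scale(block: sparse.csr_array, factors: np.ndarray) -> sparse.csr_array:
    return sparse.csr_array(sparse.diags_array(factors) @ block)


def build_transition(net: HetNet, lambda_: float) -> TransitionMatrix:
    """Assemble the four-block transition matrix for a given jump probability."""
    if not 0.0 < lambda_ < 1.0:
        raise ValidationError(f"lambda_ must be in (0, 1), got {lambda_}")

    w_g = net.gene_net.w
    w_d = net.disease_net.w
    w_gd = net.w_gd
    w_dg = sparse.csr_array(w_gd.T)

    # row sums via matvec: sequential accumulation over stored entries, the
    # same order as normalizing a written-out row term by term
    g_rs = w_g @ np.ones(w_g.shape[1])       # gene-gene row sums
    d_rs = w_d @ np.ones(w_d.shape[1])       # disease-disease row sums
    gd_rs = w_gd @ np.ones(w_gd.shape[1])    # per-gene bipartite mass
    dg_rs = w_dg @ np.ones(w_dg.shape[1])    # per-disease bipartite mass

    with np.errstate(divide="ignore", invalid="ignore"):
        # intra-layer rows: plain normalization when the node has no
        # bipartite links, (1 - lambda) share otherwise
        g_fac = np.where(gd_rs == 0, 1.0, 1.0 - lambda_) / np.where(g_rs == 0, 1.0, g_rs)
        g_fac[g_rs == 0] = 0.0
        d_fac = np.where(dg_rs == 0, 1.0, 1.0 - lambda_) / np.where(d_rs == 0, 1.0, d_rs)
        d_fac[d_rs == 0] = 0.0
        # inter-layer rows: lambda share, rescued to full mass when the
        # node has no intra-layer links at all
        gd_fac = np.where(g_rs == 0, 1.0, lambda_) / np.where(gd_rs == 0, 1.0, gd_rs)
        gd_fac[gd_rs == 0] = 0.0
        dg_fac = np.where(d_rs == 0, 1.0, lambda_) / np.where(dg_rs == 0, 1.0, dg_rs)
        dg_fac[dg_rs == 0] = 0.0

    m = sparse.block_array(
        [
            [_row_scale(w_g, g_fac), _row_scale(w_gd, gd_fac)],
            [_row_scale(w_dg, dg_fac), _row_scale(w_d, d_fac)],
        ],
        format="csr",
    )

    row_sums = np.asarray(m.sum(axis=1)).ravel()
    bad = np.flatnonzero(np.abs(row_sums - 1.0) > _ROW_SUM_TOL)
    if bad.size:
        node = net.node_ids[int(bad[0])]
        raise ValidationError(
            f"transition row for {node!r} sums to {row_sums[bad[0]]!r}, not 1"
        )
    return TransitionMatrix(sparse.csr_array(m), lambda_, net.n_genes, net.n_diseases)


def write_transition_tsv(t: TransitionMatrix, net: HetNet, path: str | Path) -> None:
    """Debug dump as (from_id, to_id, probability) triples."""
    ids = net.node_ids
    coo = sparse.coo_array(t.m)
    with open(path, "w") as fh:
        fh.write("# from_id\tto_id\tprobability\n")
        for i, j, v in sorted(zip(coo.row, coo.col, coo.data)):
            fh.write(f"{ids[i]}\t{ids[j]}\t{v:.12g}\n")
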