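"""Leave-one-out cross-validation of gene prioritization.

Each known disease-gene association of every disease with at least
``min_known_genes`` known genes is held out in turn: the association is
removed from the bipartite network, the walk is seeded with the disease
and its remaining known genes, all non-seed genes are ranked, and the
rank of the held-out gene is recorded (average rank over score ties).
The per-trial normalized rank aggregates to the area under the ROC curve
for one positive against ``n_candidates - 1`` negatives:

    AUC = mean over trials of (n_candidates - rank) / (n_candidates - 1)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError
from .hetnet_io import HetNet, assemble_heterogeneous
from .rwrh import RWRHParams, SeedSet, build_seed_vector, rwrh_steady_state
from .transition import build_transition

__all__ = ["LOOTrial", "LOOResult", "leave_one_out", "auc_from_ranks", "write_loo_report"]


class LOOTrial(NamedTuple):
    disease_id: str
    held_out_gene: str
    rank: float  # average rank over ties, 1-based
    n_candidates: int


@dataclass(frozen=True)
class LOOResult:
    trials: list[LOOTrial]
    auc: float


def auc_from_ranks(trials: list[LOOTrial]) -> float:
    """Mean normalized rank of the held-out genes, on the AUC scale."""
    if not trials:
        raise ValidationError("cannot compute AUC from an empty trial list")
    total = 0.0
    for t in trials:
        if not 1 <= t.rank <= t.n_candidates:
            raise ValidationError(f"trial rank {t.rank} outside [1, {t.n_candidates}]")
        if t.n_candidates == 1:
            total += 1.0 if t.rank == 1 else 0.0
        else:
            total += (t.n_candidates - t.rank) / (t.n_candidates - 1)
    return total / len(trials)


def _rank_of(held_out: str, candidates: list[str], scores: np.ndarray) -> float:
    ranks = rankdata(-scores, method="average")
    return float(ranks[candidates.index(held_out)])


def leave_one_out(net: HetNet, params: RWRHParams, min_known_genes: int = 2) -> LOOResult:
    """Run the full hold-out protocol over every qualifying association.

    The ranking universe of each trial is every gene outside the trial's
    remaining seed-gene set, so the held-out gene competes against all
    other unlinked genes.
    """
    if min_known_genes < 2:
        raise ValidationError(f"min_known_genes must be >= 2, got {min_known_genes}")
    qualifying = [
        d for d in net.disease_net.disease_ids
        if len(net.known_genes(d)) >= min_known_genes
    ]
    if not qualifying:
        raise ValidationError(
            f"no disease has >= {min_known_genes} known genes; cannot cross-validate"
        )

    all_genes = list(net.gene_net.gene_ids)
    trials: list[LOOTrial] = []
    for d in qualifying:
        for g in sorted(net.known_genes(d)):
            reduced = net.bipartite.without(d, g)
            trial_net = assemble_heterogeneous(net.gene_net, net.disease_net, reduced)
            t = build_transition(trial_net, params.lambda_)
            seeds = SeedSet(frozenset(reduced.genes_of(d)), frozenset({d}))
            p0 = build_seed_vector(trial_net, seeds, params.eta)
            p_inf = rwrh_steady_state(t, p0, params.gamma, params.tol, params.max_iter)
            candidates = [x for x in all_genes if x not in seeds.seed_genes]
            scores = np.array([p_inf.values[trial_net.index_map[c]] for c in candidates])
            trials.append(LOOTrial(d, g, _rank_of(g, candidates, scores), len(candidates)))
    return LOOResult(trials, auc_from_ranks(trials))


def write_loo_report(result: LOOResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# disease\tgene\trank\tn_candidates\n")
        for t in result.trials:
            fh.write(f"{t.disease_id}\t{t.held_out_gene}\t{t.rank:g}\t{t.n_candidates}\n")
        fh.write(f"# AUC\t{result.auc:.10g}\n")
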