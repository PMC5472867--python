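"""Random walk with restart on the heterogeneous network.

Given the transition matrix ``T`` and a restart distribution ``p0`` built
from the seed set (the disease of interest, or a disease class, plus its
known associated genes), the walk iterates

    p_{t+1} = (1 - gamma) * T^T @ p_t + gamma * p0

to its unique fixed point.  ``gamma`` is the restart (back) probability;
``eta`` splits the initial mass between the disease and gene layers.
Because ``T`` is row-stochastic the transpose acts column-stochastically
on probability vectors, so every iterate remains a probability
distribution, and the map is a contraction with factor ``1 - gamma`` in
L1, making the fixed point independent of the starting vector.  Candidate
genes and diseases are then ranked by their steady-state probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConvergenceError, ValidationError
from .hetnet_io import HetNet
from .transition import TransitionMatrix

__all__ = [
    "RWRHParams",
    "SeedSet",
    "ProbabilityVector",
    "Rankings",
    "build_seed_vector",
    "rwrh_steady_state",
    "rank_candidates",
    "write_rankings",
]


@dataclass(frozen=True)
class RWRHParams:
    """Walk parameters; the defaults are the settings commonly reported to
    work best for this method (gamma=0.5, lambda_=0.6, eta=0.7)."""

    gamma: float = 0.5
    lambda_: float = 0.6
    eta: float = 0.7
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        for name in ("gamma", "lambda_", "eta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.tol <= 0:
            raise ValidationError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValidationError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass(frozen=True)
class SeedSet:
    """Training data: the disease(s) of interest and their known genes.

    ``seed_genes`` may be empty — a disease without known molecular basis
    is seeded from the disease layer alone.
    """

    seed_genes: frozenset[str]
    seed_diseases: frozenset[str]

    def __post_init__(self) -> None:
        if not self.seed_diseases:
            raise ValidationError("seed_diseases must be non-empty")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.seed_genes | self.seed_diseases


@dataclass(frozen=True)
class ProbabilityVector:
    """Probability distribution over all network nodes (genes then diseases)."""

    values: np.ndarray
    kind: str  # "initial" or "steady"
    iterations: int | None = None


@dataclass(frozen=True)
class Rankings:
    """Ranked candidates: (id, score, 1-based rank), scores non-increasing,
    ties broken lexicographically by id."""

    gene_ranking: list[tuple[str, float, int]]
    disease_ranking: list[tuple[str, float, int]]


def build_seed_vector(net: HetNet, seeds: SeedSet, eta: float) -> ProbabilityVector:
    """Initial distribution: seed genes share mass ``1 - eta`` equally, seed
    diseases share ``eta`` equally; with no seed genes the disease layer
    takes all the mass."""
    if not 0.0 < eta < 1.0:
        raise ValidationError(f"eta must be in (0, 1), got {eta}")
    for sid in sorted(seeds.all_ids):
        if sid not in net.index_map:
            raise ValidationError(f"seed id {sid!r} is not a network node")
    for g in seeds.seed_genes:
        if not net.is_gene(g):
            raise ValidationError(f"seed gene {g!r} is a disease node")
    for d in seeds.seed_diseases:
        if net.is_gene(d):
            raise ValidationError(f"seed disease {d!r} is a gene node")

    p0 = np.zeros(net.n_nodes)
    if seeds.seed_genes:
        gene_mass = (1.0 - eta) / len(seeds.seed_genes)
        disease_mass = eta / len(seeds.seed_diseases)
    else:
        gene_mass = 0.0
        disease_mass = 1.0 / len(seeds.seed_diseases)
    for g in seeds.seed_genes:
        p0[net.index_map[g]] = gene_mass
    for d in seeds.seed_diseases:
        p0[net.index_map[d]] = disease_mass
    return ProbabilityVector(p0, "initial")


def rwrh_steady_state(
    t: TransitionMatrix,
    p0: ProbabilityVector,
    gamma: float,
    tol: float = 1e-10,
    max_iter: int = 1000,
    start: np.ndarray | None = None,
) -> ProbabilityVector:
    """Iterate the restart walk to its fixed point.

    ``p0`` is the restart distribution; iteration begins from it unless an
    explicit ``start`` distribution is given (the fixed point is the same
    either way — the map contracts with factor ``1 - gamma`` in L1).
    Raises :class:`ConvergenceError` (carrying the last iterate) if the L1
    change has not fallen below ``tol`` within ``max_iter`` steps.
    """
    if not 0.0 < gamma < 1.0:
        raise ValidationError(f"gamma must be in (0, 1), got {gamma}")
    restart = p0.values
    if abs(restart.sum() - 1.0) > 1e-9:
        raise ValidationError(f"p0 sums to {restart.sum()!r}, not 1")
    p = restart if start is None else start
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"start vector sums to {p.sum()!r}, not 1")
    tt = t.m.T  # column-stochastic action on probability vectors
    for it in range(1, max_iter + 1):
        p_next = (1.0 - gamma) * (tt @ p) + gamma * restart
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < tol:
            return ProbabilityVector(p, "steady", iterations=it)
    raise ConvergenceError(p, max_iter, delta)


def _ranked(ids: list[str], scores: dict[str, float]) -> list[tuple[str, float, int]]:
    ordered = sorted(ids, key=lambda i: (-scores[i], i))
    return [(i, scores[i], r) for r, i in enumerate(ordered, start=1)]


def rank_candidates(
    net: HetNet,
    p_inf: ProbabilityVector,
    candidate_genes: set[str],
    candidate_diseases: set[str],
    seeds: SeedSet | None = None,
) -> Rankings:
    """Rank candidates by steady-state score, descending; ties are broken
    lexicographically by id and ranks are 1-based and dense."""
    if seeds is not None:
        overlap = (candidate_genes | candidate_diseases) & seeds.all_ids
        if overlap:
            raise ValidationError(f"candidates overlap the seed set: {sorted(overlap)[:5]}")
    for c in candidate_genes | candidate_diseases:
        if c not in net.index_map:
            raise ValidationError(f"candidate id {c!r} is not a network node")
    scores = {c: float(p_inf.values[net.index_map[c]]) for c in candidate_genes | candidate_diseases}
    return Rankings(
        gene_ranking=_ranked(sorted(candidate_genes), scores),
        disease_ranking=_ranked(sorted(candidate_diseases), scores),
    )


def write_rankings(rankings: Rankings, net: HetNet, path: str | Path) -> None:
    """Write both ranked lists as rank/id/type/score/is_seed TSV rows."""
    with open(path, "w") as fh:
        fh.write("# rank\tid\ttype\tscore\tis_seed\n")
        for node_type, ranking in (("gene", rankings.gene_ranking), ("disease", rankings.disease_ranking)):
            for node_id, score, rank in ranking:
                fh.write(f"{rank}\t{node_id}\t{node_type}\t{score:.10g}\t0\n")
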