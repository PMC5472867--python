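"""Candidate gene and disease set construction.

Candidate genes can be chosen several ways: every non-training gene in
the network, direct network neighbours of the training genes, those
neighbours restricted to chromosomes carrying a training gene, all genes
on a susceptible chromosome band, or an arbitrary user list.  Candidate
diseases are always the non-training diseases.  Candidate sets never
intersect the training (seed) sets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError
from .hetnet_io import HetNet

__all__ = [
    "GeneAnnotations",
    "read_gene_annotations",
    "read_gene_list",
    "candidate_genes",
    "candidate_diseases",
    "STRATEGIES",
]

# gene_id -> (chromosome, band); genes absent from the map are excluded
# from chromosome-based strategies
GeneAnnotations = dict[str, tuple[str, str]]

STRATEGIES = (
    "all_non_training",
    "neighbors",
    "neighbors_same_chromosome",
    "chromosome_band",
    "user_list",
)


def read_gene_annotations(path: str | Path) -> GeneAnnotations:
    """Read gene location TSV: ``gene_id chromosome band``."""
    out: GeneAnnotations = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(path, lineno, f"expected 3 fields, got {len(fields)}")
            out[fields[0]] = (fields[1], fields[2])
    return out


def read_gene_list(path: str | Path) -> set[str]:
    """Read a user candidate list, one gene id per line."""
    out: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.add(line.split()[0])
    return out


def _network_neighbors(net: HetNet, seed_genes: set[str]) -> set[str]:
    w = net.gene_net.w
    ids = net.gene_net.gene_ids
    index = {g: i for i, g in enumerate(ids)}
    nbrs: set[str] = set()
    for g in seed_genes:
        row = w[[index[g]], :]
        nbrs.update(ids[j] for j in row.indices)
    return nbrs - seed_genes


def candidate_genes(
    net: HetNet,
    seed_genes: set[str],
    strategy: str = "all_non_training",
    annotations: GeneAnnotations | None = None,
    band_spec: str | None = None,
    user_list: set[str] | None = None,
) -> set[str]:
    """Build the candidate gene set for one of the supported strategies.

    ``band_spec`` is ``"chromosome:band"`` (e.g. ``"17:q21"``), matched
    exactly against the annotation fields.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown candidate strategy {strategy!r}")
    all_genes = set(net.gene_net.gene_ids)
    unknown = seed_genes - all_genes
    if unknown:
        raise ValidationError(f"seed genes not in network: {sorted(unknown)[:5]}")

    if strategy == "all_non_training":
        return all_genes - seed_genes

    if strategy == "neighbors":
        return _network_neighbors(net, seed_genes)

    if strategy == "neighbors_same_chromosome":
        if annotations is None:
            raise ValidationError("strategy 'neighbors_same_chromosome' requires gene annotations")
        seed_chroms = {annotations[g][0] for g in seed_genes if g in annotations}
        nbrs = _network_neighbors(net, seed_genes)
        return {g for g in nbrs if g in annotations and annotations[g][0] in seed_chroms}

    if strategy == "chromosome_band":
        if annotations is None or band_spec is None:
            raise ValidationError("strategy 'chromosome_band' requires gene annotations and a band spec")
        if ":" not in band_spec:
            raise ValidationError(f"band spec must be 'chromosome:band', got {band_spec!r}")
        chrom, band = band_spec.split(":", 1)
        hits = {g for g, (c, b) in annotations.items() if c == chrom and b == band}
        return (hits & all_genes) - seed_genes

    # user_list
    if user_list is None:
        raise ValidationError("strategy 'user_list' requires a user gene list")
    return (user_list & all_genes) - seed_genes


def candidate_diseases(net: HetNet, seed_diseases: set[str]) -> set[str]:
    """All non-training diseases in the similarity network."""
    all_diseases = set(net.disease_net.disease_ids)
    unknown = seed_diseases - all_diseases
    if unknown:
        raise ValidationError(f"seed diseases not in network: {sorted(unknown)[:5]}")
    return all_diseases - seed_diseases
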