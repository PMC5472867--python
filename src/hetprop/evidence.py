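"""Annotation-overlap evidence for predicted disease-disease associations.

A promising association between a candidate disease and the disease of
interest can be supported by the annotations the two diseases share:
known associated genes, pathways, protein complexes and disease-ontology
terms.  Genes are compared by direct intersection of the two diseases'
gene sets; a pathway or protein complex counts as shared when it contains
at least one gene of each disease (pathways and complexes annotate genes,
not diseases); ontology terms are compared by direct intersection of the
diseases' term sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .errors import ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "SharedCounts",
    "read_gmt",
    "read_disease_terms",
    "read_disease_genes",
    "shared_annotation_counts",
    "evidence_table",
    "write_evidence_table",
]


@dataclass(frozen=True)
class AnnotationMap:
    """Mapping from a term (or disease) to its set of member ids.

    ``kind`` is one of pathway / complex / disease_ontology / disease_genes.
    """

    kind: str
    mapping: dict[str, set[str]]

    def members(self, key: str) -> set[str]:
        return self.mapping.get(key, set())


@dataclass(frozen=True)
class SharedCounts:
    shared_genes: int
    shared_complexes: int
    shared_pathways: int
    shared_do_terms: int


def read_gmt(path: str | Path, kind: str = "pathway") -> AnnotationMap:
    """Read a GMT gene-set file: ``term<TAB>description<TAB>member...``.

    Duplicate terms are merged by union of their members.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"GMT line needs >= 3 fields, got {len(fields)}")
            term, members = fields[0], {f for f in fields[2:] if f}
            if not members:
                raise ParseError(path, lineno, f"GMT term {term!r} has no members")
            mapping.setdefault(term, set()).update(members)
    return AnnotationMap(kind, mapping)


def _read_two_column(path: str | Path, kind: str) -> AnnotationMap:
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(path, lineno, f"expected 2 fields, got {len(fields)}")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return AnnotationMap(kind, mapping)


def read_disease_terms(path: str | Path) -> AnnotationMap:
    """Read disease -> ontology-term TSV (one pair per line)."""
    return _read_two_column(path, "disease_ontology")


def read_disease_genes(path: str | Path) -> AnnotationMap:
    """Read disease -> known-gene TSV (one pair per line)."""
    return _read_two_column(path, "disease_genes")


_EMPTY = AnnotationMap("empty", {})


def _dual_membership(terms: AnnotationMap, genes_a: set[str], genes_b: set[str]) -> int:
    """Terms containing at least one gene from each disease's gene set."""
    return sum(1 for members in terms.mapping.values() if members & genes_a and members & genes_b)


def shared_annotation_counts(
    disease_a: str,
    disease_b: str,
    disease_genes: AnnotationMap | None,
    pathways: AnnotationMap | None = None,
    complexes: AnnotationMap | None = None,
    do_terms: AnnotationMap | None = None,
) -> SharedCounts:
    """Count annotations shared by two diseases; missing maps count as empty."""
    for name, m in (("disease_genes", disease_genes), ("pathways", pathways),
                    ("complexes", complexes), ("do_terms", do_terms)):
        if m is None:
            logger.warning("annotation map %s missing; treated as empty", name)
    disease_genes = disease_genes or _EMPTY
    pathways = pathways or _EMPTY
    complexes = complexes or _EMPTY
    do_terms = do_terms or _EMPTY

    genes_a = disease_genes.members(disease_a)
    genes_b = disease_genes.members(disease_b)
    return SharedCounts(
        shared_genes=len(genes_a & genes_b),
        shared_complexes=_dual_membership(complexes, genes_a, genes_b),
        shared_pathways=_dual_membership(pathways, genes_a, genes_b),
        shared_do_terms=len(do_terms.members(disease_a) & do_terms.members(disease_b)),
    )


def evidence_table(
    disease_of_interest: str,
    ranked_diseases: list[tuple[str, float, int]],
    top_n: int,
    disease_genes: AnnotationMap | None,
    pathways: AnnotationMap | None = None,
    complexes: AnnotationMap | None = None,
    do_terms: AnnotationMap | None = None,
) -> list[tuple[int, str, float, SharedCounts]]:
    """Shared-annotation evidence for the ``top_n`` ranked candidate diseases."""
    rows = []
    for disease_id, score, rank in ranked_diseases[:top_n]:
        counts = shared_annotation_counts(
            disease_of_interest, disease_id, disease_genes, pathways, complexes, do_terms
        )
        rows.append((rank, disease_id, score, counts))
    return rows


def write_evidence_table(rows: list[tuple[int, str, float, SharedCounts]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# rank\tdisease_id\tscore\tshared_genes\tshared_complexes\tshared_pathways\tshared_do_terms\n")
        for rank, disease_id, score, c in rows:
            fh.write(
                f"{rank}\t{disease_id}\t{score:.10g}\t{c.shared_genes}\t"
                f"{c.shared_complexes}\t{c.shared_pathways}\t{c.shared_do_terms}\n"
            )
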