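"""Broad functional categories from the GO biological-process hierarchy.

Broad categories are the direct ``is_a`` children of the BP root term
GO:0008150 (e.g. metabolic process, developmental process). A gene belongs
to a category whenever one of its annotated terms has that category among
its ``is_a`` ancestors (or is the category itself). For single-factor
analyses each gene additionally gets a *primary* category: the member
category covering the largest number of the gene's annotated terms, ties
broken by lexicographic term id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import AnnotationSet, GoDag

logger = logging.getLogger(__name__)


@dataclass
class CategoryAssignment:
    """Per-gene broad-category membership and primary category."""

    categories: dict[str, frozenset[str]]
    primary: dict[str, str | None]

    def count_by_category(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cats in self.categories.values():
            for c in cats:
                counts[c] = counts.get(c, 0) + 1
        return counts


@dataclass
class CategoryPanel:
    """Selected categories retained for the factor analyses."""

    kept: tuple[str, ...]  # category term ids
    dropped: dict[str, int] = field(default_factory=dict)  # id -> gene count at drop
    genes_by_category: dict[str, frozenset[str]] = field(default_factory=dict)


def broad_categories(dag: GoDag, root: str | None = None) -> set[str]:
    """Direct ``is_a`` children of the BP root term."""
    root = root if root is not None else dag.root
    if root not in dag:
        raise ValueError(f"root term {root!r} absent from the ontology")
    children = dag.children_of(root)
    if not children:
        logger.warning("root term %s has no children; no broad categories", root)
    return children


def assign_categories(
    annotations: AnnotationSet, dag: GoDag, categories: set[str]
) -> CategoryAssignment:
    """Map each gene's annotated terms to broad categories via ancestor traversal."""
    assigned: dict[str, frozenset[str]] = {}
    primary: dict[str, str | None] = {}
    # ancestor sets are shared across genes; memoise per term
    cache: dict[str, frozenset[str]] = {}

    def cats_of(term: str) -> frozenset[str]:
        hit = cache.get(term)
        if hit is None:
            lineage = dag.ancestors(term) | {term}
            hit = frozenset(lineage & categories)
            cache[term] = hit
        return hit

    for gene, anns in annotations.annotations.items():
        per_cat: dict[str, int] = {}
        for term in {go for go, _ev in anns}:
            for c in cats_of(term):
                per_cat[c] = per_cat.get(c, 0) + 1
        assigned[gene] = frozenset(per_cat)
        if per_cat:
            primary[gene] = min(per_cat, key=lambda c: (-per_cat[c], c))
        else:
            primary[gene] = None
    return CategoryAssignment(categories=assigned, primary=primary)


def filter_category_panel(
    assignment: CategoryAssignment,
    selected: list[str],
    min_genes: int = 50,
    dag: GoDag | None = None,
) -> CategoryPanel:
    """Restrict to the selected categories, dropping thinly populated ones.

    ``selected`` entries may be category term ids or term names (names need
    ``dag``). A selected category with fewer than ``min_genes`` member genes
    is dropped with a log entry — mirroring the exclusion of panels whose
    gene counts are too low for effective comparison.
    """
    ids: list[str] = []
    for entry in selected:
        if entry.startswith("GO:"):
            ids.append(entry)
        elif dag is not None:
            try:
                ids.append(dag.id_of_name(entry))
            except KeyError:
                raise ValueError(f"selected category {entry!r} not found in the ontology") from None
        else:
            raise ValueError(f"selected category {entry!r} is not a GO id and no ontology was given")

    genes_by_cat: dict[str, set[str]] = {c: set() for c in ids}
    for gene, cats in assignment.categories.items():
        for c in cats & set(ids):
            genes_by_cat[c].add(gene)

    kept: list[str] = []
    dropped: dict[str, int] = {}
    for c in ids:
        n = len(genes_by_cat[c])
        if n >= min_genes:
            kept.append(c)
        else:
            dropped[c] = n
            logger.warning("category %s dropped from panel: %d gene(s) < min_genes=%d", c, n, min_genes)
    if not kept:
        raise ValueError("all selected categories fell below min_genes; empty panel")
    return CategoryPanel(
        kept=tuple(kept),
        dropped=dropped,
        genes_by_category={c: frozenset(genes_by_cat[c]) for c in kept},
    )
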