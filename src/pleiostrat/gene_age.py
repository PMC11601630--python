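"""Phylostratigraphic gene-age assignment.

A focal-species gene's age is the depth (integer edge count from the root) of
the most recent common ancestor of the focal species and the most distantly
related species that shares an ortholog group with the gene. Lower depth means
the MRCA sits closer to the root, i.e. the gene is *older*. A gene found only
in the focal species gets the focal leaf's own depth — the youngest
assignable age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping
import logging

from .io_formats import OrthologGroupSet, SpeciesTree

logger = logging.getLogger(__name__)

#: exclusion reason codes
NO_GROUP = "no-group"
SPECIES_NOT_ON_TREE = "species-not-on-tree"
EMPTY_AFTER_FILTERING = "empty-after-filtering"


@dataclass
class GeneAgeTable:
    """Assigned ages plus an exclusion ledger with reason codes."""

    ages: dict[str, int]
    n_supporting: dict[str, int]  # species contributing scoreable depths
    excluded: dict[str, str]  # gene id -> reason code
    skipped_species: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.ages)


def compute_depths(tree: SpeciesTree, focal: str) -> dict[str, int]:
    """Root-to-MRCA depth of every leaf species with respect to ``focal``.

    ``depth[focal] == depth of the focal leaf`` (MRCA of a leaf with itself
    is the leaf). Runs in O(n_leaves × tree height).
    """
    try:
        focal_node = tree.node_of(focal)
    except KeyError:
        raise ValueError(f"focal species {focal!r} is not a leaf of the tree") from None
    on_focal_path = {node: tree.depth[node] for node in tree.path_to_root(focal_node)}
    depths: dict[str, int] = {}
    for leaf in tree.leaves:
        node = leaf
        while node not in on_focal_path:
            node = tree.parent[node]  # root is always on the focal path
        depths[tree.leaf_label[leaf]] = on_focal_path[node]
    return depths


def assign_ages(
    groups: OrthologGroupSet,
    depths: Mapping[str, int],
    focal: str,
    gene_universe: Iterable[str] | None = None,
) -> GeneAgeTable:
    """Assign each focal-species gene its minimum root-to-MRCA depth.

    The minimum runs over the species of *all* groups containing the gene
    (the oldest evidence wins). Member species missing from ``depths`` are
    skipped and logged; genes left with no scoreable species are excluded
    with reason ``empty-after-filtering``; genes of ``gene_universe`` that
    appear in no group are excluded with reason ``no-group``.
    """
    if focal not in depths:
        raise ValueError(f"focal species {focal!r} absent from the depth table")
    candidate: dict[str, set[int]] = {}
    skipped_species: set[str] = set()
    for members in groups.groups.values():
        focal_genes = [g for sp, g in members if sp == focal]
        if not focal_genes:
            continue
        member_depths: set[int] = set()
        for sp, _gene in members:
            if sp in depths:
                member_depths.add(depths[sp])
            else:
                skipped_species.add(sp)
        for gene in focal_genes:
            candidate.setdefault(gene, set()).update(member_depths)
    if skipped_species:
        logger.warning(
            "skipped %d species absent from the tree: %s",
            len(skipped_species), sorted(skipped_species)[:5],
        )
    ages: dict[str, int] = {}
    n_supporting: dict[str, int] = {}
    excluded: dict[str, str] = {}
    for gene, ds in candidate.items():
        if ds:
            ages[gene] = min(ds)
            n_supporting[gene] = len(ds)
        else:
            excluded[gene] = EMPTY_AFTER_FILTERING
    if gene_universe is not None:
        for gene in gene_universe:
            if gene not in candidate:
                excluded[gene] = NO_GROUP
    return GeneAgeTable(
        ages=ages,
        n_supporting=n_supporting,
        excluded=excluded,
        skipped_species=frozenset(skipped_species),
    )
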