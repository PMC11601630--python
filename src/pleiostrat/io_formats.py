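"""Readers and writers for the external file formats the pipeline consumes.

The pipeline touches six kinds of input: a rooted species tree (Newick), an
ortholog-group table, a GO biological-process sub-ontology (OBO), gene→GO
annotations, a protein–protein-interaction link table with confidence scores,
and a paralog-count table. Every reader validates its input strictly and logs
(rather than silently drops) anything it has to exclude.

Tabular dialects are deliberately simple tab-separated files with headers:

* ``orthologs.tsv``:   ``group_id  species  gene_id``
* ``annotations.tsv``: ``gene_id  go_id  evidence``
* ``ppi.tsv``:         ``protein1  protein2  combined_score`` (0–1 or 0–1000)
* ``paralogs.tsv``:    ``gene_id  paralog_count``

Newick branch lengths are ignored: the species tree is purely relational, so
every branch is treated as length 1 and node depths are integer edge counts
from the root. OBO support is a minimal subset (``[Term]`` stanzas, ``id``,
``name``, ``namespace``, ``is_a``); relation types other than ``is_a`` are
ignored.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

BP_ROOT = "GO:0008150"
BP_NAMESPACE = "biological_process"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesTree:
    """Rooted species tree with unit branch lengths.

    Nodes are integer ids; ``depth[n]`` is the number of edges from the root
    to ``n``. Polytomies are permitted. Leaf labels (species names) must be
    unique.
    """

    root: int
    parent: Mapping[int, int | None]
    children: Mapping[int, tuple[int, ...]]
    depth: Mapping[int, int]
    leaf_label: Mapping[int, str]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [self.root]:
            raise FormatError(f"tree must have exactly one root, found {roots}")
        labels = list(self.leaf_label.values())
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise FormatError(f"duplicate leaf labels: {dup}")
        if self.depth[self.root] != 0:
            raise FormatError("root depth must be 0")
        for n, p in self.parent.items():
            if p is not None and self.depth[n] != self.depth[p] + 1:
                raise FormatError(f"depth invariant violated at node {n}")

    @property
    def leaves(self) -> tuple[int, ...]:
        return tuple(sorted(self.leaf_label))

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(self.leaf_label[n] for n in self.leaves)

    def node_of(self, label: str) -> int:
        for n, lab in self.leaf_label.items():
            if lab == label:
                return n
        raise KeyError(label)

    def path_to_root(self, node: int) -> list[int]:
        """Nodes from ``node`` up to and including the root."""
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path


def _tree_from_dendropy(dtree: dendropy.Tree) -> SpeciesTree:
    parent: dict[int, int | None] = {}
    children: dict[int, list[int]] = {}
    depth: dict[int, int] = {}
    leaf_label: dict[int, str] = {}
    ids: dict[object, int] = {}
    had_lengths = False
    for i, node in enumerate(dtree.preorder_node_iter()):
        ids[node] = i
        children[i] = []
        if node.edge.length is not None:
            had_lengths = True
        if node.parent_node is None:
            parent[i] = None
            depth[i] = 0
        else:
            p = ids[node.parent_node]
            parent[i] = p
            children[p].append(i)
            depth[i] = depth[p] + 1
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise FormatError("leaf without a species label")
            leaf_label[i] = node.taxon.label
    if had_lengths:
        logger.warning("Newick input carries branch lengths; ignored (all branches treated as length 1)")
    return SpeciesTree(
        root=0,
        parent=parent,
        children={k: tuple(v) for k, v in children.items()},
        depth=depth,
        leaf_label=leaf_label,
    )


def read_newick(path: str | os.PathLike) -> SpeciesTree:
    """Read a rooted Newick species tree, discarding any branch lengths."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="default-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    if not dtree.is_rooted:
        raise FormatError(f"tree in {path} is explicitly unrooted ([&U]); a rooted tree is required")
    return _tree_from_dendropy(dtree)


def parse_newick(newick: str) -> SpeciesTree:
    """Parse a Newick string (convenience wrapper around :func:`read_newick`)."""
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="default-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick string: {exc}") from exc
    return _tree_from_dendropy(dtree)


# ---------------------------------------------------------------------------
# Ortholog groups
# ---------------------------------------------------------------------------


@dataclass
class OrthologGroupSet:
    """Ortholog groups: group id → set of (species, gene id) members."""

    groups: dict[str, frozenset[tuple[str, str]]]
    n_skipped_rows: int = 0

    def genes_of(self, species: str) -> set[str]:
        """All gene ids belonging to ``species`` across all groups."""
        out: set[str] = set()
        for members in self.groups.values():
            out.update(g for sp, g in members if sp == species)
        return out

    def __len__(self) -> int:
        return len(self.groups)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_ortholog_groups(path: str | os.PathLike) -> OrthologGroupSet:
    """Read the tab-separated ortholog-group table.

    Malformed rows (empty group id, species or gene id) are logged and
    skipped; duplicate identical rows collapse to one member.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["group_id", "species", "gene_id"], path)
    bad = (df["group_id"] == "") | (df["species"] == "") | (df["gene_id"] == "")
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed ortholog row(s)", path, n_skipped)
    df = df[~bad]
    groups: dict[str, set[tuple[str, str]]] = {}
    for gid, sp, gene in df[["group_id", "species", "gene_id"]].itertuples(index=False):
        groups.setdefault(gid, set()).add((sp, gene))
    return OrthologGroupSet(
        groups={k: frozenset(v) for k, v in groups.items()},
        n_skipped_rows=n_skipped,
    )


def write_ortholog_groups(groups: OrthologGroupSet, path: str | os.PathLike) -> None:
    rows = [
        (gid, sp, gene)
        for gid in sorted(groups.groups)
        for sp, gene in sorted(groups.groups[gid])
    ]
    pd.DataFrame(rows, columns=["group_id", "species", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GO DAG
# ---------------------------------------------------------------------------


@dataclass
class GoDag:
    """Minimal GO DAG: terms with names/namespaces and ``is_a`` child→parent edges."""

    terms: dict[str, tuple[str, str]]  # id -> (name, namespace)
    parents: dict[str, frozenset[str]]  # id -> is_a parents
    root: str = BP_ROOT

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def name(self, term: str) -> str:
        return self.terms[term][0]

    def namespace(self, term: str) -> str:
        return self.terms[term][1]

    def children_of(self, term: str) -> set[str]:
        return {t for t, ps in self.parents.items() if term in ps}

    def ancestors(self, term: str) -> set[str]:
        """All ``is_a`` ancestors of ``term`` (excluding ``term`` itself)."""
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out

    def id_of_name(self, name: str) -> str:
        for tid, (nm, _) in self.terms.items():
            if nm == name:
                return tid
        raise KeyError(name)


def _dag_from_graph(graph: nx.MultiDiGraph, path) -> GoDag:
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, set[str]] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = (data.get("name", node), data.get("namespace", ""))
        parents.setdefault(node, set())
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    isa = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    try:
        cycle = nx.find_cycle(isa)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        loop = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        raise FormatError(f"{path}: is_a graph contains a cycle: {loop}")
    return GoDag(terms=terms, parents={k: frozenset(v) for k, v in parents.items()})


def read_obo(path: str | os.PathLike) -> GoDag:
    """Read a minimal OBO 1.2 ontology (``[Term]``/id/name/namespace/is_a)."""
    try:
        graph = obonet.read_obo(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc
    return _dag_from_graph(graph, path)


def write_obo(dag: GoDag, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for tid in sorted(dag.terms):
            name, namespace = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\n")
            if namespace:
                fh.write(f"namespace: {namespace}\n")
            for parent in sorted(dag.parents.get(tid, ())):
                fh.write(f"is_a: {parent} ! {dag.terms.get(parent, (parent,))[0]}\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Gene → list of (GO term id, evidence code) annotations."""

    annotations: dict[str, tuple[tuple[str, str], ...]]
    n_dropped_dangling: int = 0

    def genes(self) -> set[str]:
        return set(self.annotations)


def read_annotations(path: str | os.PathLike, dag: GoDag) -> AnnotationSet:
    """Read gene→GO annotations; terms absent from ``dag`` are dropped and logged."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["gene_id", "go_id", "evidence"], path)
    dangling = ~df["go_id"].isin(dag.terms.keys())
    n_dropped = int(dangling.sum())
    if n_dropped:
        logger.warning("%s: dropped %d annotation(s) with GO ids absent from the ontology", path, n_dropped)
    df = df[~dangling]
    ann: dict[str, list[tuple[str, str]]] = {}
    for gene, go, ev in df[["gene_id", "go_id", "evidence"]].itertuples(index=False):
        ann.setdefault(gene, []).append((go, ev))
    return AnnotationSet(
        annotations={g: tuple(v) for g, v in ann.items()},
        n_dropped_dangling=n_dropped,
    )


def write_annotations(ann: AnnotationSet, path: str | os.PathLike) -> None:
    rows = [
        (gene, go, ev)
        for gene in sorted(ann.annotations)
        for go, ev in ann.annotations[gene]
    ]
    pd.DataFrame(rows, columns=["gene_id", "go_id", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------


@dataclass
class PpiNetwork:
    """Undirected PPI network; edge attribute ``confidence`` lies in [0, 1]."""

    graph: nx.Graph

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_ppi(path: str | os.PathLike) -> PpiNetwork:
    """Read a STRING-style link table.

    Scores are auto-detected: any score > 1 means the file uses the 0–1000
    integer scale and every score is divided by 1000. Self-loops are dropped;
    duplicate edges keep the maximum confidence.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})
    _require_columns(df, ["protein1", "protein2", "combined_score"], path)
    scores = pd.to_numeric(df["combined_score"], errors="raise").astype(float)
    if (scores < 0).any():
        raise FormatError(f"{path}: negative combined_score")
    if (scores > 1).any():
        scores = scores / 1000.0
        if (scores > 1).any():
            raise FormatError(f"{path}: combined_score exceeds 1000")
    graph: nx.Graph = nx.Graph()
    n_self = 0
    for (a, b), conf in zip(df[["protein1", "protein2"]].itertuples(index=False), scores):
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            graph[a][b]["confidence"] = max(graph[a][b]["confidence"], conf)
        else:
            graph.add_edge(a, b, confidence=conf)
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    return PpiNetwork(graph=graph)


def write_ppi(net: PpiNetwork, path: str | os.PathLike, scale: int = 1) -> None:
    """Write the network; ``scale=1000`` emits integer 0–1000 scores."""
    rows = []
    for a, b, data in sorted(net.graph.edges(data=True)):
        conf = data["confidence"]
        rows.append((a, b, round(conf * scale) if scale != 1 else conf))
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Paralog counts
# ---------------------------------------------------------------------------


@dataclass
class ParalogTable:
    """Gene id → non-negative paralog count."""

    counts: dict[str, int] = field(default_factory=dict)


def read_paralogs(path: str | os.PathLike) -> ParalogTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    _require_columns(df, ["gene_id", "paralog_count"], path)
    counts = pd.to_numeric(df["paralog_count"], errors="raise")
    if (counts < 0).any():
        bad = df.loc[counts < 0, "gene_id"].iloc[0]
        raise FormatError(f"{path}: negative paralog_count for gene {bad}")
    return ParalogTable(counts=dict(zip(df["gene_id"], counts.astype(int))))


def write_paralogs(table: ParalogTable, path: str | os.PathLike) -> None:
    pd.DataFrame(
        sorted(table.counts.items()), columns=["gene_id", "paralog_count"]
    ).to_csv(path, sep="\t", index=False)
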