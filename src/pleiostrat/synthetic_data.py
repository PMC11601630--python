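"""Synthetic input bundles with planted ground truth.

Generates all six pipeline inputs — species tree, ortholog groups, GO
ontology, annotations, PPI links, paralog counts — from a log-linear model
with a known age effect, category structure and duplication effect, so every
downstream stage can be tested without any database download.

Model. Each gene *i* gets a planted age ``a_i`` (a root-to-MRCA depth on the
focal lineage; 0 = oldest, focal leaf depth = youngest) and a BP count

    bp_i = 1 + Poisson( exp(b0 + b1 * (D - a_i) + sum(category effects) + b_dup * dup_i) )

where ``D`` is the focal leaf depth, so with ``b1 > 0`` the oldest stratum
has the largest mean and every gene carries at least one process. The PPI
degree follows the same log-linear form without the +1 shift. The gene's
ortholog group contains the focal species, one partner species whose MRCA
with the focal leaf sits at exactly depth ``a_i`` (omitted when
``a_i == D``: a species-specific gene), and optional extra members at
equal-or-greater depth — never shallower, so the planted minimum is intact
and age recovery is exact by construction.

PPI confidences avoid the 0.66 threshold: passing edges are sampled from
(0.672, 1.0) and failing noise edges from (0.0, 0.65), so strict and
inclusive threshold readings agree even after rounding to the 0–1000
integer scale. The intended Poisson degree sequence is realized by stub
matching, which can drop a stub (odd total, duplicate pair); the truth table
records the *realized* passing degree, keeping truth and files consistent.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import (
    AnnotationSet, GoDag, OrthologGroupSet, ParalogTable, PpiNetwork, SpeciesTree,
)

import networkx as nx

EVIDENCE_CODES = ("IEA", "EXP", "ISS", "IDA")

CATEGORY_NAMES = (
    "metabolic process",
    "cellular process",
    "developmental process",
    "immune system process",
)


class ConfigError(ValueError):
    """Raised when a synthetic configuration is internally inconsistent."""


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic bundle.

    Defaults give a 12-species caterpillar tree (focal leaf depth 11, all
    depths 0..11 achievable as ages), 2000 genes with ages uniform over
    achievable depths, a positive age effect on both pleiotropy scores, a
    mildly less-pleiotropic metabolic category and more-pleiotropic
    developmental category, and 30% duplicated genes with a positive
    duplication effect.
    """

    n_species: int = 12
    tree_shape: str = "caterpillar"  # balanced | caterpillar | random
    focal: str = "S00"
    n_genes: int = 2000
    age_weights: Mapping[int, float] | None = None  # depth -> weight; None = uniform
    bp_intercept: float = 0.5
    bp_age_slope: float = 0.25
    category_effects: Mapping[str, float] = field(
        default_factory=lambda: {"metabolic process": -0.3, "developmental process": 0.3}
    )
    p_dup: float = 0.3
    dup_effect: float = 0.3
    ppi_intercept: float = 0.8
    ppi_slope: float = 0.15
    n_broad_categories: int = 16
    leaves_per_category: int = 150
    max_categories_per_gene: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ConfigError("n_species must be >= 3")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not 0.0 <= self.p_dup <= 1.0:
            raise ConfigError("p_dup must lie in [0, 1]")
        if self.tree_shape not in ("balanced", "caterpillar", "random"):
            raise ConfigError(f"unknown tree_shape {self.tree_shape!r}")
        if self.n_broad_categories < 1 or self.leaves_per_category < 1:
            raise ConfigError("need at least one category with at least one leaf term")
        if not 1 <= self.max_categories_per_gene <= self.n_broad_categories:
            raise ConfigError("max_categories_per_gene out of range")


@dataclass
class SyntheticBundle:
    """In-memory bundle of the six inputs plus the planted truth."""

    config: SyntheticConfig
    newick: str
    tree: SpeciesTree
    groups: OrthologGroupSet
    dag: GoDag
    annotations: AnnotationSet
    ppi: PpiNetwork
    paralogs: ParalogTable
    truth: pd.DataFrame  # gene_id, true_age, true_bp, true_dup, true_categories, true_ppi


# ---------------------------------------------------------------------------
# Tree shapes (nested-tuple topologies; the generator does its own MRCA math)
# ---------------------------------------------------------------------------


def _topo_caterpillar(labels: list[str]):
    node = (labels[0], labels[1])
    for lab in labels[2:]:
        node = (node, lab)
    return node


def _topo_balanced(labels: list[str]):
    if len(labels) == 1:
        return labels[0]
    mid = len(labels) // 2
    return (_topo_balanced(labels[:mid]), _topo_balanced(labels[mid:]))


def _topo_random(labels: list[str], rng: np.random.Generator):
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def _topo_to_newick(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_topo_to_newick(c) for c in node) + ")"


def _root_paths(node, prefix=()) -> dict[str, tuple]:
    """Leaf label -> tuple of child indices from the root (its own path)."""
    if isinstance(node, str):
        return {node: prefix}
    paths: dict[str, tuple] = {}
    for i, child in enumerate(node):
        paths.update(_root_paths(child, prefix + (i,)))
    return paths


def _mrca_depths(paths: Mapping[str, tuple], focal: str) -> dict[str, int]:
    """Depth of MRCA(species, focal) from common path prefixes."""
    fp = paths[focal]
    out: dict[str, int] = {}
    for sp, p in paths.items():
        k = 0
        while k < min(len(fp), len(p)) and fp[k] == p[k]:
            k += 1
        out[sp] = k if sp != focal else len(fp)
    return out


def build_tree(config: SyntheticConfig, rng: np.random.Generator) -> tuple[str, dict[str, int]]:
    """Newick string and species→MRCA-depth table for the configured shape."""
    labels = [f"S{i:02d}" for i in range(config.n_species)]
    if config.focal not in labels:
        raise ConfigError(f"focal {config.focal!r} not among generated species labels")
    if config.tree_shape == "caterpillar":
        # focal first => it sits on the deepest lineage and all depths 0..n-1 exist
        ordered = [config.focal] + [x for x in labels if x != config.focal]
        topo = _topo_caterpillar(ordered)
    elif config.tree_shape == "balanced":
        topo = _topo_balanced(labels)
    else:
        topo = _topo_random(labels, rng)
    paths = _root_paths(topo)
    return _topo_to_newick(topo) + ";", _mrca_depths(paths, config.focal)


# ---------------------------------------------------------------------------
# Gene-level simulation (no file objects; used by calibration studies too)
# ---------------------------------------------------------------------------


def _category_ids_names(config: SyntheticConfig) -> list[tuple[str, str]]:
    out = []
    for k in range(config.n_broad_categories):
        name = CATEGORY_NAMES[k] if k < len(CATEGORY_NAMES) else f"category {k:02d} process"
        out.append((f"GO:10000{k:02d}", name))
    return out


def simulate_gene_table(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    depths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Draw the per-gene truth table (age, BP count, categories, duplication).

    This is the statistical core of the generator, exposed separately so
    calibration studies can resample gene tables cheaply without building
    ontology/network files. ``depths`` (species → MRCA depth) may be supplied
    to reuse an already-built tree; otherwise the configured tree is built.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if depths is None:
        _, depths = build_tree(config, rng)
    d_focal = depths[config.focal]
    achievable = np.array(sorted(set(depths.values())))
    if config.age_weights is None:
        p = np.full(achievable.size, 1.0 / achievable.size)
    else:
        w = np.array([float(config.age_weights.get(int(a), 0.0)) for a in achievable])
        if w.sum() <= 0:
            raise ConfigError("age_weights assign no mass to any achievable depth")
        p = w / w.sum()
    ages = rng.choice(achievable, size=config.n_genes, p=p)

    cats = _category_ids_names(config)
    name_by_id = dict(cats)
    effect_by_id = {
        cid: float(config.category_effects.get(name, 0.0)) for cid, name in cats
    }
    gene_cats: list[tuple[str, ...]] = []
    for _ in range(config.n_genes):
        k = int(rng.integers(1, config.max_categories_per_gene + 1))
        chosen = rng.choice(len(cats), size=k, replace=False)
        gene_cats.append(tuple(sorted(cats[j][0] for j in chosen)))

    dup = rng.random(config.n_genes) < config.p_dup
    cat_eff = np.array([sum(effect_by_id[c] for c in cc) for cc in gene_cats])
    mu_bp = np.exp(
        config.bp_intercept
        + config.bp_age_slope * (d_focal - ages)
        + cat_eff
        + config.dup_effect * dup
    )
    bp = 1 + rng.poisson(mu_bp)
    mu_ppi = np.exp(config.ppi_intercept + config.ppi_slope * (d_focal - ages))
    ppi_target = rng.poisson(mu_ppi)

    return pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(config.n_genes)],
        "true_age": ages.astype(int),
        "true_bp": bp.astype(int),
        "true_dup": dup.astype(bool),
        "true_categories": [",".join(cc) for cc in gene_cats],
        "category_names": [
            ",".join(name_by_id[c] for c in cc) for cc in gene_cats
        ],
        "ppi_target": ppi_target.astype(int),
    })


# ---------------------------------------------------------------------------
# Full bundle generation
# ---------------------------------------------------------------------------


def _build_dag(config: SyntheticConfig) -> tuple[GoDag, dict[str, list[str]]]:
    terms: dict[str, tuple[str, str]] = {
        iof.BP_ROOT: ("biological_process", iof.BP_NAMESPACE)
    }
    parents: dict[str, frozenset[str]] = {iof.BP_ROOT: frozenset()}
    leaves_by_cat: dict[str, list[str]] = {}
    for k, (cid, name) in enumerate(_category_ids_names(config)):
        terms[cid] = (name, iof.BP_NAMESPACE)
        parents[cid] = frozenset({iof.BP_ROOT})
        leaves = []
        for j in range(config.leaves_per_category):
            lid = f"GO:2{k:02d}{j:04d}"
            terms[lid] = (f"{name} leaf term {j}", iof.BP_NAMESPACE)
            parents[lid] = frozenset({cid})
            leaves.append(lid)
        leaves_by_cat[cid] = leaves
    return GoDag(terms=terms, parents=parents), leaves_by_cat


def generate(config: SyntheticConfig, out_dir: str | os.PathLike | None = None) -> SyntheticBundle:
    """Generate a full input bundle (optionally writing the files to ``out_dir``).

    All randomness flows from ``config.seed`` through per-component child
    seeds (tree, gene table, annotations, PPI), so the same seed yields
    byte-identical files while components stay independently regenerable.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_genes, rng_ann, rng_ppi, rng_groups = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    newick, depths = build_tree(config, rng_tree)
    tree = iof.parse_newick(newick)
    d_focal = depths[config.focal]
    table = simulate_gene_table(config, rng_genes, depths=depths)

    # ortholog groups: focal member + partner at exactly the planted depth +
    # extras at equal-or-greater depth (never shallower)
    by_depth: dict[int, list[str]] = {}
    for sp, d in depths.items():
        if sp != config.focal:
            by_depth.setdefault(d, []).append(sp)
    for d in by_depth:
        by_depth[d].sort()
    groups: dict[str, frozenset[tuple[str, str]]] = {}
    deeper_cache: dict[int, list[str]] = {}
    for row in table.itertuples(index=False):
        gene, age = row.gene_id, int(row.true_age)
        members = {(config.focal, gene)}
        if age < d_focal:
            partner_pool = by_depth[age]
            partner = partner_pool[int(rng_groups.integers(len(partner_pool)))]
            members.add((partner, f"{gene}_{partner}"))
            if age not in deeper_cache:
                deeper_cache[age] = sorted(
                    sp for sp, d in depths.items() if d >= age and sp != config.focal
                )
            pool = [sp for sp in deeper_cache[age] if sp != partner]
            n_extra = int(rng_groups.integers(0, 3))
            if pool and n_extra:
                for j in rng_groups.choice(len(pool), size=min(n_extra, len(pool)), replace=False):
                    members.add((pool[j], f"{gene}_{pool[j]}"))
        groups[f"og{row.gene_id[4:]}"] = frozenset(members)
    group_set = OrthologGroupSet(groups=groups)

    # GO DAG and annotations: true_bp distinct leaf terms from the gene's categories
    dag, leaves_by_cat = _build_dag(config)
    cat_of_leaf = {lid: c for c, ls in leaves_by_cat.items() for lid in ls}
    ann: dict[str, tuple[tuple[str, str], ...]] = {}
    realized_cats: dict[str, str] = {}
    for row in table.itertuples(index=False):
        cats = row.true_categories.split(",")
        pool = [lid for c in cats for lid in leaves_by_cat[c]]
        n = int(row.true_bp)
        if n > len(pool):
            raise ConfigError(
                f"gene {row.gene_id} needs {n} distinct leaf terms but its categories "
                f"offer only {len(pool)}; raise leaves_per_category"
            )
        chosen = rng_ann.choice(len(pool), size=n, replace=False)
        rows = [(pool[j], EVIDENCE_CODES[int(rng_ann.integers(len(EVIDENCE_CODES)))])
                for j in sorted(chosen)]
        if rows and rng_ann.random() < 0.1:  # duplicate entry of the same process
            term, ev = rows[0]
            other = EVIDENCE_CODES[(EVIDENCE_CODES.index(ev) + 1) % len(EVIDENCE_CODES)]
            rows.append((term, other))
        ann[row.gene_id] = tuple(rows)
        # truth records the categories actually represented among the drawn
        # terms: a multi-category gene may draw all its terms from one pool
        realized_cats[row.gene_id] = ",".join(sorted({cat_of_leaf[t] for t, _ in rows}))
    annotations = AnnotationSet(annotations=ann)

    # PPI: stub-match intended degrees into passing edges, add failing noise
    genes = table["gene_id"].tolist()
    targets = table["ppi_target"].to_numpy()
    stubs = np.repeat(np.arange(len(genes)), targets)
    rng_ppi.shuffle(stubs)
    graph: nx.Graph = nx.Graph()
    for a_i, b_i in zip(stubs[0::2], stubs[1::2]):
        if a_i == b_i:
            continue
        a, b = genes[int(a_i)], genes[int(b_i)]
        if graph.has_edge(a, b):
            continue
        graph.add_edge(a, b, confidence=float(rng_ppi.uniform(0.672, 1.0)))
    n_fail = config.n_genes // 10
    for _ in range(n_fail):
        i, j = rng_ppi.integers(0, len(genes), size=2)
        if i == j:
            continue
        a, b = genes[int(i)], genes[int(j)]
        if not graph.has_edge(a, b):
            graph.add_edge(a, b, confidence=float(rng_ppi.uniform(0.0, 0.65)))
    ppi = PpiNetwork(graph=graph)
    realized = {g: 0 for g in genes}
    for a, b, data in graph.edges(data=True):
        if data["confidence"] > 0.66:
            realized[a] += 1
            realized[b] += 1

    # paralogs
    dup = table["true_dup"].to_numpy()
    extra = rng_genes.poisson(1.0, size=len(genes))
    paralog_counts = {
        g: (1 + int(e)) if d else 0 for g, d, e in zip(genes, dup, extra)
    }
    paralogs = ParalogTable(counts=paralog_counts)

    truth = table.drop(columns=["ppi_target", "category_names"]).copy()
    truth["true_categories"] = [realized_cats[g] for g in genes]
    truth["true_ppi"] = [realized[g] for g in genes]

    bundle = SyntheticBundle(
        config=config, newick=newick, tree=tree, groups=group_set, dag=dag,
        annotations=annotations, ppi=ppi, paralogs=paralogs, truth=truth,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SyntheticBundle, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the six input files plus truth.tsv and a config echo; returns paths."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {name: os.path.join(out, fname) for name, fname in [
        ("tree", "tree.nwk"), ("orthologs", "orthologs.tsv"), ("obo", "go.obo"),
        ("annotations", "annotations.tsv"), ("ppi", "ppi.tsv"),
        ("paralogs", "paralogs.tsv"), ("truth", "truth.tsv"), ("config", "config.json"),
    ]}
    with open(paths["tree"], "w") as fh:
        fh.write(bundle.newick + "\n")
    iof.write_ortholog_groups(bundle.groups, paths["orthologs"])
    iof.write_obo(bundle.dag, paths["obo"])
    iof.write_annotations(bundle.annotations, paths["annotations"])
    iof.write_ppi(bundle.ppi, paths["ppi"], scale=1000)
    iof.write_paralogs(bundle.paralogs, paths["paralogs"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = asdict(bundle.config)
    cfg["category_effects"] = dict(bundle.config.category_effects)
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def truth_vs_pipeline_report(truth: pd.DataFrame, features: pd.DataFrame) -> dict[str, float]:
    """Exact-match recovery rates between planted truth and pipeline output.

    Compares age, BP count, duplication flag and category sets gene by gene;
    raises if the two tables cover different gene universes.
    """
    t = truth.set_index("gene_id")
    f = features.set_index("gene_id")
    if set(t.index) != set(f.index):
        raise ValueError("truth and feature tables cover different gene universes")
    f = f.loc[t.index]

    def _catset(s: object) -> frozenset[str]:
        if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
            return frozenset()
        return frozenset(str(s).split(","))

    report = {
        "n_genes": float(len(t)),
        "age_match_rate": float((t["true_age"] == f["age"]).mean()),
        "bp_match_rate": float((t["true_bp"] == f["bp_count"]).mean()),
        "dup_match_rate": float(
            (t["true_dup"].astype(bool) == f["duplicated"].astype(bool)).mean()
        ),
        "category_match_rate": float(np.mean([
            _catset(a) == _catset(b)
            for a, b in zip(t["true_categories"], f["categories"])
        ])),
    }
    return report
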