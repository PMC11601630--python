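"""End-to-end orchestration: files in, per-gene feature table and statistics out.

Stages run in order — input parsing, depth computation, age assignment,
binning, pleiotropy scoring, category mapping, duplication flagging, then the
statistical battery — and every exclusion along the way lands in a ledger
that reconciles against the input gene universe. Optional inputs (PPI links,
paralog counts) degrade gracefully: the analyses that need them are skipped
with a logged notice and everything else is still produced.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import binning as binning_mod
from . import duplication as dup_mod
from . import gene_age, go_classes, io_formats as iof, pleiotropy
from . import stats as stats_mod

logger = logging.getLogger(__name__)

DEFAULT_PANEL = (
    "metabolic process",
    "cellular process",
    "developmental process",
    "immune system process",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and suggests a remedy."""


@dataclass
class RunConfig:
    tree: str
    orthologs: str
    obo: str
    annotations: str
    focal: str
    ppi: str | None = None
    paralogs: str | None = None
    bin_threshold: int = 1000
    ppi_threshold: float = 0.66
    panel: tuple[str, ...] = DEFAULT_PANEL
    min_genes: int = 50
    bootstrap_B: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.bin_threshold < 1:
            raise ValueError("bin_threshold must be >= 1")
        if not 0.0 <= self.ppi_threshold <= 1.0:
            raise ValueError("ppi_threshold must lie in [0, 1]")


@dataclass
class PipelineResult:
    config: RunConfig
    features: pd.DataFrame
    binning: binning_mod.AgeBinning
    age_table: gene_age.GeneAgeTable
    anova: dict[str, stats_mod.AnovaTable]
    bootstrap: pd.DataFrame | None
    bootstrap_disjoint: pd.DataFrame | None
    bin_summaries: dict[str, pd.DataFrame]
    exclusions: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def retained_percent(n_input: int, n_excluded: int) -> int:
    """Retained fraction (n_input − n_excluded) / n_input to the nearest whole percent."""
    if n_input <= 0:
        raise ValueError("n_input must be positive")
    pct = round(100.0 * (n_input - n_excluded) / n_input)
    if pct == 0:
        logger.warning("all genes excluded — check inputs")
    return int(pct)


def report_exclusions(
    excluded: Mapping[str, str], n_input: int
) -> tuple[pd.DataFrame, int]:
    """Per-reason exclusion counts plus the retained whole-percent figure."""
    counts = pd.Series(list(excluded.values()), dtype=str).value_counts() if excluded else pd.Series(dtype=int)
    table = counts.rename_axis("reason").reset_index(name="n_genes")
    return table, retained_percent(n_input, len(excluded))


def _stage(name: str, hint: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc} (hint: {hint})") from exc
            return False

    return _Ctx()


def run_all(config: RunConfig) -> PipelineResult:
    """Execute every stage and (optionally) write all result tables."""
    with _stage("io", "check the input paths and file dialects"):
        tree = iof.read_newick(config.tree)
        groups = iof.read_ortholog_groups(config.orthologs)
        dag = iof.read_obo(config.obo)
        annotations = iof.read_annotations(config.annotations, dag)
        ppi_net = None
        if config.ppi is not None and os.path.exists(config.ppi):
            ppi_net = iof.read_ppi(config.ppi)
        elif config.ppi is not None:
            logger.warning("PPI file %s not found; PPI analyses skipped", config.ppi)
        paralogs = None
        if config.paralogs is not None and os.path.exists(config.paralogs):
            paralogs = iof.read_paralogs(config.paralogs)
        elif config.paralogs is not None:
            logger.warning("paralog file %s not found; duplication analyses skipped", config.paralogs)

    with _stage("gene_age", "is the focal species a leaf of the tree?"):
        depths = gene_age.compute_depths(tree, config.focal)
        universe = groups.genes_of(config.focal)
        ages = gene_age.assign_ages(groups, depths, config.focal, gene_universe=universe)

    with _stage("binning", "at least one gene must receive an age"):
        bins = binning_mod.bin_ages(ages.ages, threshold=config.bin_threshold)

    with _stage("pleiotropy", "annotations must reference the supplied ontology"):
        bp = pleiotropy.bp_count(annotations, dag)
        ppi_counts = (
            pleiotropy.ppi_count(ppi_net, threshold=config.ppi_threshold)
            if ppi_net is not None else None
        )

    with _stage("go_classes", "the ontology must contain the BP root and its children"):
        categories = go_classes.broad_categories(dag)
        assignment = go_classes.assign_categories(annotations, dag, categories)

    dup_status = None
    if paralogs is not None:
        with _stage("duplication", "paralog counts must be non-negative integers"):
            dup_status = dup_mod.flag_duplicates(paralogs, ages.ages.keys())

    with _stage("features", "stage outputs must share the gene-id namespace"):
        rows = []
        for gene in sorted(ages.ages):
            cats = assignment.categories.get(gene, frozenset())
            rows.append({
                "gene_id": gene,
                "age": ages.ages[gene],
                "bin_index": bins.gene_to_bin[gene],
                "bp_count": bp.get(gene, 0),
                "ppi_count": (
                    ppi_counts.get(gene) if ppi_counts is not None else None
                ),
                "categories": ",".join(sorted(cats)),
                "primary_category": assignment.primary.get(gene),
                "paralog_count": (
                    dup_status.paralog_count.get(gene) if dup_status is not None else None
                ),
                "duplicated": (
                    dup_status.duplicated.get(gene) if dup_status is not None else None
                ),
            })
        features = pd.DataFrame(rows)
        features["ppi_count"] = features["ppi_count"].astype("Int64") if len(features) else features.get("ppi_count")
        features["paralog_count"] = features["paralog_count"].astype("Int64") if len(features) else features.get("paralog_count")

    with _stage("stats", "need >= 3 genes with >= 2 distinct ages"):
        anova: dict[str, stats_mod.AnovaTable] = {}
        age_vec = features["age"].to_numpy(float)
        anova["bp_age"] = stats_mod.anova_one_way(features["bp_count"].to_numpy(float), age_vec)

        if ppi_counts is not None:
            has_ppi = features["ppi_count"].notna()
            if has_ppi.sum() >= 3 and features.loc[has_ppi, "age"].nunique() >= 2:
                anova["ppi_age"] = stats_mod.anova_one_way(
                    features.loc[has_ppi, "ppi_count"].to_numpy(float),
                    features.loc[has_ppi, "age"].to_numpy(float),
                )

        bootstrap = bootstrap_disjoint = None
        panel_genes = features[features["primary_category"].notna()]
        try:
            panel = go_classes.filter_category_panel(
                assignment, list(config.panel), min_genes=config.min_genes, dag=dag
            )
            in_panel = panel_genes[panel_genes["primary_category"].isin(panel.kept)]
            if in_panel["primary_category"].nunique() >= 2:
                anova["bp_age_trait"] = stats_mod.anova_two_way_sequential(
                    in_panel["bp_count"].to_numpy(float),
                    in_panel["age"].to_numpy(float),
                    in_panel["primary_category"].to_numpy(),
                    factor_name="Traits",
                )
                groups_for_ci = {
                    dag.name(c): in_panel.loc[in_panel["primary_category"] == c, "bp_count"].to_numpy(float)
                    for c in sorted(in_panel["primary_category"].unique())
                }
                results, bootstrap_disjoint = stats_mod.bootstrap_group_means(
                    groups_for_ci, B=config.bootstrap_B, seed=config.seed
                )
                bootstrap = stats_mod.bootstrap_table(results)
        except ValueError as exc:
            logger.warning("category-panel analyses skipped: %s", exc)

        if dup_status is not None:
            with_dup = features[features["duplicated"].notna()]
            if len(with_dup) >= 3 and with_dup["duplicated"].nunique() == 2:
                anova["bp_age_dup"] = stats_mod.anova_two_way_sequential(
                    with_dup["bp_count"].to_numpy(float),
                    with_dup["age"].to_numpy(float),
                    np.where(with_dup["duplicated"].astype(bool), "duplicated", "singleton"),
                    factor_name="Duplication",
                )

        bin_summaries = {
            "bp": stats_mod.summarize_bins(
                dict(zip(features["gene_id"], features["bp_count"])), bins, "bp_count"
            )
        }
        if ppi_counts is not None:
            ppi_scores = {
                g: (int(v) if pd.notna(v) else None)
                for g, v in zip(features["gene_id"], features["ppi_count"])
            }
            bin_summaries["ppi"] = stats_mod.summarize_bins(ppi_scores, bins, "ppi_count")

    exclusions = pd.DataFrame(
        sorted(ages.excluded.items()), columns=["gene_id", "reason"]
    )
    n_input = len(universe)
    _, retained = report_exclusions(ages.excluded, max(n_input, 1))
    manifest = {
        "package": "pleiostrat",
        "version": __version__,
        "focal": config.focal,
        "seed": config.seed,
        "bin_threshold": config.bin_threshold,
        "ppi_threshold": config.ppi_threshold,
        "n_input_genes": n_input,
        "n_assigned": len(ages.ages),
        "n_excluded": len(ages.excluded),
        "retained_percent": retained,
        "n_bins": len(bins),
        "n_ppi_nodes": len(ppi_net.nodes()) if ppi_net is not None else None,
        "duplication_available": dup_status is not None,
        "anova_tables": sorted(anova),
    }

    result = PipelineResult(
        config=config, features=features, binning=bins, age_table=ages,
        anova=anova, bootstrap=bootstrap, bootstrap_disjoint=bootstrap_disjoint,
        bin_summaries=bin_summaries, exclusions=exclusions, manifest=manifest,
    )
    if config.out_dir is not None:
        write_results(result, config.out_dir)
    return result


def write_results(result: PipelineResult, out_dir: str | os.PathLike) -> None:
    """Write every result table as TSV plus a JSON run manifest."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)

    def _tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(os.path.join(out, name), sep="\t", index=False)

    _tsv(result.features, "gene_features.tsv")
    _tsv(result.exclusions, "exclusions.tsv")
    ages_df = pd.DataFrame(
        [(g, a, result.age_table.n_supporting[g]) for g, a in sorted(result.age_table.ages.items())],
        columns=["gene_id", "age", "n_supporting_species"],
    )
    _tsv(ages_df, "gene_ages.tsv")
    bins_df = pd.DataFrame(
        [(b.index, b.age_values[0], b.age_values[-1], b.n_genes, b.under_threshold)
         for b in result.binning.bins],
        columns=["bin_index", "age_min", "age_max", "n_genes", "under_threshold"],
    )
    _tsv(bins_df, "bins.tsv")
    _tsv(
        pd.DataFrame(sorted(result.binning.gene_to_bin.items()), columns=["gene_id", "bin_index"]),
        "gene_bins.tsv",
    )
    for name, tab in result.anova.items():
        tab.table.rename_axis("Factor").reset_index().to_csv(
            os.path.join(out, f"anova_{name}.tsv"), sep="\t", index=False
        )
    if result.bootstrap is not None:
        _tsv(result.bootstrap, "bootstrap_ci.tsv")
        _tsv(result.bootstrap_disjoint, "bootstrap_disjoint.tsv")
    for score, df in result.bin_summaries.items():
        _tsv(df, f"bin_summary_{score}.tsv")
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
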