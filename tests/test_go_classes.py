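"""Broad-category mapping via is_a ancestor traversal."""

import networkx as nx
import numpy as np
import pytest

import pleiostrat as ps
from pleiostrat.io_formats import AnnotationSet, GoDag, BP_ROOT, BP_NAMESPACE


def layered_dag() -> GoDag:
    """root -> {met, dev}; met -> m1 -> m2; dev -> d1. m2 also is_a d1 (DAG)."""
    ids = {
        "met": "GO:0000100", "dev": "GO:0000200",
        "m1": "GO:0000110", "m2": "GO:0000120", "d1": "GO:0000210",
    }
    terms = {BP_ROOT: ("biological_process", BP_NAMESPACE)}
    terms.update({v: (k, BP_NAMESPACE) for k, v in ids.items()})
    parents = {
        BP_ROOT: frozenset(),
        ids["met"]: frozenset({BP_ROOT}),
        ids["dev"]: frozenset({BP_ROOT}),
        ids["m1"]: frozenset({ids["met"]}),
        ids["m2"]: frozenset({ids["m1"], ids["d1"]}),
        ids["d1"]: frozenset({ids["dev"]}),
    }
    return GoDag(terms=terms, parents=parents)


class TestBroadCategories:
    def test_direct_children_only(self):
        dag = layered_dag()
        assert ps.broad_categories(dag) == {"GO:0000100", "GO:0000200"}

    def test_sixteen_children_in_synthetic_dag(self, bundle_dir):
        _, _, bundle = bundle_dir
        assert len(ps.broad_categories(bundle.dag)) == 16

    def test_missing_root_raises(self):
        dag = layered_dag()
        with pytest.raises(ValueError):
            ps.broad_categories(dag, root="GO:9999999")

    def test_childless_root_gives_empty_set(self):
        dag = GoDag(terms={BP_ROOT: ("bp", BP_NAMESPACE)}, parents={BP_ROOT: frozenset()})
        assert ps.broad_categories(dag) == set()


class TestAssignCategories:
    def test_leaf_term_maps_through_ancestors(self):
        dag = layered_dag()
        ann = AnnotationSet(annotations={"g": (("GO:0000120", "IEA"),)})
        out = ps.assign_categories(ann, dag, ps.broad_categories(dag))
        # m2 reaches met via m1 and dev via d1
        assert out.categories["g"] == frozenset({"GO:0000100", "GO:0000200"})

    def test_root_only_annotation_gets_no_category(self):
        dag = layered_dag()
        ann = AnnotationSet(annotations={"g": ((BP_ROOT, "IEA"),)})
        out = ps.assign_categories(ann, dag, ps.broad_categories(dag))
        assert out.categories["g"] == frozenset()
        assert out.primary["g"] is None

    def test_primary_is_majority_category(self):
        dag = layered_dag()
        # two metabolic-descended terms, one developmental-descended term
        ann = AnnotationSet(annotations={
            "g": (("GO:0000110", "IEA"), ("GO:0000100", "IEA"), ("GO:0000210", "IEA")),
        })
        out = ps.assign_categories(ann, dag, ps.broad_categories(dag))
        assert out.primary["g"] == "GO:0000100"

    def test_primary_tie_breaks_lexicographically(self):
        dag = layered_dag()
        ann = AnnotationSet(annotations={"g": (("GO:0000110", "IEA"), ("GO:0000210", "IEA"))})
        out = ps.assign_categories(ann, dag, ps.broad_categories(dag))
        assert out.primary["g"] == "GO:0000100"  # min id on a 1-1 tie

    def test_adding_annotation_never_removes_categories(self):
        dag = layered_dag()
        cats = ps.broad_categories(dag)
        base = (("GO:0000110", "IEA"),)
        out1 = ps.assign_categories(AnnotationSet(annotations={"g": base}), dag, cats)
        out2 = ps.assign_categories(
            AnnotationSet(annotations={"g": base + (("GO:0000210", "IEA"),)}), dag, cats
        )
        assert out1.categories["g"] <= out2.categories["g"]

    def test_ancestors_match_transitive_closure_oracle_on_random_dags(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            # random DAG: edges only from higher to lower index => acyclic
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for _ in range(n * 2):
                a, b = rng.integers(0, n, 2)
                if a > b:
                    g.add_edge(a, b)  # child a -> parent b
            dag = GoDag(
                terms={f"T{i}": (f"t{i}", BP_NAMESPACE) for i in range(n)},
                parents={
                    f"T{i}": frozenset(f"T{j}" for j in g.successors(i)) for i in range(n)
                },
                root="T0",
            )
            closure = nx.transitive_closure(g)
            for i in range(n):
                expected = {f"T{j}" for j in closure.successors(i)}
                assert dag.ancestors(f"T{i}") == expected


class TestFilterCategoryPanel:
    def _assignment(self, counts: dict[str, int]) -> ps.CategoryAssignment:
        cats = {}
        i = 0
        for cat, n in counts.items():
            for _ in range(n):
                cats[f"g{i}"] = frozenset({cat})
                i += 1
        return ps.CategoryAssignment(categories=cats, primary={g: next(iter(c)) for g, c in cats.items()})

    def test_low_count_category_dropped(self):
        a = self._assignment({"GO:0000100": 500, "GO:0000200": 400, "GO:0000300": 12})
        panel = ps.filter_category_panel(a, ["GO:0000100", "GO:0000200", "GO:0000300"], min_genes=50)
        assert set(panel.kept) == {"GO:0000100", "GO:0000200"}
        assert panel.dropped == {"GO:0000300": 12}

    def test_min_genes_zero_is_identity(self):
        a = self._assignment({"GO:0000100": 3, "GO:0000200": 1})
        panel = ps.filter_category_panel(a, ["GO:0000100", "GO:0000200"], min_genes=0)
        assert set(panel.kept) == {"GO:0000100", "GO:0000200"}

    def test_unknown_name_raises(self):
        a = self._assignment({"GO:0000100": 10})
        with pytest.raises(ValueError, match="not found"):
            ps.filter_category_panel(a, ["no such process"], min_genes=0, dag=layered_dag())

    def test_all_dropped_raises(self):
        a = self._assignment({"GO:0000100": 2})
        with pytest.raises(ValueError, match="empty panel"):
            ps.filter_category_panel(a, ["GO:0000100"], min_genes=10)

    def test_names_resolved_through_dag(self):
        a = self._assignment({"GO:0000100": 60})
        panel = ps.filter_category_panel(a, ["met"], min_genes=50, dag=layered_dag())
        assert panel.kept == ("GO:0000100",)
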