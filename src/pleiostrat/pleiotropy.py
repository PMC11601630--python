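"""Per-gene pleiotropy scores.

Two complementary proxies are computed per gene: the number of distinct GO
biological-process terms it is annotated with (a functional view — each
unique process is a trait the gene affects), and its degree in a
protein–protein-interaction network counting only high-confidence edges
(default: confidence surpassing 0.66). Larger values indicate more
pleiotropy on either scale. No hard pleiotropic/non-pleiotropic cutoff is
applied; downstream analyses work with the full distributions.
"""

from __future__ import annotations

from typing import Mapping

from .io_formats import AnnotationSet, BP_NAMESPACE, GoDag, PpiNetwork


def bp_count(annotations: AnnotationSet, dag: GoDag) -> dict[str, int]:
    """Distinct biological-process term count per gene.

    All evidence codes are retained; repeated annotations of the same term
    count once; terms outside the ``biological_process`` namespace are not
    counted.
    """
    out: dict[str, int] = {}
    for gene, anns in annotations.annotations.items():
        terms = {go for go, _ev in anns if dag.namespace(go) == BP_NAMESPACE}
        out[gene] = len(terms)
    return out


def ppi_count(
    network: PpiNetwork, threshold: float = 0.66, inclusive: bool = False
) -> dict[str, int]:
    """High-confidence PPI degree per network node.

    An edge counts when its confidence is strictly greater than ``threshold``
    ("surpassed"; set ``inclusive`` for ``>=``). Nodes present in the network
    with no passing edge get 0. Genes absent from the network are simply
    absent from the result — missing, not zero — and should be excluded from
    PPI analyses.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    passes = (lambda c: c >= threshold) if inclusive else (lambda c: c > threshold)
    out: dict[str, int] = {node: 0 for node in network.graph.nodes}
    for a, b, data in network.graph.edges(data=True):
        if passes(data["confidence"]):
            out[a] += 1
            out[b] += 1
    return out


def merge_scores(
    bp: Mapping[str, int], ppi: Mapping[str, int]
) -> dict[str, tuple[int, int | None]]:
    """Join the two scores; PPI is ``None`` for genes absent from the network."""
    return {gene: (n_bp, ppi.get(gene)) for gene, n_bp in bp.items()}
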