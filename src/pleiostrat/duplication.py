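"""Duplication status from paralog counts.

A gene with at least one paralog is *duplicated*; zero paralogs makes it a
*singleton*. Genes absent from the paralog table are *missing* — not
singleton — and are excluded (with logging) from duplication analyses,
because absence from the source table means no duplication data, not
evidence of zero paralogs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .io_formats import FormatError, ParalogTable

logger = logging.getLogger(__name__)


@dataclass
class DuplicationStatus:
    paralog_count: dict[str, int]  # only genes present in the table
    duplicated: dict[str, bool]  # paralog_count >= 1
    missing: frozenset[str]

    def n_duplicated(self) -> int:
        return sum(self.duplicated.values())


def flag_duplicates(paralogs: ParalogTable, gene_universe: Iterable[str]) -> DuplicationStatus:
    """Flag each gene of the universe as duplicated / singleton / missing."""
    universe = set(gene_universe)
    counts: dict[str, int] = {}
    flags: dict[str, bool] = {}
    for gene in universe & paralogs.counts.keys():
        n = paralogs.counts[gene]
        if n < 0:
            raise FormatError(f"negative paralog count for gene {gene}")
        counts[gene] = n
        flags[gene] = n >= 1
    missing = universe - paralogs.counts.keys()
    if missing:
        logger.warning(
            "%d gene(s) absent from the paralog table; excluded from duplication analyses",
            len(missing),
        )
    return DuplicationStatus(paralog_count=counts, duplicated=flags, missing=frozenset(missing))
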