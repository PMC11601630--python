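"""Adaptive age binning.

Gene counts per raw age are wildly uneven — ancient strata hold thousands of
genes while recent strata may hold a handful — so raw ages are collapsed,
oldest first, into ordered bins each holding at least a configured number of
genes (default 1000). The trailing youngest bin may fall short of the
threshold; it is kept and flagged so downstream statistics can drop it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping


@dataclass(frozen=True)
class AgeBin:
    index: int
    age_values: tuple[int, ...]  # contiguous run of observed ages, ascending
    n_genes: int
    under_threshold: bool

    @property
    def label(self) -> str:
        return f"{self.age_values[0]}-{self.age_values[-1]}"


@dataclass
class AgeBinning:
    bins: tuple[AgeBin, ...]
    threshold: int
    strict: bool
    gene_to_bin: dict[str, int]

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def oldest(self) -> AgeBin:
        return self.bins[0]

    @property
    def youngest(self) -> AgeBin:
        return self.bins[-1]


def bin_ages(ages: Mapping[str, int], threshold: int = 1000, strict: bool = False) -> AgeBinning:
    """Greedily collapse ages (oldest → youngest) into bins of ≥ ``threshold`` genes.

    Distinct observed ages are scanned in ascending depth order (depth 0 is
    the root, hence oldest). Ages accumulate into the current bin until its
    gene count reaches the threshold (``>=``, or strictly ``>`` when
    ``strict``); the bin then closes and a new one starts. The final bin is
    kept even when under-threshold, flagged as such.
    """
    if not ages:
        raise ValueError("cannot bin an empty age table")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = Counter(ages.values())
    distinct = sorted(counts)
    closes = (lambda n: n > threshold) if strict else (lambda n: n >= threshold)

    bins: list[AgeBin] = []
    current: list[int] = []
    n_current = 0
    for age in distinct:
        current.append(age)
        n_current += counts[age]
        if closes(n_current):
            bins.append(AgeBin(len(bins), tuple(current), n_current, under_threshold=False))
            current, n_current = [], 0
    if current:
        bins.append(AgeBin(len(bins), tuple(current), n_current,
                           under_threshold=not closes(n_current)))

    age_to_bin = {age: b.index for b in bins for age in b.age_values}
    gene_to_bin = {gene: age_to_bin[age] for gene, age in ages.items()}
    return AgeBinning(bins=tuple(bins), threshold=threshold, strict=strict,
                      gene_to_bin=gene_to_bin)
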