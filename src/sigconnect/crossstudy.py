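"""Identifier harmonisation and k-way DEG-list intersection.

The "Venn diagram approach" to cross-study comparison: map each platform's
probesets to gene identifiers, restrict every study's DEG list to the gene
universe measurable on all platforms, and count the genes in every region of
the k-way Venn diagram.  Kept deliberately simple — it is the baseline the
enrichment-based connectivity score is designed to improve on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PlatformMap", "VennReport", "common_universe", "venn_counts",
           "consensus_list"]


@dataclass(frozen=True)
class PlatformMap:
    """Probeset -> gene mapping for one array platform.

    ``rows`` is a sequence of (probeset_id, gene_id) pairs; a probeset mapped
    to several genes appears once per gene (multi-mapping is expanded, with a
    warning at construction from tables).
    """

    platform_name: str
    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple((str(p), str(g))
                                               for p, g in self.rows))
        probes_genes = set(self.rows)
        if len(probes_genes) != len(self.rows):
            raise ValueError(
                f"platform {self.platform_name!r}: duplicate (probeset, gene) rows"
            )

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "PlatformMap":
        """Build from a table with ``probeset_id`` and ``gene_id`` columns;
        multi-mapped probesets are expanded to all their genes."""
        multi = frame["probeset_id"].duplicated().sum()
        if multi:
            logger.warning(
                "platform %s: %d probesets map to multiple genes; expanded",
                name, multi,
            )
        rows = list(zip(frame["probeset_id"], frame["gene_id"]))
        return cls(name, tuple(rows))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.rows)


@dataclass(frozen=True)
class VennReport:
    """Exact region counts of a k-way Venn diagram over a gene universe."""

    study_names: tuple[str, ...]
    universe_size: int
    region_counts: dict[frozenset, int]
    per_study_totals: dict[str, int]
    n_dropped_outside_universe: int

    @property
    def k(self) -> int:
        return len(self.study_names)

    @property
    def all_studies_count(self) -> int:
        return self.region_counts.get(frozenset(self.study_names), 0)

    def to_frame(self) -> pd.DataFrame:
        """Region table with one binary membership column per study."""
        rows = []
        for region, count in sorted(
            self.region_counts.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
        ):
            row = {name: int(name in region) for name in self.study_names}
            row["mask"] = "".join(str(int(n in region)) for n in self.study_names)
            row["count"] = count
            rows.append(row)
        return pd.DataFrame(rows)


def common_universe(maps: Sequence[PlatformMap]) -> frozenset[str]:
    """Gene identifiers measurable on every platform."""
    if len(maps) < 2:
        raise ValueError("need at least 2 platform maps")
    universe = reduce(lambda a, b: a & b, (m.genes for m in maps))
    if not universe:
        raise ValueError(
            "no gene identifier is common to all platforms: "
            + ", ".join(m.platform_name for m in maps)
        )
    return frozenset(universe)


def venn_counts(
    lists: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> VennReport:
    """Classify every gene in the union of the lists by its membership vector.

    Genes outside ``universe`` are dropped (counted in the report); the
    remaining regions are disjoint and sum to the size of the restricted
    union.  Order of studies does not affect region contents.
    """
    names = tuple(lists.keys())
    if not 2 <= len(names) <= 6:
        raise ValueError("venn_counts supports 2 to 6 studies")
    uni = frozenset(universe)
    sets = {name: frozenset(genes) & uni for name, genes in lists.items()}
    dropped = sum(len(frozenset(genes) - uni) for genes in lists.values())
    union = reduce(lambda a, b: a | b, sets.values(), frozenset())
    region_counts: dict[frozenset, int] = {}
    for gene in union:
        region = frozenset(n for n in names if gene in sets[n])
        region_counts[region] = region_counts.get(region, 0) + 1
    return VennReport(
        study_names=names,
        universe_size=len(uni),
        region_counts=region_counts,
        per_study_totals={n: len(sets[n]) for n in names},
        n_dropped_outside_universe=dropped,
    )


def consensus_list(lists: Mapping[str, Iterable[str]] | Sequence[Iterable[str]]
                   ) -> list[str]:
    """Genes present in every list, in deterministic lexicographic order."""
    if isinstance(lists, Mapping):
        collections = list(lists.values())
    else:
        collections = list(lists)
    if len(collections) < 2:
        raise ValueError("need at least 2 lists")
    common = reduce(lambda a, b: a & b, (frozenset(c) for c in collections))
    return sorted(common)
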