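"""Domain types for rankings, gene sets and up/down DEG signatures.

A :class:`RankedList` is a gene list ordered by a signed score (log2 fold
change in the typical use); a :class:`GeneSet` is an unordered collection of
gene identifiers; a :class:`DEGSignature` pairs an up-regulated and a
down-regulated set from one published study.  These are the substrates of the
enrichment and connectivity machinery.

Probeset-level score tables are collapsed to gene level by keeping, for each
gene, the probeset with the largest fold change; because "largest" is
ambiguous for down-regulated genes, both a signed and an absolute-value
reading are provided, with absolute value (sign preserved) as the default so
that strongly down-regulated genes are not masked by a weakly up-regulated
probeset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "DEGSignature",
    "RankedList",
    "CollapseResult",
    "collapse_probesets",
    "build_ranked_list",
    "load_signature",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, unordered collection of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def size(self) -> int:
        return len(self.members)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        """Restrict to a gene universe (identifiers outside it are dropped)."""
        return GeneSet(self.name, self.members & frozenset(universe))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass(frozen=True)
class DEGSignature:
    """Paired up/down differentially-expressed-gene sets from one study.

    The up and down sets are disjoint by construction; use
    :func:`load_signature` to build one from possibly-overlapping lists.
    """

    study_name: str
    up: GeneSet
    down: GeneSet
    conflicting: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        overlap = self.up.members & self.down.members
        if overlap:
            raise ValueError(
                f"signature {self.study_name!r}: up and down sets overlap "
                f"({len(overlap)} genes, e.g. {sorted(overlap)[:3]})"
            )

    @property
    def degenerate(self) -> bool:
        return self.up.size == 0 or self.down.size == 0


class RankedList:
    """Genes ordered by a signed score, strictly non-increasing.

    Parameters
    ----------
    genes, scores
        Parallel sequences; ``genes`` must be unique and ``scores`` sorted in
        non-increasing order.  Use :func:`build_ranked_list` to construct one
        from an unordered gene -> score mapping.
    """

    def __init__(self, genes: Sequence[str], scores: Sequence[float]):
        genes = tuple(str(g) for g in genes)
        scores = np.asarray(scores, dtype=float)
        if len(genes) != scores.size:
            raise ValueError("genes and scores must have equal length")
        if len(genes) < 2:
            raise ValueError("a ranked list needs at least 2 genes")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene identifiers in ranked list")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be non-increasing")
        self.genes = genes
        self.scores = scores
        self._index = {g: i for i, g in enumerate(genes)}

    @property
    def n(self) -> int:
        """Universe size N."""
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def positions_of(self, members: Iterable[str]) -> tuple[np.ndarray, int]:
        """Sorted rank positions of ``members``; genes absent from the
        universe are dropped (GSEA convention) and their count returned."""
        idx = [self._index[g] for g in members if g in self._index]
        n_dropped = sum(1 for g in members if g not in self._index)
        return np.sort(np.asarray(idx, dtype=np.intp)), n_dropped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores})

    def __repr__(self) -> str:  # pragma: no cover
        return f"RankedList(n={self.n}, top={self.genes[0]!r}:{self.scores[0]:.3g})"


@dataclass(frozen=True)
class CollapseResult:
    """Gene-level scores after probeset collapse, with bookkeeping."""

    scores: dict[str, float]
    n_unmapped: int
    n_multi: int


def collapse_probesets(
    table: pd.DataFrame, method: str = "abs"
) -> CollapseResult:
    """Collapse a probeset-level score table to one score per gene.

    ``table`` needs columns ``probeset_id``, ``gene_id`` and ``score``.  For
    genes represented by several probesets the retained score is the one with
    the largest absolute value, sign preserved (``method="abs"``, default),
    or the largest signed value (``method="signed"``).  Probesets with a
    missing gene identifier are dropped and counted.
    """
    if method not in ("abs", "signed"):
        raise ValueError(f"unknown collapse method {method!r}")
    if table is None or len(table) == 0:
        raise ValueError("probeset table is empty")
    required = {"probeset_id", "gene_id", "score"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"probeset table lacks columns {sorted(missing)}")
    if table["probeset_id"].duplicated().any():
        raise ValueError("duplicate probeset_id in table")

    mapped = table.dropna(subset=["gene_id"])
    mapped = mapped[mapped["gene_id"].astype(str).str.len() > 0]
    n_unmapped = len(table) - len(mapped)
    if len(mapped) == 0:
        raise ValueError(
            "no probeset maps to a gene: the gene_id mapping covers none of "
            f"the {len(table)} probesets"
        )
    scores = mapped["score"].astype(float)
    if method == "abs":
        order = scores.abs()
    else:
        order = scores
    picked = (
        mapped.assign(_key=order)
        .sort_values(["_key", "probeset_id"], ascending=[False, True])
        .drop_duplicates("gene_id", keep="first")
    )
    n_multi = int((mapped["gene_id"].value_counts() > 1).sum())
    out = dict(zip(picked["gene_id"].astype(str), picked["score"].astype(float)))
    if n_unmapped:
        logger.info("collapse_probesets: dropped %d unmapped probesets", n_unmapped)
    return CollapseResult(scores=out, n_unmapped=n_unmapped, n_multi=n_multi)


def build_ranked_list(scores: Mapping[str, float]) -> RankedList:
    """Order a gene -> score mapping into a :class:`RankedList`.

    Descending by score; ties broken lexicographically by gene identifier so
    the ranking is deterministic across runs.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 genes to build a ranked list")
    items = sorted(scores.items(), key=lambda kv: (-float(kv[1]), kv[0]))
    genes = [g for g, _ in items]
    vals = [float(v) for _, v in items]
    return RankedList(genes, vals)


def load_signature(
    up_genes: Iterable[str],
    down_genes: Iterable[str],
    study_name: str,
) -> DEGSignature:
    """Build a :class:`DEGSignature`, enforcing up/down disjointness.

    Genes appearing in both lists are removed from both and reported on the
    returned signature's ``conflicting`` field.
    """
    up = frozenset(str(g) for g in up_genes)
    down = frozenset(str(g) for g in down_genes)
    if not up and not down:
        raise ValueError(f"signature {study_name!r}: both gene lists are empty")
    conflicts = up & down
    if conflicts:
        logger.warning(
            "signature %r: %d genes appear in both directions and were "
            "removed from both", study_name, len(conflicts)
        )
    return DEGSignature(
        study_name=study_name,
        up=GeneSet(f"{study_name} - UP", up - conflicts),
        down=GeneSet(f"{study_name} - Down", down - conflicts),
        conflicting=conflicts,
    )
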