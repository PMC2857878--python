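"""Readers and writers for the plain-text formats of the pipeline.

GMT (gene-set collections), RNK (ranked gene scores), GCT 1.2 (expression
matrices), plus the small TSVs used here: DEG signatures
(``gene<TAB>direction``), pairing files
(``patient<TAB>lesional<TAB>nonlesional``) and probeset maps.  All writers
emit ``#``-prefixed provenance headers (version, seed, parameters) that all
readers skip, so every artifact round-trips.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .crossstudy import PlatformMap
from .de import PairedExpressionMatrix
from .signatures import (
    DEGSignature,
    GeneSet,
    RankedList,
    build_ranked_list,
    load_signature,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt", "write_gmt", "read_rnk", "write_rnk",
    "read_signature", "write_signature", "read_gct", "write_gct",
    "read_pairing", "write_pairing", "read_platform_map",
    "provenance_header", "write_table",
]


def provenance_header(**params) -> list[str]:
    """Provenance lines recorded at the top of every output file."""
    from . import __version__

    lines = [f"# sigconnect {__version__}"]
    for key, value in params.items():
        lines.append(f"# {key}: {value}")
    return lines


def write_table(frame: pd.DataFrame, path, index: bool = False, **params) -> None:
    """TSV writer with a provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_header(**params):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=index)


def _data_lines(path) -> list[tuple[int, str]]:
    out = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    return out


def read_gmt(path) -> list[GeneSet]:
    """GMT: one gene set per line, ``name<TAB>description<TAB>member...``."""
    sets: list[GeneSet] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and at "
                f"least one member ({len(fields)} fields found)"
            )
        name, _desc, *members = fields
        members = [m for m in members if m]
        if len(set(members)) != len(members):
            logger.warning("%s:%d: duplicate members in set %r deduplicated",
                           path, lineno, name)
        sets.append(GeneSet(name, members))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Sequence[GeneSet], path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.members)]) + "\n")


def read_rnk(path) -> RankedList:
    """RNK: ``gene<TAB>score`` per line, ``#`` comments ignored.

    The file's order is not trusted: scores are re-ranked (descending,
    lexicographic tie-break) so the result satisfies the RankedList
    invariants regardless of input order.
    """
    scores: dict[str, float] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        gene, raw_score = fields
        try:
            score = float(raw_score)
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: non-numeric score {raw_score!r}"
            ) from exc
        if gene in scores:
            raise ValueError(f"{path}:{lineno}: duplicate gene {gene!r}")
        scores[gene] = score
    return build_ranked_list(scores)


def write_rnk(ranked: RankedList, path, **params) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_header(**params):
            fh.write(line + "\n")
        for gene, score in zip(ranked.genes, ranked.scores):
            fh.write(f"{gene}\t{score:.10g}\n")


def read_signature(path, study_name: str | None = None) -> DEGSignature:
    """Signature TSV: ``gene<TAB>direction`` with direction in {up, down}."""
    up: list[str] = []
    down: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        gene, direction = fields
        d = direction.strip().lower()
        if d == "up":
            up.append(gene)
        elif d == "down":
            down.append(gene)
        elif d == "direction" and gene.strip().lower() == "gene":
            continue  # tolerated column-header line
        else:
            raise ValueError(
                f"{path}:{lineno}: direction must be 'up' or 'down', got "
                f"{direction!r}"
            )
    name = study_name or Path(path).stem
    return load_signature(up, down, name)


def write_signature(signature: DEGSignature, path, **params) -> None:
    with Path(path).open("w") as fh:
        for line in provenance_header(study=signature.study_name, **params):
            fh.write(line + "\n")
        for gene in sorted(signature.up.members):
            fh.write(f"{gene}\tup\n")
        for gene in sorted(signature.down.members):
            fh.write(f"{gene}\tdown\n")


def read_gct(path) -> pd.DataFrame:
    """GCT 1.2 expression matrix -> DataFrame (features x samples)."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"{path}: not a GCT 1.2 file (first line {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    frame = frame.drop(columns=["Description"], errors="ignore")
    if frame.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: dimension line says {n_rows}x{n_cols}, "
            f"found {frame.shape[0]}x{frame.shape[1]}"
        )
    frame.index.name = "Name"
    return frame.astype(float)


def write_gct(values: pd.DataFrame, path,
              descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        out = values.copy()
        desc = [descriptions.get(i, "na") if descriptions else "na"
                for i in out.index]
        out.insert(0, "Description", desc)
        out.index.name = "Name"
        out.to_csv(fh, sep="\t")


def read_pairing(path) -> list[tuple[str, str, str]]:
    """Pairing TSV: ``patient<TAB>lesional_sample<TAB>nonlesional_sample``."""
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        if fields[0].strip().lower() == "patient":
            continue
        pairs.append((fields[0], fields[1], fields[2]))
    if not pairs:
        raise ValueError(f"{path}: no pairs found")
    return pairs


def write_pairing(pairs: Iterable[tuple[str, str, str]], path, **params) -> None:
    with Path(path).open("w") as fh:
        for line in provenance_header(**params):
            fh.write(line + "\n")
        fh.write("patient\tlesional_sample\tnonlesional_sample\n")
        for patient, les, non in pairs:
            fh.write(f"{patient}\t{les}\t{non}\n")


def read_platform_map(path, platform_name: str | None = None) -> PlatformMap:
    """Probeset map TSV: ``probeset_id<TAB>gene_id`` (header tolerated)."""
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        if fields[0].strip().lower() in ("probeset_id", "probeset"):
            continue
        rows.append((fields[0], fields[1]))
    if not rows:
        raise ValueError(f"{path}: empty platform map")
    frame = pd.DataFrame(rows, columns=["probeset_id", "gene_id"])
    return PlatformMap.from_frame(platform_name or Path(path).stem, frame)


def matrix_from_files(expr_path, pairing_path) -> PairedExpressionMatrix:
    """Load a paired matrix from a GCT/TSV expression file and a pairing TSV."""
    expr_path = Path(expr_path)
    with expr_path.open() as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        values = read_gct(expr_path)
    else:
        values = pd.read_csv(expr_path, sep="\t", index_col=0, comment="#")
    return PairedExpressionMatrix(values, read_pairing(pairing_path))
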