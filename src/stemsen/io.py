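"""Readers and writers for the pipeline's plain-text and image formats.

Tabular data travels as TSV, gene lists as newline-delimited text,
annotation sets as GMT or two-column TSV, ROIs as JSON, and images as
single-channel 16-bit grayscale TIFF. Every reader validates its schema and
reports malformed rows with 1-based line numbers; read(write(x)) round-trips
for all tabular and JSON formats.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .enrichment import AnnotationSet
from .fpkm import ExpressionMatrix
from .imaging import RoiSpec
from .lifespan import PassageRecord

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_colony_tsv",
    "write_colony_tsv",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_annotation_tsv",
    "read_roi_json",
    "write_roi_json",
    "read_tiff",
    "write_tiff",
    "write_json",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A malformed input file; the message carries the offending line number."""


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a long-form FPKM table: feature_id, culture_id, status, t0..tK."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "culture_id": str},
                     float_precision="round_trip")
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    for col in tcols:
        bad = df.index[df[col].astype(float) < 0]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"{path}: negative FPKM in column {col} at line {bad[0] + 2}"
            )
    try:
        return ExpressionMatrix(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    cols = ["feature_id", "culture_id", "status", *matrix.time_columns]
    matrix.data[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


_COLONY_COLS = ["culture_id", "passage", "inoculum", "cfe", "cell_yield", "aborted_fraction"]


def read_colony_tsv(path: str | Path) -> list[PassageRecord]:
    """Read passage records: culture_id, passage, inoculum, cfe, cell_yield, aborted_fraction."""
    df = pd.read_csv(path, sep="\t", dtype={"culture_id": str},
                     float_precision="round_trip")
    missing = set(_COLONY_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PassageRecord(
                    culture_id=row["culture_id"],
                    passage=int(row["passage"]),
                    inoculum=float(row["inoculum"]),
                    cfe=float(row["cfe"]),
                    cell_yield=float(row["cell_yield"]),
                    aborted_fraction=float(row["aborted_fraction"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {idx + 2}: {exc}") from exc
    return records


def write_colony_tsv(records: Sequence[PassageRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "culture_id": r.culture_id,
                "passage": r.passage,
                "inoculum": r.inoculum,
                "cfe": r.cfe,
                "cell_yield": r.cell_yield,
                "aborted_fraction": r.aborted_fraction,
            }
            for r in records
        ],
        columns=_COLONY_COLS,
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_list(path: str | Path) -> list[str]:
    """Newline-delimited gene labels; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            genes.append(token)
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gmt(path: str | Path) -> list[AnnotationSet]:
    """GMT: term_id <tab> description <tab> member genes. Duplicates are dropped."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: GMT rows need >= 3 tab-separated fields")
        term_id, name, *members = parts
        members = [m for m in members if m]
        if len(members) != len(set(members)):
            logger.warning("%s: line %d: duplicate members in %s deduplicated", path, lineno, term_id)
        sets.append(AnnotationSet(term_id=term_id, term_name=name, members=frozenset(members)))
    return sets


def write_gmt(sets: Sequence[AnnotationSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.term_id, s.term_name, *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


def read_annotation_tsv(path: str | Path) -> list[AnnotationSet]:
    """Two-column TSV (gene <tab> term), aggregated into annotation sets."""
    by_term: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 'gene<TAB>term'")
        gene, term = parts
        by_term.setdefault(term, set()).add(gene)
    return [
        AnnotationSet(term_id=t, term_name=t, members=frozenset(m))
        for t, m in sorted(by_term.items())
    ]


def read_roi_json(path: str | Path) -> list[RoiSpec]:
    payload = json.loads(Path(path).read_text())
    items = payload if isinstance(payload, list) else payload.get("rois", [])
    return [RoiSpec.from_dict(d) for d in items]


def write_roi_json(rois: Sequence[RoiSpec], path: str | Path) -> None:
    write_json([r.to_dict() for r in rois], path)


def read_tiff(path: str | Path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2-D image, got shape {img.shape}")
    return img


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
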