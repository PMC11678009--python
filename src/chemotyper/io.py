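"""Readers and writers for the tabular formats the pipeline consumes.

Wide abundance matrices, sample metadata and annotation tables are plain
TSV/CSV (delimiter chosen from the file extension: ``.csv`` is comma,
anything else tab).  Metabolite sets use the GMT convention: one set per
line, ``set_id <tab> description <tab> member ids...``.

Missing abundances are written as empty cells and parsed from empty
cells or the string ``NA`` — never silently coerced to zero.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datamodel import (
    MetaboliteAnnotation,
    MetaboliteSetCollection,
    MetaboliteTable,
    SampleMetadata,
    TableState,
    ValidationError,
)

__all__ = [
    "load_dataset",
    "load_metabolite_sets",
    "write_table",
    "write_gmt",
    "read_matrix",
    "read_metadata",
]

_NA_VALUES = ["", "NA"]

#: significant digits used when serialising floats
FLOAT_FORMAT = "%.6g"

PathLike = Union[str, os.PathLike]


def _sep_for(path: PathLike) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_frame(path: PathLike) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=_NA_VALUES,
        keep_default_na=False,
    )


def _check_header_duplicates(path: PathLike) -> None:
    # pandas mangles duplicated header names; inspect the raw header instead
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise ValidationError(f"duplicated metabolite id: {name!r}")
        seen.add(name)


def read_matrix(path: PathLike, state: TableState = TableState.RAW) -> MetaboliteTable:
    """Read a wide abundance matrix (samples in rows, metabolites in columns)."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    _check_header_duplicates(path)
    df = _read_frame(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric abundance value in {path}: {exc}") from exc
    return MetaboliteTable(df, state)


def read_metadata(path: PathLike) -> SampleMetadata:
    """Read a sample-metadata table on its own."""
    return SampleMetadata(_read_frame(path))


def load_dataset(
    matrix_path: PathLike,
    metadata_path: PathLike,
    annotation_path: PathLike | None = None,
) -> tuple[MetaboliteTable, SampleMetadata, MetaboliteAnnotation]:
    """Load and cross-validate an abundance matrix with its sample metadata.

    The matrix header row holds metabolite ids and the first column holds
    sample ids.  A transposed matrix (metabolites in rows) is detected by
    cross-referencing ids against the metadata and rejected with a hint
    rather than silently auto-transposed.
    """
    table = read_matrix(matrix_path)
    metadata = SampleMetadata(_read_frame(metadata_path))

    meta_ids = set(metadata.sample_ids)
    if not meta_ids.intersection(table.sample_ids) and meta_ids.intersection(
        table.metabolite_ids
    ):
        raise ValidationError(
            "matrix rows do not match metadata sample ids but columns do: "
            "the matrix appears transposed (expected samples in rows)"
        )
    metadata.validate_against(table)

    if annotation_path is not None:
        annotation = MetaboliteAnnotation(_read_frame(annotation_path))
    else:
        annotation = MetaboliteAnnotation.empty(table.metabolite_ids)
    return table, metadata, annotation


def load_metabolite_sets(path: PathLike) -> MetaboliteSetCollection:
    """Parse a GMT file into a :class:`MetaboliteSetCollection`.

    Membership order and set order follow the file.
    """
    if not Path(path).exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise ValidationError(
                    f"malformed GMT line {lineno}: expected "
                    "set_id, description and at least one member"
                )
            set_id, description = parts[0], parts[1]
            members = [p for p in parts[2:] if p.strip()]
            if set_id in sets:
                raise ValidationError(f"duplicated set id {set_id!r} at line {lineno}")
            sets[set_id] = members
            descriptions[set_id] = description
    return MetaboliteSetCollection(sets, descriptions)


def write_gmt(sets: MetaboliteSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sets:
            fh.write(
                "\t".join([set_id, sets.description(set_id), *sets[set_id]]) + "\n"
            )


def _frame_of(obj) -> pd.DataFrame:
    if isinstance(obj, MetaboliteTable):
        return obj.values
    if isinstance(obj, (SampleMetadata, MetaboliteAnnotation)):
        return obj.frame
    if isinstance(obj, pd.DataFrame):
        return obj
    raise TypeError(f"cannot serialise object of type {type(obj).__name__}")


def write_table(obj, path: PathLike) -> None:
    """Write a tabular result deterministically (fixed column order, 6 s.d.).

    Missing values become empty cells, so a write/load round trip
    preserves the count of missing entries.
    """
    df = _frame_of(obj)
    df.to_csv(
        path,
        sep=_sep_for(path),
        float_format=FLOAT_FORMAT,
        na_rep="",
        lineterminator="\n",
    )
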