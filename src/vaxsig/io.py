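"""Readers and writers for the delimited-text formats the pipeline touches.

Formats: GMT gene-set collections (Broad dialect: name, description,
members, tab-separated), expression matrices as TSV with feature IDs in the
first column and sample IDs in the header, and sample tables as TSV with
the fixed column set ``sample_id, subject_id, timepoint, group, pair_key``.
Round-trips are lossless for IDs, order and values; below-detection cells
are written back as the literal marker (default ``#``).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
    ValidationError,
)

BELOW_DETECTION_MARKER = "#"


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line is ``name<TAB>description<TAB>member...``; duplicate members
    within a line are dropped, duplicate set names are an error. The
    description field is retained as provenance.
    """
    sets: dict[str, frozenset[str]] = {}
    provenance: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *members = fields
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            sets[name] = frozenset(members)
            provenance[name] = description
    return GeneSetCollection(sets=sets, provenance=provenance)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.provenance.get(name, "")
            members = sorted(collection[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_matrix(
    path: str | Path,
    assay_kind: str,
    sep: str = "\t",
    below_detection_marker: str = BELOW_DETECTION_MARKER,
) -> ExpressionMatrix:
    """Read a features-in-rows delimited matrix.

    Cells equal to ``below_detection_marker`` (or empty) are recorded in the
    below-detection mask and given a placeholder value of NaN until imputed;
    any other non-numeric cell is an error naming its row/column address.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        sample_ids = [h.strip() for h in header[1:]]
        if len(set(sample_ids)) != len(sample_ids):
            raise ParseError(f"{path}: duplicate sample ID in header")
        feature_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        mask_rows: list[list[bool]] = []
        for lineno, record in enumerate(reader, start=2):
            if not record or (len(record) == 1 and not record[0].strip()):
                continue
            fid = record[0].strip()
            if fid in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate feature ID {fid!r}")
            seen.add(fid)
            if len(record) != len(sample_ids) + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(record)}"
                )
            vals: list[float] = []
            mask: list[bool] = []
            for col, cell in enumerate(record[1:]):
                cell = cell.strip()
                if cell == below_detection_marker or cell == "":
                    vals.append(np.nan)
                    mask.append(True)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at feature {fid!r}, "
                        f"sample {sample_ids[col]!r}"
                    ) from None
                mask.append(False)
            feature_ids.append(fid)
            rows.append(vals)
            mask_rows.append(mask)
    values = np.array(rows, dtype=float).reshape(len(feature_ids), len(sample_ids))
    mask_arr = np.array(mask_rows, dtype=bool).reshape(values.shape)
    return ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=values,
        assay_kind=assay_kind,
        below_detection=mask_arr if mask_arr.any() else None,
    )


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    sep: str = "\t",
    below_detection_marker: str = BELOW_DETECTION_MARKER,
) -> None:
    """Write a matrix as delimited text; masked cells become the marker.

    Round-trip property: ``read_matrix(write_matrix(m))`` reproduces IDs,
    order, values and the below-detection mask exactly (values are written
    with ``repr`` so floats survive untouched).
    """
    with open(path, "w") as fh:
        fh.write(sep.join(["feature_id", *matrix.sample_ids]) + "\n")
        mask = matrix.below_detection
        for i, fid in enumerate(matrix.feature_ids):
            cells = [fid]
            for j in range(matrix.n_samples):
                if mask is not None and mask[i, j]:
                    cells.append(below_detection_marker)
                else:
                    cells.append(_format_number(matrix.values[i, j]))
            fh.write(sep.join(cells) + "\n")


def read_sample_table(path: str | Path, sep: str = "\t") -> SampleTable:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = df.replace({"pair_key": {"": None}})
    if "pair_key" in df.columns:
        df["pair_key"] = df["pair_key"].where(df["pair_key"].notna(), None)
    try:
        return SampleTable(frame=df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sample_table(table: SampleTable, path: str | Path, sep: str = "\t") -> None:
    df = table.frame.copy()
    df["pair_key"] = df["pair_key"].fillna("")
    df.to_csv(path, sep=sep, index=False)


def _format_number(x: float) -> str:
    if float(x).is_integer() and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))
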