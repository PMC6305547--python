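"""Delimited text formats for time series, networks and cohort manifests.

Dialect: tab-delimited by default (comma accepted on read), floats written
with ``repr`` so every round trip is bit-exact.  Network files carry the ROI
labels both as a header row and as the first column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ..errors import FormatError
from ..types import ConnectivityMatrix, TimeSeriesMatrix, default_roi_labels

__all__ = [
    "ManifestRow",
    "read_timeseries",
    "write_timeseries",
    "read_network",
    "write_network",
    "read_manifest",
    "write_manifest",
]

_MANIFEST_HEADER = ("subject_id", "path", "label")


@dataclass(frozen=True)
class ManifestRow:
    subject_id: str
    path: Path
    label: str


def _split_rows(text: str) -> list[list[str]]:
    rows = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if "\t" in line:
            rows.append(line.split("\t"))
        elif "," in line:
            rows.append(line.split(","))
        else:
            rows.append(line.split())
    return rows


def _is_numeric_row(tokens: Sequence[str]) -> bool:
    try:
        for tok in tokens:
            float(tok)
    except ValueError:
        return False
    return True


def _parse_block(rows: list[list[str]], path: os.PathLike | str) -> np.ndarray:
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(
            f"{path}: ragged rows (widths {sorted(widths)})"
        )
    data = np.empty((len(rows), widths.pop()))
    for i, row in enumerate(rows):
        for j, tok in enumerate(row):
            try:
                v = float(tok)
            except ValueError as err:
                raise FormatError(
                    f"{path}: unparseable cell at row {i + 1}, column {j + 1}: {tok!r}"
                ) from err
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-finite value at row {i + 1}, column {j + 1}: {tok!r}"
                )
            data[i, j] = v
    return data


def read_timeseries(path: os.PathLike | str) -> TimeSeriesMatrix:
    """Read a V x P delimited numeric matrix with an optional ROI-label header."""
    path = Path(path)
    rows = _split_rows(path.read_text())
    if not rows:
        raise FormatError(f"{path}: empty file")
    labels: list[str] = []
    if not _is_numeric_row(rows[0]):
        labels = [tok.strip() for tok in rows[0]]
        rows = rows[1:]
        if not rows:
            raise FormatError(f"{path}: header but no data rows")
    data = _parse_block(rows, path)
    if labels and len(labels) != data.shape[1]:
        raise FormatError(
            f"{path}: header has {len(labels)} labels for {data.shape[1]} columns"
        )
    return TimeSeriesMatrix(data, labels or default_roi_labels(data.shape[1]))


def write_timeseries(ts: TimeSeriesMatrix, path: os.PathLike | str) -> None:
    """Write header row of ROI labels plus repr-precision data rows."""
    lines = ["\t".join(ts.labels)]
    for row in ts.data:
        lines.append("\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_network(w: ConnectivityMatrix, path: os.PathLike | str) -> None:
    """Write a symmetric network as a labelled square table."""
    lines = ["\t".join([""] + list(w.labels))]
    for label, row in zip(w.labels, w.weights):
        lines.append("\t".join([label] + [repr(float(v)) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: os.PathLike | str) -> ConnectivityMatrix:
    """Read a labelled square table back into a symmetric network.

    Symmetry is enforced (tolerance 1e-10) by the returned container, which
    reports the worst-offending entry gap on failure.
    """
    path = Path(path)
    rows = _split_rows(path.read_text())
    if len(rows) < 2:
        raise FormatError(f"{path}: expected a header row plus data rows")
    header = [tok.strip() for tok in rows[0]]
    if header and header[0] == "":
        header = header[1:]
    body = rows[1:]
    if len(body) != len(header):
        raise FormatError(
            f"{path}: non-square table ({len(body)} rows, {len(header)} columns)"
        )
    labels, data_rows = [], []
    for row in body:
        labels.append(row[0].strip())
        data_rows.append(row[1:])
    data = _parse_block(data_rows, path)
    if data.shape[0] != data.shape[1]:
        raise FormatError(
            f"{path}: non-square matrix block {data.shape}"
        )
    return ConnectivityMatrix(data, labels)


def read_manifest(path: os.PathLike | str) -> list[ManifestRow]:
    """Read the (subject_id, path, label) cohort table.

    Relative paths resolve against the manifest's directory.  Subject ids must
    be unique and every referenced file must exist.
    """
    path = Path(path)
    rows = _split_rows(path.read_text())
    if rows and tuple(tok.strip() for tok in rows[0]) == _MANIFEST_HEADER:
        rows = rows[1:]
    out: list[ManifestRow] = []
    seen: set[str] = set()
    for i, row in enumerate(rows):
        if len(row) != 3:
            raise FormatError(
                f"{path}: manifest row {i + 1} has {len(row)} fields, expected 3"
            )
        sid, p, label = (tok.strip() for tok in row)
        if sid in seen:
            raise FormatError(f"{path}: duplicate subject id {sid!r}")
        seen.add(sid)
        target = Path(p)
        if not target.is_absolute():
            target = path.parent / target
        if not target.is_file():
            raise FormatError(f"{path}: missing data file for {sid!r}: {target}")
        out.append(ManifestRow(sid, target, label))
    if not out:
        raise FormatError(f"{path}: empty manifest")
    return out


def write_manifest(rows: Sequence[ManifestRow], path: os.PathLike | str) -> None:
    """Write the cohort table with a header, paths relative to the manifest."""
    path = Path(path)
    lines = ["\t".join(_MANIFEST_HEADER)]
    for row in rows:
        p = Path(row.path)
        try:
            p = p.relative_to(path.parent)
        except ValueError:
            pass
        lines.append(f"{row.subject_id}\t{p.as_posix()}\t{row.label}")
    path.write_text("\n".join(lines) + "\n")
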