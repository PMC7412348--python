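"""Reading and writing vGRF records and pipeline artifacts.

Records travel as delimited text (whitespace or comma, autodetected).
Three-column files carry time, left force, right force; two-column files
carry only the forces, with time synthesized from the sampling rate. A
thin ``wfdb-like`` dialect accepts ``#``-prefixed header lines ahead of
the same three-column layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from gaitrp.records import GaitRecord

DIALECTS = ("three-column-text", "two-column-text", "wfdb-like")


class FormatError(ValueError):
    """Raised for unparseable record files; names the offending line."""


def _parse_numeric_table(path: Path, n_cols: int, skip_comments: bool) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if skip_comments and stripped.startswith("#"):
                continue
            cells = stripped.replace(",", " ").split()
            if len(cells) != n_cols:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                bad = next(c for c in cells if not _is_number(c))
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric cell {bad!r}"
                ) from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_record(
    path: str | Path,
    dialect: str = "three-column-text",
    fs: float | None = None,
    subject_id: str | None = None,
    label: str = "unknown",
) -> GaitRecord:
    """Read one subject's record from a delimited text file.

    Parameters
    ----------
    path : path
        Input file.
    dialect : str
        ``three-column-text`` (time, left, right), ``two-column-text``
        (left, right; time synthesized from ``fs``) or ``wfdb-like``
        (three columns, ``#`` header lines allowed).
    fs : float, optional
        Sampling rate. Required for ``two-column-text``; for the other
        dialects it is inferred from the time column when omitted.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "two-column-text":
        if fs is None:
            raise ValueError("two-column-text dialect requires fs")
        data = _parse_numeric_table(path, 2, skip_comments=False)
        n = data.shape[0]
        time = np.arange(n) / fs
        left, right = data[:, 0], data[:, 1]
    else:
        data = _parse_numeric_table(path, 3, skip_comments=(dialect == "wfdb-like"))
        time, left, right = data[:, 0], data[:, 1], data[:, 2]
        if fs is None:
            dt = np.diff(time)
            if len(dt) == 0:
                raise FormatError(f"{path}: cannot infer fs from a single row")
            fs = 1.0 / float(np.median(dt))

    try:
        return GaitRecord(
            subject_id=subject_id or path.stem,
            label=label,
            fs=float(fs),
            time=time - time[0],
            left=left,
            right=right,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_record(path: str | Path, record: GaitRecord) -> Path:
    """Write a record as three-column whitespace-delimited text."""
    path = Path(path)
    data = np.column_stack([record.time, record.left, record.right])
    np.savetxt(path, data, fmt="%.10g")
    return path


def read_cohort(manifest_path: str | Path) -> list[GaitRecord]:
    """Read every record listed in a cohort manifest CSV."""
    import csv

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    records = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                read_record(
                    base / row["path"],
                    dialect="three-column-text",
                    fs=float(row["fs"]),
                    subject_id=row["subject_id"],
                    label=row["label"],
                )
            )
    return records


def write_image_png(path: str | Path, pixels: np.ndarray) -> Path:
    """Export a [0,1] gray-level image as 8-bit grayscale PNG
    (value = round(255 * pixel))."""
    from PIL import Image

    arr = np.asarray(pixels, dtype=float)
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError("pixels must lie in [0, 1]")
    quant = np.round(255.0 * np.clip(arr, 0.0, 1.0)).astype(np.uint8)
    Image.fromarray(quant, mode="L").save(path)
    return Path(path)


def read_image_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back to a [0,1] float image."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float) / 255.0


def write_json(path: str | Path, obj) -> Path:
    """Deterministic JSON dump (sorted keys, no timestamps)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
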