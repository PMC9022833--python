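"""Readers and writers for the pipeline's tabular formats.

Expression matrices travel as TSV with probes as rows (first column the probe
id, header row the sample ids); metadata such as the measurement scale and
generator seed are carried in leading ``#`` comment lines. Detection p-values
live in a sibling file of identical shape. Masks, medication tables, sample
and probe annotations and result tables are plain TSV. Floats are written
with 10 significant digits so write -> read -> write is a fixed point.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, ProbeMask, SampleMask, ValidationError

__all__ = [
    "read_expression",
    "write_expression",
    "read_table",
    "write_table",
    "read_medication",
    "write_mask",
    "read_config",
    "write_config",
]

FLOAT_FORMAT = "%.10g"


def _read_tsv_with_comments(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV skipping '#' comment lines; collect '# key: value' metadata."""
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if raw.startswith("#"):
                stripped = raw[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            lines.append((lineno, raw.rstrip("\n")))
    if not lines:
        raise ValidationError(f"{path}: no data lines")
    header = lines[0][1].split("\t")
    n_cols = len(header)
    records = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ValidationError(
                f"{path}:{lineno}: expected {n_cols} fields, got {len(fields)}"
            )
        records.append(fields)
    df = pd.DataFrame(records, columns=header)
    df = df.set_index(header[0])
    return df, meta


def read_expression(path, detection_path=None) -> ExpressionMatrix:
    """Read a probes x samples expression TSV (optional sibling detection file).

    The scale tag is taken from a ``# scale: raw|log2`` comment, defaulting
    to raw.
    """
    df, meta = _read_tsv_with_comments(path)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate probe ids {dupes[:5]}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric cell {cell!r} at probe "
                        f"{df.index[i]!r}, sample {df.columns[j]!r}"
                    ) from exc
        raise
    detection = None
    if detection_path is not None:
        ddf, _ = _read_tsv_with_comments(detection_path)
        detection = ddf.astype(float)
        if detection.shape != values.shape:
            raise ValidationError(
                f"{detection_path}: shape {detection.shape} does not match "
                f"expression shape {values.shape}"
            )
        detection.index = values.index if detection.index.equals(values.index) else detection.index
    return ExpressionMatrix(
        values=values, detection_p=detection, scale=meta.get("scale", "raw")
    )


def write_expression(
    expr: ExpressionMatrix,
    path,
    detection_path=None,
    seed: int | None = None,
) -> None:
    header = [f"# scale: {expr.scale}"]
    if seed is not None:
        header.append(f"# seed: {seed}")
    _write_df(expr.values, path, index_label="probe_id", header_lines=header)
    if detection_path is not None:
        if expr.detection_p is None:
            raise ValidationError("matrix has no detection p-values to write")
        _write_df(
            expr.detection_p, detection_path, index_label="probe_id",
            header_lines=header,
        )


def _write_df(df: pd.DataFrame, path, index_label="id", header_lines=()) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        fh.write(buf.getvalue())


def write_table(df: pd.DataFrame, path, index=True, seed: int | None = None) -> None:
    """Generic TSV writer with 10-significant-digit floats."""
    header = [f"# seed: {seed}"] if seed is not None else []
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", float_format=FLOAT_FORMAT, index=index)
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        fh.write(buf.getvalue())


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_medication(path) -> pd.DataFrame:
    """Read a samples x substances 0/1 medication TSV."""
    med = read_table(path)
    vals = med.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ValidationError(f"{path}: medication entries must be 0/1")
    return med.astype(np.int8)


def write_mask(mask: SampleMask | ProbeMask, path) -> None:
    write_table(mask.to_frame(), path, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
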