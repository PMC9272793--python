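"""Readers and writers: point tables, palette files, mapping and report output."""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .colors import parse_hex
from .density import validate_points
from .optimize import PaletteResult

__all__ = [
    "read_points",
    "read_palette",
    "write_mapping",
    "read_mapping",
    "write_report",
]

_HEX_TOKEN = re.compile(r"\A#(?:[0-9a-fA-F]{6}|[0-9a-fA-F]{3})\Z")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_points(
    path: str | Path,
    x_col: str = "x",
    y_col: str = "y",
    cluster_col: str = "cluster",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a delimited point table into standardized columns x, y, cluster.

    The delimiter is taken from the extension (.csv -> comma, otherwise tab)
    unless given explicitly. Rows with missing values are rejected with a
    count; non-numeric coordinates are rejected with their row numbers
    (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    for col in (x_col, y_col, cluster_col):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not found in {path}; available: {list(df.columns)}"
            )
    out = pd.DataFrame(
        {"x": df[x_col], "y": df[y_col], "cluster": df[cluster_col].astype(str)}
    )
    for col in ("x", "y"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        non_numeric = coerced.isna() & out[col].notna()
        if non_numeric.any():
            rows = (np.nonzero(non_numeric.to_numpy())[0] + 1).tolist()
            raise ValueError(
                f"non-numeric {col} coordinate in {path} at row(s) {rows[:5]}"
            )
        out[col] = coerced
    missing = out[["x", "y"]].isna().any(axis=1) | df[cluster_col].isna()
    if missing.any():
        raise ValueError(
            f"{int(missing.sum())} rows with missing values in {path} "
            f"(first rows: {(np.nonzero(missing.to_numpy())[0] + 1)[:5].tolist()})"
        )
    return validate_points(out)


def read_palette(path: str | Path) -> list[str]:
    """Read a palette file: one #RRGGBB per line; comment lines allowed.

    The first whitespace-delimited token of each line is taken as the color;
    text after it is ignored. A non-blank line whose first token is not a
    valid hex color is treated as a comment if it starts with '#', and is an
    error otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"palette file not found: {path}")
    colors: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        token = line.split()[0]
        if _HEX_TOKEN.match(token):
            colors.append(token)
        elif line.startswith("#"):
            continue  # comment line
        else:
            raise ValueError(
                f"palette file {path} line {lineno}: {token!r} is not a hex color"
            )
    if not colors:
        raise ValueError(f"palette file {path} contains no colors")
    for i, c in enumerate(colors):  # fail fast, with index, on malformed entries
        parse_hex(c, index=i)
    return colors


def write_mapping(mapping: dict, path: str | Path) -> None:
    """Write the cluster -> hex mapping as TSV, clusters in canonical order.

    Row order is lexicographic on the label's text form and hex strings are
    preserved byte-for-byte, so reruns with the same seed are byte-identical.
    """
    path = Path(path)
    lines = ["cluster\thex"]
    for lab in sorted(mapping, key=str):
        lines.append(f"{lab}\t{mapping[lab]}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mapping(path: str | Path) -> dict:
    """Round-trip reader for :func:`write_mapping` output."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["cluster"], df["hex"]))


def write_report(result: PaletteResult, path: str | Path) -> None:
    """Write a machine-readable run report (scores, trace, J matrix, config, seed)."""
    report = {
        "score": result.score,
        "restart_score": result.restart_score,
        "seed": result.seed,
        "config": asdict(result.config),
        "mapping": {str(k): v for k, v in result.mapping.items()},
        "cutoffs": {str(k): v for k, v in result.cutoffs.items()},
        "overlap": {
            "clusters": [str(c) for c in result.overlap.index],
            "jaccard": result.overlap.to_numpy().tolist(),
        },
        "trace": [[int(t), float(s)] for t, s in result.trace],
    }
    with open(path, "w", newline="\n") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
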