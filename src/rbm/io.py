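"""Reading expression matrices / targets files and writing result tables.

The interchange format is TSV: a genes x arrays matrix with a header row
of array identifiers and gene identifiers in the first column.  ``NA``
cells are mapped to zero-weight observations rather than dropped, so
ragged information never silently changes the design.  Result tables
round-trip at full double precision (p-values are serialised with 12
significant digits).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .linmod import ExpressionData

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "read_groups",
    "RunMetadata",
    "write_results",
    "read_results",
]

_NA_TOKENS = {"NA", "NaN", "nan", ""}


class MatrixParseError(ValueError):
    """Malformed expression matrix file."""


def read_matrix(path) -> ExpressionData:
    """Read a TSV expression matrix (first column gene IDs).

    ``NA`` cells become zero-weight entries; duplicate gene IDs, ragged
    rows and non-numeric cells raise :class:`MatrixParseError` with the
    offending line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        if n_cols < 2:
            raise MatrixParseError(f"{path}:1: header must name at least one array")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        wrows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise MatrixParseError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(parts)}"
                )
            gid = parts[0]
            if gid in seen:
                raise MatrixParseError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
            seen.add(gid)
            gene_ids.append(gid)
            vals, ws = [], []
            for tok in parts[1:]:
                if tok in _NA_TOKENS:
                    vals.append(0.0)
                    ws.append(0.0)
                else:
                    try:
                        vals.append(float(tok))
                    except ValueError as exc:
                        raise MatrixParseError(
                            f"{path}:{lineno}: non-numeric cell {tok!r}"
                        ) from exc
                    ws.append(1.0)
            rows.append(vals)
            wrows.append(ws)
    if not rows:
        raise MatrixParseError(f"{path}: no data rows")
    Y = np.asarray(rows)
    W = np.asarray(wrows)
    weights = None if np.all(W == 1.0) else W
    return ExpressionData(Y, gene_ids=gene_ids, weights=weights)


def read_groups(path) -> tuple:
    """Read a two-column targets file (array ID, group label).

    The array order must match the matrix columns; only the labels are
    returned.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MatrixParseError(f"{path}: targets file needs two columns (array, group)")
    return tuple(df.iloc[:, 1])


@dataclass(frozen=True)
class RunMetadata:
    """Sidecar metadata sufficient to re-run a deterministic analysis."""

    method: str
    seed: int
    B: int
    alpha: float
    config_hash: str
    version: str
    n_genes: int
    n_arrays: int
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "RunMetadata":
        payload = json.loads(text)
        required = {"method", "seed", "B", "alpha", "config_hash", "version", "n_genes", "n_arrays"}
        missing = required - payload.keys()
        if missing:
            raise ValueError(f"metadata missing fields: {sorted(missing)}")
        return RunMetadata(**payload)


def config_hash(params: dict) -> str:
    """Stable short hash of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(table: pd.DataFrame, path, metadata: RunMetadata | None = None) -> None:
    """Write a per-gene results table as TSV plus an optional JSON sidecar.

    Floats keep 12 significant digits so a read-back reproduces the
    values to full reported precision.
    """
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
    if metadata is not None:
        path.with_suffix(path.suffix + ".meta.json").write_text(metadata.to_json())


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
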