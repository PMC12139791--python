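"""Domain types and on-disk dialects.

All artifacts are plain delimited text: node×node numeric matrices for edge
masks and connectomes (whitespace- or comma-delimited; masks may be given as
one triangle only), a CSV session manifest, and CSV go/no-go trial tables.
Every reader is the exact inverse of its writer on the writer's own output.
Node indexing is 0-based internally; the manifest's ``missing_nodes`` column
is 1-based (the 268-node atlas convention) and converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not parse as the expected dialect/shape."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


CONDITIONS = ("MA", "PL")
RUN_TYPES = ("rest", "mid", "doors1", "doors2", "orientation")

#: Manifest columns required by :func:`read_manifest`.
MANIFEST_COLUMNS = (
    "subject_id", "condition", "run_type", "path",
    "max_displacement_mm", "mean_censored_motion_mm", "frac_censored",
    "missing_nodes",
)


# ---------------------------------------------------------------------------
# Edge masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeMask:
    """Binary symmetric node×node edge set.

    ``matrix`` holds 0/1 with a zero diagonal; an edge is an unordered node
    pair, so ``edge_count`` counts upper-triangle ones.
    """

    matrix: np.ndarray
    label: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise FormatError(f"edge mask must be square, got shape {m.shape}")
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("edge mask entries must be 0 or 1")
        if np.diagonal(m).any():
            raise ValidationError("edge mask diagonal must be zero")
        if not np.array_equal(m, m.T):
            raise ValidationError("edge mask must be symmetric")
        object.__setattr__(self, "matrix", m.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.matrix.sum()) // 2

    def edge_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) index arrays of the mask's edges."""
        iu = np.triu_indices(self.n_nodes, k=1)
        keep = self.matrix[iu] == 1
        return iu[0][keep], iu[1][keep]

    @staticmethod
    def from_edges(n_nodes: int, edges: Sequence[tuple[int, int]], label: str = "") -> "EdgeMask":
        m = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        for i, j in edges:
            if i == j:
                raise ValidationError("self-edges are not allowed")
            m[i, j] = m[j, i] = 1
        return EdgeMask(m, label=label)


def _load_numeric_table(path: str | Path) -> np.ndarray:
    """Load a whitespace- or comma-delimited numeric matrix."""
    text = Path(path).read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    delim = "," if "," in first else None
    try:
        arr = np.loadtxt(Path(path), delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: not a numeric matrix: {exc}") from exc
    return arr


def read_edge_mask(path: str | Path, n_nodes: int, label: str | None = None) -> EdgeMask:
    """Read a binary mask matrix; mirror a strictly one-triangle input.

    Accepts a full symmetric 0/1 matrix or a matrix whose nonzeros all lie in
    one triangle (mirrored to symmetric). Non-binary entries or an n_nodes
    mismatch raise.
    """
    m = _load_numeric_table(path)
    if m.shape != (n_nodes, n_nodes):
        raise FormatError(f"{path}: expected {n_nodes}×{n_nodes}, got {m.shape}")
    if not np.isin(m, (0, 1)).all():
        raise ValidationError(f"{path}: mask entries must be 0 or 1")
    lower, upper = np.tril(m, k=-1), np.triu(m, k=1)
    if not np.array_equal(m, m.T):
        if not lower.any():
            m = upper + upper.T
        elif not upper.any():
            m = lower + lower.T
        else:
            raise ValidationError(f"{path}: mask is asymmetric and not triangular")
    np.fill_diagonal(m, 0)
    return EdgeMask(m, label=label if label is not None else Path(path).stem)


def write_edge_mask(mask: EdgeMask, path: str | Path) -> None:
    np.savetxt(Path(path), mask.matrix, fmt="%d", delimiter="\t")


# ---------------------------------------------------------------------------
# Session records / manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionRecord:
    """One scan run's identity, QC metrics and file pointer."""

    subject_id: str
    condition: str
    run_type: str
    path: str = ""
    max_displacement: float = np.nan    # mm, maximum censored displacement
    mean_censored_motion: float = np.nan  # mm
    frac_censored: float = np.nan       # proportion of TRs censored, [0, 1]
    missing_nodes: tuple[int, ...] = ()  # 0-based node indices
    session_index: int | None = None    # 1-based administration order, if known

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.run_type not in RUN_TYPES:
            raise ValidationError(f"unknown run_type {self.run_type!r}")
        if np.isfinite(self.frac_censored) and not 0.0 <= self.frac_censored <= 1.0:
            raise ValidationError(f"frac_censored {self.frac_censored} outside [0, 1]")
        object.__setattr__(self, "missing_nodes", tuple(int(i) for i in self.missing_nodes))


def _parse_missing_nodes(cell) -> tuple[int, ...]:
    # manifest column is 1-based, semicolon-separated; empty means none
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return ()
    return tuple(int(tok) - 1 for tok in str(cell).split(";"))


def _format_missing_nodes(nodes: Sequence[int]) -> str:
    return ";".join(str(int(i) + 1) for i in nodes)


def read_manifest(path: str | Path) -> list[SessionRecord]:
    """Read a CSV session manifest into validated records."""
    df = pd.read_csv(path, dtype={"subject_id": str, "missing_nodes": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(SessionRecord(
            subject_id=str(row["subject_id"]),
            condition=str(row["condition"]),
            run_type=str(row["run_type"]),
            path=str(row["path"]) if pd.notna(row["path"]) else "",
            max_displacement=float(row["max_displacement_mm"]),
            mean_censored_motion=float(row["mean_censored_motion_mm"]),
            frac_censored=float(row["frac_censored"]),
            missing_nodes=_parse_missing_nodes(row["missing_nodes"]),
            session_index=(int(row["session_index"])
                           if "session_index" in df.columns and pd.notna(row["session_index"])
                           else None),
        ))
    return records


def write_manifest(records: Sequence[SessionRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "condition": r.condition,
            "run_type": r.run_type,
            "path": r.path,
            "max_displacement_mm": r.max_displacement,
            "mean_censored_motion_mm": r.mean_censored_motion,
            "frac_censored": r.frac_censored,
            "missing_nodes": _format_missing_nodes(r.missing_nodes),
            "session_index": r.session_index,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------

@dataclass
class ConnMatrix:
    """Node×node Fisher-z functional connectome.

    Rows/columns of invalid nodes are all-NaN off the diagonal; ``valid_nodes``
    flags them. The diagonal carries no information (self-connectivity is
    excluded from every edge statistic).
    """

    values: np.ndarray
    valid_nodes: np.ndarray
    meta: SessionRecord | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError(f"connectivity matrix must be square, got {v.shape}")
        self.values = v
        self.valid_nodes = np.asarray(self.valid_nodes, dtype=bool)
        if self.valid_nodes.shape != (v.shape[0],):
            raise ValidationError("valid_nodes length must equal n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def with_meta(self, meta: SessionRecord) -> "ConnMatrix":
        return ConnMatrix(self.values, self.valid_nodes, meta=meta)


def write_conn_matrix(conn: ConnMatrix, path: str | Path) -> None:
    """Write at full float64 precision (%.17g round-trips exactly)."""
    np.savetxt(Path(path), conn.values, fmt="%.17g", delimiter="\t")


def read_conn_matrix(path: str | Path, meta: SessionRecord | None = None) -> ConnMatrix:
    """Read a square matrix; all-NaN off-diagonal rows mark invalid nodes."""
    v = _load_numeric_table(path)
    if v.shape[0] != v.shape[1]:
        raise FormatError(f"{path}: connectivity matrix must be square, got {v.shape}")
    n = v.shape[0]
    off_diag = ~np.eye(n, dtype=bool)
    if n == 1:
        valid = ~np.isnan(np.diagonal(v))
    else:
        valid = ~np.all(np.isnan(np.where(off_diag, v, np.nan)), axis=1)
    return ConnMatrix(v, valid, meta=meta)


# ---------------------------------------------------------------------------
# gradCPT trial tables
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ("trial_index", "category", "responded")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a gradCPT trial table: trial_index, category∈{go,nogo}, responded."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: trial table missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: trial table is empty")
    bad = set(df["category"].unique()) - {"go", "nogo"}
    if bad:
        raise ValidationError(f"{path}: unknown trial categories {sorted(bad)}")
    df = df.loc[:, list(TRIAL_COLUMNS)].copy()
    df["trial_index"] = df["trial_index"].astype(int)
    df["responded"] = df["responded"].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials.loc[:, list(TRIAL_COLUMNS)].copy()
    out["responded"] = out["responded"].astype(bool)
    out.to_csv(path, index=False)
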