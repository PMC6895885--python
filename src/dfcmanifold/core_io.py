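"""Readers, writers and the canonical connection-pair indexing.

Every downstream stage — dFC estimation, embedding, CCP labels, coreness
vectors, statistical maps — indexes the R(R-1)/2 ROI pairs identically:
row-major upper-triangle order (0,1), (0,2), ..., (0,R-1), (1,2), ...
Indices are 0-based internally; 1-based ROI ids are permitted in files and
mapped on read.

File formats are tab-delimited UTF-8 text with a header row. The n x D dFC
matrix is stored in a portable binary container (NumPy ``.npz``) carrying
its shape, pair-order tag and window metadata, because a 12,720 x D TSV is
impractical.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PAIR_ORDER_TAG = "row-major-upper-triangle-v1"

__all__ = [
    "ValidationError",
    "ParseError",
    "NumericError",
    "RoiTimeSeries",
    "Atlas",
    "PairIndex",
    "n_pairs",
    "pair_to_index",
    "index_to_pair",
    "read_timeseries",
    "write_timeseries",
    "read_atlas",
    "read_labels",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "save_dfc_container",
    "load_dfc_container",
    "file_digest",
]


class ValidationError(ValueError):
    """Invalid inputs or parameters (CLI exit code 2)."""


class ParseError(ValidationError):
    """Malformed input file; message names the offending line."""


class NumericError(RuntimeError):
    """Numerical failure in an algorithm (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# Pair indexing
# ---------------------------------------------------------------------------

def n_pairs(R: int) -> int:
    """Number of distinct ROI pairs for ``R`` regions: R(R-1)/2.

    For the 160-ROI atlas this is the 12,720-connection vectorization of one
    correlation matrix's upper triangle.
    """
    if R < 2:
        raise ValidationError(f"need at least 2 ROIs, got R={R}")
    return R * (R - 1) // 2


def pair_to_index(i: int, j: int, R: int) -> int:
    """Map ROI pair (i, j), i < j, to its row-major upper-triangle index."""
    if not (0 <= i < j < R):
        raise IndexError(f"pair ({i}, {j}) out of range for R={R} (need 0 <= i < j < R)")
    # pairs (0,*) occupy [0, R-1), (1,*) the next R-2 slots, ...
    return i * R - i * (i + 1) // 2 + (j - i - 1)


def index_to_pair(p: int, R: int) -> tuple[int, int]:
    """Inverse of :func:`pair_to_index`."""
    npair = n_pairs(R)
    if not (0 <= p < npair):
        raise IndexError(f"pair index {p} out of range for R={R} ({npair} pairs)")
    # row i is the largest i with offset(i) = i*R - i(i+1)/2 <= p
    i = int((2 * R - 1 - np.sqrt((2 * R - 1) ** 2 - 8 * p)) // 2)
    offset = i * R - i * (i + 1) // 2
    while offset > p:  # guard float slop at row boundaries
        i -= 1
        offset = i * R - i * (i + 1) // 2
    while i + 1 < R and (i + 1) * R - (i + 1) * (i + 2) // 2 <= p:
        i += 1
        offset = i * R - i * (i + 1) // 2
    j = p - offset + i + 1
    return i, j


@dataclasses.dataclass(frozen=True)
class PairIndex:
    """Canonical ordering of the R(R-1)/2 ROI pairs."""

    R: int

    def __post_init__(self) -> None:
        if self.R < 2:
            raise ValidationError(f"need at least 2 ROIs, got R={self.R}")

    @property
    def n(self) -> int:
        return n_pairs(self.R)

    def pairs(self) -> np.ndarray:
        """(n, 2) array of (i, j) rows in canonical order."""
        iu = np.triu_indices(self.R, k=1)
        return np.column_stack(iu)

    def to_index(self, i: int, j: int) -> int:
        return pair_to_index(i, j, self.R)

    def to_pair(self, p: int) -> tuple[int, int]:
        return index_to_pair(p, self.R)

    def vector_to_matrix(self, v: np.ndarray, diagonal: float = np.nan) -> np.ndarray:
        """Rearrange a length-n pair vector into a symmetric R x R matrix."""
        v = np.asarray(v)
        if v.shape != (self.n,):
            raise ValidationError(f"expected vector of length {self.n}, got shape {v.shape}")
        M = np.full((self.R, self.R), diagonal, dtype=float)
        iu = np.triu_indices(self.R, k=1)
        M[iu] = v
        M[(iu[1], iu[0])] = v
        return M

    def matrix_to_vector(self, M: np.ndarray) -> np.ndarray:
        """Extract the upper triangle of an R x R matrix in canonical order."""
        M = np.asarray(M)
        if M.shape != (self.R, self.R):
            raise ValidationError(f"expected ({self.R}, {self.R}) matrix, got {M.shape}")
        return M[np.triu_indices(self.R, k=1)].astype(float)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RoiTimeSeries:
    """ROI-averaged BOLD time courses: T timepoints x R regions."""

    data: np.ndarray
    tr_seconds: float
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time series must be a 2-D array (T x R)")
        T, R = self.data.shape
        if T < 2 or R < 2:
            raise ValidationError(f"need T >= 2 and R >= 2, got T={T}, R={R}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValidationError(f"TR must be positive, got {self.tr_seconds}")
        if len(self.roi_ids) != R:
            raise ValidationError(f"{len(self.roi_ids)} ROI ids for {R} columns")
        if len(set(self.roi_ids)) != R:
            raise ValidationError("duplicate ROI ids")

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def R(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class Atlas:
    """ROI atlas: id, name, functional-network membership, mm coordinates."""

    table: pd.DataFrame  # columns: roi_id, name, network, x, y, z

    def __post_init__(self) -> None:
        required = ["roi_id", "name", "network", "x", "y", "z"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"atlas missing columns: {missing}")
        ids = self.table["roi_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate ROI id in atlas: {dup!r}")
        if (self.table["network"].astype(str).str.len() == 0).any():
            raise ValidationError("empty network label in atlas")

    @property
    def R(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        return sorted(self.table["network"].astype(str).unique())

    def network_sort_order(self) -> np.ndarray:
        """Row permutation grouping ROIs by network block (display order)."""
        return np.argsort(self.table["network"].astype(str).to_numpy(), kind="stable")


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> tuple[list[str], list[list[str]], dict[str, str]]:
    """Raw TSV reader: returns header, rows, and '# key = value' metadata."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
            else:
                if len(cells) != len(header):
                    raise ParseError(
                        f"{path}: line {lineno}: expected {len(header)} columns, got {len(cells)}"
                    )
                rows.append(cells)
    if header is None:
        raise ParseError(f"{path}: empty file")
    return header, rows, meta


def read_timeseries(path: str | Path, tr_seconds: float | None = None) -> RoiTimeSeries:
    """Read a T x R time-series TSV (header = ROI ids).

    TR is taken from a ``# tr_seconds = <x>`` metadata line unless supplied
    explicitly; the explicit value wins.
    """
    header, rows, meta = _read_tsv(path)
    if tr_seconds is None:
        if "tr_seconds" not in meta:
            raise ParseError(f"{path}: no '# tr_seconds = ...' metadata line and no TR given")
        tr_seconds = float(meta["tr_seconds"])
    if len(set(header)) != len(header):
        raise ParseError(f"{path}: duplicated ROI id in header")
    try:
        data = np.array([[float(c) for c in row] for row in rows], dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    return RoiTimeSeries(data=data, tr_seconds=float(tr_seconds), roi_ids=list(header))


def write_timeseries(path: str | Path, ts: RoiTimeSeries) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tr_seconds = {ts.tr_seconds!r}\n")
        fh.write("\t".join(ts.roi_ids) + "\n")
        for row in ts.data:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_atlas(path: str | Path) -> Atlas:
    """Read an atlas TSV: roi_id, name, network, x, y, z."""
    header, rows, _ = _read_tsv(path)
    df = pd.DataFrame(rows, columns=header)
    for col in ("x", "y", "z"):
        if col in df.columns:
            try:
                df[col] = df[col].astype(float)
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric coordinate in column {col!r}") from exc
    return Atlas(table=df)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a label table TSV: run_id, class (extra columns preserved)."""
    header, rows, _ = _read_tsv(path)
    df = pd.DataFrame(rows, columns=header)
    for col in ("run_id", "class"):
        if col not in df.columns:
            raise ParseError(f"{path}: label table needs a {col!r} column")
    return df


def write_matrix_tsv(path: str | Path, M: np.ndarray,
                     row_labels: Sequence | None = None,
                     col_labels: Sequence | None = None) -> None:
    """Write a small matrix as TSV with full float precision (repr round-trip)."""
    M = np.asarray(M)
    with open(path, "w", encoding="utf-8") as fh:
        if col_labels is not None:
            prefix = [""] if row_labels is not None else []
            fh.write("\t".join(prefix + [str(c) for c in col_labels]) + "\n")
        for r, row in enumerate(M):
            cells = [repr(float(x)) for x in np.atleast_1d(row)]
            if row_labels is not None:
                cells = [str(row_labels[r])] + cells
            fh.write("\t".join(cells) + "\n")


def read_matrix_tsv(path: str | Path, has_row_labels: bool = False,
                    has_col_labels: bool = False) -> np.ndarray:
    header, rows, _ = _read_tsv(path)
    all_rows = rows if has_col_labels else [header] + rows
    if has_row_labels:
        all_rows = [r[1:] for r in all_rows]
    try:
        return np.array([[float(c) for c in row] for row in all_rows], dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc


# ---------------------------------------------------------------------------
# dFC binary container
# ---------------------------------------------------------------------------

def save_dfc_container(path: str | Path, S: np.ndarray, R: int,
                       tr_seconds: float, window_seconds: float,
                       step_trs: int) -> None:
    """Save an n x D dFC matrix with pair-order and window metadata."""
    S = np.asarray(S, dtype=float)
    if S.shape[0] != n_pairs(R):
        raise ValidationError(f"S has {S.shape[0]} rows but R={R} implies {n_pairs(R)} pairs")
    np.savez(
        path,
        S=S,
        R=np.int64(R),
        tr_seconds=np.float64(tr_seconds),
        window_seconds=np.float64(window_seconds),
        step_trs=np.int64(step_trs),
        pair_order=np.bytes_(PAIR_ORDER_TAG.encode()),
    )


def load_dfc_container(path: str | Path) -> dict:
    with np.load(path) as z:
        tag = bytes(z["pair_order"]).decode()
        if tag != PAIR_ORDER_TAG:
            raise ValidationError(f"unknown pair-order tag {tag!r}")
        return {
            "S": z["S"],
            "R": int(z["R"]),
            "tr_seconds": float(z["tr_seconds"]),
            "window_seconds": float(z["window_seconds"]),
            "step_trs": int(z["step_trs"]),
        }


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
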