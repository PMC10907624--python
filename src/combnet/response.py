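"""Screen ingestion: raw cell-death readouts to normalized inhibition matrices.

An ex vivo drug-response screen is a samples × drugs matrix of raw readouts
(e.g. dead-cell fluorescence), typically with missing cells because not every
drug was tested on every sample. Downstream network analysis requires a
complete matrix of comparable values, so ingestion proceeds in two steps:

1. :func:`extract_complete_submatrix` — drop rows/columns until no missing
   entries remain, greedily removing the row or column carrying the most
   missing cells and then restoring any deletion that turns out to be
   unnecessary (the result is maximal: no single deleted row or column can be
   added back without reintroducing a missing cell).
2. :func:`normalize_inhibition` — min–max normalize to an inhibition rate

   .. math:: R = \\frac{x - \\min(x)}{\\max(x) - \\min(x)} \\in [0, 1]

   so that 1 is the highest sensitivity and 0 the lowest, either globally
   (default; one comparable scale across the screen) or per drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

PATIENT = "patient"
HEALTHY = "healthy"

__all__ = [
    "RawScreen",
    "ResponseMatrix",
    "normalize_inhibition",
    "extract_complete_submatrix",
    "read_screen_csv",
    "write_screen_csv",
]


@dataclass
class RawScreen:
    """Raw samples × drugs readout matrix; NaN marks a missing cell.

    Parameters
    ----------
    values : (n_samples, n_drugs) float array, arbitrary units.
    sample_ids, drug_ids : row / column labels.
    sample_class : per-sample label, ``"patient"`` or ``"healthy"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    drug_ids: list[str]
    sample_class: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples × drugs matrix")
        n_s, n_d = self.values.shape
        if len(self.sample_ids) != n_s:
            raise ValueError(f"sample_ids has {len(self.sample_ids)} entries for {n_s} rows")
        if len(self.drug_ids) != n_d:
            raise ValueError(f"drug_ids has {len(self.drug_ids)} entries for {n_d} columns")
        if len(self.sample_class) != n_s:
            raise ValueError("sample_class must label every sample")
        bad = sorted(set(self.sample_class) - {PATIENT, HEALTHY})
        if bad:
            raise ValueError(f"sample_class labels must be 'patient' or 'healthy', got {bad}")

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the cell was not measured."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.drug_ids)


@dataclass
class ResponseMatrix:
    """Complete samples × drugs matrix of normalized inhibition rates in [0, 1]."""

    a: np.ndarray
    sample_ids: list[str]
    drug_ids: list[str]
    sample_class: list[str]
    normalization_scope: str = "global"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if np.isnan(self.a).any():
            raise ValueError("ResponseMatrix must not contain missing entries")
        if self.a.size and (self.a.min() < -1e-12 or self.a.max() > 1 + 1e-12):
            raise ValueError("inhibition rates must lie in [0, 1]")

    @property
    def patient_index(self) -> np.ndarray:
        return np.array([c == PATIENT for c in self.sample_class])

    @property
    def healthy_index(self) -> np.ndarray:
        return np.array([c == HEALTHY for c in self.sample_class])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.sample_ids, columns=self.drug_ids)


def normalize_inhibition(
    raw: RawScreen, scope: Literal["global", "per_drug"] = "global"
) -> ResponseMatrix:
    """Min–max normalize raw readouts to inhibition rates R = (x−min)/(max−min).

    ``scope="global"`` uses one min/max over the whole matrix (a uniform
    measure across the screen); ``scope="per_drug"`` rescales each drug column
    independently.

    Raises
    ------
    ValueError
        If missing entries are present (run :func:`extract_complete_submatrix`
        first) or if a normalization scope has a degenerate (constant) range.
    """
    x = raw.values
    if np.isnan(x).any():
        raise ValueError(
            "raw screen contains missing entries; extract a complete submatrix first"
        )
    if scope == "global":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("degenerate range: all values equal in global scope")
        a = (x - lo) / (hi - lo)
    elif scope == "per_drug":
        lo = x.min(axis=0, keepdims=True)
        hi = x.max(axis=0, keepdims=True)
        flat = np.where((hi == lo).ravel())[0]
        if flat.size:
            names = [raw.drug_ids[i] for i in flat[:5]]
            raise ValueError(f"degenerate range: constant values for drug scope(s) {names}")
        a = (x - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization scope {scope!r}")
    return ResponseMatrix(
        a=a,
        sample_ids=list(raw.sample_ids),
        drug_ids=list(raw.drug_ids),
        sample_class=list(raw.sample_class),
        normalization_scope=scope,
    )


def _greedy_complete(
    mask: np.ndarray, priority: str
) -> tuple[list[int], list[int]]:
    """Greedy row/column deletion until the kept block has no True cells.

    Returns (kept_rows, kept_cols) index lists in original order.
    """
    n_r, n_c = mask.shape
    rows = list(range(n_r))
    cols = list(range(n_c))
    deleted_rows: list[int] = []
    deleted_cols: list[int] = []

    while True:
        sub = mask[np.ix_(rows, cols)]
        if not sub.any():
            break
        if not rows or not cols:
            break
        rm = sub.sum(axis=1)
        cm = sub.sum(axis=0)
        ri = int(np.argmax(rm))
        ci = int(np.argmax(cm))
        # primary criterion: missing *fraction* of the line (absolute counts
        # are incomparable between rows and columns of different lengths and
        # would always sacrifice the longer dimension)
        row_frac = rm[ri] / len(cols)
        col_frac = cm[ci] / len(rows)
        if row_frac > col_frac:
            drop_row = True
        elif col_frac > row_frac:
            drop_row = False
        elif int(rm[ri]) != int(cm[ci]):  # tie on fraction: larger absolute count
            drop_row = int(rm[ri]) > int(cm[ci])
        else:
            if priority == "max_area":
                # remaining cells: drop row -> (R-1)*C, drop col -> R*(C-1)
                drop_row = (len(rows) - 1) * len(cols) >= len(rows) * (len(cols) - 1)
            else:  # rows_first
                drop_row = True
        if drop_row:
            deleted_rows.append(rows.pop(ri))
        else:
            deleted_cols.append(cols.pop(ci))

    # restoration pass: greedy deletion can overshoot; add back any deleted
    # row/column that is complete w.r.t. the kept block, until maximal
    changed = True
    while changed:
        changed = False
        for r in sorted(deleted_rows):
            if cols and not mask[r, cols].any():
                rows.append(r)
                deleted_rows.remove(r)
                changed = True
        for c in sorted(deleted_cols):
            if rows and not mask[np.ix_(rows, [c])].any():
                cols.append(c)
                deleted_cols.remove(c)
                changed = True
    return sorted(rows), sorted(cols)


def extract_complete_submatrix(
    raw: RawScreen, priority: Literal["max_area", "rows_first"] = "max_area"
) -> RawScreen:
    """Extract a maximal complete (no-missing) submatrix by greedy deletion.

    Iteratively deletes the row or column with the most missing cells
    (``max_area`` breaks row/column ties toward the larger remaining cell
    count, ``rows_first`` toward deleting the row), then restores any deleted
    line that no longer covers a missing cell. The result is guaranteed
    complete and maximal, but not globally optimal.
    """
    if raw.values.size == 0:
        raise ValueError("empty screen")
    mask = raw.missing_mask
    if not mask.any():
        return raw
    rows, cols = _greedy_complete(mask, priority)
    if not rows or not cols:
        raise ValueError("no complete submatrix exists (a fully missing axis remains)")
    return RawScreen(
        values=raw.values[np.ix_(rows, cols)],
        sample_ids=[raw.sample_ids[i] for i in rows],
        drug_ids=[raw.drug_ids[j] for j in cols],
        sample_class=[raw.sample_class[i] for i in rows],
    )


def read_screen_csv(path) -> RawScreen:
    """Read a screen CSV: sample id, sample class, then one column per drug.

    Empty cells denote missing measurements.
    """
    df = pd.read_csv(path, index_col=0)
    cls = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 1:]
    return RawScreen(
        values=vals.to_numpy(dtype=float),
        sample_ids=[str(i) for i in df.index],
        drug_ids=[str(c) for c in vals.columns],
        sample_class=cls,
    )


def write_screen_csv(screen: RawScreen, path) -> None:
    df = screen.to_frame()
    df.insert(0, "sample_class", screen.sample_class)
    df.to_csv(path, index_label="sample_id")
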