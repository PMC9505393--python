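"""CSV readers and writers for item parameters, responses, times and scores.

All tabular formats are headered, UTF-8, decimal-point CSV:

* item parameter file — columns ``a,b,k`` (required, in that order by name),
  optional ``gamma``; one row per item, row order defines item index
  (1-based in reports);
* response file — persons as rows, items as columns, cells in {0, 1, empty};
  an optional leading ``person`` column holds identifiers;
* response-time file — same layout, seconds as decimals, empty = missing;
* score file — ``person,theta,se,method,model,correction,converged,n_iter,
  at_boundary`` with theta/se printed at 4 decimals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .effort import EffortProfile
from .models import ItemParameters
from .scoring import ThetaEstimate

__all__ = [
    "FormatError",
    "read_item_parameters",
    "read_rbe",
    "read_responses",
    "read_times",
    "write_effort_profile",
    "write_estimates",
]

PERSON_COL = "person"


class FormatError(ValueError):
    """An input file does not match its documented format."""


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: header only, no data rows")
    return df


def read_item_parameters(path) -> list[ItemParameters]:
    """Read an item parameter CSV (columns ``a,b,k``, optional ``gamma``).

    A missing ``gamma`` column (or empty cell) means no lower asymptote;
    it is stored as ``-inf``.
    """
    df = _read_csv(path)
    for col in ("a", "b", "k"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    items = []
    for idx, row in df.iterrows():
        vals = {}
        for col in ("a", "b", "k"):
            try:
                vals[col] = float(row[col])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric value {row[col]!r} at row "
                    f"{idx + 1}, column {col!r}") from None
            if np.isnan(vals[col]):
                raise FormatError(
                    f"{path}: missing value at row {idx + 1}, column {col!r}")
        gamma = -np.inf
        if "gamma" in df.columns and not pd.isna(row["gamma"]):
            gamma = float(row["gamma"])
        items.append(ItemParameters(a=vals["a"], b=vals["b"], k=vals["k"],
                                    gamma=gamma))
    return items


def _split_person_column(df: pd.DataFrame):
    if df.columns[0].lower() == PERSON_COL:
        ids = df.iloc[:, 0].astype(str).tolist()
        data = df.iloc[:, 1:]
    else:
        ids = [str(i + 1) for i in range(len(df))]
        data = df
    return ids, data


def read_responses(path):
    """Read a persons x items 0/1 response CSV.

    Returns ``(grid, person_ids)`` where the grid is a float array with NaN
    for missing cells.
    """
    df = _read_csv(path)
    ids, data = _split_person_column(df)
    grid = data.to_numpy(dtype=float)
    present = ~np.isnan(grid)
    bad = present & ~np.isin(grid, (0.0, 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-binary response {grid[r, c]!r} at row {r + 1}, "
            f"column {data.columns[c]!r}")
    return grid, ids


def read_times(path):
    """Read a persons x items response-time CSV (seconds, NaN = missing)."""
    df = _read_csv(path)
    ids, data = _split_person_column(df)
    grid = data.to_numpy(dtype=float)
    if np.any(grid[~np.isnan(grid)] < 0):
        raise FormatError(f"{path}: negative response time")
    return grid, ids


def read_rbe(path) -> np.ndarray:
    """Read a per-person rapid(0)/effortful(1) flag CSV (column ``rbe``)."""
    df = _read_csv(path)
    col = "rbe" if "rbe" in df.columns else df.columns[-1]
    vals = df[col].to_numpy(dtype=float)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise FormatError(f"{path}: rbe values must be 0 or 1")
    return vals.astype(int)


def write_estimates(path, estimates: Sequence[ThetaEstimate | None],
                    person_ids: Sequence[str], model: str) -> None:
    """Write per-person score rows; unscored persons get empty theta/se."""
    rows = []
    for pid, est in zip(person_ids, estimates):
        if est is None:
            rows.append({PERSON_COL: pid, "theta": "", "se": "",
                         "method": "", "model": model, "correction": "",
                         "converged": False, "n_iter": 0,
                         "at_boundary": False})
            continue
        rows.append({
            PERSON_COL: pid,
            "theta": f"{est.theta:.4f}",
            "se": "" if np.isnan(est.se) else f"{est.se:.4f}",
            "method": est.method,
            "model": model,
            "correction": est.corrected,
            "converged": est.converged,
            "n_iter": est.n_iter,
            "at_boundary": est.at_boundary,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_effort_profile(path, profile: EffortProfile,
                         person_ids: Sequence[str]) -> None:
    """Write SB flags plus per-person ``rte`` and ``rbe`` columns."""
    n_items = profile.sb.shape[1]
    df = pd.DataFrame(profile.sb,
                      columns=[f"sb_{i + 1}" for i in range(n_items)])
    df.insert(0, PERSON_COL, list(person_ids))
    df["rte"] = profile.rte
    df["rbe"] = profile.rbe
    df.to_csv(path, index=False, float_format="%.4f")
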