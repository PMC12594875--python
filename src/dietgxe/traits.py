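"""Trait derivation from activity-monitor counts, dataset balancing and
line means.

Activity monitors emit one count per fly per 10-second bin.  Locomotor
activity is the total count over a 6-hour window at 23 C; heat-knockdown
time (HKDT) is the time of the last recorded count during a 2-hour
window at 39 C, in minutes.  Healthspan analyses are run on a balanced
subset: ages from the first two test days only (later days lose too
many flies), and, per trait, only lines still represented on both diets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BIN_SECONDS",
    "N_BINS_23C",
    "N_BINS_39C",
    "MAX_AGE_DAYS",
    "AGE_SCHEDULE",
    "derive_locomotor_activity",
    "derive_hkdt",
    "BalanceReport",
    "balance_dataset",
    "compute_line_means",
]

BIN_SECONDS = 10
N_BINS_23C = 6 * 3600 // BIN_SECONDS    # 2160 bins over 6 h
N_BINS_39C = 2 * 3600 // BIN_SECONDS    # 720 bins over 2 h
MAX_AGE_DAYS = 25                       # ages >= this are dropped
AGE_SCHEDULE = (7, 16, 25, 34, 43, 52, 61)


def _check_series(series, expected: int, strict: bool, label: str) -> np.ndarray:
    arr = np.asarray(series)
    if arr.ndim != 1:
        raise ValueError(f"{label} series must be 1-d")
    if strict and len(arr) != expected:
        raise ValueError(
            f"{label} series has {len(arr)} bins, expected {expected}"
        )
    if np.any(arr < 0):
        raise ValueError(f"{label} series contains negative counts")
    return arr


def derive_locomotor_activity(
    series, n_bins: int = N_BINS_23C, strict: bool = False
) -> int:
    """Total activity counts over the 23 C window (sum of 10-s bins)."""
    arr = _check_series(series, n_bins, strict, "23C")
    return int(arr.sum())


def derive_hkdt(
    series, n_bins: int = N_BINS_39C, strict: bool = False,
    bin_seconds: float = BIN_SECONDS,
) -> float:
    """Heat-knockdown time in minutes: time of the last nonzero bin.

    A fly whose 39 C series is all zeros never recorded activity under
    heat; its knockdown time is undefined and returned as NaN with a
    warning rather than zero.
    """
    arr = _check_series(series, n_bins, strict, "39C")
    nz = np.nonzero(arr)[0]
    if len(nz) == 0:
        warnings.warn("all-zero 39C series: HKDT undefined", stacklevel=2)
        return float("nan")
    return float((nz[-1] + 1) * bin_seconds / 60.0)


@dataclass
class BalanceReport:
    """What `balance_dataset` removed, and the retained table."""

    table: pd.DataFrame
    n_rows_in: int
    n_rows_age_removed: int
    lines_removed: list[str] = field(default_factory=list)
    n_rows_line_removed: int = 0

    @property
    def n_rows_out(self) -> int:
        return len(self.table)


def balance_dataset(
    table: pd.DataFrame,
    trait: str | None = None,
    max_age: int = MAX_AGE_DAYS,
) -> BalanceReport:
    """Apply the healthspan balancing rules.

    1. Rows with ``age_days >= max_age`` are dropped (too few survivors
       at later test days).
    2. If ``trait`` is given, lines with no surviving flies (no
       non-missing trait value) on either diet at any retained test age
       are removed entirely — i.e. every retained (diet, age) cell must
       be occupied for the line to stay.

    Idempotent: balancing an already balanced table changes nothing.
    """
    if table["diet"].nunique() < 2:
        raise ValueError("table must contain both diets")
    n_in = len(table)
    with_age = table["age_days"].notna()
    keep = ~with_age | (table["age_days"] < max_age)
    df = table[keep]
    n_age_removed = n_in - len(df)

    lines_removed: list[str] = []
    n_line_rows = 0
    if trait is not None:
        present = df[df[trait].notna()]
        if present.empty:
            raise ValueError(f"no data after balancing for trait {trait!r}")
        diets = sorted(present["diet"].unique())
        ages = sorted(present["age_days"].dropna().unique())
        cells = present.groupby(["line_id", "diet", "age_days"], sort=False).size()
        occupied = cells.groupby("line_id").size()
        need = len(diets) * len(ages)
        ok_lines = set(occupied[occupied >= need].index)
        lines_removed = sorted(set(df["line_id"]) - ok_lines)
        before = len(df)
        df = df[df["line_id"].isin(ok_lines)]
        n_line_rows = before - len(df)
        if df.empty:
            raise ValueError(f"no data after balancing for trait {trait!r}")
    return BalanceReport(
        table=df.reset_index(drop=True),
        n_rows_in=n_in,
        n_rows_age_removed=n_age_removed,
        lines_removed=lines_removed,
        n_rows_line_removed=n_line_rows,
    )


def compute_line_means(
    table: pd.DataFrame,
    trait: str,
    grouping: tuple[str, ...] = ("line_id", "diet", "age_days"),
) -> pd.DataFrame:
    """Per-group arithmetic mean, count and SD of one trait.

    Groups with no non-missing observations are absent from the output;
    SD is NaN for singleton groups.
    """
    if trait not in table.columns:
        raise ValueError(f"trait column {trait!r} not present")
    sub = table[table[trait].notna()]
    if sub.empty:
        raise ValueError(f"all values missing for trait {trait!r}")
    cols = [g for g in grouping if table[g].notna().any()]
    out = (
        sub.groupby(cols, sort=True, dropna=True)[trait]
        .agg(mean="mean", n="count", sd="std")
        .reset_index()
    )
    out["trait"] = trait
    return out
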