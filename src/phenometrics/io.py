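"""Schema-validated CSV I/O for the long-format observation dialect.

Columns of the observation table::

    tree_id, species, area, method, day, value, observer_id

``method`` is one of bud_score, lai, ndvi, frass_mass_g, count_total,
count_fwm.  ``day`` is integer day-of-year (1 = 1 January); ISO calendar
dates are accepted and converted, with the year recorded on the frame.
Row-level problems are collected with line numbers and reported together;
the run aborts unless ``skip_bad`` is set, in which case offending rows are
dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "OBS_COLUMNS",
    "ObservationValidationError",
    "read_observations",
    "read_trees",
    "write_observations",
]

METHODS = ("bud_score", "lai", "ndvi", "frass_mass_g", "count_total", "count_fwm")
OBS_COLUMNS = ["tree_id", "species", "area", "method", "day", "value", "observer_id"]
COUNT_METHODS = ("count_total", "count_fwm")


class ObservationValidationError(ValueError):
    """Raised when observation rows fail validation; carries per-row errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "\n".join(errors[:20])
        more = "" if len(errors) <= 20 else f"\n... and {len(errors) - 20} more"
        super().__init__(f"{len(errors)} invalid observation row(s):\n{preview}{more}")


def _parse_days(raw: pd.Series):
    """Integer day-of-year, or calendar dates converted (year recorded)."""
    num = pd.to_numeric(raw, errors="coerce")
    if num.notna().all():
        return num.astype(float), None
    dates = pd.to_datetime(raw, errors="coerce", format="mixed")
    if dates.notna().all():
        years = dates.dt.year.unique()
        return dates.dt.dayofyear.astype(float), int(years[0])
    return num, None  # NaNs flagged row-by-row downstream


def read_observations(path, trees: pd.DataFrame | None = None,
                      skip_bad: bool = False) -> pd.DataFrame:
    """Read and validate the long-format observation CSV.

    ``trees`` (optional metadata with ``tree_id`` and ``max_stage``) enables
    species-specific bud-score range checks; without it the permissive bound
    [1, 7] applies.
    """
    df = pd.read_csv(path, dtype={"tree_id": str}, keep_default_na=False,
                     na_values=[""])
    if df.empty:
        raise ValueError(f"empty observation file: {path}")
    missing = [c for c in OBS_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"observation file {path} lacks columns: {missing}")
    if "observer_id" not in df.columns:
        df["observer_id"] = ""
    df["observer_id"] = df["observer_id"].fillna("")

    days, year = _parse_days(df["day"])
    df["day"] = days
    if year is not None:
        df.attrs["year"] = year
    values = pd.to_numeric(df["value"], errors="coerce")
    df["value"] = values

    max_stage = {}
    if trees is not None and "max_stage" in trees.columns:
        max_stage = dict(zip(trees["tree_id"].astype(str), trees["max_stage"]))

    errors, bad = [], np.zeros(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        problems = []
        if row.method not in METHODS:
            problems.append(f"unknown method {row.method!r}")
        if not np.isfinite(row.day) or not (1 <= row.day <= 366):
            problems.append(f"day {row.day!r} is not a valid day-of-year")
        if not np.isfinite(row.value):
            problems.append(f"value {row.value!r} is not numeric")
        elif row.method == "bud_score":
            hi = max_stage.get(str(row.tree_id), 7)
            if not (1.0 - 1e-9 <= row.value <= hi + 1e-9):
                problems.append(
                    f"bud score {row.value} outside [1, {hi}] for tree {row.tree_id}"
                )
        elif row.value < 0:
            problems.append(f"negative value {row.value} for method {row.method}")
        if not problems and row.method in COUNT_METHODS:
            if abs(row.value - round(row.value)) > 1e-9:
                problems.append(f"non-integer count {row.value}")
        if problems:
            bad[i] = True
            errors.append(f"line {line} (tree {row.tree_id}): " + "; ".join(problems))

    if errors and not skip_bad:
        raise ObservationValidationError(errors)
    if errors:
        df = df.loc[~bad].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no valid observation rows remain in {path}")
    return df


def read_trees(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tree_id": str})
    if df.empty:
        raise ValueError(f"empty tree metadata file: {path}")
    for col in ("tree_id", "species", "area"):
        if col not in df.columns:
            raise ValueError(f"tree metadata {path} lacks column {col!r}")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
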