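"""Construction of the social trait and its spatial/phenological covariates.

The trait is the number of *actively breeding neighbours*: for a focal nest,
the other nests on the same island within a fixed radius (default 2 m) whose
clutch was initiated in the four-week window *before* (and including) the
focal laying date.  Islands are identical rectangles of 10.7 m x 4.6 m
separated by walls, so neighbourhoods do not cross islands by default; a
global-coordinates mode that bridges the 0.9 m gaps between islands is
available but off.

All functions operate on plain pandas DataFrames with the nest-record schema
``female_id, year, island, x, y, laying_date, age`` (one record per female
per year, first clutch only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import (
    ConfigError,
    GroupingError,
    InvalidArgumentError,
    InvalidCoordinateError,
    SchemaError,
)

ISLAND_LENGTH_M = 10.7  #: long side of each breeding island
ISLAND_WIDTH_M = 4.6  #: narrow side of each breeding island
ISLAND_GAP_M = 0.9  #: spacing between adjacent islands
N_ISLANDS = 6
DEFAULT_RADIUS_M = 2.0
DEFAULT_WINDOW_DAYS = 28

NEST_COLUMNS = ("female_id", "year", "island", "x", "y", "laying_date", "age")


def _require_columns(df: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")


def _positions(group: pd.DataFrame, global_coordinates: bool) -> np.ndarray:
    xy = group[["x", "y"]].to_numpy(dtype=float)
    if global_coordinates:
        offset = (group["island"].to_numpy(dtype=float) - 1) * (
            ISLAND_LENGTH_M + ISLAND_GAP_M
        )
        xy = xy.copy()
        xy[:, 0] += offset
    return xy


def count_active_neighbours(
    records: pd.DataFrame,
    radius_m: float = DEFAULT_RADIUS_M,
    window_days: int = DEFAULT_WINDOW_DAYS,
    global_coordinates: bool = False,
) -> pd.Series:
    """Active-neighbour count per nest for a single breeding season.

    A nest g is an active neighbour of focal f when it lies within
    ``radius_m`` (ties at the radius count), on the same island unless
    ``global_coordinates``, and its laying date falls in the closed window
    ``[laying_date_f - window_days, laying_date_f]``.  Same-day layers count
    each other mutually; the window is strictly one-sided otherwise.
    """
    if radius_m <= 0:
        raise InvalidArgumentError(f"radius_m must be positive, got {radius_m}")
    if window_days < 0:
        raise InvalidArgumentError(f"window_days must be >= 0, got {window_days}")
    _require_columns(records, ("island", "x", "y", "laying_date", "year"))
    if records["year"].nunique() > 1:
        raise GroupingError(
            "count_active_neighbours expects records from a single season; "
            f"got years {sorted(records['year'].unique())}"
        )
    counts = pd.Series(0, index=records.index, dtype=int, name="neighbour_count")
    groups = (
        [(None, records)]
        if global_coordinates
        else list(records.groupby("island", sort=False))
    )
    for _, grp in groups:
        if len(grp) < 2:
            continue
        xy = _positions(grp, global_coordinates)
        close = cdist(xy, xy) <= radius_m
        ld = grp["laying_date"].to_numpy(dtype=float)
        active = (ld[None, :] >= ld[:, None] - window_days) & (
            ld[None, :] <= ld[:, None]
        )
        mask = close & active
        np.fill_diagonal(mask, False)
        counts.loc[grp.index] = mask.sum(axis=1)
    return counts


def island_density_at_breeding(
    records: pd.DataFrame, window_days: int = DEFAULT_WINDOW_DAYS
) -> pd.Series:
    """Nests initiated on the focal island in the window before focal laying.

    Equals the active-neighbour count at infinite radius: the focal record is
    excluded, the time window is the same closed one-sided window.
    """
    if window_days < 0:
        raise InvalidArgumentError(f"window_days must be >= 0, got {window_days}")
    _require_columns(records, ("island", "laying_date", "year"))
    if records["year"].nunique() > 1:
        raise GroupingError("island_density_at_breeding expects a single season")
    out = pd.Series(0, index=records.index, dtype=int, name="island_density")
    for _, grp in records.groupby("island", sort=False):
        ld = grp["laying_date"].to_numpy(dtype=float)
        active = (ld[None, :] >= ld[:, None] - window_days) & (
            ld[None, :] <= ld[:, None]
        )
        np.fill_diagonal(active, False)
        out.loc[grp.index] = active.sum(axis=1)
    return out


def distance_to_nearest_wall(x, y):
    """min(x, 10.7 - x, y, 4.6 - y): metres to the closest island wall."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(x > ISLAND_LENGTH_M) or np.any(y < 0) or np.any(
        y > ISLAND_WIDTH_M
    ):
        raise InvalidCoordinateError(
            "coordinates outside the island rectangle "
            f"[0, {ISLAND_LENGTH_M}] x [0, {ISLAND_WIDTH_M}]"
        )
    d = np.minimum.reduce([x, ISLAND_LENGTH_M - x, y, ISLAND_WIDTH_M - y])
    return float(d) if d.ndim == 0 else d


def apply_study_filters(
    records: pd.DataFrame,
    mode: str = "known_age",
    last_observation_year: int | None = None,
) -> pd.DataFrame:
    """Apply the study's record filters.

    ``known_age`` drops every record of females whose age is ever unknown.
    ``presumed_dead`` additionally keeps only females that can be presumed
    dead, i.e. not observed in either of the two most recent breeding
    seasons (``last_observation_year`` and the year before).
    """
    _require_columns(records, ("female_id", "age", "year"))
    if mode not in ("known_age", "presumed_dead"):
        raise InvalidArgumentError(f"unknown filter mode: {mode!r}")
    unknown_females = records.loc[records["age"].isna(), "female_id"].unique()
    out = records[~records["female_id"].isin(unknown_females)]
    if mode == "presumed_dead":
        if last_observation_year is None:
            raise ConfigError(
                "presumed_dead filtering requires last_observation_year"
            )
        recent = {last_observation_year, last_observation_year - 1}
        alive = records.loc[records["year"].isin(recent), "female_id"].unique()
        out = out[~out["female_id"].isin(alive)]
    return out.copy()


def build_trait_table(
    nests: pd.DataFrame,
    radius_m: float = DEFAULT_RADIUS_M,
    window_days: int = DEFAULT_WINDOW_DAYS,
    global_coordinates: bool = False,
) -> pd.DataFrame:
    """Assemble the analysis-ready table from multi-season nest records.

    Adds, per record: ``neighbour_count`` (the social trait),
    ``island_density`` (nests initiated on the focal island in the focal
    window), ``wall_distance`` and ``colony_density`` (breeding pairs that
    year, computed from the records).  Input columns are carried through
    unchanged.
    """
    _require_columns(nests, ("female_id", "year", "island", "x", "y", "laying_date"))
    dup = nests.duplicated(subset=["female_id", "year"])
    if dup.any():
        raise InvalidArgumentError(
            f"{int(dup.sum())} duplicate female-year record(s); keep first clutches only"
        )
    out = nests.copy()
    out["neighbour_count"] = 0
    out["island_density"] = 0
    for _, season in nests.groupby("year", sort=False):
        out.loc[season.index, "neighbour_count"] = count_active_neighbours(
            season, radius_m=radius_m, window_days=window_days,
            global_coordinates=global_coordinates,
        )
        out.loc[season.index, "island_density"] = island_density_at_breeding(
            season, window_days=window_days
        )
    out["wall_distance"] = distance_to_nearest_wall(
        out["x"].to_numpy(), out["y"].to_numpy()
    )
    out["colony_density"] = out.groupby("year")["female_id"].transform("size")
    return out
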