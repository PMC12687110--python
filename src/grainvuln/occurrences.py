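"""Occurrence records: IO, eligibility filtering, spatial thinning, annotation.

Occurrence collections are pandas DataFrames with the column contract

    species_id : str      — species identifier
    x_km, y_km : float    — planar coordinates, km
    year       : int      — observation year
    month      : int      — observation month, 1–12
    travel_km  : float    — travel distance associated with the record, km

Annotation appends one column per environmental variable holding the
breeding-season mean of the record's year at the record's grid cell.

The breeding season is hemisphere specific (May–July north of the equator,
November–January south of it by default) and is decided *per record* from
the sign of ``y_km``, so no species-level hemisphere metadata is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidArgumentError, MissingLayerError
from .grids import Grid, MonthlyStack

__all__ = [
    "OCCURRENCE_COLUMNS",
    "FilterParams",
    "read_occurrences",
    "write_occurrences",
    "filter_records",
    "thin",
    "annotate",
]

logger = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ["species_id", "x_km", "y_km", "year", "month", "travel_km"]


@dataclass(frozen=True)
class FilterParams:
    """Eligibility rules for occurrence records.

    Defaults follow the breeding-season filtering used for hemispheric bird
    data: records from 1981–2018, within 1 km travel distance, in May–July
    (northern hemisphere) or November–January (southern hemisphere), and a
    species must retain more than 20 records after spatial thinning.
    """

    year_range: tuple[int, int] = (1981, 2018)
    max_travel_km: float = 1.0
    breeding_months_north: frozenset[int] = frozenset({5, 6, 7})
    breeding_months_south: frozenset[int] = frozenset({11, 12, 1})
    min_records_after_thinning: int = 20

    def __post_init__(self):
        if self.year_range[0] > self.year_range[1]:
            raise InvalidArgumentError("year_range must satisfy min ≤ max")
        if not self.breeding_months_north or not self.breeding_months_south:
            raise InvalidArgumentError("breeding month sets must be non-empty")

    def breeding_months(self, y_km: float) -> frozenset[int]:
        """Breeding window for a record at latitude-proxy ``y_km`` (≥ 0 → north)."""
        return self.breeding_months_north if y_km >= 0 else self.breeding_months_south


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read an occurrence CSV with the documented header."""
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"occurrence CSV lacks columns {missing}")
    return df


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def filter_records(records: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Keep records inside the year window, travel limit and breeding season.

    Idempotent; returns a copy preserving row order and index.
    """
    y0, y1 = params.year_range
    north = records["y_km"].to_numpy() >= 0
    month = records["month"].to_numpy()
    in_season = np.where(
        north,
        pd.Series(month).isin(params.breeding_months_north).to_numpy(),
        pd.Series(month).isin(params.breeding_months_south).to_numpy(),
    )
    keep = (
        (records["year"] >= y0)
        & (records["year"] <= y1)
        & (records["travel_km"] <= params.max_travel_km)
        & in_season
    )
    return records.loc[keep].copy()


def thin(
    points: pd.DataFrame,
    min_distance: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Spatially thin points so that all pairwise distances ≥ ``min_distance``.

    Uses the randomized-greedy scheme of the spThin R package: while any pair
    of retained points conflicts (distance < ``min_distance``), delete one
    point from the currently most-crowded conflict neighbourhood, breaking
    ties uniformly at random with the seeded generator.  The result is a
    maximal conflict-free subset (no deleted point could be re-added) and is
    deterministic given the seed.  Coordinates are read from ``x_km``/``y_km``.
    """
    if min_distance < 0:
        raise InvalidArgumentError("min_distance must be ≥ 0")
    n = len(points)
    if n <= 1 or min_distance == 0:
        return points.copy()
    rng = np.random.default_rng(seed)
    coords = points[["x_km", "y_km"]].to_numpy(dtype=float)
    # conflict iff strictly closer than the minimum separation
    conflict = squareform(pdist(coords)) < min_distance
    np.fill_diagonal(conflict, False)
    alive = np.ones(n, dtype=bool)
    counts = conflict.sum(axis=1)
    while True:
        cmax = counts[alive].max() if alive.any() else 0
        if cmax == 0:
            break
        candidates = np.flatnonzero(alive & (counts == cmax))
        victim = rng.choice(candidates)
        alive[victim] = False
        counts[conflict[victim]] -= 1
        counts[victim] = 0
    return points.loc[points.index[alive]].copy()


def annotate(
    records: pd.DataFrame,
    stacks: list[MonthlyStack],
    params: FilterParams,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Attach breeding-season mean environments to occurrence records.

    For each record and each variable, the annotation is the mean over the
    record's hemisphere's breeding months, in the record's year, of that
    variable at the grid cell containing ``(x_km, y_km)`` (half-open cell
    membership).  The grain is whatever grain the supplied monthly grids are
    at.  Records falling outside the lattice or on missing cells are dropped
    and the count is logged.

    Raises :class:`MissingLayerError` if a required (variable, year, month)
    layer is absent from ``stacks``.
    """
    if variables is None:
        variables = sorted({s.variable for s in stacks})
    layers: dict[tuple[str, int, int], Grid] = {}
    geom: Grid | None = None
    for s in stacks:
        layers[(s.variable, s.year, s.month)] = s.grid
        if geom is None:
            geom = s.grid
        elif not geom.same_geometry(s.grid):
            raise InvalidArgumentError("monthly stacks do not share one geometry")
    if geom is None:
        raise InvalidArgumentError("no monthly stacks supplied")

    rows, cols = geom.cell_index(records["x_km"].to_numpy(), records["y_km"].to_numpy())
    nr, nc = geom.shape
    in_bounds = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)

    env = np.full((len(records), len(variables)), np.nan)
    years = records["year"].to_numpy()
    norths = records["y_km"].to_numpy() >= 0
    for key_north, months in (
        (True, sorted(params.breeding_months_north)),
        (False, sorted(params.breeding_months_south)),
    ):
        sel = norths == key_north
        if not sel.any():
            continue
        for year in np.unique(years[sel]):
            grp = sel & (years == year) & in_bounds
            if not grp.any():
                continue
            for vi, var in enumerate(variables):
                acc = np.zeros(grp.sum())
                for m in months:
                    grid = layers.get((var, int(year), m))
                    if grid is None:
                        raise MissingLayerError(
                            f"missing layer variable={var!r} year={year} month={m}"
                        )
                    acc += grid.values[rows[grp], cols[grp]]
                env[grp, vi] = acc / len(months)

    ok = in_bounds & ~np.isnan(env).any(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("annotate: dropped %d record(s) on missing or out-of-bounds cells", dropped)
    out = records.loc[records.index[ok]].copy()
    for vi, var in enumerate(variables):
        out[var] = env[ok, vi]
    return out
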