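"""Species attributes and assemblage-level summaries.

Covers the range-geometry side of the analysis: buffered/merged range
polygons, Levin's dietary niche breadth, coarse-grid maps of mean grain
dependence (weighted by inverse range size so wide-ranged species do not
dominate), counts of the most vulnerable species per coarse cell, and the
species × grain predictor table exported for an external mixed-model fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, box, mapping, shape

from .errors import InvalidArgumentError
from .grids import Grid
from .scaling import GrainLadder, ScalingCurve

__all__ = [
    "SpeciesAttributes",
    "buffer_merge_range",
    "polygon_to_geojson",
    "geojson_to_polygon",
    "levins_breadth",
    "grain_dependence_map",
    "top_vulnerable_counts",
    "driver_table",
    "DRIVER_COLUMNS",
]

DEFAULT_BUFFER_KM = 50.0  # planar stand-in for a 0.5° buffer (~50 km)


@dataclass
class SpeciesAttributes:
    """Range- and trait-derived predictors for one species.

    ``elev_mean``/``elev_range`` are optional (None when no elevation source
    covers the species) and exported as empty fields, not zeros.
    """

    species_id: str
    range_size: float  # km², buffered and merged
    centroid_x: float
    centroid_y: float
    morans_i_temp: float
    morans_i_precip: float
    levins_b: float
    body_mass_log: float
    island_fraction: float = 0.0
    elev_mean: float | None = None
    elev_range: float | None = None

    def __post_init__(self):
        if not self.range_size > 0:
            raise InvalidArgumentError("range_size must be > 0")
        if not 0.0 <= self.island_fraction <= 1.0:
            raise InvalidArgumentError("island_fraction must be in [0, 1]")


def buffer_merge_range(range_polygon, points, buffer_km: float = DEFAULT_BUFFER_KM):
    """Buffer a range polygon and occurrence points and merge them.

    Returns the union of the polygon buffered by ``buffer_km`` with a disc
    of radius ``buffer_km`` around every point, guaranteeing all occurrence
    points lie inside the result.  ``range_polygon`` may be None (points
    only) and ``points`` may be empty (polygon only), but not both.
    """
    if buffer_km < 0:
        raise InvalidArgumentError("buffer_km must be ≥ 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2) if points is not None else np.empty((0, 2))
    parts = []
    if range_polygon is not None and not range_polygon.is_empty:
        parts.append(range_polygon.buffer(buffer_km))
    if len(pts):
        parts.append(MultiPoint(pts).buffer(buffer_km))
    if not parts:
        raise InvalidArgumentError("need a range polygon and/or occurrence points")
    return shapely.unary_union(parts)


def polygon_to_geojson(geom, path: str | Path | None = None) -> str:
    """Serialise a (multi)polygon as a GeoJSON Feature."""
    doc = {"type": "Feature", "properties": {}, "geometry": mapping(geom)}
    text = json.dumps(doc)
    if path is not None:
        Path(path).write_text(text)
    return text


def geojson_to_polygon(source: str | Path):
    """Read a polygon from a GeoJSON Feature, FeatureCollection or geometry."""
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if not text.lstrip().startswith("{"):
        text = Path(text).read_text()
    doc = json.loads(text)
    if doc.get("type") == "FeatureCollection":
        return shapely.unary_union([shape(f["geometry"]) for f in doc["features"]])
    if doc.get("type") == "Feature":
        return shape(doc["geometry"])
    return shape(doc)


def levins_breadth(p, R: int | None = None) -> float:
    """Levin's niche breadth B = 1 / (R · Σᵢ pᵢ²).

    ``p`` is a vector of relative frequencies over R categories (summing to
    one).  B is 1 for a uniform diet and 1/R for complete specialisation on
    a single category.
    """
    p = np.asarray(p, dtype=float)
    if R is None:
        R = p.size
    if p.size != R:
        raise InvalidArgumentError(f"p has {p.size} entries but R = {R}")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("p must be non-negative and sum to 1")
    return float(1.0 / (R * np.sum(p**2)))


def _dependence_of(curve) -> float:
    return curve.grain_dependence if isinstance(curve, ScalingCurve) else float(curve)


def _overlaps(range_polygon, cell) -> bool:
    # positive-area overlap: a range merely touching a cell edge or corner
    # does not count as being distributed within that cell
    return shapely.intersects(range_polygon, cell) and not shapely.touches(
        range_polygon, cell
    )


def _cell_boxes(coarse: Grid):
    nr, nc = coarse.shape
    s = coarse.cell_size
    x0, y0 = coarse.origin
    for r in range(nr):
        for c in range(nc):
            yield r, c, box(x0 + c * s, y0 + r * s, x0 + (c + 1) * s, y0 + (r + 1) * s)


def grain_dependence_map(
    curves: dict[str, ScalingCurve | float],
    attributes: dict[str, SpeciesAttributes] | None,
    ranges: dict[str, object],
    coarse: Grid,
) -> Grid:
    """Mean grain dependence per coarse cell, weighted by 1/range size.

    For every coarse cell, averages the grain dependence of the species
    whose buffered range polygon intersects the cell rectangle, with
    weights ``1/range_size`` (range size from ``attributes`` when given,
    else the polygon area).  Cells intersecting no range are missing.
    Invariant to species ordering.
    """
    species = sorted(curves)
    deps = {sp: _dependence_of(curves[sp]) for sp in species}
    wts = {}
    for sp in species:
        if attributes is not None and sp in attributes:
            wts[sp] = 1.0 / attributes[sp].range_size
        else:
            wts[sp] = 1.0 / ranges[sp].area
    vals = np.full(coarse.shape, np.nan)
    for sp in species:
        shapely.prepare(ranges[sp])
    for r, c, cell in _cell_boxes(coarse):
        num = den = 0.0
        for sp in species:
            if _overlaps(ranges[sp], cell):
                num += wts[sp] * deps[sp]
                den += wts[sp]
        if den > 0:
            vals[r, c] = num / den
    return Grid(vals, coarse.cell_size, coarse.origin)


def top_vulnerable_counts(
    evs: dict[str, float],
    q: float,
    ranges: dict[str, object],
    coarse: Grid,
) -> tuple[Grid, list[str]]:
    """Count the top-q most vulnerable species per coarse cell.

    Flags the ⌈q·S⌉ species with the highest EVS (ties resolved by EVS rank
    descending, then species id ascending) and counts, in each coarse cell,
    the flagged species whose buffered range intersects the cell rectangle.
    Returns the count grid (no missing cells; zero where none intersect)
    and the flagged species ids.
    """
    if not 0 < q < 1:
        raise InvalidArgumentError("q must be in (0, 1)")
    order = sorted(evs, key=lambda sp: (-evs[sp], sp))
    k = math.ceil(q * len(order))
    flagged = order[:k]
    counts = np.zeros(coarse.shape)
    for r, c, cell in _cell_boxes(coarse):
        counts[r, c] = sum(1 for sp in flagged if _overlaps(ranges[sp], cell))
    return Grid(counts, coarse.cell_size, coarse.origin), flagged


DRIVER_COLUMNS = [
    "species_id",
    "grain_km",
    "evs",
    "range_size",
    "centroid_x",
    "centroid_y",
    "morans_i_temp",
    "morans_i_precip",
    "levins_b",
    "body_mass_log",
    "island_fraction",
    "elev_mean",
    "elev_range",
]


def driver_table(
    attributes: dict[str, SpeciesAttributes],
    curves: dict[str, ScalingCurve],
    ladder: GrainLadder,
) -> pd.DataFrame:
    """Species × grain predictor table for an external mixed-model fit.

    One row per species per ladder grain with the EVS response and all
    range/trait predictors; EVS is NaN for grains that failed for a
    species, and optional elevation attributes stay NaN (empty CSV fields).
    Column names and order follow :data:`DRIVER_COLUMNS`.
    """
    rows = []
    for sp in sorted(curves):
        curve = curves[sp]
        attr = attributes[sp]
        for grain in ladder.grains:
            res = curve.results.get(grain)
            rows.append(
                {
                    "species_id": sp,
                    "grain_km": float(grain),
                    "evs": res.evs if res is not None else np.nan,
                    "range_size": attr.range_size,
                    "centroid_x": attr.centroid_x,
                    "centroid_y": attr.centroid_y,
                    "morans_i_temp": attr.morans_i_temp,
                    "morans_i_precip": attr.morans_i_precip,
                    "levins_b": attr.levins_b,
                    "body_mass_log": attr.body_mass_log,
                    "island_fraction": attr.island_fraction,
                    "elev_mean": np.nan if attr.elev_mean is None else attr.elev_mean,
                    "elev_range": np.nan if attr.elev_range is None else attr.elev_range,
                }
            )
    return pd.DataFrame(rows, columns=DRIVER_COLUMNS)
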