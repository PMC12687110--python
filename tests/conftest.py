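import numpy as np
import pytest

from grainvuln import FilterParams, Grid, MonthlyStack, NicheModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def correlated_niche_2d():
    """2-D niche with unit variances and correlation 0.5."""
    return NicheModel(
        mu=np.array([0.0, 0.0]),
        sigma=np.array([[1.0, 0.5], [0.5, 1.0]]),
        variables=["temperature", "precipitation"],
        n_records=100,
    )


@pytest.fixture
def scalar_niche_1d():
    return NicheModel(
        mu=np.array([0.0]), sigma=np.array([[1.0]]), variables=["temperature"],
        n_records=100,
    )


@pytest.fixture
def breeding_params():
    return FilterParams(year_range=(2001, 2005))


def constant_stacks(value, years, months, shape=(4, 4), cell=1.0, variables=("temperature", "precipitation")):
    """Monthly stacks holding a constant value everywhere."""
    return [
        MonthlyStack(v, y, m, Grid(np.full(shape, float(value)), cell))
        for v in variables
        for y in years
        for m in months
    ]


def brute_force_morans_i(grid: Grid, max_distance: float) -> float:
    """O(N²) double-sum evaluation of the Moran's I formula."""
    nr, nc = grid.shape
    pts, zs = [], []
    for r in range(nr):
        for c in range(nc):
            if grid.missing_mask[r, c]:
                continue
            pts.append(
                (
                    grid.origin[0] + (c + 0.5) * grid.cell_size,
                    grid.origin[1] + (r + 0.5) * grid.cell_size,
                )
            )
            zs.append(grid.values[r, c])
    z = np.array(zs) - np.mean(zs)
    n = len(z)
    num = w_sum = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
            if 0 < d <= max_distance:
                num += z[i] * z[j]
                w_sum += 1.0
    return (n / w_sum) * num / float(z @ z)


def brute_force_aggregate(values: np.ndarray, factor: int) -> np.ndarray:
    """Loop-based block means over possibly partial trailing blocks."""
    nr, nc = values.shape
    out = np.full((int(np.ceil(nr / factor)), int(np.ceil(nc / factor))), np.nan)
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            block = values[r * factor : (r + 1) * factor, c * factor : (c + 1) * factor]
            if np.isfinite(block).any():
                out[r, c] = np.nanmean(block)
    return out
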