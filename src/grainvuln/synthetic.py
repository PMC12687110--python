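"""Synthetic test worlds with known truth.

Generates complete study systems for validating the vulnerability pipeline:
spatially autocorrelated temperature and precipitation landscapes with
seasonal and interannual variation, a deterministic future-shift scenario,
virtual species with known bivariate-normal niches, occurrence records
sampled in proportion to suitability, and a range polygon enclosing the
occurrences.  Every generator is a pure function of its parameters and seed.

The landscape is planar in km.  Base fields are stationary zero-mean
Gaussian random fields with exponential correlation exp(−d/ℓ) simulated by
circulant embedding; ℓ = 0 gives spatially white noise.  A monthly layer is

    base + seasonal cycle(month) + year anomaly

where the year anomaly is a white-noise field drawn once per (variable,
year) and shared by all months of that year.  Sharing the anomaly within a
year makes the breeding-season mean of a record's year identical to the
condition under which the record was accepted, so estimation pipelines can
be validated against the exact truth.  The future condition t1 is the
recent mean t0 plus a deterministic shift (constant or gradient field).

Occurrence sampling is rejection sampling over (cell, year, breeding
month): a proposal is accepted with probability exp(−MD²/2) of its
environment under the true niche — the standard Gaussian *density* kernel
(with the ½), which is a property of the simulated species and independent
of the suitability weighting convention used by the vulnerability metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ScenarioMismatchError
from .grids import Grid, MonthlyStack, PeriodMean, write_grid

__all__ = [
    "LandscapeScenario",
    "VirtualSpecies",
    "ScenarioWorld",
    "gaussian_random_field",
    "make_scenario",
    "sample_occurrences",
    "make_world",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class LandscapeScenario:
    """Parameters of a synthetic climate landscape and its future shift.

    Units: temperature °C, precipitation mm (monthly totals), lengths km.
    ``shift_*`` may be a scalar (uniform exposure) or an array matching
    ``dims`` (gradient exposure).
    """

    dims: tuple[int, int] = (64, 64)
    cell_km: float = 1.0
    corr_length_temp: float = 10.0
    corr_length_precip: float = 10.0
    sill_temp: float = 9.0
    sill_precip: float = 900.0
    mean_temp: float = 15.0
    mean_precip: float = 100.0
    cycle_amp_temp: float = 0.0
    cycle_amp_precip: float = 0.0
    interannual_sd_temp: float = 1.0
    interannual_sd_precip: float = 10.0
    shift_temp: float | np.ndarray = 1.0
    shift_precip: float | np.ndarray = 10.0
    years: tuple[int, ...] = (2001, 2002, 2003, 2004, 2005)
    months: tuple[int, ...] = (5, 6, 7)
    clamp_precip: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.dims[0] < 8 or self.dims[1] < 8:
            raise InvalidArgumentError("landscape must be at least 8×8 cells")
        if self.sill_temp <= 0 or self.sill_precip <= 0:
            raise InvalidArgumentError("sills must be > 0")
        if self.corr_length_temp < 0 or self.corr_length_precip < 0:
            raise InvalidArgumentError("correlation lengths must be ≥ 0")


@dataclass(frozen=True)
class VirtualSpecies:
    """A simulated species with a known bivariate-normal niche."""

    species_id: str = "virtual_1"
    true_mu: tuple[float, float] = (15.0, 100.0)  # (°C, mm)
    true_sigma: tuple[tuple[float, float], tuple[float, float]] = (
        (4.0, 0.0),
        (0.0, 400.0),
    )
    n_occurrences: int = 500
    seed: int = 0

    def mu_array(self) -> np.ndarray:
        return np.asarray(self.true_mu, dtype=float)

    def sigma_array(self) -> np.ndarray:
        s = np.asarray(self.true_sigma, dtype=float)
        if np.linalg.eigvalsh(s).min() <= 0:
            raise InvalidArgumentError("true_sigma must be positive definite")
        return s


@dataclass
class ScenarioWorld:
    """A realised scenario: monthly layers plus the t0/t1 period means."""

    scenario: LandscapeScenario
    stacks: list[MonthlyStack]
    t0: dict[str, PeriodMean]
    t1: dict[str, PeriodMean]

    def layer(self, variable: str, year: int, month: int) -> Grid:
        for s in self.stacks:
            if (s.variable, s.year, s.month) == (variable, year, month):
                return s.grid
        raise KeyError((variable, year, month))


def gaussian_random_field(
    dims: tuple[int, int],
    cell_km: float,
    corr_length: float,
    sill: float,
    seed: int | np.random.Generator,
) -> Grid:
    """Zero-mean stationary Gaussian field with exponential correlation.

    Correlation between cells at distance d is exp(−d/corr_length) and the
    marginal variance is ``sill``; ``corr_length = 0`` gives iid white
    noise.  Simulated by circulant embedding on a 2×-padded torus; the few
    slightly negative embedding eigenvalues of the exponential kernel are
    clipped at zero, which perturbs the target covariance negligibly at
    this padding.  Deterministic given the seed.
    """
    if corr_length < 0:
        raise InvalidArgumentError("corr_length must be ≥ 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nr, nc = dims
    if corr_length == 0:
        return Grid(rng.normal(0.0, np.sqrt(sill), size=(nr, nc)), cell_km)
    m, n = 2 * nr, 2 * nc
    di = np.minimum(np.arange(m), m - np.arange(m)) * cell_km
    dj = np.minimum(np.arange(n), n - np.arange(n)) * cell_km
    dist = np.hypot(di[:, None], dj[None, :])
    cov = sill * np.exp(-dist / corr_length)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    eps = rng.normal(size=(m, n)) + 1j * rng.normal(size=(m, n))
    fld = np.fft.fft2(np.sqrt(lam) * eps).real / np.sqrt(m * n)
    return Grid(fld[:nr, :nc], cell_km)


def _seasonal_cycle(month: int, amplitude: float) -> float:
    # peak in July, trough in January
    return amplitude * np.cos(2.0 * np.pi * (month - 7) / 12.0)


def make_scenario(s: LandscapeScenario) -> ScenarioWorld:
    """Realise a scenario into monthly layers and the t0/t1 period means.

    Monthly layer(variable, year, month) = mean + base field +
    seasonal cycle(month) + year anomaly.  The recent condition t0 is the
    mean of the breeding-month layers across all scenario years; the future
    condition t1 adds the (constant or gradient) shift to t0.
    """
    root = np.random.SeedSequence(s.seed)
    base_ss, anom_ss = root.spawn(2)
    base_rngs = [np.random.default_rng(c) for c in base_ss.spawn(2)]
    nr, nc = s.dims

    base = {
        "temperature": gaussian_random_field(
            s.dims, s.cell_km, s.corr_length_temp, s.sill_temp, base_rngs[0]
        ).values
        + s.mean_temp,
        "precipitation": gaussian_random_field(
            s.dims, s.cell_km, s.corr_length_precip, s.sill_precip, base_rngs[1]
        ).values
        + s.mean_precip,
    }
    amp = {"temperature": s.cycle_amp_temp, "precipitation": s.cycle_amp_precip}
    ia_sd = {"temperature": s.interannual_sd_temp, "precipitation": s.interannual_sd_precip}

    anom_children = anom_ss.spawn(len(s.years))
    anomalies: dict[tuple[str, int], np.ndarray] = {}
    for year, child in zip(s.years, anom_children):
        r = np.random.default_rng(child)
        for var in ("temperature", "precipitation"):
            anomalies[(var, year)] = r.normal(0.0, ia_sd[var], size=(nr, nc))

    stacks: list[MonthlyStack] = []
    for var in ("temperature", "precipitation"):
        for year in s.years:
            for month in s.months:
                vals = base[var] + _seasonal_cycle(month, amp[var]) + anomalies[(var, year)]
                if var == "precipitation" and s.clamp_precip:
                    vals = np.maximum(vals, 0.0)
                stacks.append(
                    MonthlyStack(var, int(year), int(month), Grid(vals, s.cell_km))
                )

    shift = {
        "temperature": np.broadcast_to(np.asarray(s.shift_temp, dtype=float), s.dims),
        "precipitation": np.broadcast_to(np.asarray(s.shift_precip, dtype=float), s.dims),
    }
    t0: dict[str, PeriodMean] = {}
    t1: dict[str, PeriodMean] = {}
    for var in ("temperature", "precipitation"):
        layers = [st.grid.values for st in stacks if st.variable == var]
        mean0 = np.mean(layers, axis=0)
        t0[var] = PeriodMean(var, "recent_t0", Grid(mean0, s.cell_km))
        t1[var] = PeriodMean(var, "future_t1", Grid(mean0 + shift[var], s.cell_km))
    return ScenarioWorld(s, stacks, t0, t1)


def sample_occurrences(
    sp: VirtualSpecies,
    world: ScenarioWorld,
    n: int | None = None,
    seed: int | None = None,
    max_attempts_per_record: int = 5000,
) -> pd.DataFrame:
    """Sample occurrence records in proportion to true niche suitability.

    Rejection sampling over (cell, year, breeding month) uniform proposals;
    a proposal with environment x is accepted with probability
    exp(−(x−μ)ᵀΣ⁻¹(x−μ)/2).  Records carry the cell-center coordinates,
    the proposal's year and month, and zero travel distance.  Raises
    :class:`ScenarioMismatchError` when the attempt budget is exhausted,
    i.e. the landscape offers essentially no suitable environments.
    """
    n = sp.n_occurrences if n is None else int(n)
    rng = np.random.default_rng(sp.seed if seed is None else seed)
    if n == 0:
        return pd.DataFrame(
            columns=["species_id", "x_km", "y_km", "year", "month", "travel_km"]
        )
    mu = sp.mu_array()
    sigma_inv = np.linalg.inv(sp.sigma_array())
    s = world.scenario
    nr, nc = s.dims
    ym = [(y, m) for y in s.years for m in s.months]
    temp_cube = np.stack([world.layer("temperature", y, m).values for y, m in ym])
    precip_cube = np.stack([world.layer("precipitation", y, m).values for y, m in ym])
    ym_arr = np.array(ym)

    chunks = []
    attempts = 0
    budget = max_attempts_per_record * n
    accepted = 0
    batch = max(4 * n, 256)
    while accepted < n:
        if attempts >= budget:
            raise ScenarioMismatchError(
                f"accepted only {accepted}/{n} records after {attempts} proposals; "
                "the landscape offers too little suitable environment for this niche"
            )
        rr = rng.integers(0, nr, size=batch)
        cc = rng.integers(0, nc, size=batch)
        ti = rng.integers(0, len(ym), size=batch)
        u = rng.random(batch)
        attempts += batch
        d = np.column_stack([temp_cube[ti, rr, cc], precip_cube[ti, rr, cc]]) - mu
        md2 = np.einsum("ij,jk,ik->i", d, sigma_inv, d)
        hit = u < np.exp(-md2 / 2.0)
        if hit.any():
            take = np.flatnonzero(hit)[: n - accepted]
            chunks.append(
                pd.DataFrame(
                    {
                        "x_km": (cc[take] + 0.5) * s.cell_km,
                        "y_km": (rr[take] + 0.5) * s.cell_km,
                        "year": ym_arr[ti[take], 0],
                        "month": ym_arr[ti[take], 1],
                    }
                )
            )
            accepted += len(take)
    df = pd.concat(chunks, ignore_index=True)
    df.insert(0, "species_id", sp.species_id)
    df["travel_km"] = 0.0
    return df


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("generalist", "specialist", "autocorrelated", "white_noise", "uniform_shift")

# Landscape sills are the squared spatial SDs of the mean fields; the
# white-noise world is deliberately very heterogeneous (SD 8 °C / 80 mm)
# so that occurrence environments span far more than the virtual species'
# niche breadth and parameter recovery is dominated by the niche, not the
# landscape.  Niche SDs: specialist 0.75 °C / 7.5 mm; generalist 20 °C /
# 200 mm (breadth ≫ landscape variability).
_FIXTURES: dict[str, tuple[dict, dict]] = {
    "white_noise": (
        # sized so distinct (cell, year) environments far outnumber the
        # occurrences: records resample a finite environment pool, and niche
        # recovery is only as good as that pool is rich
        dict(
            corr_length_temp=0.0, corr_length_precip=0.0,
            sill_temp=64.0, sill_precip=6400.0,
            dims=(96, 96), years=tuple(range(1996, 2006)),
        ),
        dict(
            true_mu=(15.0, 100.0),
            true_sigma=((2.25, 9.0), (9.0, 225.0)),  # SD 1.5 °C, 15 mm, ρ = 0.4
            n_occurrences=2000,
        ),
    ),
    "autocorrelated": (
        dict(
            corr_length_temp=10.0, corr_length_precip=10.0,
            sill_temp=9.0, sill_precip=900.0,
        ),
        dict(true_mu=(15.0, 100.0), true_sigma=((4.0, 0.0), (0.0, 400.0)), n_occurrences=500),
    ),
    "specialist": (
        dict(
            corr_length_temp=10.0, corr_length_precip=10.0,
            sill_temp=9.0, sill_precip=900.0,
        ),
        dict(
            true_mu=(15.0, 100.0),
            true_sigma=((0.5625, 0.0), (0.0, 56.25)),
            n_occurrences=400,
        ),
    ),
    "generalist": (
        dict(
            corr_length_temp=10.0, corr_length_precip=10.0,
            sill_temp=9.0, sill_precip=900.0,
        ),
        dict(
            true_mu=(15.0, 100.0),
            true_sigma=((400.0, 0.0), (0.0, 40000.0)),
            n_occurrences=400,
        ),
    ),
    "uniform_shift": (
        dict(
            corr_length_temp=10.0, corr_length_precip=10.0,
            sill_temp=9.0, sill_precip=900.0,
            interannual_sd_temp=0.5, interannual_sd_precip=5.0,
        ),
        dict(true_mu=(15.0, 100.0), true_sigma=((4.0, 0.0), (0.0, 400.0)), n_occurrences=400),
    ),
}


def make_world(
    name: str, seed: int = 0, **overrides
) -> tuple[ScenarioWorld, VirtualSpecies, pd.DataFrame]:
    """Build a named fixture world in memory.

    Returns (world, virtual species, occurrence records).  ``overrides``
    update the scenario parameters (e.g. smaller ``dims`` for quick tests).
    """
    if name not in _FIXTURES:
        raise InvalidArgumentError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    scen_kw, sp_kw = _FIXTURES[name]
    ss = np.random.SeedSequence([seed, FIXTURE_NAMES.index(name)])
    scen_seed, sp_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    scenario = LandscapeScenario(seed=scen_seed, **{**scen_kw, **overrides})
    species = VirtualSpecies(species_id=name, seed=sp_seed, **sp_kw)
    world = make_scenario(scenario)
    occ = sample_occurrences(species, world)
    return world, species, occ


def make_fixture(name: str, out_dir: str | Path, seed: int = 0, **overrides) -> Path:
    """Write a self-contained fixture directory and its truth manifest.

    Layout: ``monthly/<var>_<year>_<month>.asc`` monthly layers,
    ``<var>_t0.asc``/``<var>_t1.asc`` period means, ``occurrences.csv``,
    ``range.geojson`` (occurrence points buffered and merged), and
    ``truth.json`` recording every scenario/species parameter and seed.
    Re-running with the same name and seed reproduces the files exactly.
    """
    from .assemblage import buffer_merge_range, polygon_to_geojson

    out = Path(out_dir)
    (out / "monthly").mkdir(parents=True, exist_ok=True)
    world, species, occ = make_world(name, seed, **overrides)
    for st in world.stacks:
        write_grid(st.grid, out / "monthly" / f"{st.variable}_{st.year}_{st.month:02d}.asc")
    for var in ("temperature", "precipitation"):
        write_grid(world.t0[var].grid, out / f"{var}_t0.asc")
        write_grid(world.t1[var].grid, out / f"{var}_t1.asc")
    occ.to_csv(out / "occurrences.csv", index=False)
    poly = buffer_merge_range(None, occ[["x_km", "y_km"]].to_numpy(), buffer_km=10.0)
    (out / "range.geojson").write_text(polygon_to_geojson(poly))
    s = world.scenario
    manifest = {
        "name": name,
        "seed": seed,
        "scenario": {
            **{k: v for k, v in asdict(s).items() if not isinstance(v, np.ndarray)},
            "shift_temp": np.asarray(s.shift_temp).tolist(),
            "shift_precip": np.asarray(s.shift_precip).tolist(),
        },
        "species": asdict(species),
        "range_buffer_km": 10.0,
    }
    (out / "truth.json").write_text(json.dumps(manifest, indent=1, default=list))
    return out
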