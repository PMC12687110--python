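"""Mahalanobis-based climate-change vulnerability scoring.

The vulnerability score (VS) of a location is the change in squared
Mahalanobis distance from the species' niche center between the current
(t0) and future (t1) environmental conditions:

    VS = (x_t1 − μ)ᵀ Σ⁻¹ (x_t1 − μ) − (x_t0 − μ)ᵀ Σ⁻¹ (x_t0 − μ)

Positive scores mean climate change moves the local population away from
the niche center; negative scores mean conditions become more central.
The multivariate score partitions additively into one univariate component
per variable, (d_{k,t1}² − d_{k,t0}²)/σ_k², plus an interaction component —
the residual contributed by correlations among niche axes.

Suitability weights w = exp(−MD²) down-weight locations whose current
climate is already far from the niche center (likely false presences) when
averaging VS across a species' range into the expected vulnerability score
(EVS).  Because MD² of multivariate-normal data follows a chi-square law
with as many degrees of freedom as niche dimensions, an increase of VS from
0 has a probabilistic reading: 100·P(χ²_dims ≤ VS) is the percent drop in
suitability relative to the niche center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.stats import chi2

from .errors import DegenerateNicheError, InsufficientDataError, InvalidArgumentError
from .niche import NicheModel

__all__ = [
    "ExposurePair",
    "VulnerabilityComponents",
    "SpeciesVulnerability",
    "mahalanobis_sq",
    "vulnerability_score",
    "partition",
    "evaluate_pixels",
    "suitability",
    "suitability_drop",
    "species_evs",
]


@dataclass(frozen=True)
class ExposurePair:
    """Current (``x_t0``) and future (``x_t1``) conditions at one location."""

    x_t0: np.ndarray
    x_t1: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x_t0", np.asarray(self.x_t0, dtype=float).ravel())
        object.__setattr__(self, "x_t1", np.asarray(self.x_t1, dtype=float).ravel())
        if self.x_t0.shape != self.x_t1.shape:
            raise InvalidArgumentError("x_t0 and x_t1 must have the same length")
        if not (np.isfinite(self.x_t0).all() and np.isfinite(self.x_t1).all()):
            raise InvalidArgumentError("exposure vectors must be finite")


@dataclass
class VulnerabilityComponents:
    """Per-location VS with its additive partition and suitability weight."""

    total: float
    per_variable: np.ndarray
    interaction: float
    weight: float
    md2_t0: float
    md2_t1: float

    def __post_init__(self):
        self.per_variable = np.asarray(self.per_variable, dtype=float)
        assert abs(self.total - (self.per_variable.sum() + self.interaction)) < 1e-9
        assert abs(self.total - (self.md2_t1 - self.md2_t0)) < 1e-9
        assert self.md2_t0 >= 0 and self.md2_t1 >= 0


@dataclass
class SpeciesVulnerability:
    """Suitability-weighted expected vulnerability (EVS) over a species' range."""

    evs: float
    ci_low: float
    ci_high: float
    evs_components: dict[str, float]
    n_pixels: int
    grain_km: float | None = None


def _chol(niche: NicheModel):
    try:
        return cho_factor(niche.sigma, lower=True)
    except LinAlgError as exc:
        raise DegenerateNicheError(f"covariance not positive definite: {exc}") from exc


def mahalanobis_sq(x: np.ndarray, niche: NicheModel) -> float | np.ndarray:
    """Squared Mahalanobis distance (x−μ)ᵀΣ⁻¹(x−μ) from the niche center.

    Computed through a Cholesky solve rather than an explicit inverse.
    ``x`` may be a single vector of length n or an array of shape (..., n);
    the distance is returned with the leading shape.
    """
    x = np.asarray(x, dtype=float)
    d = x - niche.mu
    flat = np.atleast_2d(d.reshape(-1, niche.n_dims))
    sol = cho_solve(_chol(niche), flat.T)
    md2 = np.einsum("ij,ji->i", flat, sol)
    md2 = np.maximum(md2, 0.0)
    if x.ndim == 1:
        return float(md2[0])
    return md2.reshape(d.shape[:-1])


def vulnerability_score(pair: ExposurePair, niche: NicheModel) -> float:
    """VS = MD²(x_t1) − MD²(x_t0); positive = moving away from the center."""
    return float(mahalanobis_sq(pair.x_t1, niche) - mahalanobis_sq(pair.x_t0, niche))


def suitability(x: np.ndarray, niche: NicheModel, kernel: str = "full") -> float | np.ndarray:
    """Gaussian-kernel suitability of condition ``x`` under the niche.

    The primary form is ``exp(−MD²)`` (``kernel="full"``), which is 1 at the
    niche center and decreases strictly along any ray from it.
    ``kernel="half"`` gives the standard Gaussian density kernel
    ``exp(−MD²/2)`` for sensitivity analysis.
    """
    md2 = mahalanobis_sq(x, niche)
    if kernel == "full":
        return np.exp(-md2)
    if kernel == "half":
        return np.exp(-md2 / 2.0)
    raise InvalidArgumentError(f"kernel must be 'full' or 'half', got {kernel!r}")


def suitability_drop(vs: float, dims: int) -> float:
    """Percent drop in suitability for an increase of VS from 0 to ``vs``.

    Under the chi-square law of MD² this is 100·P(χ²_dims ≤ vs): e.g. in two
    dimensions a rise of VS from 0 to 2 forgoes about 63% of the suitability
    mass available at the niche center.
    """
    if vs < 0:
        raise InvalidArgumentError("vs must be ≥ 0")
    if dims < 1:
        raise InvalidArgumentError("dims must be ≥ 1")
    return float(100.0 * chi2.cdf(vs, df=dims))


def partition(pair: ExposurePair, niche: NicheModel, kernel: str = "full") -> VulnerabilityComponents:
    """Partition VS into univariate components plus an interaction residual.

    ``per_variable[k] = (d_{k,t1}² − d_{k,t0}²) / σ_k²`` with
    ``d_k = x_k − μ_k``; the interaction component is defined residually as
    ``total − Σ_k per_variable[k]``, which for two dimensions coincides with
    the closed-form correlation term and vanishes when Σ is diagonal.
    """
    if pair.x_t0.size != niche.n_dims:
        raise InvalidArgumentError("exposure dimension differs from niche dimension")
    md2_t0 = float(mahalanobis_sq(pair.x_t0, niche))
    md2_t1 = float(mahalanobis_sq(pair.x_t1, niche))
    var = np.diag(niche.sigma)
    per_var = ((pair.x_t1 - niche.mu) ** 2 - (pair.x_t0 - niche.mu) ** 2) / var
    total = md2_t1 - md2_t0
    interaction = total - float(per_var.sum())
    if kernel == "full":
        weight = float(np.exp(-md2_t0))
    elif kernel == "half":
        weight = float(np.exp(-md2_t0 / 2.0))
    else:
        raise InvalidArgumentError(f"kernel must be 'full' or 'half', got {kernel!r}")
    return VulnerabilityComponents(total, per_var, interaction, weight, md2_t0, md2_t1)


def evaluate_pixels(
    x_t0: np.ndarray,
    x_t1: np.ndarray,
    niche: NicheModel,
    kernel: str = "full",
) -> pd.DataFrame:
    """Vectorised :func:`partition` over many locations.

    ``x_t0``/``x_t1`` have shape (n_pixels, n_dims).  Returns a DataFrame
    with columns ``vs_total``, ``vs_<variable>`` per niche variable,
    ``vs_interaction``, ``weight``, ``md2_t0``, ``md2_t1``.
    """
    x_t0 = np.atleast_2d(np.asarray(x_t0, dtype=float))
    x_t1 = np.atleast_2d(np.asarray(x_t1, dtype=float))
    if x_t0.shape != x_t1.shape or x_t0.shape[1] != niche.n_dims:
        raise InvalidArgumentError("pixel arrays must be (n_pixels, n_dims) and match")
    md2_t0 = mahalanobis_sq(x_t0, niche)
    md2_t1 = mahalanobis_sq(x_t1, niche)
    total = md2_t1 - md2_t0
    var = np.diag(niche.sigma)
    per_var = ((x_t1 - niche.mu) ** 2 - (x_t0 - niche.mu) ** 2) / var
    interaction = total - per_var.sum(axis=1)
    if kernel == "full":
        weight = np.exp(-md2_t0)
    elif kernel == "half":
        weight = np.exp(-md2_t0 / 2.0)
    else:
        raise InvalidArgumentError(f"kernel must be 'full' or 'half', got {kernel!r}")
    out = pd.DataFrame({"vs_total": total})
    for k, var_name in enumerate(niche.variables):
        out[f"vs_{var_name}"] = per_var[:, k]
    out["vs_interaction"] = interaction
    out["weight"] = weight
    out["md2_t0"] = md2_t0
    out["md2_t1"] = md2_t1
    return out


def species_evs(
    pixels: pd.DataFrame,
    ci_reps: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    grain_km: float | None = None,
) -> SpeciesVulnerability:
    """Suitability-weighted expected vulnerability over range pixels.

    EVS = Σ_i w_i·VS_i / Σ_i w_i over the pixel table produced by
    :func:`evaluate_pixels`; the same weighted mean is applied to every
    partition component.  The 95% interval is a seeded percentile bootstrap
    over pixels (resampled with replacement, ``ci_reps`` draws).
    """
    if len(pixels) == 0:
        raise InsufficientDataError("no pixels with suitability weight", count=0)
    w = pixels["weight"].to_numpy(dtype=float)
    if not (w > 0).any():
        raise InsufficientDataError("no pixels with positive weight", count=0)
    vs = pixels["vs_total"].to_numpy(dtype=float)
    evs = float(np.average(vs, weights=w))
    comp_cols = [c for c in pixels.columns if c.startswith("vs_") and c != "vs_total"]
    components = {
        c: float(np.average(pixels[c].to_numpy(dtype=float), weights=w))
        for c in comp_cols
    }
    n = len(pixels)
    if n == 1:
        lo = hi = evs
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(ci_reps, n))
        bw = w[idx]
        boots = np.sum(bw * vs[idx], axis=1) / np.sum(bw, axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    return SpeciesVulnerability(evs, float(lo), float(hi), components, n, grain_km)
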