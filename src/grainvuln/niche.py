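"""Multivariate-normal niche estimation.

A species' climatic niche is summarised by the center vector μ and the
covariance matrix Σ of the environments at its occurrence records.  To
reduce spatial sampling bias, (μ, Σ) are estimated as the element-wise
average of the sample mean and sample covariance over many independently
seeded spatial-thinning replicates, each replicate drawn from the full
filtered occurrence pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateNicheError, InsufficientDataError, InvalidArgumentError
from .occurrences import thin

__all__ = ["NicheModel", "estimate_niche"]

# Σ counts as singular when an eigenvalue falls below this fraction of the
# mean eigenvalue (trace/n).
_SINGULAR_RTOL = 1e-12


@dataclass
class NicheModel:
    """Gaussian niche: center ``mu`` and covariance ``sigma`` over ``variables``."""

    mu: np.ndarray
    sigma: np.ndarray
    variables: list[str]
    n_records: int
    grain_km: float | None = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.mu.size
        if self.sigma.shape != (n, n) or len(self.variables) != n:
            raise InvalidArgumentError("mu, sigma and variables dimensions disagree")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-12):
            raise InvalidArgumentError("sigma must be symmetric")
        _check_positive_definite(self.sigma)

    @property
    def n_dims(self) -> int:
        return self.mu.size

    def to_json(self, path: str | Path | None = None, seed: int | None = None) -> str:
        doc = {
            "variables": self.variables,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "n_records": self.n_records,
            "grain_km": self.grain_km,
        }
        if seed is not None:
            doc["seed"] = seed
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NicheModel":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text()
        doc = json.loads(text)
        return cls(
            np.array(doc["mu"]),
            np.array(doc["sigma"]),
            list(doc["variables"]),
            int(doc["n_records"]),
            doc.get("grain_km"),
        )


def _check_positive_definite(sigma: np.ndarray) -> None:
    eig = np.linalg.eigvalsh(sigma)
    n = sigma.shape[0]
    if eig.min() <= _SINGULAR_RTOL * max(np.trace(sigma) / n, np.finfo(float).tiny):
        raise DegenerateNicheError(
            f"covariance matrix is singular or not positive definite "
            f"(min eigenvalue {eig.min():.3e})"
        )


def estimate_niche(
    annotated: pd.DataFrame,
    variables: list[str],
    n_reps: int = 100,
    min_distance: float = 5.0,
    min_records: int = 20,
    seed: int | np.random.SeedSequence = 0,
    ridge: float = 0.0,
    grain_km: float | None = None,
) -> NicheModel:
    """Estimate (μ, Σ) by averaging over seeded thinning replicates.

    Each of ``n_reps`` replicates independently thins the full annotated pool
    to ``min_distance`` km separation and computes the sample mean and sample
    covariance (n−1 denominator) of the env vectors; the returned model holds
    the element-wise means of the replicate estimates.  With
    ``min_distance = 0`` thinning is disabled and every replicate reduces to
    the plain sample moments.  A ridge ε·I is added to Σ only when ``ridge``
    is explicitly positive.  Deterministic given ``seed``.

    Raises :class:`InsufficientDataError` if one thinning pass leaves
    ``min_records`` or fewer records, and :class:`DegenerateNicheError` if
    the averaged Σ is singular.
    """
    if n_reps < 1:
        raise InvalidArgumentError("n_reps must be ≥ 1")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(n_reps + 1)
    # eligibility check: one thinning pass on its own child seed
    probe = thin(annotated, min_distance, np.random.default_rng(children[0]))
    if len(probe) <= min_records:
        raise InsufficientDataError(
            f"only {len(probe)} records after thinning (need > {min_records})",
            count=len(probe),
        )
    env_cols = annotated[variables]
    mus = []
    sigmas = []
    counts = []
    for child in children[1:]:
        sub = thin(annotated, min_distance, np.random.default_rng(child))
        x = env_cols.loc[sub.index].to_numpy(dtype=float)
        mus.append(x.mean(axis=0))
        sigmas.append(np.cov(x, rowvar=False, ddof=1))
        counts.append(len(sub))
    mu = np.mean(mus, axis=0)
    sigma = np.mean(sigmas, axis=0)
    sigma = np.atleast_2d(sigma)
    if ridge > 0:
        sigma = sigma + ridge * np.eye(sigma.shape[0])
    sigma = (sigma + sigma.T) / 2.0
    return NicheModel(
        mu, sigma, list(variables), int(round(float(np.mean(counts)))), grain_km
    )
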