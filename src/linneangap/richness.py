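"""Incidence-based species-richness extrapolation.

The description history is recast as an incidence survey from community
ecology: each calendar year is a sampling unit and a species "occurs" in
the year it was described, giving a binary species × year matrix in which
every species is a singleton (Q1 = S_obs, Q2 = 0).  Nonparametric
estimators then extrapolate the total pool: the second-order jackknife

    S_jack2 = S_obs + Q1 (2m - 3)/m - Q2 (m - 2)^2 / (m (m - 1)),

with the first-order jackknife and the bias-corrected Chao2 as companions.
Adding the species described before the window yields the total richness K,
the remaining-to-describe count and its fraction of K (the Linnean
shortfall of the taxon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .records import SurveyDataset

__all__ = [
    "IncidenceMatrix",
    "RichnessEstimate",
    "RichnessBudget",
    "build_incidence",
    "jackknife2",
    "jackknife1",
    "chao2",
    "resampled_se",
    "richness_budget",
]


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary species × period matrix with its incidence summaries."""

    species_ids: tuple[str, ...]
    periods: tuple[int, ...]
    cells: np.ndarray  # shape (S_obs, m), dtype uint8

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.uint8)
        object.__setattr__(self, "cells", cells)
        if cells.shape != (len(self.species_ids), len(self.periods)):
            raise UsageError("cells shape must be (n_species, n_periods)")
        if cells.size and not np.all((cells == 0) | (cells == 1)):
            raise UsageError("cells must be binary")
        if cells.size and (cells.sum(axis=1) == 0).any():
            raise UsageError("every species row needs at least one occurrence")

    @property
    def m(self) -> int:
        return len(self.periods)

    @property
    def S_obs(self) -> int:
        return len(self.species_ids)

    @property
    def incidence_freq(self) -> np.ndarray:
        """Number of periods each species occurs in."""
        return self.cells.sum(axis=1)

    @property
    def Q1(self) -> int:
        return int(np.count_nonzero(self.incidence_freq == 1))

    @property
    def Q2(self) -> int:
        return int(np.count_nonzero(self.incidence_freq == 2))


@dataclass(frozen=True)
class RichnessEstimate:
    estimator: str
    estimate: float
    se: float | None = None
    n_randomizations: int | None = None


@dataclass(frozen=True)
class RichnessBudget:
    """Total richness K, described total, and the remaining gap."""

    K_total: float
    described_total: int
    remaining: float
    remaining_fraction: float


def build_incidence(
    dataset: SurveyDataset, granularity: str = "year"
) -> IncidenceMatrix:
    """Species × year incidence matrix over the full survey window.

    Zero-count years are kept as empty columns: they are sampling units
    that yielded no new species, and they enter the estimators through m.
    """
    if granularity != "year":
        raise UsageError("only granularity='year' is supported")
    if not dataset.records:
        raise UsageError("empty dataset")
    periods = tuple(dataset.window_years)
    col = {y: j for j, y in enumerate(periods)}
    species = tuple(r.species_id for r in dataset.records)
    cells = np.zeros((len(species), len(periods)), dtype=np.uint8)
    for i, r in enumerate(dataset.records):
        cells[i, col[r.year]] = 1
    return IncidenceMatrix(species_ids=species, periods=periods, cells=cells)


def _summaries(freq: np.ndarray, m: int) -> tuple[int, int, int]:
    s = int(np.count_nonzero(freq > 0))
    q1 = int(np.count_nonzero(freq == 1))
    q2 = int(np.count_nonzero(freq == 2))
    return s, q1, q2


def _jack2(s: int, q1: int, q2: int, m: int) -> float:
    return s + q1 * (2 * m - 3) / m - q2 * (m - 2) ** 2 / (m * (m - 1))


def _jack1(s: int, q1: int, q2: int, m: int) -> float:
    return s + q1 * (m - 1) / m


def _chao2(s: int, q1: int, q2: int, m: int) -> float:
    # bias-corrected form: finite even when Q2 = 0, as it always is for
    # pure description data
    return s + ((m - 1) / m) * q1 * (q1 - 1) / (2 * (q2 + 1))

_FORMULAS = {"jack2": _jack2, "jack1": _jack1, "chao2": _chao2}


def _estimate(matrix: IncidenceMatrix, name: str, min_m: int) -> RichnessEstimate:
    if matrix.m < min_m:
        raise UsageError(f"{name} requires at least {min_m} periods; m={matrix.m}")
    value = _FORMULAS[name](matrix.S_obs, matrix.Q1, matrix.Q2, matrix.m)
    return RichnessEstimate(estimator=name, estimate=float(value))


def jackknife2(matrix: IncidenceMatrix) -> RichnessEstimate:
    """Second-order jackknife extrapolation of the species pool."""
    return _estimate(matrix, "jack2", min_m=3)


def jackknife1(matrix: IncidenceMatrix) -> RichnessEstimate:
    """First-order jackknife: S_obs + Q1 (m-1)/m."""
    return _estimate(matrix, "jack1", min_m=2)


def chao2(matrix: IncidenceMatrix) -> RichnessEstimate:
    """Bias-corrected Chao2: S_obs + ((m-1)/m) Q1(Q1-1) / (2(Q2+1))."""
    return _estimate(matrix, "chao2", min_m=2)


def resampled_se(
    matrix: IncidenceMatrix,
    estimator: str = "jack2",
    n: int = 1000,
    seed: int = 0,
) -> RichnessEstimate:
    """Bootstrap standard error over ``n`` resamples of the periods.

    Each replicate draws m columns (sampling units) with replacement,
    recomputes the incidence summaries on the species present in the draw
    and re-applies the estimator; the SE is the sample standard deviation of
    the replicate estimates.  The point estimate is from the full matrix.
    """
    if estimator not in _FORMULAS:
        raise UsageError(f"unknown estimator {estimator!r}")
    if n < 2:
        raise UsageError("n must be at least 2")
    if matrix.m < 3:
        raise UsageError("resampling requires at least 3 periods")
    rng = np.random.default_rng(seed)
    m = matrix.m
    reps = np.empty(n)
    for b in range(n):
        cols = rng.integers(0, m, size=m)
        freq = matrix.cells[:, cols].sum(axis=1)
        s, q1, q2 = _summaries(freq, m)
        reps[b] = _FORMULAS[estimator](s, q1, q2, m)
    point = _FORMULAS[estimator](matrix.S_obs, matrix.Q1, matrix.Q2, m)
    return RichnessEstimate(
        estimator=estimator,
        estimate=float(point),
        se=float(np.std(reps, ddof=1)),
        n_randomizations=n,
    )


def richness_budget(
    est: RichnessEstimate, dataset: SurveyDataset
) -> RichnessBudget:
    """Combine an extrapolated in-window pool with the pre-window described
    count into the total richness K and the remaining-to-describe gap."""
    if est.estimate < dataset.n_species:
        raise UsageError("estimate below the observed species count")
    K = est.estimate + dataset.pre_window_species
    described = dataset.pre_window_species + dataset.n_species
    remaining = K - described
    return RichnessBudget(
        K_total=float(K),
        described_total=described,
        remaining=float(remaining),
        remaining_fraction=float(remaining / K),
    )
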