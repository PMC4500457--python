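"""Synthetic description-record generator with known ground truth.

Emulates the structure of a real description survey so every pipeline
stage can be tested without any external data: yearly counts follow a
Poisson process with a slow polynomial intensity that switches to a steeper
linear regime at a change-point year; family frequencies are strongly
skewed; journals follow a Zipf rank distribution; articles bundle one to
four species; team sizes rise over the years; author ages come from a
mixture of career-stage normals.  Every generated dataset carries a
``truth`` record of the generating parameters for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .curve import AccumulationCurve
from .errors import ConsistencyError, UsageError
from .records import AuthorRecord, DescriptionRecord, SurveyDataset

__all__ = [
    "SimulationConfig",
    "simulate_counts",
    "simulate_records",
    "simulate_discovery_process",
]

_DEFAULT_FAMILY_PROBS = {
    "Loricariidae": 0.48,
    "Trichomycteridae": 0.22,
    "Heptapteridae": 0.08,
    "Callichthyidae": 0.06,
    "Doradidae": 0.04,
    "Pimelodidae": 0.04,
    "Auchenipteridae": 0.03,
    "Cetopsidae": 0.02,
    "Astroblepidae": 0.02,
    "Aspredinidae": 0.01,
}

_DEFAULT_JOURNALS = (
    "Neotropical Ichthyology",
    "Copeia",
    "Ichthyological Exploration of Freshwaters",
    "Zootaxa",
    "Revue Suisse de Zoologie",
    "Proceedings of the Biological Society of Washington",
    "Vertebrate Zoology",
    "Cybium",
    "Iheringia Serie Zoologia",
    "Bulletin of the American Museum of Natural History",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic description survey.

    Defaults mirror the 1990-2014 Neotropical catfish survey: a gentle
    pre-change-point regime whose annual intensity rises from ~4 to ~16
    species/year (the increments of a quadratic cumulative curve), then a
    steep ~40 species/year linear regime from 2004 on; family shares led by
    Loricariidae (0.48) and Trichomycteridae (0.22); Zipf-distributed
    journals; mean team size growing from ~1.2 by ~0.07 authors/year.
    """

    seed: int
    window: tuple[int, int] = (1990, 2014)
    changepoint_year: int = 2004
    #: (c2, c1, c0): expected annual counts c2*i^2 + c1*i + c0 with i = years
    #: since window start, applied before the change-point.
    pre_rate_poly: tuple[float, float, float] = (0.0, 0.923, 4.35)
    #: (slope, intercept): expected annual counts slope*j + intercept with
    #: j = years since the change-point, applied from the change-point on.
    post_rate_slope_and_intercept: tuple[float, float] = (0.0, 39.92)
    family_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FAMILY_PROBS)
    )
    journal_zipf_s: float = 1.1
    journals: tuple[str, ...] = _DEFAULT_JOURNALS
    team_size_trend: tuple[float, float] = (1.2, 0.07)
    #: (mean age, sd, weight) components of the author age-at-career mixture
    age_mixture: tuple[tuple[float, float, float], ...] = (
        (30.0, 4.0, 0.35),
        (44.0, 7.0, 0.45),
        (58.0, 7.0, 0.20),
    )
    pre_window_species: int = 1452
    pre_window_start: int = 1758
    true_K: int | None = None
    discovery_r: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.window
        if lo > hi:
            raise ConsistencyError("empty window")
        if not (lo <= self.changepoint_year <= hi + 1):
            raise ConsistencyError("changepoint_year outside window")
        total_p = sum(self.family_probs.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ConsistencyError(f"family_probs sum to {total_p}, not 1")
        w = sum(wt for _, _, wt in self.age_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ConsistencyError("age_mixture weights must sum to 1")
        for y in range(lo, hi + 1):
            if self.intensity(y) < 0:
                raise ConsistencyError(f"negative expected count in year {y}")

    def intensity(self, year: int) -> float:
        """Expected annual description count in ``year``."""
        if year < self.changepoint_year:
            i = year - self.window[0]
            c2, c1, c0 = self.pre_rate_poly
            return c2 * i * i + c1 * i + c0
        j = year - self.changepoint_year
        slope, intercept = self.post_rate_slope_and_intercept
        return slope * j + intercept


def simulate_counts(config: SimulationConfig) -> dict[int, int]:
    """Draw Poisson annual counts from the piecewise intensity."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.window
    return {
        y: int(rng.poisson(config.intensity(y))) for y in range(lo, hi + 1)
    }


def _draw_team_size(rng: np.random.Generator, mean: float) -> int:
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def simulate_records(
    config: SimulationConfig,
) -> tuple[SurveyDataset, dict]:
    """Expand simulated annual counts into full description records.

    Species within a year are grouped into articles of 1-4 species (the
    per-article range seen in real surveys); the grouping is a generator
    convenience, not a claim about real authorship.  Returns the dataset
    and a ``truth`` dict carrying every generating parameter.
    """
    counts = simulate_counts(config)
    # separate stream from simulate_counts so the two stages don't replay
    # each other's draws
    rng = np.random.default_rng((config.seed, 1))
    lo, hi = config.window

    families = list(config.family_probs)
    fam_p = np.array([config.family_probs[f] for f in families])
    jw = 1.0 / np.arange(1, len(config.journals) + 1) ** config.journal_zipf_s
    jw /= jw.sum()
    journal_if = {
        j: round(float(x), 3)
        for j, x in zip(config.journals, rng.uniform(0.1, 2.5, len(config.journals)))
    }

    # author registry: birth years fixed at first appearance so the same
    # author ages consistently across publications
    birth_years: list[int] = []

    def _author(year: int) -> int:
        if birth_years and rng.random() < 0.5:
            return int(rng.integers(len(birth_years)))
        comp_w = np.array([w for _, _, w in config.age_mixture])
        k = rng.choice(len(config.age_mixture), p=comp_w / comp_w.sum())
        mu, sd, _ = config.age_mixture[k]
        age = float(np.clip(rng.normal(mu, sd), 20, 85))
        birth_years.append(year - int(round(age)))
        return len(birth_years) - 1

    records: list[DescriptionRecord] = []
    art_no = sp_no = 0
    t0, t_inc = config.team_size_trend
    for year in range(lo, hi + 1):
        remaining = counts[year]
        while remaining > 0:
            size = min(int(rng.integers(1, 5)), remaining)
            remaining -= size
            art_no += 1
            journal = config.journals[int(rng.choice(len(jw), p=jw))]
            team_mean = t0 + t_inc * (year - lo)
            team = []
            for _ in range(_draw_team_size(rng, team_mean)):
                u = _author(year)
                if u not in team:
                    team.append(u)
            authors = tuple(
                AuthorRecord(
                    f"A{u + 1:04d}",
                    int(np.clip(year - birth_years[u], 15, 110)),
                )
                for u in team
            )
            for _ in range(size):
                sp_no += 1
                records.append(
                    DescriptionRecord(
                        species_id=f"sim{sp_no:05d}",
                        year=year,
                        article_id=f"simart{art_no:05d}",
                        journal=journal,
                        impact_factor=journal_if[journal],
                        family=families[int(rng.choice(len(families), p=fam_p))],
                        authors=authors,
                    )
                )

    dataset = SurveyDataset(
        records=tuple(records),
        window_start=lo,
        window_end=hi,
        pre_window_species=config.pre_window_species,
        pre_window_start=config.pre_window_start,
    )
    truth = {
        "seed": config.seed,
        "window": list(config.window),
        "changepoint_year": config.changepoint_year,
        "pre_rate_poly": list(config.pre_rate_poly),
        "post_rate_slope_and_intercept": list(
            config.post_rate_slope_and_intercept
        ),
        "family_probs": dict(config.family_probs),
        "journal_zipf_s": config.journal_zipf_s,
        "team_size_trend": list(config.team_size_trend),
        "age_mixture": [list(c) for c in config.age_mixture],
        "annual_counts": {str(y): counts[y] for y in sorted(counts)},
        "true_K": config.true_K,
        "discovery_r": config.discovery_r,
    }
    return dataset, truth


def simulate_discovery_process(
    true_K: float,
    N0: float,
    r: float,
    window: tuple[int, int],
    seed: int = 0,
) -> AccumulationCurve:
    """Annual described counts as stochastically rounded increments of a
    logistic trajectory from N0 toward true_K.

    The first window year absorbs the initial stock N0, so the cumulative
    curve tracks the logistic N(t) itself and converges to true_K for large
    r·t.  Stochastic rounding keeps counts integral while preserving the
    continuous model in expectation.
    """
    if not (true_K > N0 > 0):
        raise UsageError("need true_K > N0 > 0")
    if r <= 0:
        raise UsageError("need r > 0")
    lo, hi = window
    if lo > hi:
        raise UsageError("empty window")
    rng = np.random.default_rng(seed)
    years = range(lo, hi + 1)
    counts: dict[int, int] = {}
    cum = 0
    for i, year in enumerate(years, start=1):
        target = true_K / (1.0 + (true_K / N0 - 1.0) * np.exp(-r * i))
        d = max(target - cum, 0.0)
        whole, frac = int(np.floor(d)), d - np.floor(d)
        c = whole + (1 if rng.random() < frac else 0)
        counts[year] = c
        cum += c
    return AccumulationCurve.from_counts(counts)
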