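"""Logistic projection of inventory completeness.

The cumulative count of described species is treated as a population
growing toward a carrying capacity K — the extrapolated total richness —
under density-dependent logistic growth

    N(t) = K / (1 + (K/N0 - 1) e^{-r t}),

where N0 is the count already described at the projection origin t0 and r
is a description-effort growth rate per year.  Because the model never
literally reaches K, "inventory complete" means crossing a threshold
fraction f of K (default f = 0.995), which has the closed form

    t = (1/r) ln[(K/N0 - 1) f / (1 - f)].

Scenarios over a grid of r values are scored for sigmoidicity — how
centrally the logistic inflection sits within the joined observed +
projected curve — to flag the shape most like a classic completed-inventory
accumulation curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .curve import AccumulationCurve
from .errors import UsageError
from .richness import RichnessBudget

__all__ = [
    "LogisticScenario",
    "ScenarioSuite",
    "logistic_N",
    "completion_time",
    "project_scenarios",
    "sigmoidicity_score",
    "DEFAULT_R_GRID",
]

DEFAULT_R_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class LogisticScenario:
    """One (K, N0, r) logistic projection with its completion year."""

    K: float
    N0: float
    r: float
    t0: float
    threshold_fraction: float
    completion_year: float
    sigmoidicity: float

    @property
    def inflection_year(self) -> float:
        """Calendar year at which N(t) = K/2 (maximum description rate)."""
        return self.t0 + math.log(self.K / self.N0 - 1.0) / self.r


@dataclass(frozen=True)
class ScenarioSuite:
    scenarios: tuple[LogisticScenario, ...]
    selected: int
    real_curve: AccumulationCurve
    n0_mode: str

    def to_dict(self) -> dict:
        return {
            "n0_mode": self.n0_mode,
            "selected": self.selected,
            "scenarios": [
                {
                    "r": s.r,
                    "K": s.K,
                    "N0": s.N0,
                    "t0": s.t0,
                    "threshold_fraction": s.threshold_fraction,
                    "completion_year": s.completion_year,
                    "sigmoidicity": s.sigmoidicity,
                }
                for s in self.scenarios
            ],
        }


def logistic_N(K: float, N0: float, r: float, t) -> float | np.ndarray:
    """Described count after ``t`` years: K / (1 + (K/N0 - 1) e^{-r t})."""
    if not (K > N0 > 0):
        raise UsageError("need K > N0 > 0")
    if r <= 0:
        raise UsageError("need r > 0")
    t = np.asarray(t, dtype=float)
    out = K / (1.0 + (K / N0 - 1.0) * np.exp(-r * t))
    return float(out) if out.ndim == 0 else out


def completion_time(K: float, N0: float, r: float, f: float) -> float:
    """Years until N(t) first reaches f·K (closed form)."""
    if not (K > N0 > 0) or r <= 0:
        raise UsageError("need K > N0 > 0 and r > 0")
    if not (N0 / K <= f < 1.0):  # f = N0/K is already reached: t = 0
        raise UsageError(f"threshold f must lie in [N0/K, 1); got {f}")
    return math.log((K / N0 - 1.0) * f / (1.0 - f)) / r


def sigmoidicity_score(
    curve: AccumulationCurve, scenario: LogisticScenario
) -> float:
    """Centrality of the logistic inflection within the joined curve.

    score = 1 - |y_infl - y_mid| / ((y_c - y_start)/2), clipped to [0, 1],
    where y_start is the first observed year, y_c the completion year,
    y_infl the inflection year and y_mid the midpoint of [y_start, y_c].
    A score of 1 means the inflection is exactly central — the joined
    observed + projected curve is a symmetric sigmoid; 0 means the
    inflection sits at or beyond an endpoint (the curve looks one-sided).
    """
    y_start = float(curve.years[0])
    y_c = scenario.completion_year
    y_infl = scenario.inflection_year
    y_mid = (y_start + y_c) / 2.0
    half = (y_c - y_start) / 2.0
    if half <= 0:
        return 0.0
    return float(np.clip(1.0 - abs(y_infl - y_mid) / half, 0.0, 1.0))


def project_scenarios(
    budget: RichnessBudget,
    curve: AccumulationCurve,
    r_grid: Sequence[float] = DEFAULT_R_GRID,
    f: float = 0.995,
    t0: float | None = None,
    n0_mode: str = "window_only",
) -> ScenarioSuite:
    """One logistic scenario per growth rate, sharing K = total richness.

    ``n0_mode`` fixes the accounting convention for the starting count N0:
    ``"window_only"`` uses the species described within the survey window
    (the convention under which the published completion years are
    reproduced), ``"described_total"`` uses all species described by t0
    including the pre-window backlog.  t0 defaults to the last observed
    year.  The suite's ``selected`` index is the sigmoidicity argmax.
    """
    if len(r_grid) == 0:
        raise UsageError("r_grid must be nonempty")
    if len(set(r_grid)) != len(r_grid) or any(r <= 0 for r in r_grid):
        raise UsageError("r_grid values must be distinct and positive")
    if n0_mode == "window_only":
        N0 = float(curve.cumulative[-1])
    elif n0_mode == "described_total":
        N0 = float(budget.described_total)
    else:
        raise UsageError(f"unknown n0_mode {n0_mode!r}")
    K = budget.K_total
    if not K > N0:
        raise UsageError("K_total must exceed the starting count N0")
    if t0 is None:
        t0 = float(curve.years[-1])

    scenarios = []
    for r in r_grid:
        t_done = completion_time(K, N0, r, f)
        scen = LogisticScenario(
            K=K,
            N0=N0,
            r=float(r),
            t0=float(t0),
            threshold_fraction=float(f),
            completion_year=float(t0) + t_done,
            sigmoidicity=float("nan"),
        )
        scen = LogisticScenario(
            **{**scen.__dict__, "sigmoidicity": sigmoidicity_score(curve, scen)}
        )
        scenarios.append(scen)
    selected = int(np.argmax([s.sigmoidicity for s in scenarios]))
    return ScenarioSuite(
        scenarios=tuple(scenarios),
        selected=selected,
        real_curve=curve,
        n0_mode=n0_mode,
    )
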