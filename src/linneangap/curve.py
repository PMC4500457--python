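"""Cumulative species-description curve and two-segment breakpoint fit.

The accumulation curve counts species described per calendar year and its
running total.  A change in description regime (e.g. a new journal or a
funded inventory programme) shows up as a breakpoint: the curve is fitted
as two independent least-squares polynomial segments — by default quadratic
before the breakpoint and linear after — with the breakpoint chosen by an
exhaustive scan minimising the total sum of squared errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numpy.polynomial import Polynomial

from .errors import DegenerateInputError, UsageError
from .records import SurveyDataset

__all__ = [
    "AccumulationCurve",
    "BreakpointFit",
    "accumulation_curve",
    "fit_breakpoint",
    "predict_segmented",
]


@dataclass(frozen=True)
class AccumulationCurve:
    """Annual description counts and their running total, one entry per
    calendar year (zero-count years included)."""

    years: tuple[int, ...]
    annual_counts: tuple[int, ...]
    cumulative: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.annual_counts) or len(self.years) != len(
            self.cumulative
        ):
            raise UsageError("years, annual_counts and cumulative must align")
        if list(self.years) != sorted(set(self.years)):
            raise UsageError("years must be strictly increasing")
        if tuple(np.cumsum(self.annual_counts)) != tuple(self.cumulative):
            raise UsageError("cumulative must be the running sum of counts")

    @classmethod
    def from_counts(cls, counts: Mapping[int, int]) -> "AccumulationCurve":
        """Build a curve from a year → count map, filling missing years of
        the spanned range with zeros."""
        if not counts:
            raise DegenerateInputError("no counts")
        years = tuple(range(min(counts), max(counts) + 1))
        annual = tuple(int(counts.get(y, 0)) for y in years)
        return cls(years, annual, tuple(int(c) for c in np.cumsum(annual)))


def accumulation_curve(dataset: SurveyDataset) -> AccumulationCurve:
    """Per-year description counts over the full survey window."""
    if not dataset.records:
        raise DegenerateInputError("empty dataset")
    counts = {y: 0 for y in dataset.window_years}
    for r in dataset.records:
        counts[r.year] += 1
    years = tuple(dataset.window_years)
    annual = tuple(counts[y] for y in years)
    return AccumulationCurve(years, annual, tuple(int(c) for c in np.cumsum(annual)))


@dataclass(frozen=True)
class BreakpointFit:
    """Two independent least-squares segments split at ``breakpoint_year``
    (the first year owned by the second segment).

    Coefficient tuples are in the shared calendar-year power basis,
    lowest order first, so ``sum(c * year**k for k, c in enumerate(coeffs))``
    evaluates a segment.  ``cumulative_at_breakpoint`` is the observed
    running total at the last pre-segment year, i.e. the inventory size at
    the start of the second regime.
    """

    breakpoint_year: int
    cumulative_at_breakpoint: int
    pre_model: tuple[float, ...]
    post_model: tuple[float, ...]
    sse_pre: float
    sse_post: float
    sse_total: float
    coordinate_convention: str = "calendar_year"
    # scaled-domain representations used for numerically stable prediction
    _pre_poly: Polynomial = field(repr=False, compare=False, default=None)
    _post_poly: Polynomial = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        return {
            "breakpoint_year": self.breakpoint_year,
            "cumulative_at_breakpoint": self.cumulative_at_breakpoint,
            "pre_model": list(self.pre_model),
            "post_model": list(self.post_model),
            "sse_pre": self.sse_pre,
            "sse_post": self.sse_post,
            "sse_total": self.sse_total,
            "coordinate_convention": self.coordinate_convention,
        }


def _fit_segment(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[Polynomial, float]:
    poly = Polynomial.fit(x, y, deg=degree)
    sse = float(np.sum((poly(x) - y) ** 2))
    return poly, sse


def fit_breakpoint(
    curve: AccumulationCurve, pre_degree: int = 2, post_degree: int = 1
) -> BreakpointFit:
    """Exhaustively scan admissible breakpoints and keep the total-SSE
    minimiser (ties broken toward the earliest year).

    Each segment needs at least ``max(3, degree + 1)`` points.  The two
    segments are fitted independently (no continuity constraint) in the
    shared calendar-year coordinate.
    """
    years = np.asarray(curve.years, dtype=float)
    y = np.asarray(curve.cumulative, dtype=float)
    min_pre = max(3, pre_degree + 1)
    min_post = max(3, post_degree + 1)
    n = len(years)
    if n < max(min_pre + min_post, pre_degree + post_degree + 4):
        raise UsageError(
            f"need at least {max(min_pre + min_post, pre_degree + post_degree + 4)} "
            f"points for degrees ({pre_degree}, {post_degree}); got {n}"
        )

    # SSEs equal up to round-off count as ties, which go to the earliest year
    tie_tol = 1e-9 * (1.0 + float(np.sum(y**2)))
    best = None
    for i in range(min_pre, n - min_post + 1):  # i = index of first post point
        pre_poly, sse_pre = _fit_segment(years[:i], y[:i], pre_degree)
        post_poly, sse_post = _fit_segment(years[i:], y[i:], post_degree)
        total = sse_pre + sse_post
        if best is None or total < best[0] - tie_tol:
            best = (total, i, pre_poly, sse_pre, post_poly, sse_post)

    total, i, pre_poly, sse_pre, post_poly, sse_post = best
    return BreakpointFit(
        breakpoint_year=int(curve.years[i]),
        cumulative_at_breakpoint=int(curve.cumulative[i - 1]),
        pre_model=tuple(float(c) for c in pre_poly.convert().coef),
        post_model=tuple(float(c) for c in post_poly.convert().coef),
        sse_pre=sse_pre,
        sse_post=sse_post,
        sse_total=total,
        _pre_poly=pre_poly,
        _post_poly=post_poly,
    )


def predict_segmented(fit: BreakpointFit, year: float) -> float:
    """Evaluate the segment owning ``year`` (the post segment owns the
    breakpoint year itself)."""
    poly = fit._post_poly if year >= fit.breakpoint_year else fit._pre_poly
    if poly is not None:
        return float(poly(year))
    coeffs = fit.post_model if year >= fit.breakpoint_year else fit.pre_model
    return float(sum(c * year**k for k, c in enumerate(coeffs)))
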