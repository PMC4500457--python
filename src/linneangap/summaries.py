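"""Descriptive bibliometrics of a description survey.

Rate means (species/year, species/article, articles/author), categorical
frequency tables, journal relative weight, Spearman rank correlation,
author-age production and productivity, the family sampling classification
against an origin-anchored theoretical line, the per-year mean team size,
and the pre-window baseline description rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConsistencyError, DegenerateInputError, UsageError
from .records import SurveyDataset

__all__ = [
    "RatesSummary",
    "JournalWeight",
    "AgeGroupMetrics",
    "FamilySamplingClass",
    "rates_summary",
    "frequency_table",
    "journal_weight",
    "spearman_rho",
    "age_group_metrics",
    "classify_family_sampling",
    "authors_per_article_series",
    "baseline_description_rate",
    "stratify_impact_factor",
]

_CATEGORICAL_FIELDS = ("journal", "family", "country", "state", "ecoregion")

AGE_BINS = tuple((lo, lo + 9) for lo in range(20, 90, 10))  # 20-29 ... 80-89


@dataclass(frozen=True)
class RatesSummary:
    """Survey-wide rate means with the ranges of their per-unit counts."""

    species_per_year: float
    species_per_article: float
    articles_per_author: float
    #: (min, max) of per-year species counts, per-article species counts and
    #: per-author article counts respectively.
    ranges: Mapping[str, tuple[int, int]]


@dataclass(frozen=True)
class JournalWeight:
    journal: str
    n_describing_papers: int
    describing_fraction_of_corpus: float
    #: 100 * (d_j / D) * (d_j / T_j); None when the journal-output table
    #: needed for T_j was not supplied.
    weight: float | None


@dataclass(frozen=True)
class AgeGroupMetrics:
    """Species production of a decade-wide author age bin.

    ``production`` counts (species, coauthor) credit pairs: a species is
    credited once to the bin of each coauthor whose age at that publication
    is known.  ``productivity_per_author`` divides by the total number of
    distinct authors in the dataset; ``productivity_per_group`` divides by
    the number of distinct authors whose age fell in the bin at least once.
    """

    age_bin: str
    production: int
    productivity_per_author: float
    productivity_per_group: float


@dataclass(frozen=True)
class FamilySamplingClass:
    family: str
    valid_species: int
    described_in_window: int
    classification: str  # well_sampled | low_sampled | on_line


def rates_summary(dataset: SurveyDataset) -> RatesSummary:
    """Mean description rates over the survey window.

    species/year divides by the number of calendar years in the window
    (zero-count years included); species/article and articles/author divide
    by distinct articles and authors.
    """
    if not dataset.records:
        raise DegenerateInputError("rates are undefined on an empty dataset")
    n_years = dataset.window_end - dataset.window_start + 1
    per_year = {y: 0 for y in dataset.window_years}
    per_article: dict[str, int] = {}
    per_author_articles: dict[str, set[str]] = {}
    for r in dataset.records:
        per_year[r.year] += 1
        per_article[r.article_id] = per_article.get(r.article_id, 0) + 1
        for a in r.authors:
            per_author_articles.setdefault(a.author_id, set()).add(r.article_id)
    author_counts = [len(s) for s in per_author_articles.values()]
    return RatesSummary(
        species_per_year=dataset.n_species / n_years,
        species_per_article=dataset.n_species / dataset.n_articles,
        articles_per_author=dataset.n_articles / dataset.n_authors,
        ranges={
            "species_per_year": (min(per_year.values()), max(per_year.values())),
            "species_per_article": (
                min(per_article.values()),
                max(per_article.values()),
            ),
            "articles_per_author": (min(author_counts), max(author_counts)),
        },
    )


def frequency_table(
    dataset: SurveyDataset, field: str
) -> dict[str, tuple[int, float]]:
    """Count records per category label with the fraction of the non-missing
    total, sorted by decreasing count.

    Records with a missing (null) value of the field are excluded; for the
    never-null fields (journal, family) counts therefore sum to the number
    of species and fractions to 1.
    """
    if field not in _CATEGORICAL_FIELDS:
        raise UsageError(
            f"field {field!r} is not categorical; expected one of "
            f"{_CATEGORICAL_FIELDS}"
        )
    counts: dict[str, int] = {}
    for r in dataset.records:
        label = getattr(r, field)
        if label is not None:
            counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    return {
        lab: (c, c / total)
        for lab, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


def journal_weight(
    dataset: SurveyDataset,
    journal_output: Mapping[str, int] | None = None,
) -> list[JournalWeight]:
    """Relative weight w of each journal in the describing corpus.

    w_j = 100 * (d_j / D) * (d_j / T_j), where d_j is the number of papers
    in journal j describing new species, D the total number of describing
    papers and T_j the journal's total output over the window.  The second
    factor discounts journals that are large overall but rarely publish
    descriptions; without a ``journal_output`` table it is unknowable and
    the weight is reported as None rather than guessed.
    """
    articles: dict[str, str] = {}
    for r in dataset.records:
        articles[r.article_id] = r.journal
    d: dict[str, int] = {}
    for journal in articles.values():
        d[journal] = d.get(journal, 0) + 1
    D = len(articles)
    out = []
    for journal, dj in sorted(d.items(), key=lambda kv: (-kv[1], kv[0])):
        if journal_output is None:
            w = None
        else:
            if journal not in journal_output:
                raise UsageError(f"journal_output lacks {journal!r}")
            tj = journal_output[journal]
            if tj == 0 and dj > 0:
                raise ConsistencyError(
                    f"{journal!r} has {dj} describing papers but zero output"
                )
            w = 100.0 * (dj / D) * (dj / tj)
        out.append(
            JournalWeight(
                journal=journal,
                n_describing_papers=dj,
                describing_fraction_of_corpus=dj / D,
                weight=w,
            )
        )
    if journal_output is not None:
        out.sort(key=lambda jw: (-jw.weight, jw.journal))
    return out


def spearman_rho(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with mean ranks for ties and the
    large-sample p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be 1-d sequences of equal length")
    if x.size < 3:
        raise UsageError("spearman_rho requires n >= 3")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise DegenerateInputError("constant input: rank variance is zero")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def age_group_metrics(dataset: SurveyDataset) -> list[AgeGroupMetrics]:
    """Production and productivity per decade-wide author age group.

    Ages are taken at each publication, so one author can contribute to
    several bins over a career.  Coverage (the fraction of author slots with
    a known age) is emitted as a warning context because age data are
    typically opportunistic and incomplete.
    """
    production = {b: 0 for b in AGE_BINS}
    group_authors: dict[tuple[int, int], set[str]] = {b: set() for b in AGE_BINS}
    slots = known = 0
    for r in dataset.records:
        for a in r.authors:
            slots += 1
            age = a.age_at_publication
            if age is None:
                continue
            known += 1
            for lo, hi in AGE_BINS:
                if lo <= age <= hi:
                    production[(lo, hi)] += 1
                    group_authors[(lo, hi)].add(a.author_id)
                    break
    if known == 0:
        warnings.warn("no author ages known; age-group metrics are empty")
        return []
    total_authors = dataset.n_authors
    return [
        AgeGroupMetrics(
            age_bin=f"{lo}-{hi}",
            production=production[(lo, hi)],
            productivity_per_author=production[(lo, hi)] / total_authors,
            productivity_per_group=(
                production[(lo, hi)] / len(group_authors[(lo, hi)])
                if group_authors[(lo, hi)]
                else 0.0
            ),
        )
        for lo, hi in AGE_BINS
    ]


def classify_family_sampling(
    dataset: SurveyDataset, rel_tol: float = 1e-9
) -> list[FamilySamplingClass]:
    """Classify families against the origin-anchored theoretical line.

    The line through the origin with slope (total described in window) /
    (total valid species) represents proportional description effort.  A
    family below the line (fewer new descriptions than its valid richness
    predicts) is considered well sampled — its diversity was largely
    described already; a family above it is low sampled, with many species
    still being found.
    """
    valid = dataset.valid_species_by_family
    if not valid:
        raise UsageError("dataset lacks valid_species_by_family")
    described = {fam: 0 for fam in valid}
    for r in dataset.records:
        if r.family in described:
            described[r.family] += 1
    total_valid = sum(valid.values())
    if total_valid == 0:
        raise UsageError("total valid species is zero")
    slope = sum(described.values()) / total_valid
    out = []
    for fam in sorted(valid):
        expected = slope * valid[fam]
        d = described[fam]
        if abs(d - expected) <= rel_tol * max(1.0, abs(expected)):
            cls = "on_line"
        elif d < expected:
            cls = "well_sampled"
        else:
            cls = "low_sampled"
        out.append(
            FamilySamplingClass(
                family=fam,
                valid_species=valid[fam],
                described_in_window=d,
                classification=cls,
            )
        )
    return out


def authors_per_article_series(dataset: SurveyDataset) -> dict[int, float]:
    """Mean number of authors per article, per publication year.

    Years with no articles are absent from the map.
    """
    team_by_article: dict[str, tuple[int, int]] = {}
    for r in dataset.records:
        team_by_article[r.article_id] = (r.year, len(r.authors))
    sums: dict[int, list[int]] = {}
    for year, team in team_by_article.values():
        sums.setdefault(year, []).append(team)
    return {y: float(np.mean(t)) for y, t in sorted(sums.items())}


def baseline_description_rate(
    pre_window_species: int, pre_window_start: int, window_start: int
) -> float:
    """Mean description rate (species/year) before the survey window."""
    if window_start <= pre_window_start:
        raise UsageError("window_start must be after pre_window_start")
    if pre_window_species < 0:
        raise UsageError("pre_window_species must be nonnegative")
    return pre_window_species / (window_start - pre_window_start)


def stratify_impact_factor(
    values: Sequence[float], width: float = 0.3, upper: float = 6.7
) -> dict[str, int]:
    """Bin impact factors into fixed-width strata (a plotting convenience;
    correlations use the unbinned values)."""
    edges = np.arange(0.0, upper + width / 2, width)
    counts = {f"{lo:.1f}-{lo + width:.1f}": 0 for lo in edges[:-1]}
    for v in values:
        if v is None:
            continue
        i = min(int(v / width), len(edges) - 2)
        counts[f"{edges[i]:.1f}-{edges[i] + width:.1f}"] += 1
    return counts
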