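"""Descriptive bibliometrics: rates, frequencies, weights, correlations,
age groups and the family sampling classification."""

import itertools

import numpy as np
import pytest

from linneangap import (
    AuthorRecord,
    DescriptionRecord,
    SurveyDataset,
    age_group_metrics,
    authors_per_article_series,
    baseline_description_rate,
    classify_family_sampling,
    frequency_table,
    journal_weight,
    rates_summary,
    spearman_rho,
)
from linneangap.errors import DegenerateInputError, UsageError
from linneangap.summaries import stratify_impact_factor


def _ds(records, valid=None, window=(1990, 2014)):
    return SurveyDataset(
        records=tuple(records),
        window_start=window[0],
        window_end=window[1],
        pre_window_species=0,
        valid_species_by_family=valid,
    )


def _rec(i, year=1995, article="a1", journal="J", family="F", authors=None):
    return DescriptionRecord(
        species_id=f"s{i}",
        year=year,
        article_id=article,
        journal=journal,
        family=family,
        authors=authors or (AuthorRecord("au1", 40),),
    )


class TestRates:
    def test_single_record_single_year_all_rates_one(self):
        ds = _ds([_rec(1, year=2000)], window=(2000, 2000))
        r = rates_summary(ds)
        assert r.species_per_year == r.species_per_article == 1.0
        assert r.articles_per_author == 1.0
        assert r.ranges["species_per_year"] == (1, 1)

    def test_empty_dataset_rejected(self):
        with pytest.raises(DegenerateInputError):
            rates_summary(_ds([]))

    def test_rates_reproduce_margins(self, fixture_dataset):
        r = rates_summary(fixture_dataset)
        assert r.species_per_year == pytest.approx(595 / 25)
        assert r.species_per_article == pytest.approx(595 / 402)
        assert r.articles_per_author == pytest.approx(402 / 252)
        lo, hi = r.ranges["species_per_article"]
        assert 1 <= lo <= hi <= 4


class TestFrequencies:
    def test_single_label_fraction_one(self):
        table = frequency_table(_ds([_rec(1)]), "family")
        assert table == {"F": (1, 1.0)}

    def test_counts_and_fractions_sum(self, sim_dataset):
        for field in ("journal", "family"):
            table = frequency_table(sim_dataset, field)
            assert sum(c for c, _ in table.values()) == sim_dataset.n_species
            assert sum(f for _, f in table.values()) == pytest.approx(1.0)

    def test_unknown_field_rejected(self, sim_dataset):
        with pytest.raises(UsageError):
            frequency_table(sim_dataset, "year")

    def test_fixture_family_shares(self, fixture_dataset):
        table = frequency_table(fixture_dataset, "family")
        assert table["Loricariidae"][1] == pytest.approx(285 / 595)
        assert table["Trichomycteridae"][1] == pytest.approx(129 / 595)


class TestJournalWeight:
    def test_single_journal_maximal_concentration(self):
        ds = _ds([_rec(i, article=f"a{i}") for i in range(5)])
        (jw,) = journal_weight(ds, journal_output={"J": 5})
        assert jw.weight == pytest.approx(100.0)

    def test_hand_evaluated_two_journal_case(self):
        recs = [_rec(i, article=f"a{i}", journal="A") for i in range(8)]
        recs += [_rec(10 + i, article=f"b{i}", journal="B") for i in range(2)]
        out = journal_weight(_ds(recs), journal_output={"A": 10, "B": 100})
        w = {jw.journal: jw.weight for jw in out}
        assert w["A"] == pytest.approx(64.0)  # 100 * 0.8 * 0.8
        assert w["B"] == pytest.approx(0.4)  # 100 * 0.2 * 0.02

    def test_without_output_table_weight_is_none(self):
        out = journal_weight(_ds([_rec(1)]))
        assert out[0].weight is None
        assert out[0].describing_fraction_of_corpus == 1.0

    def test_fractions_sum_to_one(self, sim_dataset):
        out = journal_weight(sim_dataset)
        assert sum(j.describing_fraction_of_corpus for j in out) == pytest.approx(1.0)


def _brute_spearman(x, y):
    """Independent oracle: average ranks, then product-moment correlation."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_identity_is_one(self):
        rho, _ = spearman_rho([1, 2, 5], [1, 2, 5])
        assert rho == pytest.approx(1.0)

    def test_hand_evaluated_permutation(self):
        rho, _ = spearman_rho([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 2, 3], [4, 4, 4])

    def test_too_short_rejected(self):
        with pytest.raises(UsageError):
            spearman_rho([1, 2], [2, 1])

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_brute_force_on_permutations(self, n):
        x = list(range(1, n + 1))
        for y in itertools.permutations(x):
            rho, _ = spearman_rho(x, list(y))
            assert rho == pytest.approx(_brute_spearman(x, y), abs=1e-12)

    def test_ties_use_mean_ranks(self):
        x, y = [1, 1, 2, 3], [2, 2, 2, 5]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(_brute_spearman(x, y), abs=1e-12)


class TestAgeGroups:
    def test_single_author_lands_in_their_bin(self):
        m = age_group_metrics(_ds([_rec(1, authors=(AuthorRecord("a", 45),))]))
        by_bin = {g.age_bin: g.production for g in m}
        assert by_bin["40-49"] == 1
        assert sum(by_bin.values()) == 1

    def test_age_taken_at_each_publication(self):
        a_young = (AuthorRecord("a", 31),)
        a_older = (AuthorRecord("a", 41),)
        ds = _ds([_rec(1, authors=a_young), _rec(2, authors=a_older)])
        by_bin = {g.age_bin: g.production for g in age_group_metrics(ds)}
        assert by_bin["30-39"] == 1 and by_bin["40-49"] == 1

    def test_production_sum_matches_brute_force(self, sim_dataset):
        metrics = age_group_metrics(sim_dataset)
        total = sum(g.production for g in metrics)
        expected = sum(
            1
            for r in sim_dataset.records
            for a in r.authors
            if a.age_at_publication is not None
            and 20 <= a.age_at_publication <= 89
        )
        assert total == expected

    def test_productivity_divisors(self):
        authors = (AuthorRecord("a", 45), AuthorRecord("b", 47))
        ds = _ds([_rec(1, authors=authors), _rec(2, authors=(AuthorRecord("c", 25),))])
        by_bin = {g.age_bin: g for g in age_group_metrics(ds)}
        g = by_bin["40-49"]
        assert g.production == 2
        assert g.productivity_per_author == pytest.approx(2 / 3)  # 3 authors total
        assert g.productivity_per_group == pytest.approx(1.0)  # 2 authors in bin

    def test_no_known_ages_warns_and_returns_empty(self):
        ds = _ds([_rec(1, authors=(AuthorRecord("a", None),))])
        with pytest.warns(UserWarning):
            assert age_group_metrics(ds) == []


class TestFamilyLine:
    def test_single_family_sits_on_line(self):
        ds = _ds([_rec(1, family="A")], valid={"A": 50})
        (c,) = classify_family_sampling(ds)
        assert c.classification == "on_line"

    def test_two_family_hand_case(self):
        recs = [_rec(i, family="A") for i in range(10)]
        recs += [_rec(100 + i, family="B") for i in range(30)]
        out = classify_family_sampling(
            _ds(recs, valid={"A": 100, "B": 100}), rel_tol=1e-9
        )
        cls = {c.family: c.classification for c in out}
        # slope 40/200 = 0.2: A described 10 < 20 -> below line, B 30 > 20
        assert cls == {"A": "well_sampled", "B": "low_sampled"}

    def test_zero_described_family_is_well_sampled(self):
        ds = _ds([_rec(1, family="A")], valid={"A": 10, "B": 10})
        cls = {c.family: c.classification for c in classify_family_sampling(ds)}
        assert cls["B"] == "well_sampled"

    def test_missing_valid_counts_rejected(self, sim_dataset):
        with pytest.raises(UsageError):
            classify_family_sampling(sim_dataset)


class TestTeamSizeSeries:
    def test_single_article_mean(self):
        authors = tuple(AuthorRecord(f"a{i}", 40) for i in range(3))
        series = authors_per_article_series(_ds([_rec(1, year=1991, authors=authors)]))
        assert series == {1991: 3.0}

    def test_two_articles_one_year(self):
        r1 = _rec(1, year=1995, article="a1", authors=(AuthorRecord("a", 40),))
        r2 = _rec(
            2,
            year=1995,
            article="a2",
            authors=(AuthorRecord("b", 40), AuthorRecord("c", 41)),
        )
        assert authors_per_article_series(_ds([r1, r2])) == {1995: 1.5}

    def test_simulated_rising_trend(self, sim_dataset):
        series = authors_per_article_series(sim_dataset)
        years = sorted(series)
        slope = np.polyfit(years, [series[y] for y in years], 1)[0]
        assert slope > 0  # generator builds teams that grow over time


class TestBaselineRate:
    def test_pre_window_rate(self):
        assert baseline_description_rate(1452, 1758, 1990) == pytest.approx(
            1452 / 232
        )
        assert round(baseline_description_rate(1452, 1758, 1990), 1) == 6.3

    def test_trivial_values(self):
        assert baseline_description_rate(0, 1758, 1990) == 0.0
        assert baseline_description_rate(232, 1758, 1990) == pytest.approx(1.0)

    def test_zero_span_rejected(self):
        with pytest.raises(UsageError):
            baseline_description_rate(10, 1990, 1990)


def test_impact_factor_strata_count_all_values():
    counts = stratify_impact_factor([0.05, 0.31, 0.32, 6.9, None])
    assert sum(counts.values()) == 4
    assert counts["0.3-0.6"] == 2
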