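"""Incidence matrix construction and nonparametric richness estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linneangap import (
    IncidenceMatrix,
    build_incidence,
    chao2,
    jackknife1,
    jackknife2,
    resampled_se,
    richness_budget,
)
from linneangap.errors import UsageError
from linneangap.records import AuthorRecord, DescriptionRecord, SurveyDataset


def _matrix(cells):
    cells = np.asarray(cells, dtype=np.uint8)
    return IncidenceMatrix(
        species_ids=tuple(f"s{i}" for i in range(cells.shape[0])),
        periods=tuple(range(2000, 2000 + cells.shape[1])),
        cells=cells,
    )


def _singleton_matrix(s, m, rng=None):
    rng = rng or np.random.default_rng(0)
    cells = np.zeros((s, m), dtype=np.uint8)
    cells[np.arange(s), rng.integers(0, m, s)] = 1
    return _matrix(cells)


def _dataset(years, window=(1990, 1992)):
    recs = tuple(
        DescriptionRecord(
            species_id=f"s{i}",
            year=y,
            article_id=f"a{i}",
            journal="J",
            family="F",
            authors=(AuthorRecord("a", 40),),
        )
        for i, y in enumerate(years)
    )
    return SurveyDataset(
        records=recs,
        window_start=window[0],
        window_end=window[1],
        pre_window_species=0,
    )


class TestIncidence:
    def test_description_data_are_singletons(self):
        mat = build_incidence(_dataset([1990, 1990, 1991]))
        assert (mat.m, mat.S_obs, mat.Q1, mat.Q2) == (3, 3, 3, 0)
        assert (mat.cells.sum(axis=1) == 1).all()

    def test_fixture_dimensions(self, fixture_dataset):
        mat = build_incidence(fixture_dataset)
        assert (mat.m, mat.S_obs) == (25, 595)
        assert mat.Q1 == 595 and mat.Q2 == 0

    def test_zero_count_years_kept_as_columns(self):
        mat = build_incidence(_dataset([1990, 1990], window=(1990, 1999)))
        assert mat.m == 10

    def test_empty_rows_rejected(self):
        with pytest.raises(UsageError):
            _matrix([[0, 0, 0], [1, 0, 0]])


# direct-formula oracles, written independently of the implementation
def _oracle(freq, m):
    s = (freq > 0).sum()
    q1, q2 = (freq == 1).sum(), (freq == 2).sum()
    return {
        "jack2": s + q1 * (2 * m - 3) / m - q2 * (m - 2) ** 2 / (m * (m - 1)),
        "jack1": s + q1 * (m - 1) / m,
        "chao2": s + ((m - 1) / m) * q1 * (q1 - 1) / (2 * (q2 + 1)),
    }


class TestEstimators:
    def test_jack2_hand_evaluated(self):
        # S=5, m=3, Q1=2, Q2=1
        mat = _matrix(
            [
                [1, 0, 0],
                [0, 1, 0],
                [1, 1, 0],
                [1, 1, 1],
                [1, 1, 1],
            ]
        )
        assert (mat.S_obs, mat.Q1, mat.Q2) == (5, 2, 1)
        assert jackknife2(mat).estimate == pytest.approx(5 + 2 - 1 / 6)

    def test_no_rare_species_collapses_to_observed(self):
        mat = _matrix(np.ones((4, 5)))
        assert jackknife2(mat).estimate == 4.0
        assert jackknife1(mat).estimate == 4.0
        assert chao2(mat).estimate == 4.0

    def test_all_singleton_closed_form(self):
        mat = _singleton_matrix(595, 25)
        assert jackknife2(mat).estimate == pytest.approx(3 * 595 * 24 / 25)
        assert jackknife2(mat).estimate == pytest.approx(1713.6)

    def test_jack1_hand_evaluated(self):
        mat = _matrix(
            [
                [1, 0, 0, 0],
                [0, 1, 0, 0],
                [1, 1, 0, 0],
                [1, 1, 1, 0],
                [1, 1, 1, 1],
            ]
        )
        assert (mat.S_obs, mat.m, mat.Q1, mat.Q2) == (5, 4, 2, 1)
        assert jackknife1(mat).estimate == pytest.approx(6.5)

    def test_chao2_bias_corrected_when_no_duplicates(self):
        mat = _matrix(
            [
                [1, 0, 0, 0],
                [0, 1, 0, 0],
                [1, 1, 1, 0],
                [1, 1, 1, 1],
                [1, 1, 1, 1],
            ]
        )
        assert (mat.S_obs, mat.m, mat.Q1, mat.Q2) == (5, 4, 2, 0)
        assert chao2(mat).estimate == pytest.approx(5 + 0.75 * 2 * 1 / 2)

    def test_insufficient_periods_rejected(self):
        mat = _matrix([[1, 0], [0, 1]])
        with pytest.raises(UsageError):
            jackknife2(mat)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_estimators_match_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        s, m = int(rng.integers(1, 12)), int(rng.integers(3, 10))
        cells = (rng.random((s, m)) < 0.4).astype(np.uint8)
        cells[np.arange(s), rng.integers(0, m, s)] = 1  # no empty rows
        mat = _matrix(cells)
        freq = cells.sum(axis=1)
        oracle = _oracle(freq, m)
        assert jackknife2(mat).estimate == pytest.approx(oracle["jack2"])
        assert jackknife1(mat).estimate == pytest.approx(oracle["jack1"])
        assert chao2(mat).estimate == pytest.approx(oracle["chao2"])

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_jackknife_ordering_under_premise(self, seed):
        rng = np.random.default_rng(seed)
        mat = _singleton_matrix(int(rng.integers(2, 30)), int(rng.integers(3, 12)), rng)
        if mat.Q1 >= mat.Q2:
            assert (
                jackknife2(mat).estimate
                >= jackknife1(mat).estimate
                >= mat.S_obs
            )


class TestResampling:
    def test_identical_columns_have_zero_se(self):
        mat = _matrix(np.ones((6, 5)))
        est = resampled_se(mat, "jack2", n=200, seed=1)
        assert est.se == 0.0

    def test_seeded_determinism(self, fixture_dataset):
        mat = build_incidence(fixture_dataset)
        a = resampled_se(mat, "jack2", n=100, seed=42)
        b = resampled_se(mat, "jack2", n=100, seed=42)
        assert a == b

    def test_against_independent_resampler(self):
        rng = np.random.default_rng(5)
        cells = (rng.random((8, 5)) < 0.5).astype(np.uint8)
        cells[np.arange(8), rng.integers(0, 5, 8)] = 1
        mat = _matrix(cells)
        est = resampled_se(mat, "jack2", n=10000, seed=9)

        # independent second implementation: explicit column-resampled
        # matrices, fresh rng stream
        rng2 = np.random.default_rng(77)
        reps = []
        for _ in range(10000):
            sub = cells[:, rng2.integers(0, 5, 5)]
            freq = sub.sum(axis=1)
            reps.append(_oracle(freq, 5)["jack2"])
        assert est.se == pytest.approx(np.std(reps, ddof=1), rel=0.05)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(UsageError):
            resampled_se(_matrix(np.eye(3)), n=1)


class TestBudget:
    def test_nothing_undiscovered(self):
        from linneangap import RichnessEstimate

        ds = _dataset([1990, 1991])
        budget = richness_budget(RichnessEstimate("jack2", 2.0), ds)
        assert budget.remaining == 0.0
        assert budget.remaining_fraction == 0.0

    def test_reported_budget_arithmetic(self):
        from linneangap import RichnessEstimate

        # with the published in-window pool of 1,715 and 595 described
        budget = richness_budget(
            RichnessEstimate("jack2", 1715.0),
            SurveyDataset(
                records=_dataset(
                    [1990 + (i % 3) for i in range(595)], window=(1990, 1992)
                ).records,
                window_start=1990,
                window_end=1992,
                pre_window_species=1452,
            ),
        )
        assert budget.K_total == 3167.0
        assert budget.described_total == 2047
        assert budget.remaining == 1120.0
        assert budget.remaining_fraction == pytest.approx(1120 / 3167)

    def test_full_chain_rounds_to_35_percent(self, fixture_dataset):
        mat = build_incidence(fixture_dataset)
        budget = richness_budget(jackknife2(mat), fixture_dataset)
        assert budget.remaining == pytest.approx(1118.6)
        assert round(100 * budget.remaining_fraction) == 35

    def test_scale_invariance_of_remaining_fraction(self):
        # with the singleton closed form jack2 = 3 S (m-1)/m, scaling both
        # S_obs and the pre-window count by c leaves the fraction unchanged
        m = 10
        for s, pre in ((20, 50), (40, 100), (200, 500)):
            mat = _singleton_matrix(s, m)
            est = jackknife2(mat)
            K = est.estimate + pre
            frac = (K - (pre + s)) / K
            if s == 20:
                base = frac
            assert frac == pytest.approx(base)
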