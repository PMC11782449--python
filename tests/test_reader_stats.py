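"""Reader-study statistics: confusion, kappa, Mann-Whitney U, rating summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scorerecon.errors import DegenerateInputError
from scorerecon.metrics import MetricReport
from scorerecon.reader_stats import (
    cohens_kappa,
    confusion_matrix,
    high_rating_fraction,
    load_ratings,
    mann_whitney_u,
    metric_rating_summary,
    simulate_raters,
    validate_ratings,
)


def _reader_frames(ratings_df):
    readers = sorted(ratings_df["reader_id"].unique())
    return [
        ratings_df[ratings_df["reader_id"] == r][["case_id", "R", "rating"]]
        for r in readers
    ]


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        a = pd.DataFrame({"case_id": range(10), "R": 2.0, "rating": [5, 4, 3, 2, 1] * 2})
        m = confusion_matrix(a, a)
        assert m.sum() == 10
        assert np.trace(m) == 10

    def test_swapped_readers_transpose(self):
        ratings = simulate_raters(range(30), seed=1)
        a, b = _reader_frames(ratings)
        np.testing.assert_array_equal(confusion_matrix(a, b).T, confusion_matrix(b, a))

    def test_total_equals_matched_pairs(self):
        ratings = simulate_raters(range(25), seed=2)
        a, b = _reader_frames(ratings)
        assert confusion_matrix(a, b).sum() == len(a)

    def test_unmatched_cases_excluded(self):
        a = pd.DataFrame({"case_id": [1, 2, 3], "R": 2.0, "rating": [5, 4, 3]})
        b = pd.DataFrame({"case_id": [2, 3, 4], "R": 2.0, "rating": [4, 3, 2]})
        assert confusion_matrix(a, b).sum() == 2

    def test_no_overlap_rejected(self):
        a = pd.DataFrame({"case_id": [1], "R": 2.0, "rating": [5]})
        b = pd.DataFrame({"case_id": [2], "R": 2.0, "rating": [5]})
        with pytest.raises(DegenerateInputError):
            confusion_matrix(a, b)


class TestCohensKappa:
    def test_perfect_agreement(self):
        m = np.diag([4, 3, 2, 1, 5])
        report = cohens_kappa(m, ci_bootstrap=200, seed=0)
        assert report.kappa == pytest.approx(1.0)
        assert report.ci_low <= report.kappa <= report.ci_high

    def test_hand_derived_2x2_example(self):
        # p_o = 35/50 = 0.7; p_e = (25*30 + 25*20)/50^2 = 0.5; kappa = 0.4
        m = np.array([[20, 5], [10, 15]])
        report = cohens_kappa(m, ci_bootstrap=0)
        assert report.kappa == pytest.approx(0.4)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 6, size=10_000)
        b = rng.integers(1, 6, size=10_000)
        m = np.zeros((5, 5), dtype=int)
        np.add.at(m, (a - 1, b - 1), 1)
        assert abs(cohens_kappa(m, ci_bootstrap=0).kappa) < 0.05

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        ratings = simulate_raters(range(60), seed=4)
        a, b = _reader_frames(ratings)
        merged = a.merge(b, on=["case_id", "R"], suffixes=("_a", "_b"))
        expected = cohen_kappa_score(merged["rating_a"], merged["rating_b"])
        m = confusion_matrix(a, b)
        assert cohens_kappa(m, ci_bootstrap=0).kappa == pytest.approx(expected)

    def test_linear_weights_match_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        ratings = simulate_raters(range(60), seed=5)
        a, b = _reader_frames(ratings)
        merged = a.merge(b, on=["case_id", "R"], suffixes=("_a", "_b"))
        expected = cohen_kappa_score(
            merged["rating_a"], merged["rating_b"], labels=[1, 2, 3, 4, 5], weights="linear"
        )
        m = confusion_matrix(a, b)
        assert cohens_kappa(m, ci_bootstrap=0, weights="linear").kappa == pytest.approx(expected)

    def test_degenerate_single_cell_rejected(self):
        m = np.zeros((5, 5), dtype=int)
        m[2, 2] = 40  # all mass in one cell pair: p_e = 1
        with pytest.raises(DegenerateInputError):
            cohens_kappa(m, ci_bootstrap=0)

    def test_bootstrap_ci_contains_point_and_shrinks_with_n(self):
        widths = {}
        for n_cases in (50, 500):
            ratings = simulate_raters(range(n_cases), seed=6)
            a, b = _reader_frames(ratings)
            report = cohens_kappa(confusion_matrix(a, b), ci_bootstrap=500, seed=1)
            assert report.ci_low <= report.kappa <= report.ci_high
            widths[n_cases] = report.ci_high - report.ci_low
        assert widths[500] < widths[50]

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=1000))
    def test_invariant_under_category_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 10, size=(5, 5))
        m += np.diag(rng.integers(1, 10, size=5))  # avoid degenerate tables
        perm = rng.permutation(5)
        k1 = cohens_kappa(m, ci_bootstrap=0).kappa
        k2 = cohens_kappa(m[np.ix_(perm, perm)], ci_bootstrap=0).kappa
        assert k1 == pytest.approx(k2)


class TestMannWhitney:
    def test_enumeration_derived_example(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_samples_u_half(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, _ = mann_whitney_u(a, list(a), mode="normal_approx")
        assert u == pytest.approx(len(a) ** 2 / 2)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        u_ab, p_ab = mann_whitney_u(a, b, mode="exact", exact_limit=20)
        u_ba, p_ba = mann_whitney_u(b, a, mode="exact", exact_limit=20)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)

    def test_exact_and_normal_agree_tie_free(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.8, 1, 10)
        _, p_exact = mann_whitney_u(a, b, mode="exact")
        _, p_norm = mann_whitney_u(a, b, mode="normal_approx")
        assert abs(p_exact - p_norm) < 0.02

    def test_matches_scipy_normal_approx_with_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(9)
        a = rng.integers(1, 6, size=40).astype(float)
        b = rng.integers(1, 6, size=35).astype(float)
        u, p = mann_whitney_u(a, b, mode="normal_approx")
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_exact_limit_enforced(self):
        with pytest.raises(ValueError):
            mann_whitney_u(np.arange(20), np.arange(20), mode="exact", exact_limit=25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0], mode="exact")


class TestHighRatingFraction:
    def test_all_fives(self):
        df = pd.DataFrame(
            {"reader_id": "r1", "case_id": range(4), "R": 2.0, "rating": 5}
        )
        out = high_rating_fraction(df, threshold=4)
        assert out["fraction"].tolist() == [1.0]

    def test_half_high(self):
        df = pd.DataFrame(
            {"reader_id": "r1", "case_id": range(4), "R": 5.0, "rating": [5, 4, 3, 2]}
        )
        assert high_rating_fraction(df, threshold=4)["fraction"].iloc[0] == 0.5

    def test_threshold_one_is_always_full(self):
        ratings = simulate_raters(range(20), seed=10)
        out = high_rating_fraction(ratings, threshold=1)
        assert (out["fraction"] == 1.0).all()

    def test_fraction_declines_with_acceleration(self):
        ratings = simulate_raters(range(200), seed=11)
        out = high_rating_fraction(ratings, threshold=4)
        for _, grp in out.groupby("reader_id"):
            fr = grp.sort_values("R")["fraction"].to_numpy()
            assert fr[0] >= fr[1] >= fr[2]


class TestMetricRatingSummary:
    def _report(self, case_ids, R, values):
        per_item = pd.DataFrame(
            {
                "case_id": case_ids,
                "R": R,
                "psnr_db": values,
                "ssim": np.asarray(values) / 50,
                "data_range": 1.0,
            }
        )
        return MetricReport(per_item=per_item, aggregate=pd.DataFrame())

    def test_monotone_metrics_give_spearman_one(self):
        ratings = pd.DataFrame(
            {
                "reader_id": "r1",
                "case_id": range(5),
                "R": 2.0,
                "rating": [1, 2, 3, 4, 5],
            }
        )
        report = self._report(range(5), 2.0, [10.0, 20.0, 30.0, 40.0, 50.0])
        _, corr = metric_rating_summary(report, ratings)
        assert corr["spearman_psnr"] == pytest.approx(1.0)
        assert corr["spearman_ssim"] == pytest.approx(1.0)

    def test_single_category(self):
        ratings = pd.DataFrame(
            {"reader_id": "r1", "case_id": range(3), "R": 2.0, "rating": 4}
        )
        report = self._report(range(3), 2.0, [10.0, 20.0, 30.0])
        summary, _ = metric_rating_summary(report, ratings)
        assert len(summary) == 1
        assert summary["psnr_median"].iloc[0] == pytest.approx(20.0)

    def test_shuffled_metric_uncorrelated(self):
        rng = np.random.default_rng(12)
        n = 1000
        ratings = pd.DataFrame(
            {
                "reader_id": "r1",
                "case_id": range(n),
                "R": 2.0,
                "rating": rng.integers(1, 6, size=n),
            }
        )
        report = self._report(range(n), 2.0, rng.permutation(np.linspace(10, 50, n)))
        _, corr = metric_rating_summary(report, ratings)
        assert abs(corr["spearman_psnr"]) < 0.1

    def test_empty_join_rejected(self):
        ratings = pd.DataFrame(
            {"reader_id": "r1", "case_id": [100], "R": 2.0, "rating": [4]}
        )
        report = self._report([0], 5.0, [20.0])
        with pytest.raises(DegenerateInputError):
            metric_rating_summary(report, ratings)


class TestRatingsIngest:
    def test_csv_roundtrip(self, tmp_path):
        ratings = simulate_raters(range(10), seed=13)
        path = tmp_path / "ratings.csv"
        ratings.to_csv(path, index=False)
        back = load_ratings(path)
        pd.testing.assert_frame_equal(
            back.sort_index(axis=1), ratings.sort_index(axis=1)
        )

    def test_out_of_scale_rating_rejected(self):
        df = pd.DataFrame(
            {"reader_id": ["r1"], "case_id": [0], "R": [2.0], "rating": [6]}
        )
        with pytest.raises(ValueError):
            validate_ratings(df)

    def test_duplicate_key_rejected(self):
        df = pd.DataFrame(
            {"reader_id": ["r1", "r1"], "case_id": [0, 0], "R": [2.0, 2.0], "rating": [4, 5]}
        )
        with pytest.raises(ValueError):
            validate_ratings(df)

    def test_simulated_raters_reach_target_agreement_regime(self):
        ratings = simulate_raters(range(300), reader_noise=0.7, seed=14)
        a, b = _reader_frames(ratings)
        report = cohens_kappa(confusion_matrix(a, b), ci_bootstrap=0)
        assert 0.2 < report.kappa < 0.9  # substantial but imperfect agreement
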