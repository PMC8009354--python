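"""Cross-validated regression: folds, forms, scores, reports."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import leafwater as lw
from leafwater.regression import (FORMS, association_pvalue, format_equation,
                                  _score)


def _table(x, y, species=None):
    df = pd.DataFrame({"sample_id": [f"S{i}" for i in range(len(x))],
                       "idx": x, "ewt": y})
    if species is not None:
        df["species"] = species
    return df


class TestFolds:
    def test_study_size_fold_sizes(self):
        plan = lw.make_folds(292, 10, seed=1)
        assert sorted(plan.fold_sizes()) == [29] * 8 + [30] * 2

    def test_leave_one_out(self):
        plan = lw.make_folds(10, 10, seed=1)
        assert plan.fold_sizes() == [1] * 10

    def test_deterministic_given_seed(self):
        a = lw.make_folds(100, 10, seed=5)
        b = lw.make_folds(100, 10, seed=5)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        c = lw.make_folds(100, 10, seed=6)
        assert not np.array_equal(a.assignment, c.assignment)

    def test_partition_property(self):
        plan = lw.make_folds(57, 7, seed=2)
        seen = np.concatenate([plan.test_indices(f) for f in range(7)])
        assert sorted(seen) == list(range(57))

    def test_n_less_than_k_rejected(self):
        with pytest.raises(ValueError):
            lw.make_folds(5, 10)


class TestFitForm:
    def test_exact_line(self):
        x = np.arange(5.0)
        coef = lw.fit_form(x, 2 * x + 1, "linear")
        np.testing.assert_allclose(coef, [2, 1], atol=1e-10)

    def test_exact_parabola(self):
        x = np.linspace(-2, 2, 9)
        coef = lw.fit_form(x, 3 * x ** 2 - x + 0.5, "quadratic")
        np.testing.assert_allclose(coef, [3, -1, 0.5], atol=1e-10)

    def test_exact_exponential(self):
        x = np.linspace(0, 2, 12)
        coef = lw.fit_form(x, 1.5 * np.exp(0.8 * x), "exponential")
        np.testing.assert_allclose(coef, [1.5, 0.8], atol=1e-8)

    def test_noisy_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(9)
        n, slope, sigma = 200, 0.7, 0.3
        x = rng.uniform(0, 1, n)
        y = slope * x + rng.normal(0, sigma, n)
        coef = lw.fit_form(x, y, "linear")
        se = sigma / (np.std(x) * np.sqrt(n))
        assert abs(coef[0] - slope) < 3 * se

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            lw.fit_form(np.ones(10), np.arange(10.0), "linear")

    def test_equation_formatting(self):
        eq = format_equation(np.array([0.204, -0.205]), "linear")
        assert eq == "y = 0.204*x-0.205"
        eq2 = format_equation(np.array([-26.346, 58.963, -32.200]), "quadratic")
        assert eq2 == "y = -26.346*x^2+58.963*x-32.200"


class TestCrossValidate:
    def test_noiseless_linear_is_perfect(self):
        x = np.linspace(1.0, 1.2, 50)
        res = lw.cross_validate(_table(x, 0.2 * x - 0.1), "idx", "ewt", "linear", seed=4)
        assert res.r2cv == pytest.approx(1.0, abs=1e-12)
        assert res.rrmse_cv == pytest.approx(0.0, abs=1e-10)

    def test_rrmse_matches_independent_recomputation(self, index_table):
        res = lw.cross_validate(index_table, "SAI_1200", "ewt", "linear", seed=8)
        pf = res.per_fold_predictions
        rmse = np.sqrt(np.mean((pf.observed - pf.predicted) ** 2))
        assert res.rrmse_cv == pytest.approx(rmse / pf.observed.mean(), abs=1e-12)

    def test_out_of_fold_predictions_cover_each_sample_once(self, index_table):
        res = lw.cross_validate(index_table, "SAI_1200", "ewt", "linear", seed=8)
        pf = res.per_fold_predictions
        assert len(pf) == res.n_used
        assert pf.sample_id.is_unique
        assert pf.predicted.notna().all()

    def test_independent_index_scores_near_zero(self):
        rng = np.random.default_rng(12)
        n = 300
        res = lw.cross_validate(_table(rng.normal(size=n), rng.normal(size=n) + 5),
                                "idx", "ewt", "linear", seed=12)
        assert res.r2cv < 0.05

    def test_generator_relation_recovered(self, index_table):
        res = lw.cross_validate(index_table, "SAI_1200", "ewt", "linear", seed=8)
        assert res.r2cv > 0.9

    def test_r2cv_affine_invariant_for_linear_form(self, index_table):
        base = lw.cross_validate(index_table, "SAI_1200", "ewt", "linear", seed=8)
        shifted = index_table.copy()
        shifted["SAI_1200"] = 3.0 * shifted["SAI_1200"] - 1.7
        res = lw.cross_validate(shifted, "SAI_1200", "ewt", "linear", seed=8)
        assert res.r2cv == pytest.approx(base.r2cv, abs=1e-9)

    def test_monotone_degradation_with_index_noise(self, index_table):
        rng = np.random.default_rng(21)
        spread = index_table["SAI_1200"].std()
        noise = rng.standard_normal(len(index_table))
        scores = []
        for level in [0.0, 0.5, 1.0, 2.0, 4.0]:
            noisy = index_table.copy()
            noisy["SAI_1200"] = noisy["SAI_1200"] + level * spread * noise
            scores.append(lw.cross_validate(noisy, "SAI_1200", "ewt", "linear",
                                            seed=8).r2cv)
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_sse_variant_available(self, index_table):
        res = lw.cross_validate(index_table, "SAI_1200", "ewt", "linear", seed=8,
                                r2_variant="sse")
        assert 0.8 < res.r2cv <= 1.0

    def test_missing_rows_dropped(self, index_table):
        broken = index_table.copy()
        broken.loc[broken.index[:7], "SAI_1200"] = np.nan
        res = lw.cross_validate(broken, "SAI_1200", "ewt", "linear", seed=8)
        assert res.n_used == len(index_table) - 7


class TestReports:
    def test_ranking_columns_and_order(self, index_table):
        report = lw.rank_indices(index_table, "ewt", forms=("linear", "quadratic"))
        assert {"index", "P", "regression_equation", "r2cv", "rrmse_cv_pct"} <= set(report.columns)
        scored = report.dropna(subset=["r2cv"])
        assert list(scored.r2cv) == sorted(scored.r2cv, reverse=True)
        # the adaptive 1200-nm index outranks the adaptive 970-nm one for EWT
        ranks = {row["index"]: i for i, row in report.iterrows()}
        assert ranks["SAI_1200"] < ranks["SAI_970"]

    def test_not_significant_marked_ns(self):
        rng = np.random.default_rng(33)
        n = 100
        tab = _table(rng.normal(size=n), rng.normal(size=n) + 5)
        tab["idx2"] = 0.2 * tab["ewt"] + rng.normal(0, 0.01, n)
        report = lw.rank_indices(tab, "ewt", index_names=["idx", "idx2"],
                                 forms=("linear",))
        row = report[report["index"] == "idx"].iloc[0]
        assert row.P == "n.s." and row.regression_equation == "-"
        assert report[report["index"] == "idx2"].iloc[0].P != "n.s."

    def test_single_index_ranking_rejected(self, index_table):
        with pytest.raises(ValueError):
            lw.rank_indices(index_table, "ewt", index_names=["SAI_1200"])


class TestSimilarity:
    def test_identity_pair(self, index_table):
        sim = lw.similarity_analysis(index_table, ("SAI_1200", "SAI_1200"), "ewt")
        assert sim == pytest.approx(1.0, abs=1e-12)

    def test_independent_indices_near_null_level(self):
        # out-of-fold prediction vectors have roughly k effective degrees of
        # freedom (fold-level intercept jitter), so the null similarity is
        # O(1/(k-1)), not machine zero; 0.35 covers the null spread while
        # staying far from the >0.8 correlated-signal regime
        rng = np.random.default_rng(44)
        n = 300
        tab = _table(rng.normal(size=n), rng.normal(size=n) + 5)
        tab["idx2"] = rng.normal(size=n)
        assert lw.similarity_analysis(tab, ("idx", "idx2"), "ewt") < 0.35

    def test_sai_and_ratio_track_same_signal(self, index_table):
        sim = lw.similarity_analysis(index_table, ("SAI_1200", "RATIO_1200"), "ewt")
        assert sim > 0.8


class TestSpeciesFits:
    def test_shared_truth_gives_tight_slope_range(self):
        rng = np.random.default_rng(55)
        n = 240
        x = rng.uniform(1.0, 1.2, n)
        y = 0.2 * x - 0.1 + rng.normal(0, 0.001, n)
        tab = _table(x, y, species=np.repeat(["A", "B", "C"], n // 3))
        fits = lw.group_by_species(tab, "ewt", "idx")
        lo, hi = fits.attrs["slope_range"]
        assert hi - lo < 0.05 * 0.2

    def test_single_species(self, index_table):
        one = index_table[index_table.species == "VX"]
        fits = lw.group_by_species(one, "ewt", "SAI_1200")
        assert len(fits) == 1

    def test_small_species_skipped(self, index_table):
        tab = pd.concat([index_table, index_table.iloc[:2].assign(species="ZZ",
                        sample_id=["z1", "z2"])], ignore_index=True)
        fits = lw.group_by_species(tab, "ewt", "SAI_1200")
        assert "ZZ" not in set(fits.species)


class TestAssociationPValue:
    def test_strong_relation_significant(self):
        x = np.linspace(0, 1, 50)
        assert association_pvalue(x, 2 * x + 0.01 * np.sin(99 * x), "linear") < 1e-6

    def test_exponential_form_pvalue_sane(self):
        rng = np.random.default_rng(66)
        x = rng.uniform(0, 1, 80)
        y = 0.5 * np.exp(1.2 * x) + rng.normal(0, 0.05, 80)
        assert association_pvalue(x, y, "exponential") < 1e-6
        y_null = rng.normal(1, 0.1, 80)
        assert association_pvalue(x, y_null, "exponential") > 0.001
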