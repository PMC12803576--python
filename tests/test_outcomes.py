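"""Outcome classification, staging, and statistical plumbing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from myokin.outcomes import (
    DEFAULT_STAGING_RULE,
    classify_response,
    correlate,
    group_compare,
    pca_features,
    roc_auc,
    standardized_beta_regression,
    utah_inova_stage,
)


def outcome_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "lvef_pre", "lvef_post", "lvedd_pre", "lvedd_post"]
    )


class TestClassifyResponse:
    def test_inclusive_lvef_boundary(self):
        out = classify_response(outcome_frame([
            ("a", 20.0, 30.0, 70.0, 70.0),   # delta exactly 10 -> responder
            ("b", 20.0, 29.9, 70.0, 70.0),   # 9.9 -> not
        ]))
        assert bool(out.loc[0, "functional_responder"]) is True
        assert bool(out.loc[1, "functional_responder"]) is False

    def test_inclusive_lvedd_boundary(self):
        out = classify_response(outcome_frame([
            ("a", 20, 20, 70.0, 59.5),   # reduction exactly 15% -> responder
            ("b", 20, 20, 70.0, 59.6),
        ]))
        assert bool(out.loc[0, "optimal_unloading"]) is True
        assert bool(out.loc[1, "optimal_unloading"]) is False
        assert out.loc[0, "lvedd_rel_change"] == pytest.approx(0.15)

    def test_missing_rows_flagged_not_dropped(self):
        out = classify_response(outcome_frame([
            ("a", 20.0, np.nan, 70.0, 59.0),
        ]))
        assert len(out) == 1
        assert pd.isna(out.loc[0, "functional_responder"])
        assert bool(out.loc[0, "optimal_unloading"]) is True

    def test_zero_lvedd_rejected(self):
        with pytest.raises(ValueError):
            classify_response(outcome_frame([("a", 20, 25, 0.0, 0.0)]))

    def test_planted_labels_recount(self):
        rng = np.random.default_rng(8)
        d_lvef = rng.uniform(-5, 25, 50)
        red = rng.uniform(-0.05, 0.4, 50)
        rows = [(f"p{i}", 20.0, 20.0 + d, 70.0, 70.0 * (1 - r))
                for i, (d, r) in enumerate(zip(d_lvef, red))]
        out = classify_response(outcome_frame(rows))
        assert out["functional_responder"].astype(bool).sum() == (d_lvef >= 10).sum()
        assert out["optimal_unloading"].astype(bool).sum() == (red >= 0.15 - 1e-12).sum()


class TestStaging:
    def test_identical_patients_single_stage(self):
        out = outcome_frame([("a", 20, 32, 70, 60), ("b", 20, 32, 70, 60)])
        stages = utah_inova_stage(out)
        assert stages.nunique() == 1

    def test_rule_swap_changes_labels_only(self):
        out = outcome_frame([("a", 20, 27, 70, 60)])
        default = utah_inova_stage(out)
        relaxed = utah_inova_stage(out, {"responder": 6.0, "partial responder": 3.0,
                                         "non-responder": -np.inf})
        assert default.iloc[0] == "partial responder"
        assert relaxed.iloc[0] == "responder"

    def test_unknown_stage_rejected(self):
        out = outcome_frame([("a", 20, 27, 70, 60)])
        with pytest.raises(ValueError):
            utah_inova_stage(out, {"super-responder": 20.0})

    def test_ordering(self):
        out = outcome_frame([
            ("n", 20, 22, 70, 70), ("p", 20, 27, 70, 70), ("r", 20, 35, 70, 70)
        ])
        stages = utah_inova_stage(out)
        assert list(stages) == ["non-responder", "partial responder", "responder"]
        assert stages.cat.ordered


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert correlate(x, x).r == pytest.approx(1.0)
        assert correlate(x, -x).r == pytest.approx(-1.0)

    def test_fixture_matches_independent_computation(self):
        # 10-pair fixture; oracle via direct definition at float precision
        x = np.array([1.2, 2.1, 2.9, 3.4, 4.8, 5.1, 6.3, 7.0, 8.2, 9.9])
        y = np.array([0.9, 2.4, 2.2, 4.1, 4.0, 6.2, 5.9, 7.5, 8.8, 9.1])
        r_oracle = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        res = correlate(x, y)
        assert res.r == pytest.approx(r_oracle, rel=1e-12)
        assert res.ci_low < res.r < res.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=50, seed=0)
        assert res.auc == 1.0

    def test_random_score_near_half(self):
        rng = np.random.default_rng(3)
        score = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        res = roc_auc(score, labels, n_boot=50, seed=0)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_eight_point_fixture_equals_pair_counting(self):
        score = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9, 0.5, 0.5])
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 1], dtype=bool)
        conc = 0.0
        pairs = 0
        for i, j in itertools.product(np.where(labels)[0], np.where(~labels)[0]):
            pairs += 1
            if score[i] > score[j]:
                conc += 1.0
            elif score[i] == score[j]:
                conc += 0.5
        res = roc_auc(score, labels, n_boot=100, seed=1)
        assert res.auc == pytest.approx(conc / pairs, rel=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_bootstrap_seeded(self):
        score = np.random.default_rng(0).normal(size=40)
        labels = score + np.random.default_rng(1).normal(size=40) > 0
        a = roc_auc(score, labels, n_boot=200, seed=7)
        b = roc_auc(score, labels, n_boot=200, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestGroupCompare:
    def test_identical_groups_t_near_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        res = group_compare(np.concatenate([v, v]), ["a"] * 40 + ["b"] * 40)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_non_normal_falls_back_to_mannwhitney(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(0, 2.5, 80)
        b = rng.lognormal(0.5, 2.5, 80)
        res = group_compare(np.concatenate([a, b]), ["a"] * 80 + ["b"] * 80)
        assert res.test == "mannwhitney"


class TestStandardizedBeta:
    def test_single_predictor_equals_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = 2.0 * x + rng.normal(size=60)
        feats = pd.DataFrame({"x": x})
        table = standardized_beta_regression(feats, y)
        r = np.corrcoef(x, y)[0, 1]
        assert table.loc["x", "abs_beta"] == pytest.approx(abs(r), rel=1e-9)

    def test_six_row_fixture_matches_statsmodels(self):
        feats = pd.DataFrame({
            "u": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "v": [2.0, 1.5, 3.5, 2.5, 5.5, 4.0],
        })
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.4, 5.6])
        table = standardized_beta_regression(feats, y)
        import statsmodels.api as sm

        Xz = (feats - feats.mean()) / feats.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
        for col in ("u", "v"):
            assert table.loc[col, "beta"] == pytest.approx(fit.params[col], rel=1e-9)

    def test_rank_deficiency_rejected(self):
        feats = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        with pytest.raises(ValueError):
            standardized_beta_regression(feats, [1.0, 2.0, 3.0])


class TestPca:
    def test_variance_explained_sums_below_one(self):
        rng = np.random.default_rng(4)
        feats = pd.DataFrame(rng.normal(size=(30, 6)))
        scores, evr = pca_features(feats, n_components=2)
        assert scores.shape == (30, 2)
        assert 0 < evr.sum() <= 1.0 + 1e-9
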