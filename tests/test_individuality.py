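"""KMO, correlation-matrix PCA and Beecher's information statistic."""
import math

import numpy as np
import pandas as pd
import pytest

from aukcalls import PARAMETER_COLUMNS, SimConfig, generate_dataset
from aukcalls.individuality import (
    HsSettings,
    beecher_hs,
    distinguishable_individuals,
    individuality_report,
    kmo,
    pca_scores,
    subsample_balanced,
)
from aukcalls.schema import DataError


class TestKMO:
    def test_two_variables_always_half(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((300, 1))
        X = np.hstack([x, 0.7 * x + 0.5 * rng.standard_normal((300, 1))])
        overall, per_var = kmo(X)
        assert overall == pytest.approx(0.5, abs=1e-12)
        assert per_var == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_one_factor_structure_scores_high(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((500, 1))
        X = f @ np.ones((1, 6)) + 0.5 * rng.standard_normal((500, 6))
        overall, _ = kmo(X)
        assert overall > 0.7

    def test_independent_variables_score_near_half(self):
        rng = np.random.default_rng(2)
        overall, _ = kmo(rng.standard_normal((500, 6)))
        assert overall == pytest.approx(0.5, abs=0.1)

    def test_collinear_columns_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((100, 2))
        with pytest.raises(DataError):
            kmo(np.hstack([x, x[:, :1]]))


class TestPCAScores:
    def test_scores_uncorrelated_and_shares_sum_to_one(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 5)) @ rng.standard_normal((5, 5))
        scores, loadings, shares = pca_scores(X)
        cov = np.cov(scores, rowvar=False)
        assert np.allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-8)
        assert shares.sum() == pytest.approx(1.0)

    def test_two_variable_leading_share_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(400)
        y = 0.6 * x + 0.8 * rng.standard_normal(400)
        X = np.column_stack([x, y])
        r = np.corrcoef(X, rowvar=False)[0, 1]
        _, _, shares = pca_scores(X)
        assert shares[0] == pytest.approx((1 + abs(r)) / 2, abs=1e-10)

    def test_constant_column_rejected(self):
        X = np.ones((50, 3))
        X[:, :2] = np.random.default_rng(6).standard_normal((50, 2))
        with pytest.raises(DataError):
            pca_scores(X)


class TestBeecherHs:
    def test_constructed_f_values_give_one_bit(self):
        # two identical within-group samples shifted by d: for 2 groups of
        # size k with unit within-group variance, F = k d^2 / 2 exactly, so
        # d = sqrt(8/k) gives F = 4 (1 bit) and d = sqrt(2/k) gives F = 1
        # (0 bits); hs_all = 1
        rng = np.random.default_rng(7)
        k = 40
        z = rng.standard_normal(k)
        z = (z - z.mean()) / z.std(ddof=1)

        def column(d):
            return np.concatenate([z, z + d])

        labels = np.repeat(["a", "b"], k)
        scores = np.column_stack([column(np.sqrt(8 / k)),
                                  column(np.sqrt(2 / k))])
        rep = beecher_hs(scores, labels, HsSettings(calls_per_individual=k,
                                                    min_calls_to_include=k))
        assert rep.per_component[0].information_bits == pytest.approx(1.0, abs=1e-9)
        assert rep.per_component[1].information_bits == pytest.approx(0.0, abs=1e-9)
        assert rep.hs_all == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_individuals_highly_distinguishable(self):
        rng = np.random.default_rng(8)
        scores = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(50, 1, (10, 3))])
        rep = beecher_hs(scores, np.repeat(["a", "b"], 10),
                         HsSettings(calls_per_individual=10,
                                    min_calls_to_include=10))
        assert rep.distinguishable_all >= 2
        assert rep.hs_all > 2

    def test_shuffled_labels_yield_little_significant_information(self):
        rng = np.random.default_rng(9)
        scores = rng.standard_normal((60, 5))
        labels = np.repeat([f"i{j}" for j in range(12)], 5)
        rep = beecher_hs(scores, rng.permutation(labels),
                         HsSettings(calls_per_individual=5))
        assert rep.hs_significant <= rep.hs_all
        assert rep.hs_significant < 1.0

    def test_unbalanced_input_rejected(self):
        scores = np.zeros((7, 2))
        labels = ["a"] * 3 + ["b"] * 4
        with pytest.raises(DataError, match="balance"):
            beecher_hs(scores, labels)

    def test_oracle_equivalence_brute_force_anova(self):
        # hs_all must equal 0.5*sum(max(0, log2 F)) with every F recomputed
        # from explicit group-mean sums of squares
        rng = np.random.default_rng(10)
        for rep_i in range(10):
            n_ind, k = rng.integers(3, 8), int(rng.integers(3, 7))
            scores = rng.standard_normal((n_ind * k, 4)) \
                + np.repeat(rng.normal(0, 1.5, (n_ind, 4)), k, axis=0)
            labels = np.repeat([f"i{j}" for j in range(n_ind)], k)
            rep = beecher_hs(scores, labels,
                             HsSettings(calls_per_individual=k,
                                        min_calls_to_include=k))
            hs_brute = 0.0
            for j in range(scores.shape[1]):
                col = scores[:, j]
                grand = col.mean()
                gm = col.reshape(n_ind, k).mean(axis=1)
                ss_among = k * np.sum((gm - grand) ** 2)
                ss_within = np.sum((col.reshape(n_ind, k) - gm[:, None]) ** 2)
                f = (ss_among / (n_ind - 1)) / (ss_within / (n_ind * (k - 1)))
                hs_brute += max(0.0, 0.5 * math.log2(f))
            assert rep.hs_all == pytest.approx(hs_brute, abs=1e-9)


class TestDistinguishable:
    @pytest.mark.parametrize("hs,expected", [(5.26, 38), (1.11, 2), (0.45, 1),
                                             (0.0, 1), (1.0, 2)])
    def test_floor_of_two_to_the_hs(self, hs, expected):
        assert distinguishable_individuals(hs) == expected

    def test_negative_information_rejected(self):
        with pytest.raises(DataError):
            distinguishable_individuals(-0.1)


class TestIndividualityReport:
    def test_subsampling_balanced_and_seeded(self, default_feature_dataset):
        df = default_feature_dataset.features
        s = HsSettings(seed=3)
        sub = subsample_balanced(df, s)
        counts = sub.groupby("individual_id").size()
        assert (counts == 5).all()
        pd.testing.assert_frame_equal(sub, subsample_balanced(df, s))

    def test_context_specific_reports(self, default_feature_dataset):
        rep = individuality_report(default_feature_dataset.features,
                                   context="begging", settings=HsSettings(seed=1))
        assert rep.n_components == len(PARAMETER_COLUMNS)
        assert 0 < rep.kmo_overall < 1
        assert rep.hs_significant <= rep.hs_all + 1e-12

    def test_weaker_individual_signal_lowers_hs(self):
        strong = generate_dataset(SimConfig(seed=21), tier="feature")
        weak = generate_dataset(
            SimConfig(seed=21, sigma_individual_scale={"begging": 1.0,
                                                       "handling": 0.2}),
            tier="feature")
        s = HsSettings(seed=2)
        hs_strong = individuality_report(strong.features, "handling", s).hs_all
        hs_weak = individuality_report(weak.features, "handling", s).hs_all
        assert hs_weak < hs_strong
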