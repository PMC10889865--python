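"""Nested permuted DFA: selection arithmetic, the LDA core (cross-checked
against scikit-learn), permutation machinery and its invariances."""
import itertools

import numpy as np
import pandas as pd
import pytest

from aukcalls import PARAMETER_COLUMNS
from aukcalls.pdfa import (
    PDFASettings,
    balanced_selection,
    classify_lda,
    nested_pdfa,
)
from aukcalls.schema import DataError


def make_table(rng, n_per_ctx=4, calls=6, shift=0.0, n_feat=4):
    cols = PARAMETER_COLUMNS[:n_feat]
    rows = []
    for ctx, mu in [("begging", shift), ("handling", 0.0)]:
        for i in range(n_per_ctx):
            b = rng.normal(0, 1, n_feat)
            for j in range(calls):
                rows.append({
                    "call_id": f"{ctx}{i}_{j}", "individual_id": f"{ctx}_{i}",
                    "context": ctx,
                    **dict(zip(cols, mu + b + rng.normal(0, 1, n_feat))),
                })
    return pd.DataFrame(rows), cols


class TestBalancedSelection:
    def test_split_sizes(self):
        rng = np.random.default_rng(0)
        groups = [np.arange(5), np.arange(5, 10), np.arange(10, 15)]
        der, val = balanced_selection(groups, 2, rng)
        assert der.size == 6 and val.size == 9
        assert set(der) | set(val) == set(range(15))
        assert not set(der) & set(val)

    def test_select_all_leaves_empty_validation(self):
        rng = np.random.default_rng(0)
        der, val = balanced_selection([np.arange(3), np.arange(3, 6)], 3, rng)
        assert val.size == 0

    def test_undersized_individual_raises(self):
        with pytest.raises(DataError):
            balanced_selection([np.arange(2)], 3, np.random.default_rng(0))

    def test_seeded_reproducibility(self):
        groups = [np.arange(8), np.arange(8, 16)]
        a = balanced_selection(groups, 3, np.random.default_rng(5))
        b = balanced_selection(groups, 3, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestClassifyLDA:
    def test_perfect_separation(self):
        rng = np.random.default_rng(1)
        X0 = rng.normal(0, 1, (30, 3))
        X1 = rng.normal(20, 1, (30, 3))
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 30)
        pct, pct_cross = classify_lda(X, y, X, y)
        assert pct == 100.0 and pct_cross == 100.0

    def test_empty_validation_returns_none(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 3))
        y = np.repeat([0, 1], 10)
        _, pct_cross = classify_lda(X, y, None, None)
        assert pct_cross is None

    def test_matches_sklearn_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        Xtr = rng.normal(0, 1, (60, 5))
        ytr = (rng.random(60) < 0.35).astype(int)
        ytr[:2] = [0, 1]
        Xte = rng.normal(0, 1, (200, 5))
        sk = LinearDiscriminantAnalysis().fit(Xtr, ytr)
        from aukcalls.pdfa import _lda_train
        w, b = _lda_train(Xtr, ytr)
        mine = (Xte @ w + b > 0).astype(int)
        assert np.array_equal(mine, sk.predict(Xte))

    def test_single_class_derivation_raises(self):
        X = np.random.default_rng(4).normal(0, 1, (10, 3))
        with pytest.raises(DataError):
            classify_lda(X, np.zeros(10, dtype=int), None, None)


class TestNestedPDFA:
    def test_crossed_design_rejected(self):
        df, cols = make_table(np.random.default_rng(0))
        df.loc[df.index[-1], "individual_id"] = df["individual_id"].iloc[0]
        with pytest.raises(DataError, match="nested"):
            nested_pdfa(df, PDFASettings(n_perm=5), feature_columns=cols)

    def test_reproducible_given_seed(self):
        df, cols = make_table(np.random.default_rng(1), shift=1.0)
        s = PDFASettings(n_perm=50, k_selections_observed=5,
                         k_selections_perm=5, seed=9)
        a = nested_pdfa(df, s, feature_columns=cols)
        b = nested_pdfa(df, s, feature_columns=cols)
        assert a.as_dict() == b.as_dict()

    def test_invariant_to_individual_relabelling_and_column_order(self):
        df, cols = make_table(np.random.default_rng(2), shift=1.0)
        s = PDFASettings(n_perm=30, k_selections_observed=5,
                         k_selections_perm=5, seed=3)
        a = nested_pdfa(df, s, feature_columns=cols)
        relabel = {ind: f"z{i}" for i, ind in
                   enumerate(df["individual_id"].unique())}
        df2 = df.assign(individual_id=df["individual_id"].map(relabel))
        b = nested_pdfa(df2, s, feature_columns=cols)
        c = nested_pdfa(df, s, feature_columns=list(reversed(cols)))
        assert a.pct_classified == b.pct_classified == c.pct_classified
        assert a.p_cross_classified == b.p_cross_classified == c.p_cross_classified

    def test_separated_contexts_reach_minimum_p(self):
        # design large enough that tie permutations (reproducing the true
        # labelling by chance) are negligible among 99 draws
        df, cols = make_table(np.random.default_rng(3), n_per_ctx=10,
                              calls=4, shift=30.0)
        res = nested_pdfa(df, PDFASettings(n_sel_calls=2, n_perm=99,
                                           k_selections_observed=5,
                                           k_selections_perm=2, seed=0),
                          feature_columns=cols)
        assert res.p_cross_classified == pytest.approx(1 / 100)
        assert res.pct_cross_classified == 100.0
        assert res.relative_cross_classification == pytest.approx(
            res.pct_cross_classified / res.chance_cross_classified)

    def test_small_individual_excluded_with_log(self):
        df, cols = make_table(np.random.default_rng(4), calls=4)
        df = df[~((df.individual_id == "begging_0")
                  & (df.call_id.str.endswith(("1", "2", "3"))))]
        res = nested_pdfa(df, PDFASettings(n_sel_calls=2, n_perm=10,
                                           k_selections_observed=3,
                                           k_selections_perm=1, seed=0),
                          feature_columns=cols)
        assert res.excluded_individuals == ["begging_0"]

    def test_chance_level_matches_exhaustive_relabelling(self):
        # tiny 2+2 design: permutation chance must approach the mean over
        # all 6 count-preserving label assignments, computed by brute force
        rng = np.random.default_rng(5)
        df, cols = make_table(rng, n_per_ctx=2, calls=8, shift=0.5)
        res = nested_pdfa(df, PDFASettings(n_sel_calls=5, n_perm=400,
                                           k_selections_observed=20,
                                           k_selections_perm=20, seed=1),
                          feature_columns=cols)

        from aukcalls.pdfa import _statistic
        inds = df["individual_id"].unique()
        idx = {ind: i for i, ind in enumerate(inds)}
        call_ind = df["individual_id"].map(idx).to_numpy()
        groups = [np.flatnonzero(call_ind == i) for i in range(4)]
        X = df[cols].to_numpy(float)
        rng2 = np.random.default_rng(2)
        vals = []
        for combo in itertools.combinations(range(4), 2):
            labels = np.zeros(4, dtype=int)
            labels[list(combo)] = 1
            _, cross = _statistic(X, call_ind, groups, labels, 5, 60, rng2)
            vals.append(cross)
        assert res.chance_cross_classified == pytest.approx(np.mean(vals), abs=3.0)
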