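"""Split, SMOTE, threshold selection, tuning and scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.core import deduplicate_followups
from pvsignal.features import build_features
from pvsignal.ml import (
    balanced_auroc_at_best_threshold,
    score_pairs,
    select_threshold,
    smote_balance,
    split_gold_standard,
    tune_and_fit,
)
from pvsignal.simulate import default_scenario, generate_reports, truth_table


def _frame(n, d=3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.random((n, d)),
        index=[f"p{i:03d}" for i in range(n)],
        columns=[f"f{j}" for j in range(d)],
    )


class TestSplit:
    def test_exact_stratified_counts(self):
        X = _frame(16)
        y = np.array([True] * 8 + [False] * 8)
        split = split_gold_standard(X, y, fraction=0.75, seed=0)
        train_y = [y[int(p[1:])] for p in split.train_pairs]
        test_y = [y[int(p[1:])] for p in split.test_pairs]
        assert (len(split.train_pairs), len(split.test_pairs)) == (12, 4)
        assert sum(train_y) == 6 and sum(test_y) == 2

    def test_deterministic_per_seed(self):
        X = _frame(40)
        y = np.arange(40) % 2 == 0
        a = split_gold_standard(X, y, seed=3)
        b = split_gold_standard(X, y, seed=3)
        assert a == b

    def test_seeds_change_membership_not_ratios(self):
        X = _frame(100)
        y = np.arange(100) < 30
        a = split_gold_standard(X, y, seed=1)
        b = split_gold_standard(X, y, seed=2)
        assert a.train_pairs != b.train_pairs
        for split in (a, b):
            train_y = [y[int(p[1:])] for p in split.train_pairs]
            assert sum(train_y) == 22 or sum(train_y) == 23  # 30 * 0.75

    def test_small_class_rejected(self):
        X = _frame(5)
        y = np.array([True, False, False, False, False])
        with pytest.raises(ValueError, match="stratify"):
            split_gold_standard(X, y)


class TestSmote:
    def test_balances_counts_and_keeps_originals(self):
        X = _frame(50, seed=1)
        y = np.array([True] * 10 + [False] * 40)
        Xb, yb = smote_balance(X, y, seed=0)
        assert int(yb.sum()) == int((~yb).sum()) == 40
        pd.testing.assert_frame_equal(Xb.loc[X.index], X)  # verbatim originals

    def test_already_balanced_is_noop(self):
        X = _frame(20)
        y = np.arange(20) < 10
        Xb, yb = smote_balance(X, y)
        pd.testing.assert_frame_equal(Xb, X)
        assert (yb == y).all()

    def test_synthetic_rows_stay_in_segment(self):
        X = pd.DataFrame({"f": [0.0, 1.0] + [5.0] * 8},
                         index=[f"p{i}" for i in range(10)])
        y = np.array([True, True] + [False] * 8)
        Xb, yb = smote_balance(X, y, k_neighbors=1, seed=2)
        synth = Xb.loc[[i for i in Xb.index if "smote" in str(i)], "f"]
        assert len(synth) == 6
        assert ((synth >= 0.0) & (synth <= 1.0)).all()

    def test_convex_hull_membership_multidim(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((30, 4)),
                         index=[f"p{i}" for i in range(30)])
        y = np.array([True] * 8 + [False] * 22)
        mins = X.loc[y].min()
        maxs = X.loc[y].max()
        Xb, _ = smote_balance(X, y, seed=4)
        synth = Xb.loc[[i for i in Xb.index if "smote" in str(i)]]
        assert ((synth >= mins - 1e-12) & (synth <= maxs + 1e-12)).all().all()

    def test_tiny_minority_suggests_smaller_k(self):
        X = _frame(10)
        y = np.array([True] * 3 + [False] * 7)
        with pytest.raises(ValueError, match="reduce k"):
            smote_balance(X, y, k_neighbors=5)


def _brute_force_best(scores, labels):
    """Independent exhaustive scan used as the threshold oracle."""
    candidates = sorted(set(list(scores) + [0.0, 1.0]))
    best = (-1.0, None)
    for t in candidates:
        tp = sum(1 for s, l in zip(scores, labels) if s >= t and l)
        fn = sum(1 for s, l in zip(scores, labels) if s < t and l)
        tn = sum(1 for s, l in zip(scores, labels) if s < t and not l)
        fp = sum(1 for s, l in zip(scores, labels) if s >= t and not l)
        value = (tp / (tp + fn) + tn / (tn + fp)) / 2
        if value > best[0] + 1e-12:
            best = (value, t)
    return best


class TestSelectThreshold:
    def test_separable_scores(self):
        t = select_threshold([0.9, 0.8, 0.2, 0.1], ["Y", "Y", "N", "N"])
        assert t == pytest.approx(0.8)
        assert balanced_auroc_at_best_threshold(
            [0.9, 0.8, 0.2, 0.1], ["Y", "Y", "N", "N"]
        ) == pytest.approx(1.0)

    def test_uninformative_scores(self):
        value = balanced_auroc_at_best_threshold(
            [0.5] * 6, ["Y", "N", "Y", "N", "Y", "N"]
        )
        assert value == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            select_threshold([0.1, 0.9], ["Y", "Y"])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=50),
        st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_oracle(self, scores, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        if all(labels) or not any(labels):
            labels[0] = not labels[0]
        best_value, best_t = _brute_force_best(scores, labels)
        t = select_threshold(scores, labels)
        assert t == pytest.approx(best_t)
        assert balanced_auroc_at_best_threshold(scores, labels) == pytest.approx(best_value)


def _separable_problem(n=24, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(3.0, 0.2, size=(n // 2, 4))
    neg = rng.normal(0.0, 0.2, size=(n // 2, 4))
    X = pd.DataFrame(np.vstack([pos, neg]),
                     index=[f"p{i}" for i in range(n)])
    y = np.array([True] * (n // 2) + [False] * (n // 2))
    return X, y


class TestTuneAndFit:
    def test_separable_problem_reaches_perfect_training_auroc(self):
        X, y = _separable_problem()
        for algo in ("gbm", "rf"):
            model = tune_and_fit(algo, X, y, seed=0)
            scores = score_pairs(model, X)
            assert balanced_auroc_at_best_threshold(scores.to_numpy(), y) == 1.0
            assert 0.0 <= model.threshold <= 1.0

    def test_single_config_grid_is_returned(self):
        X, y = _separable_problem(seed=1)
        grid = [{"n_estimators": 25, "max_depth": 2, "max_features": "sqrt"}]
        model = tune_and_fit("rf", X, y, grid=grid, seed=0)
        assert model.tuned_hyperparameters == grid[0]

    def test_permuted_labels_give_chance_level_cv(self):
        # the CV metric is the max over thresholds of (sens+spec)/2, which
        # carries a small-sample upward bias; validation folds of 40 keep
        # the null mean near chance
        X, _ = _separable_problem(n=200, seed=2)
        rng = np.random.default_rng(7)
        aurocs = []
        grid = [{"n_estimators": 30, "max_depth": 2, "max_features": "sqrt"}]
        for seed in range(10):
            y = rng.permutation([True] * 100 + [False] * 100)
            model = tune_and_fit("rf", X, y, grid=grid, seed=seed)
            aurocs.append(model.cv_summary[0]["mean_cv_auroc"])
        assert 0.35 <= float(np.mean(aurocs)) <= 0.65

    def test_class_too_small_rejected(self):
        X, y = _separable_problem()
        y = np.zeros(len(y), dtype=bool)
        y[0] = True
        with pytest.raises(ValueError, match="stratified"):
            tune_and_fit("rf", X, y, seed=0)


class TestScorePairs:
    def test_deterministic_and_bounded(self):
        X, y = _separable_problem(seed=3)
        model = tune_and_fit("gbm", X, y, seed=1)
        a = score_pairs(model, X)
        b = score_pairs(model, X)
        pd.testing.assert_series_equal(a, b)
        assert ((a >= 0) & (a <= 1)).all()

    def test_all_zero_row_scores_without_crash(self):
        X, y = _separable_problem(seed=4)
        model = tune_and_fit("rf", X, y, seed=1)
        zero = pd.DataFrame([[0.0] * X.shape[1]], columns=X.columns,
                            index=["zero"])
        value = score_pairs(model, zero)["zero"]
        assert 0.0 <= value <= 1.0

    def test_schema_mismatch_lists_columns(self):
        X, y = _separable_problem(seed=5)
        model = tune_and_fit("rf", X, y, seed=1)
        bad = X.rename(columns={X.columns[0]: "rogue"})
        with pytest.raises(ValueError, match="rogue"):
            score_pairs(model, bad)

    def test_planted_pairs_outscore_null_pairs(self):
        margins = []
        for seed in range(6):
            cfg = default_scenario(seed=seed, n_reports=3000)
            rs = deduplicate_followups(generate_reports(cfg))
            truth = truth_table(cfg)
            terms = sorted(t for t in truth if t <= "ae40")
            feats = build_features(rs, terms, cfg.study_drug)
            y = np.array([truth[t] for t in terms])
            model = tune_and_fit("rf", feats, y, seed=seed)
            probs = score_pairs(model, feats)
            margins.append(probs[y].mean() - probs[~y].mean())
        assert all(m > 0 for m in margins)
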