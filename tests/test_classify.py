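"""Metrics, cross-validation, training, and classifier combination."""

import numpy as np
import pandas as pd
import pytest

from flipcheck.classify import (
    ConfusionTable,
    accuracy,
    auc,
    combine_classifiers,
    confusion_table,
    cross_validate,
    load_classifier,
    mcc,
    save_classifier,
    train_classifier,
)
from flipcheck.features import features_dataframe
from flipcheck.synthetic import generate_labeled_dataset


class TestConfusionTable:
    def test_all_correct(self):
        ct = confusion_table(["+", "-", "+"], ["+", "-", "+"], "+")
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (2, 0, 0, 1)

    def test_enumeration(self):
        ct = confusion_table(["+", "+", "-"], ["+", "-", "-"], "+")
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (1, 1, 0, 1)

    def test_positive_label_swap_transposes(self):
        truth, pred = ["+", "+", "-", "-"], ["+", "-", "+", "-"]
        a = confusion_table(truth, pred, "+")
        b = confusion_table(truth, pred, "-")
        assert (a.tp, a.fn, a.fp, a.tn) == (b.tn, b.fp, b.fn, b.tp)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_table(["+"], ["+", "-"], "+")


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((107, 14, 6, 412), 0.89),   # Random Forest tc−/tt− test table
            ((15, 106, 0, 418), 0.31),   # WH method, original threshold
            ((110, 11, 24, 394), 0.82),  # WH method, redetermined cutoff
        ],
    )
    def test_mcc_printed_tables(self, counts, expected):
        assert round(mcc(ConfusionTable(*counts)), 2) == expected

    def test_mcc_perfect(self):
        assert mcc(ConfusionTable(10, 0, 0, 20)) == pytest.approx(1.0)

    def test_mcc_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            mcc(ConfusionTable(5, 0, 5, 0))  # nobody predicted negative... margin 0

    @pytest.mark.parametrize(
        "counts,expected",
        [((107, 14, 6, 412), 0.96), ((15, 106, 0, 418), 0.80), ((110, 11, 24, 394), 0.94)],
    )
    def test_accuracy_printed_tables(self, counts, expected):
        assert round(accuracy(ConfusionTable(*counts)), 2) == expected

    def test_auc_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_auc_brute_force_oracle(self):
        """AUC equals pairwise-comparison counting (ties count half)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            scores = rng.integers(0, 10, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (len(pos) * len(neg))
            assert auc(scores, labels) == pytest.approx(expected)

    def test_auc_null_distribution(self):
        rng = np.random.default_rng(4)
        scores = rng.random(10000)
        labels = np.repeat([0, 1], 5000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_auc_one_class_error(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


@pytest.fixture(scope="module")
def toy_features():
    data = generate_labeled_dataset(
        {("X-Xnpg", "tc-"): 40, ("X-Xnpg", "tt-"): 40}, seed=21
    )
    return features_dataframe(data)


class TestCrossValidate:
    def test_fold_structure(self, toy_features):
        y = (toy_features["label"] == "tc-").to_numpy().astype(int)
        tables, summary = cross_validate(toy_features, y, k=5, repeats=1, seed=0,
                                         n_estimators=20)
        assert len(tables) == 5
        assert sum(t.total for t in tables) == len(y)

    def test_repeats(self, toy_features):
        y = (toy_features["label"] == "tc-").to_numpy().astype(int)
        tables, summary = cross_validate(toy_features, y, k=5, repeats=3, seed=0,
                                         n_estimators=20)
        assert len(tables) == 15
        assert summary["repeats"] == 3

    def test_too_many_folds(self, toy_features):
        y = (toy_features["label"] == "tc-").to_numpy().astype(int)
        with pytest.raises(ValueError):
            cross_validate(toy_features.head(3), y[:3], k=5)

    def test_permutation_null(self, toy_features):
        """Label-permuted data: mean CV MCC compatible with zero."""
        rng = np.random.default_rng(7)
        y = rng.permutation((toy_features["label"] == "tc-").to_numpy().astype(int))
        _, summary = cross_validate(toy_features, y, k=5, repeats=2, seed=1,
                                    n_estimators=50)
        assert abs(summary["mcc"]) < 0.35
        assert abs(summary["auc"] - 0.5) < 0.2


class TestTrainClassifier:
    def test_separable_training_mcc(self, toy_features):
        clf = train_classifier(toy_features, "X-Xnpg", "tc-", seed=0, tune=False)
        pred = clf.predict(toy_features[toy_features["residue_class"] == "X-Xnpg"])
        y = (toy_features["label"] == "tc-").to_numpy().astype(int)
        assert mcc(confusion_table(y, pred, 1)) == pytest.approx(1.0)

    def test_determinism(self, toy_features):
        a = train_classifier(toy_features, "X-Xnpg", "tc-", seed=3, tune=False)
        b = train_classifier(toy_features, "X-Xnpg", "tc-", seed=3, tune=False)
        assert np.array_equal(a.predict_score(toy_features), b.predict_score(toy_features))

    def test_single_label_error(self, toy_features):
        only_neg = toy_features[toy_features["label"] == "tt-"]
        with pytest.raises(ValueError):
            train_classifier(only_neg, "X-Xnpg", "tc-", seed=0)

    def test_tuning_populates_cv_summary(self, toy_features):
        from flipcheck.config import RunConfig

        cfg = RunConfig(n_trees=30, cv_repeats=1)
        clf = train_classifier(toy_features, "X-Xnpg", "tc-", cfg=cfg, seed=0, tune=True)
        assert "mcc" in clf.cv_summary and clf.cv_summary["mcc"] > 0.8

    def test_feature_importance_ranks_strain_variables(self, toy_features):
        """The variables reported as most discriminating for tc− (φ_i,
        C–N–Cα, Cα–Cα, O–C–N) should appear among the top 8 importances."""
        clf = train_classifier(toy_features, "X-Xnpg", "tc-", seed=0, tune=False)
        top8 = set(clf.feature_importances().head(8).index)
        named = {"phi3", "ang_c2_n3_ca3", "ca_ca", "ang_o2_c2_n3"}
        assert len(top8 & named) >= 3

    def test_save_load_roundtrip(self, toy_features, tmp_path):
        clf = train_classifier(toy_features, "X-Xnpg", "tc-", seed=0, tune=False)
        save_classifier(clf, tmp_path / "m.joblib")
        loaded = load_classifier(tmp_path / "m.joblib")
        assert loaded.flip_type == "tc-"
        assert np.array_equal(
            clf.predict_score(toy_features), loaded.predict_score(toy_features)
        )


class TestCombine:
    def _fake(self, flip_type, score):
        class Fake:
            residue_class = "X-Xnpg"

            def __init__(self):
                self.flip_type = flip_type

            def predict_score(self, df):
                return np.full(len(df), score)

        return Fake()

    def test_none_fire(self):
        v = combine_classifiers([self._fake("tc-", 0.1), self._fake("tt+", 0.2)])
        out = v(pd.DataFrame({"x": [0]}))
        assert out[0][0] == "correct"

    def test_single_fires(self):
        v = combine_classifiers([self._fake("tc-", 0.2), self._fake("tc+", 0.9)])
        assert v(pd.DataFrame({"x": [0]}))[0][0] == "tc+"

    def test_exact_tie_prefers_ttplus(self):
        v = combine_classifiers([self._fake("tc+", 0.8), self._fake("tt+", 0.8)])
        assert v(pd.DataFrame({"x": [0]}))[0][0] == "tt+"

    def test_empty_error(self):
        with pytest.raises(ValueError):
            combine_classifiers([])

    def test_mixed_class_error(self):
        a = self._fake("tc-", 0.5)
        b = self._fake("tt+", 0.5)
        b.residue_class = "X-Pro"
        with pytest.raises(ValueError):
            combine_classifiers([a, b])
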