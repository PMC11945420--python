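"""Split, learners, ranking, metrics, cutoff normalization, applicability domain."""

import math

import numpy as np
import pandas as pd
import pytest

import mronjpred as mp
from mronjpred import modeling
from mronjpred.modeling import ConfusionMatrix

from conftest import random_confusion_matrices


def metric_oracle(tp, fp, fn, tn):
    """Independent direct-formula evaluation of the nine metrics."""
    n = tp + fp + fn + tn
    div = lambda a, b: a / b if b else 0.0
    recall = div(tp, tp + fn)
    specificity = div(tn, tn + fp)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "accuracy": (tp + tn) / n,
        "precision": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
        "recall": recall,
        "specificity": specificity,
        "balanced_accuracy": (recall + specificity) / 2,
        "f1": div(2 * tp, 2 * tp + fp + fn),
        "mcc": div(tp * tn - fp * fn, mcc_den) if mcc_den else 0.0,
    }


def auroc_oracle(scores, labels):
    """Exhaustive pairwise comparison with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def _toy_matrix(n_pos, n_neg, separation=3.0, n_noise=3, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "drug_name": [f"d{i}" for i in range(n_pos + n_neg)],
        "label": ["positive"] * n_pos + ["negative"] * n_neg,
        "signal": np.concatenate([rng.normal(separation, 1, n_pos),
                                  rng.normal(0, 1, n_neg)])})
    for j in range(n_noise):
        frame[f"noise_{j}"] = rng.normal(size=n_pos + n_neg)
    return frame


class TestSplit:
    def test_curated_table_splits_to_15_27_validation(self):
        matrix = _toy_matrix(60, 108)
        train, val = mp.split_train_validation(matrix, seed=0)
        counts = val["label"].value_counts()
        assert counts["positive"] == 15 and counts["negative"] == 27
        assert len(val) == 42 and len(train) == 126

    def test_minimal_classes_split_one_each(self):
        train, val = mp.split_train_validation(_toy_matrix(4, 4), seed=1)
        assert val["label"].value_counts().tolist() == [1, 1]

    def test_same_seed_same_split(self):
        matrix = _toy_matrix(20, 30)
        a = mp.split_train_validation(matrix, seed=5)[1]
        b = mp.split_train_validation(matrix, seed=5)[1]
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_class_is_error(self):
        with pytest.raises(mp.DataError):
            mp.split_train_validation(_toy_matrix(3, 10))


class TestFitModel:
    def test_separable_classes_give_perfect_training_auroc(self):
        matrix = _toy_matrix(30, 30, separation=10.0)
        feats = ["signal"] + [c for c in matrix if c.startswith("noise")]
        rf = mp.fit_model(matrix[feats], matrix["label"],
                          modeling.ModelConfig(algorithm="random_forest"))
        _, auroc = mp.roc_curve(mp.predict_scores(rf, matrix[feats]),
                                matrix["label"])
        assert auroc == 1.0

    def test_label_permutation_gives_chance_level_auroc(self):
        aurocs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            matrix = _toy_matrix(60, 60, separation=2.0, seed=seed)
            matrix["label"] = rng.permutation(matrix["label"].to_numpy())
            feats = ["signal"]
            train, val = mp.split_train_validation(matrix, seed=seed)
            model = mp.fit_model(
                train[feats], train["label"],
                modeling.ModelConfig(algorithm="neural_network", seed=seed))
            _, auroc = mp.roc_curve(mp.predict_scores(model, val[feats]),
                                    val["label"])
            aurocs.append(auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.15

    def test_single_overlapping_feature_beats_chance(self):
        """One feature at the polar-surface-area class parameters separates
        the classes modestly but reliably at n=500/class."""
        cfg = mp.DescriptorSimConfig(
            n_positive=500, n_negative=500, n_noise_features=0,
            n_collinear_duplicates=0, n_missing_columns=0, seed=13)
        sim = mp.generate_descriptor_matrix(cfg)
        train, val = mp.split_train_validation(sim.matrix, seed=13)
        model = mp.fit_model(train[["ASA_P"]], train["label"],
                             modeling.ModelConfig(seed=13))
        _, auroc = mp.roc_curve(mp.predict_scores(model, val[["ASA_P"]]),
                                val["label"])
        assert auroc > 0.55

    def test_non_numeric_feature_rejected(self):
        matrix = _toy_matrix(5, 5)
        matrix["bad"] = "text"
        with pytest.raises(mp.DataError):
            mp.fit_model(matrix[["signal", "bad"]], matrix["label"],
                         modeling.ModelConfig())

    def test_gradient_boosting_respects_tree_size(self):
        matrix = _toy_matrix(30, 30)
        feats = ["signal", "noise_0"]
        gb = mp.fit_model(matrix[feats], matrix["label"],
                          modeling.ModelConfig(algorithm="gradient_boosting"))
        assert len(gb.estimators_) == 48
        assert all(t[0].tree_.n_leaves <= 3 for t in gb.estimators_)


class TestImportanceRanking:
    def test_informative_feature_ranked_first(self):
        matrix = _toy_matrix(50, 50, separation=3.0, n_noise=8, seed=2)
        feats = [c for c in matrix if c not in ("drug_name", "label")]
        rf = mp.fit_model(matrix[feats], matrix["label"],
                          modeling.ModelConfig(algorithm="random_forest",
                                               seed=2))
        ranking = mp.rf_importance_ranking(rf, feats)
        assert ranking.loc[0, "descriptor"] == "signal"
        assert ranking.loc[0, "n_splits"] > 0
        assert ranking["importance"].is_monotonic_decreasing

    def test_unfitted_model_is_error(self):
        from sklearn.ensemble import RandomForestClassifier
        with pytest.raises(mp.DataError):
            mp.rf_importance_ranking(RandomForestClassifier(), ["a"])


class TestRocAndCutoff:
    def test_perfect_separation_auroc_one(self):
        _, auroc = mp.roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auroc == 1.0

    def test_identical_scores_auroc_half(self):
        _, auroc = mp.roc_curve([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auroc == 0.5

    def test_pairwise_count_example(self):
        _, auroc = mp.roc_curve([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert auroc == 0.75

    def test_auroc_matches_pairwise_oracle_on_random_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(4, 30))
            labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            _, auroc = mp.roc_curve(scores, labels)
            assert auroc == pytest.approx(auroc_oracle(scores, labels),
                                          abs=1e-12)

    def test_single_class_is_error(self):
        with pytest.raises(mp.DataError):
            mp.roc_curve([0.1, 0.9], [1, 1])

    def test_youden_cutoff_maximizes_j(self):
        scores = [0.9, 0.8, 0.45, 0.4, 0.3, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        cut = mp.youden_cutoff(scores, labels)
        assert cut == pytest.approx(0.45)

    @pytest.mark.parametrize("cutoff", [0.291, 0.5, 0.8])
    def test_normalization_puts_cutoff_at_half(self, cutoff):
        assert mp.normalize_scores([cutoff], cutoff)[0] == pytest.approx(0.5)

    def test_cutoff_half_is_identity(self):
        s = np.linspace(0, 1, 11)
        np.testing.assert_allclose(mp.normalize_scores(s, 0.5), s)

    def test_normalization_preserves_auroc_bit_identically(self):
        rng = np.random.default_rng(6)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        _, before = mp.roc_curve(scores, labels)
        for c in (0.1, 0.291, 0.73):
            _, after = mp.roc_curve(mp.normalize_scores(scores, c), labels)
            assert after == before


class TestMetricSuite:
    def test_matches_direct_formula_oracle_on_random_matrices(self):
        for tp, fp, fn, tn in random_confusion_matrices(1000, seed=9):
            if tp + fp + fn + tn == 0:
                continue
            got = mp.compute_metrics(ConfusionMatrix(tp, fp, fn, tn)).as_dict()
            want = metric_oracle(tp, fp, fn, tn)
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=1e-12), key

    def test_degenerate_all_negative_convention(self):
        m = mp.compute_metrics(ConfusionMatrix(0, 0, 0, 10))
        assert m.precision == 0.0 and m.recall == 0.0
        assert m.specificity == 1.0
        assert {"precision", "recall", "f1", "mcc"} <= set(
            m.zero_division_flags)

    def test_empty_matrix_is_error(self):
        with pytest.raises(mp.DataError):
            mp.compute_metrics(ConfusionMatrix(0, 0, 0, 0))


@pytest.fixture(scope="module")
def sweep_setup():
    matrix = _toy_matrix(40, 60, separation=2.5, n_noise=6, seed=3)
    feats = [c for c in matrix if c not in ("drug_name", "label")]
    train, val = mp.split_train_validation(matrix, seed=3)
    rf = mp.fit_model(train[feats], train["label"],
                      modeling.ModelConfig(algorithm="random_forest", seed=3))
    ranking = mp.rf_importance_ranking(rf, feats)
    return train, val, ranking, feats


class TestTopKSweep:
    def test_one_row_per_k(self, sweep_setup):
        train, val, ranking, _ = sweep_setup
        sweep = mp.top_k_model_sweep(train, val, ranking,
                                     modeling.ModelConfig(seed=3),
                                     k_list=[2, 3, 5])
        assert sweep["n_descriptors"].tolist() == [2, 3, 5]
        assert {"validation_auroc", "cutoff", "mcc"} <= set(sweep.columns)

    def test_k_equal_to_all_features_matches_unrestricted_model(self, sweep_setup):
        train, val, ranking, feats = sweep_setup
        cfg = modeling.ModelConfig(seed=3)
        sweep = mp.top_k_model_sweep(train, val, ranking, cfg,
                                     k_list=[len(feats)])
        full = mp.fit_model(train[ranking["descriptor"].tolist()],
                            train["label"], cfg)
        ev = mp.evaluate_model(full, train, val, ranking["descriptor"].tolist())
        assert sweep.loc[0, "validation_auroc"] == pytest.approx(
            ev["validation_auroc"])

    def test_k_beyond_available_features_is_error(self, sweep_setup):
        train, val, ranking, feats = sweep_setup
        with pytest.raises(mp.DataError):
            mp.top_k_model_sweep(train, val, ranking,
                                 modeling.ModelConfig(seed=3),
                                 k_list=[len(feats) + 1])


class TestApplicabilityDomain:
    def test_no_exclusion_band_keeps_everything_off_cutoff(self):
        rng = np.random.default_rng(10)
        scores = rng.random(42) * 0.98 + 0.01
        labels = rng.integers(0, 2, 42)
        labels[:2] = [0, 1]
        ad = mp.applicability_domain(scores, labels, band=0.0)
        assert ad.retained_drugs == 42

    def test_retained_count_non_increasing_in_band(self):
        rng = np.random.default_rng(11)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        retained = [mp.applicability_domain(scores, labels, b).retained_drugs
                    for b in (0.0, 0.1, 0.2, 0.3)]
        assert retained == sorted(retained, reverse=True)

    def test_all_excluded_is_error(self):
        with pytest.raises(mp.DataError):
            mp.applicability_domain([0.5, 0.51], [1, 0], band=0.4)


class TestPerClassAccuracy:
    def test_accuracy_counts(self):
        atc = {"a": "M05BA03", "b": "M05BA04", "c": "L01EX01", "d": None}
        out = mp.per_class_accuracy(
            ["a", "b", "c", "d"], [1, 1, 0, 1], [1, 0, 0, 1], atc)
        m05b = out.set_index("atc_class").loc["M05B"]
        assert m05b["n_drugs"] == 2 and m05b["accuracy"] == 0.5
        assert "unmapped" in out["atc_class"].tolist()

    def test_all_correct_class_scores_one(self):
        atc = {f"d{i}": "M05BA01" for i in range(6)}
        out = mp.per_class_accuracy([f"d{i}" for i in range(6)],
                                    [1] * 6, [1] * 6, atc)
        assert out.loc[0, "accuracy"] == 1.0
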