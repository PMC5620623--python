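"""PUK kernel, SVM training, LOSO cross-validation, accuracy arithmetic,
and channel-subset ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drowsefuse import (
    ConfusionMatrix2x2,
    EmptyDataError,
    KernelParams,
    ParameterError,
    accuracy,
    accuracy_display,
    channel_reduction,
    fit_svm,
    instance_matrix,
    loso_cv,
    puk_gram,
    puk_kernel,
)


def _clouds(n=40, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n // 2, 2)),
                   rng.normal(sep, 1, (n // 2, 2))])
    y = np.array(["alert"] * (n // 2) + ["drowsy"] * (n // 2))
    return X, y


def _instances(n_subjects=6, effect=2.0, seed=0, n_features=3):
    """Minute-instance matrix with a subject-structured class effect."""
    rng = np.random.default_rng(seed)
    X, y, groups = [], [], []
    for s in range(n_subjects):
        base = rng.normal(0, 1, n_features)
        for state, shift in (("alert", 0.0), ("drowsy", effect)):
            for _ in range(5):
                X.append(base + rng.normal(0, 0.5, n_features)
                         + shift * np.ones(n_features))
                y.append(state)
                groups.append(f"S{s}")
    return np.array(X), np.array(y), np.array(groups)


class TestPukKernel:
    def test_self_similarity_is_one(self):
        x = np.array([0.3, -1.2, 5.0])
        assert puk_kernel(x, x) == pytest.approx(1.0)

    def test_hand_evaluated_value(self):
        # omega = sigma = 1, ||x - y|| = 0.5 -> 1 / (1 + 4 * 0.25) = 0.5
        assert puk_kernel(np.array([0.0]), np.array([0.5])) \
            == pytest.approx(0.5)

    @given(st.floats(min_value=0.2, max_value=5),
           st.floats(min_value=0.2, max_value=5))
    def test_strictly_decreasing_in_distance(self, omega, sigma):
        params = KernelParams(omega=omega, sigma=sigma)
        k_near = puk_kernel(np.array([0.0]), np.array([0.5]), params)
        k_far = puk_kernel(np.array([0.0]), np.array([1.0]), params)
        assert 0 < k_far < k_near <= 1

    def test_gram_symmetric_positive_semidefinite(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 4))
        G = puk_gram(X, X)
        np.testing.assert_allclose(G, G.T, atol=1e-12)
        assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ParameterError):
            puk_kernel(np.array([np.nan]), np.array([0.0]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            KernelParams(omega=0.0)


class TestFitSvm:
    def test_separable_clouds_perfect_training_accuracy(self):
        X, y = _clouds()
        model = fit_svm(X, y)
        assert (model.predict(X) == y).all()

    def test_duplicate_point_gets_same_prediction(self):
        X, y = _clouds()
        X2 = np.vstack([X, X[3]])
        y2 = np.append(y, y[3])
        model = fit_svm(X2, y2)
        preds = model.predict(np.vstack([X[3], X[3]]))
        assert preds[0] == preds[1]

    def test_single_class_fold_rejected(self):
        X, _ = _clouds()
        with pytest.raises(ParameterError, match="single-class"):
            fit_svm(X, np.array(["alert"] * len(X)))

    def test_scaling_uses_training_statistics_only(self):
        X, y = _clouds()
        model = fit_svm(X, y)
        # an out-of-range test point must still be classifiable
        pred = model.predict(np.array([[100.0, 100.0]]))
        assert pred[0] in ("alert", "drowsy")


class TestLoso:
    def test_pooled_totals_and_row_sums(self):
        X, y, g = _instances(n_subjects=6)
        rep = loso_cv(X, y, g)
        cm = rep.confusion
        assert cm.total == 60
        assert cm.tp + cm.fn == 30
        assert cm.fp + cm.tn == 30
        assert len(rep.fold_accuracies) == 6

    def test_two_subjects_minimal_case(self):
        X, y, g = _instances(n_subjects=2)
        rep = loso_cv(X, y, g)
        assert rep.confusion.total == 20

    def test_single_subject_rejected(self):
        X, y, g = _instances(n_subjects=1)
        with pytest.raises(ParameterError, match=">= 2 subjects"):
            loso_cv(X, y, g)

    def test_no_leakage_from_held_out_subject(self):
        X, y, g = _instances(n_subjects=5, seed=3)
        rep = loso_cv(X, y, g)
        held = "S0"
        train = g != held
        model = fit_svm(X[train], y[train])
        manual = float(100 * np.mean(model.predict(X[g == held])
                                     == y[g == held]))
        assert rep.fold_accuracies[held] == pytest.approx(manual)

    def test_permuted_labels_near_chance(self):
        X, y, g = _instances(n_subjects=8, effect=2.0, seed=4)
        rng = np.random.default_rng(5)
        accs = []
        for _ in range(20):
            accs.append(loso_cv(X, rng.permutation(y), g)
                        .accuracy_pct)
        assert 35.0 <= float(np.mean(accs)) <= 65.0


class TestAccuracy:
    @pytest.mark.parametrize("rows,pct,display", [
        ([[39, 16], [17, 38]], 7700 / 110, "70.00"),
        ([[43, 12], [14, 41]], 8400 / 110, "76.36"),
        ([[46, 9], [12, 43]], 8900 / 110, "80.90"),
    ])
    def test_published_style_confusion_tables(self, rows, pct, display):
        cm = ConfusionMatrix2x2.from_rows(rows)
        assert cm.total == 110
        assert accuracy(cm) == pytest.approx(pct, abs=1e-9)
        assert accuracy_display(cm) == display

    def test_exact_rational_before_rounding(self):
        cm = ConfusionMatrix2x2(1, 0, 0, 2)
        assert accuracy(cm) == pytest.approx(100.0, abs=1e-12)
        assert accuracy_display(ConfusionMatrix2x2(1, 1, 1, 0)) == "33.33"

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            accuracy(ConfusionMatrix2x2(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionMatrix2x2(-1, 0, 0, 1)


def _feature_table(n_subjects=6, seed=0, o2_effect=2.0):
    """Tidy table where only O2 (and ECG weakly) carries the effect."""
    rng = np.random.default_rng(seed)
    rows = []
    channels = [("O2", "p_rel_alpha"), ("C3", "p_rel_alpha"),
                ("P7", "energy"), ("ECG", "lf_hf_ratio")]
    for s in range(n_subjects):
        base = {c: rng.normal(0, 1) for c in channels}
        for state in ("alert", "drowsy"):
            for minute in range(5):
                for c in channels:
                    val = base[c] + rng.normal(0, 0.4)
                    if state == "drowsy":
                        if c[0] == "O2":
                            val += o2_effect
                        if c[0] == "ECG":
                            val -= 0.8
                    rows.append({
                        "subject_id": f"S{s}", "state": state,
                        "minute": minute, "channel": c[0],
                        "feature": c[1], "value": val,
                    })
    return pd.DataFrame(rows)


class TestChannelReduction:
    pairs = [("O2", "p_rel_alpha"), ("ECG", "lf_hf_ratio")]

    def test_effect_carrying_channel_ranks_first(self):
        table = _feature_table(seed=1)
        ranking = channel_reduction(
            table, self.pairs, ["C3", "P4", "P7", "O1", "O2"],
            max_subset_size=1)
        assert len(ranking) == 5  # five singleton rows
        assert ranking.iloc[0]["channels"] == "O2"
        assert not ranking.iloc[0]["no_eeg_features"]

    def test_channel_without_features_flagged_ecg_only(self):
        table = _feature_table(seed=2)
        ranking = channel_reduction(table, self.pairs, ["C3"],
                                    max_subset_size=1)
        assert ranking.iloc[0]["no_eeg_features"]
        assert ranking.iloc[0]["ecg_included"]

    def test_runs_as_eeg_only_without_ecg_features(self):
        table = _feature_table(seed=3)
        ranking = channel_reduction(
            table, [("O2", "p_rel_alpha")], ["O2"], max_subset_size=1)
        assert len(ranking) == 1
        assert not ranking.iloc[0]["ecg_included"]

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ParameterError):
            channel_reduction(_feature_table(), self.pairs, [])

    def test_instance_matrix_shape(self):
        table = _feature_table(n_subjects=4, seed=4)
        X, y, subjects, cols = instance_matrix(table, self.pairs)
        assert X.shape == (4 * 2 * 5, 2)
        assert set(y) == {"alert", "drowsy"}
        assert len(set(subjects)) == 4

    def test_no_selected_features_rejected(self):
        with pytest.raises(EmptyDataError):
            instance_matrix(_feature_table(), [])
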