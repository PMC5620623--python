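"""Subject-state pairing, normality gating, paired t-tests, and the
selection report."""

import math

import numpy as np
import pandas as pd
import pytest

from drowsefuse import (
    DegenerateInputError,
    ParameterError,
    ks_normality,
    paired_t,
    select,
    subject_state_means,
)


def _tidy(n_subjects=6, effects=None, sigma=1.0, seed=0, n_features=4):
    """Tiny tidy feature table: ``effects`` maps (channel, feature) to a
    drowsy-minus-alert shift."""
    effects = effects or {}
    rng = np.random.default_rng(seed)
    rows = []
    pairs = [(f"CH{i}", f"f{j}") for i in range(n_features) for j in (0, 1)]
    for s in range(n_subjects):
        base = {p: rng.normal(0, 2) for p in pairs}
        for state in ("alert", "drowsy"):
            for minute in range(5):
                for p in pairs:
                    val = base[p] + rng.normal(0, sigma)
                    if state == "drowsy":
                        val += effects.get(p, 0.0)
                    rows.append({
                        "subject_id": f"S{s}", "state": state,
                        "minute": minute, "channel": p[0],
                        "feature": p[1], "value": val,
                    })
    return pd.DataFrame(rows)


class TestSubjectStateMeans:
    def test_one_paired_observation_per_subject(self):
        means = subject_state_means(_tidy(n_subjects=11))
        per = means.groupby(["channel", "feature"]).size()
        assert (per == 22).all()  # 11 subjects x 2 states

    def test_missing_minutes_averaged_over_remainder(self):
        tidy = _tidy(n_subjects=3)
        tidy = tidy[~((tidy.subject_id == "S0") & (tidy.minute == 4))]
        means = subject_state_means(tidy)
        assert means[means.subject_id == "S0"].notna().all().all()

    def test_subject_missing_a_state_excluded_with_warning(self):
        tidy = _tidy(n_subjects=3)
        tidy = tidy[~((tidy.subject_id == "S1") & (tidy.state == "drowsy"))]
        with pytest.warns(UserWarning, match="S1"):
            means = subject_state_means(tidy)
        assert "S1" not in set(means.subject_id)

    def test_single_subject_forbidden_downstream(self):
        with pytest.raises(DegenerateInputError, match="df = 0"):
            select(_tidy(n_subjects=1))


class TestKSNormality:
    def test_normal_draws_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(11)
            _, p = ks_normality(x, seed=1)
            hits += p > 0.05
        assert hits >= 90

    def test_gross_outlier_rejected(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.choice([-10.0, 10.0], size=10), [1000.0]])
        _, p = ks_normality(x, seed=1)
        assert p < 0.05

    def test_identical_values_rejected_by_convention(self):
        _, p = ks_normality(np.full(11, 2.5))
        assert p == 0.0

    def test_statistic_matches_independent_implementation(self):
        from statsmodels.stats.diagnostic import lilliefors
        x = np.random.default_rng(9).standard_normal(11)
        d, _ = ks_normality(x)
        d_ref, _ = lilliefors(x, dist="norm")
        assert d == pytest.approx(d_ref, abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ParameterError):
            ks_normality(np.array([1.0, 2.0]))


class TestPairedT:
    def test_hand_computed_example(self):
        # d = [1, 0, 1, 1]: mean .75, sd .5 -> t = 3.0 on df = 3
        res = paired_t([1, 2, 3, 4], [2, 2, 4, 5])
        assert res["t"] == pytest.approx(3.0)
        assert res["df"] == 3
        # closed-form Student-t (df=3) survival function as the oracle
        x = 3.0
        u = x / math.sqrt(3)
        F = 0.5 + (math.atan(u) + u / (1 + u ** 2)) / math.pi
        assert res["p"] == pytest.approx(2 * (1 - F), abs=1e-12)
        assert res["p"] == pytest.approx(0.0577, abs=5e-4)

    def test_identical_groups_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_swapping_groups_flips_sign_keeps_p(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=8), rng.normal(size=8)
        r1, r2 = paired_t(a, b), paired_t(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ParameterError):
            paired_t([1, 2], [1, 2, 3])


class TestSelect:
    def test_injected_effect_flagged_with_positive_direction(self):
        effects = {("CH0", "f0"): 3.0, ("CH2", "f1"): 3.0}
        report = select(_tidy(n_subjects=11, effects=effects, seed=5))
        sig = set(map(tuple, report.significant[["channel", "feature"]]
                      .itertuples(index=False, name=None)))
        assert {("CH0", "f0"), ("CH2", "f1")} <= sig
        flagged = report.significant.set_index(["channel", "feature"])
        assert flagged.loc[("CH0", "f0"), "direction"] == 1

    def test_alpha_zero_selects_nothing(self):
        report = select(_tidy(seed=6), alpha=0.0)
        assert report.significant.empty

    def test_significant_implies_normality_and_threshold(self):
        report = select(_tidy(n_subjects=11,
                              effects={("CH1", "f0"): 2.0}, seed=7))
        sig = report.significant
        assert (sig["p_adjusted"] < report.alpha).all()
        assert sig["normality_ok"].all()

    def test_bh_correction_is_no_looser(self):
        tidy = _tidy(n_subjects=11, effects={("CH0", "f0"): 2.0}, seed=8)
        none = select(tidy, correction="none")
        bh = select(tidy, correction="bh")
        assert set(map(tuple, bh.significant[["channel", "feature"]]
                       .itertuples(index=False, name=None))) <= \
            set(map(tuple, none.significant[["channel", "feature"]]
                    .itertuples(index=False, name=None)))

    def test_degenerate_feature_reported_not_selected(self):
        tidy = _tidy(n_subjects=5, seed=9)
        const = tidy[(tidy.channel == "CH0") & (tidy.feature == "f0")].index
        tidy.loc[const, "value"] = 1.0
        report = select(tidy)
        row = report.table[(report.table.channel == "CH0")
                           & (report.table.feature == "f0")].iloc[0]
        assert not row["significant"]
        assert "degenerate" in row["note"]

    def test_report_is_pure_function_of_inputs_and_seed(self):
        tidy = _tidy(n_subjects=6, seed=10)
        r1 = select(tidy, ks_seed=3)
        r2 = select(tidy, ks_seed=3)
        pd.testing.assert_frame_equal(r1.table, r2.table)
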