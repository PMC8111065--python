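"""Contingency arithmetic, ROC/AUC oracles, odds ratios, univariate screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfomics.cohort import reference_fixtures
from csfomics.diagnostics import (
    ContingencyTable,
    best_threshold,
    binary_marker_auc,
    bonferroni,
    confusion_stats,
    diagnostic_or,
    roc_curve,
    univariate_screen,
)
from csfomics.errors import DegenerateLabelError, DomainError


def mann_whitney_auc(scores, labels):
    """Brute-force AUC: pairwise win fraction with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestContingency:
    def test_ocgb_fixture_stats(self):
        t = reference_fixtures()["ocgb"]
        cs = confusion_stats(t)
        assert cs.sens == pytest.approx(1.00)
        assert cs.spec == pytest.approx(0.3125)
        assert cs.acc == pytest.approx(0.5926, abs=1e-4)
        assert cs.ppv == pytest.approx(0.50)
        assert cs.npv == pytest.approx(1.00)

    def test_mmp13_fixture_stats(self):
        cs = confusion_stats(ContingencyTable(9, 13, 1, 31))
        assert cs.acc == pytest.approx(0.7407, abs=1e-4)
        assert cs.ppv == pytest.approx(0.90)
        assert cs.npv == pytest.approx(0.7045, abs=1e-4)

    def test_perfect_classifier(self):
        cs = confusion_stats(ContingencyTable(7, 0, 0, 9))
        assert (cs.sens, cs.spec, cs.acc, cs.ppv, cs.npv) == (1, 1, 1, 1, 1)

    def test_undefined_ratio_flagged_not_zeroed(self):
        cs = confusion_stats(ContingencyTable(0, 0, 3, 4))
        assert np.isnan(cs.sens)
        assert "sens" in cs.undefined

    def test_accuracy_is_prevalence_weighted_mix(self):
        t = ContingencyTable(9, 13, 1, 31)
        cs = confusion_stats(t)
        w_pos = (t.tp + t.fn) / t.total
        assert cs.acc == pytest.approx(w_pos * cs.sens + (1 - w_pos) * cs.spec)

    def test_all_zero_table_rejected(self):
        with pytest.raises(DomainError):
            ContingencyTable(0, 0, 0, 0)


class TestDiagnosticOR:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((9, 13, 1, 31), 21.46),    # all cells positive: plain ratio
            ((22, 0, 22, 10), 21.0),    # empty cell: +0.5 everywhere
            ((5, 5, 5, 5), 1.0),
            ((11, 11, 2, 30), 15.0),
            ((11, 11, 3, 29), 9.67),
        ],
    )
    def test_known_tables(self, table, expected):
        assert diagnostic_or(ContingencyTable(*table)) == pytest.approx(
            expected, abs=0.005
        )

    def test_label_swap_invariance_and_reciprocal(self):
        t = ContingencyTable(9, 13, 1, 31)
        swapped = ContingencyTable(31, 1, 13, 9)     # both margins flipped
        one_margin = ContingencyTable(13, 9, 31, 1)  # marker call flipped
        assert diagnostic_or(t) == pytest.approx(diagnostic_or(swapped))
        assert diagnostic_or(one_margin) == pytest.approx(1.0 / diagnostic_or(t))


class TestBinaryMarkerAuc:
    def test_ocgb_value(self):
        auc = binary_marker_auc(reference_fixtures()["ocgb"])
        assert auc == pytest.approx(0.65625)
        assert round(auc, 2) == 0.66

    def test_chance_marker(self):
        assert binary_marker_auc(ContingencyTable(5, 5, 5, 5)) == pytest.approx(0.5)

    def test_equals_roc_on_binary_scores(self):
        t = ContingencyTable(16, 6, 13, 19)
        scores = np.array([1.0] * t.tp + [0.0] * t.fn + [1.0] * t.fp + [0.0] * t.tn)
        labels = np.array([1] * (t.tp + t.fn) + [0] * (t.fp + t.tn))
        assert roc_curve(scores, labels).auc == pytest.approx(binary_marker_auc(t))


class TestRoc:
    def test_constant_scores_auc_half(self):
        r = roc_curve(np.ones(10), np.array([1] * 5 + [0] * 5))
        assert r.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        scores = np.r_[np.arange(5) + 10.0, np.arange(5)]
        labels = np.array([1] * 5 + [0] * 5)
        r = roc_curve(scores, labels)
        assert r.auc == pytest.approx(1.0)
        assert r.ci95[1] == pytest.approx(1.0)
        assert r.acc == pytest.approx(1.0)

    def test_hand_listed_pairs_match_pair_count_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2, 0.7, 0.35]
        labels = [0, 1, 0, 1, 0, 0, 1, 1]
        r = roc_curve(np.array(scores), np.array(labels))
        assert r.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=30).filter(
            lambda v: len(v) >= 2
        ),
        st.randoms(use_true_random=False),
    )
    def test_auc_equals_mann_whitney_on_random_instances(self, raw, rnd):
        labels = [1, 0] + [rnd.randint(0, 1) for _ in raw[2:]]
        scores = [float(v) + 0.5 * rnd.randint(0, 1) for v in raw]
        r = roc_curve(np.array(scores), np.array(labels))
        expected = mann_whitney_auc(scores, labels)
        expected = max(expected, 1 - expected)  # auto-orientation
        assert r.auc == pytest.approx(expected, abs=1e-12)

    def test_auc_inside_ci(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40) + np.r_[np.ones(20), np.zeros(20)]
        labels = np.array([1] * 20 + [0] * 20)
        r = roc_curve(scores, labels)
        assert r.ci95[0] <= r.auc <= r.ci95[1]
        assert 0 < r.p_auc <= 1

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            roc_curve(np.arange(4.0), np.ones(4, dtype=int))


class TestBestThreshold:
    @staticmethod
    def exhaustive_best_accuracy(scores, labels):
        scores = np.asarray(scores)
        labels = np.asarray(labels)
        cands = np.unique(scores)
        cands = np.r_[cands[0] - 1, (cands[:-1] + cands[1:]) / 2, cands[-1] + 1]
        return max(((scores >= thr).astype(int) == labels).mean() for thr in cands)

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(4, 25)
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = rng.choice(np.arange(6.0), size=n)
            thr = best_threshold(scores, labels)
            acc = (((scores >= thr).astype(int) == labels)).mean()
            assert acc == pytest.approx(self.exhaustive_best_accuracy(scores, labels))

    def test_shift_equivariance(self):
        scores = np.array([0.2, 0.9, 0.4, 1.4, 1.1, 0.1])
        labels = np.array([0, 1, 0, 1, 1, 0])
        t0 = best_threshold(scores, labels)
        t1 = best_threshold(scores + 5.0, labels)
        assert t1 == pytest.approx(t0 + 5.0)

    def test_separated_classes_unique_midpoint(self):
        scores = np.array([1.0, 2.0, 10.0, 11.0])
        labels = np.array([0, 0, 1, 1])
        assert best_threshold(scores, labels) == pytest.approx(6.0)


class TestUnivariateScreen:
    def test_ocgb_contingency_significant(self):
        # 22/22 converters positive vs 22/32 non-converters; Pearson
        # chi-square without continuity correction gives p = 0.0037
        ocgb = np.array([1] * 22 + [1] * 22 + [0] * 10)
        labels = np.array([1] * 22 + [0] * 32)
        out = univariate_screen(
            pd.DataFrame({"ocgb": ocgb}), labels, {"ocgb": "categorical"}
        )
        assert out.loc["ocgb", "p_raw"] == pytest.approx(0.00367, abs=0.0005)
        assert out.loc["ocgb", "p_raw"] < 0.005

    def test_identical_groups_t_stat_zero(self):
        x = np.r_[np.arange(10.0), np.arange(10.0)]
        labels = np.array([1] * 10 + [0] * 10)
        out = univariate_screen(pd.DataFrame({"v": x}), labels)
        assert out.loc["v", "statistic"] == pytest.approx(0.0)
        assert out.loc["v", "p_raw"] == pytest.approx(1.0)

    def test_bonferroni_multiplier_counts_tested_features(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        labels = np.array([1] * 10 + [0] * 10)
        out = univariate_screen(X, labels)
        assert np.allclose(
            out["p_bonferroni"], np.minimum(1.0, out["p_raw"] * 5)
        )

    def test_single_level_categorical_skipped(self):
        X = pd.DataFrame({"flat": np.zeros(20), "ok": np.r_[np.zeros(10), np.ones(10)]})
        labels = np.array([1] * 10 + [0] * 10)
        out = univariate_screen(
            X, labels, {"flat": "categorical", "ok": "categorical"}
        )
        assert bool(out.loc["flat", "skipped"])
        # multiplier excludes the skipped feature
        assert out.loc["ok", "p_bonferroni"] == pytest.approx(
            min(1.0, out.loc["ok", "p_raw"] * 1)
        )

    @given(st.floats(1e-6, 1.0), st.integers(1, 50))
    def test_bonferroni_never_decreases_and_caps(self, p, m):
        out = float(bonferroni([p], m)[0])
        assert out >= p - 1e-15
        assert out <= 1.0
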