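import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from ssbdsb import classifier, features, synth
from ssbdsb.classifier import (ConfusionCounts, compute_metrics, cross_validate,
                               independent_test, predict, random_baseline,
                               rank_auc, train_ensemble)


def _metrics_oracle(tp, fp, tn, fn):
    """Eq.-by-eq. evaluation in exact rational arithmetic."""
    total = tp + fp + tn + fn
    acc = Fraction(tp + tn, total) if total else None
    sn = Fraction(tp, tp + fn) if tp + fn else None
    sp = Fraction(tn, tn + fp) if tn + fp else None
    f1 = Fraction(2 * tp, 2 * tp + fp + fn) if 2 * tp + fp + fn else None
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom2 == 0 else (tp * tn - fp * fn) / math.sqrt(denom2)
    return acc, sn, sp, f1, mcc


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionCounts(5, 0, 5, 0))
        assert (m.acc, m.mcc, m.f1, m.sn, m.sp) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_symmetric_confusion_is_chance(self):
        m = compute_metrics(ConfusionCounts(25, 25, 25, 25))
        assert (m.acc, m.mcc, m.sn, m.sp, m.f1) == (0.5, 0.0, 0.5, 0.5, 0.5)

    def test_hand_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=8, fn=2, tn=6, fp=4))
        assert m.acc == pytest.approx(0.70)
        assert m.sn == pytest.approx(0.80)
        assert m.sp == pytest.approx(0.60)
        assert m.f1 == pytest.approx(16 / 22)
        assert m.mcc == pytest.approx((8 * 6 - 4 * 2) / math.sqrt(12 * 10 * 10 * 8))

    def test_matches_rational_oracle_on_1000_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 50, 4))
            m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            acc, sn, sp, f1, mcc = _metrics_oracle(tp, fp, tn, fn)
            for got, want in ((m.acc, acc), (m.sn, sn), (m.sp, sp), (m.f1, f1)):
                if want is None:
                    assert math.isnan(got)
                else:
                    assert got == float(want)
            assert m.mcc == mcc

    def test_zero_denominator_mcc_is_zero(self):
        assert compute_metrics(ConfusionCounts(0, 0, 10, 5)).mcc == 0.0


class TestAuc:
    def test_rank_auc_matches_trapezoidal_roc(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 60
            truth = np.where(rng.random(n) < 0.4, "SSB", "DSB")
            if len(set(truth)) < 2:
                continue
            scores = rng.random(n).round(2)  # rounding forces ties
            ours = rank_auc(scores, truth)
            ref = roc_auc_score((truth == "SSB").astype(int), scores)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_perfect_separation_gives_one(self):
        truth = np.array(["SSB"] * 5 + ["DSB"] * 5)
        assert rank_auc(np.r_[np.ones(5), np.zeros(5)], truth) == 1.0


@pytest.fixture(scope="module")
def population():
    return synth.make_feature_population(synth.FeaturePopulationSpec(seed=11))


class TestEnsemble:
    def test_members_are_exactly_balanced(self, population):
        model = train_ensemble(population, seed=0)
        labels = population["label"].to_numpy()
        assert len(model.members) == 15
        for idx in model.member_indices:
            y = labels[idx]
            assert (y == "SSB").sum() == (y == "DSB").sum() == 75

    def test_degenerate_downsampling_uses_everything(self):
        t = synth.make_feature_population(
            synth.FeaturePopulationSpec(n_ssb=10, n_dsb=10, seed=2))
        model = train_ensemble(t, seed=1)
        for idx in model.member_indices:
            assert len(idx) == 20

    def test_same_seed_reproduces_member_draws(self, population):
        m1 = train_ensemble(population, seed=42)
        m2 = train_ensemble(population, seed=42)
        for a, b in zip(m1.member_indices, m2.member_indices):
            np.testing.assert_array_equal(a, b)

    def test_single_class_input_raises(self):
        t = synth.make_feature_population(
            synth.FeaturePopulationSpec(n_ssb=0, n_dsb=20, seed=0))
        with pytest.raises(ValueError):
            train_ensemble(t, seed=0)

    def test_even_member_count_rejected(self, population):
        with pytest.raises(ValueError, match="odd"):
            train_ensemble(population, seed=0, n_members=14)

    def test_vote_fraction_and_no_ties(self, population):
        model = train_ensemble(population, seed=3)
        labels, fractions = predict(model, population)
        assert set(np.round(fractions * 15)) <= set(range(16))
        assert not np.any(np.isclose(fractions, 0.5))
        np.testing.assert_array_equal(labels == "SSB", fractions > 0.5)

    def test_missing_feature_named_in_error(self, population):
        model = train_ensemble(population, seed=0)
        with pytest.raises(ValueError, match="length"):
            predict(model, population.drop(columns=["length"]))

    def test_prediction_invariant_to_row_order(self, population):
        model = train_ensemble(population, seed=5)
        labels, fr = predict(model, population)
        perm = np.random.default_rng(0).permutation(len(population))
        labels_p, fr_p = predict(model, population.iloc[perm].reset_index(drop=True))
        np.testing.assert_array_equal(labels[perm], labels_p)
        np.testing.assert_array_equal(fr[perm], fr_p)


class TestCrossValidation:
    def test_separable_population_scores_high(self):
        t = synth.make_feature_population(
            synth.FeaturePopulationSpec(n_ssb=60, n_dsb=120, separation=3.0, seed=4))
        pooled, per_fold = cross_validate(t, seed=4)
        assert pooled.acc >= 0.95
        assert len(per_fold) == 10

    def test_permuted_labels_give_chance_auc(self, population):
        rng = np.random.default_rng(9)
        aucs = []
        for s in range(10):
            t = population.copy()
            t["label"] = rng.permutation(t["label"].to_numpy())
            pooled, _ = cross_validate(t, seed=s)
            aucs.append(pooled.auc)
        assert 0.40 <= np.mean(aucs) <= 0.60

    def test_same_seed_reproduces_metrics(self, population):
        p1, _ = cross_validate(population, seed=21)
        p2, _ = cross_validate(population, seed=21)
        assert p1.as_dict() == p2.as_dict()

    def test_small_class_reduces_folds_with_warning(self, caplog):
        t = synth.make_feature_population(
            synth.FeaturePopulationSpec(n_ssb=6, n_dsb=30, seed=6))
        with caplog.at_level("WARNING"):
            pooled, per_fold = cross_validate(t, seed=0)
        assert len(per_fold) == 6
        assert "reducing folds" in caplog.text


class TestBaselineAndHoldout:
    def test_baseline_is_chance_level(self):
        t = synth.make_feature_population(
            synth.FeaturePopulationSpec(n_ssb=500, n_dsb=500, seed=14))
        m = random_baseline(t, seed=1)
        assert 0.45 <= m.acc <= 0.55
        assert random_baseline(t, seed=1).as_dict() == m.as_dict()

    def test_holdout_between_shifted_populations(self):
        holo = synth.make_feature_population(
            synth.FeaturePopulationSpec(seed=1, form="HOLO"))
        apo = synth.make_feature_population(
            synth.FeaturePopulationSpec(seed=2, form="APO", length_shift=2.0,
                                        tm_shift=-0.03))
        m = independent_test(holo, apo, seed=1)
        assert m.acc > 0.6

    def test_overlapping_ids_rejected(self):
        t = synth.make_feature_population(
            synth.FeaturePopulationSpec(n_ssb=10, n_dsb=10, seed=1))
        with pytest.raises(ValueError, match="overlap"):
            independent_test(t, t, seed=0)

    def test_empty_test_table_rejected(self):
        t = synth.make_feature_population(
            synth.FeaturePopulationSpec(n_ssb=10, n_dsb=10, seed=1))
        with pytest.raises(ValueError, match="empty"):
            independent_test(t, t.iloc[0:0], seed=0)
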