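"""Feature selection, transfer evaluation and split-half classification."""

import numpy as np
import pytest

from fcrepro import (
    SimConfig,
    aggregate_accuracy,
    evaluate,
    select_features,
    simulate_cohort,
    split_half_batch,
)
from fcrepro.classify import EvalResult, EvaluationError
from fcrepro.connectivity import collection_fc


def _cohort(seed, effect_pairs=(), n_subjects=8, dataset_id="d", **kw):
    params = dict(
        n_regions=10, n_timepoints=120, n_subjects_nc=n_subjects,
        n_subjects_pd=n_subjects, effect_pairs=effect_pairs,
        sigma_subject=0.08, sigma_scan=0.05, seed=seed, dataset_id=dataset_id,
    )
    params.update(kw)
    return simulate_cohort(SimConfig(**params))[0]


class TestFeatureSelection:
    def test_planted_strong_pairs_selected(self):
        scans = _cohort(1, effect_pairs=(((3, 7), 1.2),), n_subjects=15)
        fc, _ = collection_fc(scans)
        is_nc = np.array([s.group == "NC" for s in scans])
        assert set(select_features(fc, is_nc, 2)) == {3, 7}

    def test_n_equals_p_returns_all(self, rng):
        fc = rng.normal(size=(12, 45))
        is_nc = np.arange(12) < 6
        np.testing.assert_array_equal(select_features(fc, is_nc, 45), np.arange(45))

    def test_tie_break_by_ascending_pair_index(self):
        # all columns identical => exact ties; lowest indices win
        col = np.random.default_rng(3).normal(size=12)
        fc = np.tile(col[:, None], (1, 4))
        is_nc = np.arange(12) < 6
        assert list(select_features(fc, is_nc, 2)) == [0, 1]

    def test_selection_depends_on_labels_not_test_data(self, rng):
        fc = rng.normal(size=(20, 30))
        sets = [
            tuple(select_features(fc, rng.permutation(np.arange(20) < 10), 10))
            for _ in range(2)
        ]
        assert sets[0] != sets[1]  # shuffled labels change the selected set

    def test_invalid_n_rejected(self, rng):
        fc = rng.normal(size=(10, 5))
        with pytest.raises(ValueError):
            select_features(fc, np.arange(10) < 5, 6)


class TestEvaluate:
    def test_resubstitution_refused_without_override(self):
        scans = _cohort(5)
        with pytest.raises(EvaluationError, match="resubstitution"):
            evaluate(scans, scans, n_features=5)

    def test_resubstitution_sanity_ceiling(self):
        scans = _cohort(5, effect_pairs=(((0, 1, 2), 0.8),))
        res = evaluate(scans, scans, n_features=5, allow_resubstitution=True)
        assert res.a_acc >= 0.5

    def test_shared_effect_transfers(self):
        effect = (tuple(range(8)), 0.8)
        train = _cohort(11, effect_pairs=(effect,), n_subjects=15, dataset_id="tr")
        test = _cohort(12, effect_pairs=(effect,), n_subjects=15, dataset_id="te")
        res = evaluate(train, test, n_features=8)
        assert res.a_acc > 0.8
        assert res.a_acc == (res.acc_nc + res.acc_pd) / 2

    def test_missing_test_class_rejected(self):
        train = _cohort(13)
        test = [s for s in _cohort(14, dataset_id="e") if s.group == "PD"]
        with pytest.raises(EvaluationError, match="absent"):
            evaluate(train, test, n_features=3)

    def test_gnb_runs(self):
        effect = (tuple(range(8)), 0.8)
        train = _cohort(15, effect_pairs=(effect,), n_subjects=12, dataset_id="tr")
        test = _cohort(16, effect_pairs=(effect,), n_subjects=12, dataset_id="te")
        res = evaluate(train, test, classifier="gnb", n_features=8)
        assert res.a_acc > 0.7


class TestSplitHalfBatch:
    def test_seed_reproducible(self):
        scans = _cohort(20, effect_pairs=(((0, 1), 0.5),))
        b1 = split_half_batch(scans, n_features=5, n_repeats=10, seed=3)
        b2 = split_half_batch(scans, n_features=5, n_repeats=10, seed=3)
        np.testing.assert_array_equal(b1.a_acc_values, b2.a_acc_values)
        assert b1.mean == pytest.approx(np.mean(b1.a_acc_values))

    def test_strong_homogeneous_effect_classifies(self):
        scans = _cohort(21, effect_pairs=((tuple(range(10)), 0.9),), n_subjects=12)
        batch = split_half_batch(scans, n_features=10, n_repeats=30, seed=4)
        assert batch.mean > 0.8

    def test_subject_level_split_keeps_replicates_together(self):
        # with scan-level splits a subject's replicates leak across the
        # boundary and inflate accuracy relative to subject-level splits
        scans = _cohort(22, effect_pairs=(((0, 1, 2), 0.4),), sigma_subject=0.25)
        subj = split_half_batch(scans, n_features=5, n_repeats=40, seed=5).mean
        scan = split_half_batch(
            scans, n_features=5, n_repeats=40, seed=5, split_unit="scan"
        ).mean
        assert scan >= subj - 0.02


def test_aggregate_accuracy_examples():
    def ev(train, test, a):
        return EvalResult(
            train_id=train, test_id=test, classifier="linear_svm",
            n_features=10, acc_nc=a, acc_pd=a,
        )

    assert aggregate_accuracy([ev("a", "b", 0.6), ev("a", "c", 0.4)]) == pytest.approx(0.5)
    assert aggregate_accuracy([ev("a", "b", 0.7), ev("a", "c", 0.7)]) == pytest.approx(0.7)
    with pytest.raises(ValueError):
        aggregate_accuracy([ev("a", "b", 0.6), ev("x", "c", 0.4)])
    with pytest.raises(ValueError):
        aggregate_accuracy([])
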