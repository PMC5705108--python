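"""Classifier-based evaluation of cross-dataset generalisation.

Classifiers (linear SVM, Gaussian naive Bayes) are trained on one
collection's Fisher-z FC features and tested on another. Features are the
n ROI pairs with the largest |Welch t| for the NC-vs-PD contrast *on the
training data only*. Because the classes are unbalanced, performance is the
balanced average accuracy

    Aacc = (acc(NC) + acc(PD)) / 2,

which is 0.5 in expectation for a random classifier. Within-dataset
performance is measured over repeated random half-splits (train on one
half, test on the other), stratified by group at the subject level so that
replicate scans of a subject never straddle the train/test boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectivity import collection_fc
from .contrast import welch_t_batch
from .records import ScanRecord, group_labels
from .reproducibility import _half_partition
from .records import subject_index

log = logging.getLogger(__name__)

Classifier = Literal["linear_svm", "gnb"]
SplitUnit = Literal["subject", "scan"]


class EvaluationError(ValueError):
    pass


@dataclass
class EvalResult:
    train_id: str
    test_id: str
    classifier: Classifier
    n_features: int
    acc_nc: float
    acc_pd: float

    @property
    def a_acc(self) -> float:
        return (self.acc_nc + self.acc_pd) / 2.0


@dataclass
class SplitHalfBatch:
    a_acc_values: np.ndarray
    classifier: Classifier
    n_features: int
    split_unit: SplitUnit
    seed: int

    @property
    def n_repeats(self) -> int:
        return self.a_acc_values.size

    @property
    def mean(self) -> float:
        return float(self.a_acc_values.mean())

    @property
    def sd(self) -> float:
        return float(self.a_acc_values.std(ddof=1))


def select_features(fc: np.ndarray, is_nc: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n pairs with largest |Welch t| on the training data.

    Deterministic: ties are broken by ascending pair index. The selection
    never sees test data.
    """
    fc = np.asarray(fc, dtype=float)
    if not 1 <= n <= fc.shape[1]:
        raise ValueError(f"n_features must be in [1, {fc.shape[1]}], got {n}")
    t, _, _ = welch_t_batch(fc, np.asarray(is_nc, dtype=bool), with_p=False)
    order = np.lexsort((np.arange(t.size), -np.abs(t)))
    return np.sort(order[:n])

def _make_classifier(classifier: Classifier):
    if classifier == "linear_svm":
        # fixed C=1, no tuning: the evaluation protocol, not the classifier,
        # is the object of study
        return SVC(kernel="linear", C=1.0)
    if classifier == "gnb":
        return GaussianNB()
    raise ValueError(f"unknown classifier {classifier!r}")


def _fit_predict_aacc(
    fc_train: np.ndarray,
    y_train: np.ndarray,
    fc_test: np.ndarray,
    y_test: np.ndarray,
    classifier: Classifier,
    n_features: int,
) -> tuple[float, float]:
    """(acc_nc, acc_pd) of a classifier fit on train features only."""
    if y_test.all() or not y_test.any():
        raise EvaluationError("a class is absent from the test collection")
    feats = select_features(fc_train, y_train, n_features)
    x_train, x_test = fc_train[:, feats], fc_test[:, feats]
    # per-feature standardisation on train statistics only
    scaler = StandardScaler().fit(x_train)
    clf = _make_classifier(classifier)
    clf.fit(scaler.transform(x_train), y_train)
    pred = clf.predict(scaler.transform(x_test))
    acc_nc = float(np.mean(pred[y_test]))
    acc_pd = float(np.mean(~pred[~y_test]))
    return acc_nc, acc_pd


def evaluate(
    train: Sequence[ScanRecord],
    test: Sequence[ScanRecord],
    classifier: Classifier = "linear_svm",
    n_features: int = 100,
    allow_resubstitution: bool = False,
    _train_fc: np.ndarray | None = None,
    _test_fc: np.ndarray | None = None,
) -> EvalResult:
    """Train on one collection, test on another, report Aacc.

    Train and test scan sets must be disjoint unless
    ``allow_resubstitution=True`` is passed explicitly (useful only as a
    sanity ceiling; a warning is logged).
    """
    train_keys = {(s.dataset_id, s.scan_id) for s in train}
    test_keys = {(s.dataset_id, s.scan_id) for s in test}
    overlap = train_keys & test_keys
    if overlap and not allow_resubstitution:
        raise EvaluationError(
            f"train and test share {len(overlap)} scan(s); "
            "pass allow_resubstitution=True to evaluate anyway"
        )
    if overlap:
        log.warning("resubstitution evaluation on %d shared scan(s)", len(overlap))
    fc_train = _train_fc if _train_fc is not None else collection_fc(train)[0]
    fc_test = _test_fc if _test_fc is not None else collection_fc(test)[0]
    acc_nc, acc_pd = _fit_predict_aacc(
        fc_train, group_labels(train), fc_test, group_labels(test), classifier, n_features
    )
    train_ids = sorted({s.dataset_id for s in train})
    test_ids = sorted({s.dataset_id for s in test})
    return EvalResult(
        train_id="+".join(train_ids),
        test_id="+".join(test_ids),
        classifier=classifier,
        n_features=n_features,
        acc_nc=acc_nc,
        acc_pd=acc_pd,
    )


def split_half_batch(
    collection: Sequence[ScanRecord],
    classifier: Classifier = "linear_svm",
    n_features: int = 100,
    n_repeats: int = 500,
    seed: int = 0,
    split_unit: SplitUnit = "subject",
    labels: np.ndarray | None = None,
    permute_labels: bool = False,
) -> SplitHalfBatch:
    """Aacc over repeated random half-splits of one collection.

    Each repeat splits the collection in half stratified by group (at
    subject level by default: all scans of a subject stay on one side),
    trains on one half and tests on the other. ``labels`` optionally
    overrides the scans' group labels (boolean NC membership per scan).
    ``permute_labels=True`` freshly permutes the unit-level group labels on
    every repeat -- the label-randomisation null, whose Aacc distribution
    is centred at 0.5 by symmetry. (A single fixed permutation is *not* a
    null when the cohort carries a real effect: chance alignment between
    shuffled and true labels is learnable and generalises across subjects.)
    """
    rng = np.random.default_rng(seed)
    fc, _ = collection_fc(collection)
    is_nc = group_labels(collection) if labels is None else np.asarray(labels, dtype=bool)
    if split_unit == "subject":
        _, scan_to_subj, _ = subject_index(collection)
        n_subj = scan_to_subj.max() + 1
        subj_is_nc = np.zeros(n_subj, dtype=bool)
        subj_is_nc[scan_to_subj] = is_nc  # scans of a subject share a label
        units, unit_of_scan, unit_is_nc = np.arange(n_subj), scan_to_subj, subj_is_nc
    elif split_unit == "scan":
        units = np.arange(len(collection))
        unit_of_scan = units
        unit_is_nc = is_nc
    else:
        raise ValueError(f"unknown split_unit {split_unit!r}")
    a_acc = np.empty(n_repeats)
    for rep in range(n_repeats):
        rep_unit_is_nc = rng.permutation(unit_is_nc) if permute_labels else unit_is_nc
        rep_is_nc = rep_unit_is_nc[unit_of_scan]
        train_units: set[int] = set()
        for grp in (units[rep_unit_is_nc], units[~rep_unit_is_nc]):
            s1, _ = _half_partition(list(grp), rng)
            train_units.update(s1)
        on_train = np.array([u in train_units for u in unit_of_scan])
        acc_nc, acc_pd = _fit_predict_aacc(
            fc[on_train], rep_is_nc[on_train], fc[~on_train], rep_is_nc[~on_train],
            classifier, n_features,
        )
        a_acc[rep] = (acc_nc + acc_pd) / 2.0
    return SplitHalfBatch(
        a_acc_values=a_acc,
        classifier=classifier,
        n_features=n_features,
        split_unit=split_unit,
        seed=seed,
    )


def aggregate_accuracy(results: Sequence[EvalResult]) -> float:
    """Mean Aacc of one training dataset's evaluations on the other datasets."""
    if not results:
        raise ValueError("no evaluations to aggregate")
    if len({r.train_id for r in results}) != 1:
        raise ValueError("aggregate_accuracy expects a single training dataset")
    return float(np.mean([r.a_acc for r in results]))
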