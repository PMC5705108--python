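"""Canned study designs used by the analysis drivers and acceptance checks.

These functions wire the generator and the statistics together into the
standard in-silico experiments: a single-disease (homogeneous) cohort, a
two-subtype (heterogeneous) cohort, null cohorts without any group effect,
label-randomised classifier controls, and cross-dataset transfer designs.

Study conditions (fixed here): Fisher-z effect size delta_z = 0.2 on 20
ROI pairs per disease subtype, subject-level z-noise 0.15 and scan-level
0.10, T = 120 timepoints at TR 2 s, 12 + 12 subjects with 2 replicate
scans each at R = 20 regions for the split analyses -- chosen so per-half
group t-values on affected pairs sit near 2-3, the regime clinical rs-fMRI
cohorts actually occupy. Classifier designs use 15 + 15 subjects
(30 + 30 scans) with a stronger delta_z = 0.8 transfer effect.
"""

from __future__ import annotations

import itertools

import numpy as np

from .classify import Classifier, SplitHalfBatch, evaluate, split_half_batch
from .records import ScanRecord, subject_index
from .reproducibility import SplitBatchResult, permutation_p, split_batch
from .simulate import SimConfig, simulate_cohort

DELTA_Z = 0.25
SIGMA_SUBJECT = 0.15
SIGMA_SCAN = 0.10
N_EFFECT_PAIRS = 20


def subtype_pairs(n_regions: int, n_pairs: int = N_EFFECT_PAIRS) -> tuple[tuple, tuple]:
    """Two disjoint effect-pair sets on disjoint region blocks.

    Subtype A shifts pairs among regions 0..9, subtype B among regions
    10..19, so the two disease subtypes touch entirely separate edges
    (and separate regions -- no coupling through the PSD projection).
    """
    if n_regions < 20:
        raise ValueError("subtype designs need at least 20 regions")
    from .pairs import PairIndex

    pidx = PairIndex(n_regions)
    block_a = [pidx.to_flat(i, j) for i, j in itertools.combinations(range(10), 2)]
    block_b = [pidx.to_flat(i, j) for i, j in itertools.combinations(range(10, 20), 2)]
    return tuple(block_a[:n_pairs]), tuple(block_b[:n_pairs])


def cohort_config(
    kind: str,
    seed: int,
    dataset_id: str = "sim",
    n_regions: int = 20,
    n_subjects: int = 12,
    n_timepoints: int = 120,
    n_replicates: int = 2,
    base_seed: int | None = None,
) -> SimConfig:
    """Standard cohort designs.

    ``homogeneous``: every PD subject carries the subtype-A effect.
    ``two_subtype``: PD subjects split 50/50 between two disjoint effects.
    ``subtype_b``: every PD subject carries the subtype-B effect.
    ``null``: no group effect at all.
    """
    if kind == "null":
        pairs_a = pairs_b = ()
    else:
        pairs_a, pairs_b = subtype_pairs(n_regions)
    effects = {
        "homogeneous": ((pairs_a, DELTA_Z),),
        "two_subtype": ((pairs_a, DELTA_Z), (pairs_b, DELTA_Z)),
        "subtype_b": ((pairs_b, DELTA_Z),),
        "null": (),
    }
    if kind not in effects:
        raise ValueError(f"unknown cohort kind {kind!r}")
    return SimConfig(
        n_regions=n_regions,
        n_timepoints=n_timepoints,
        n_subjects_nc=n_subjects,
        n_subjects_pd=n_subjects,
        n_replicates=n_replicates,
        effect_pairs=effects[kind],
        sigma_subject=SIGMA_SUBJECT,
        sigma_scan=SIGMA_SCAN,
        subtype_assignment="stratified",
        seed=seed,
        dataset_id=dataset_id,
        base_seed=base_seed,
    )


def make_cohort(kind: str, seed: int, **kw) -> list[ScanRecord]:
    return simulate_cohort(cohort_config(kind, seed, **kw))[0]


def randomized_label_split_half(
    collection: list[ScanRecord],
    n_features: int = 100,
    n_repeats: int = 500,
    seed: int = 0,
    classifier: Classifier = "linear_svm",
) -> SplitHalfBatch:
    """Split-half classification under per-repeat label randomisation.

    Every repeat permutes the subject-level group labels uniformly at
    random before the stratified subject-level half-split evaluation. With
    the labels destroyed there is no information left to exploit, so the
    mean balanced accuracy must sit at 0.5.
    """
    return split_half_batch(
        collection,
        classifier=classifier,
        n_features=n_features,
        n_repeats=n_repeats,
        seed=seed,
        permute_labels=True,
    )


def null_calibration_p_values(
    n_repetitions: int = 200,
    n_perm: int = 1000,
    seed: int = 0,
    n_regions: int = 12,
    n_subjects: int = 6,
    n_timepoints: int = 80,
) -> np.ndarray:
    """p_perm over repeated pairs of independent no-effect cohorts.

    Under the null the permutation p-value should be (super-)uniform, so
    the fraction of repetitions with p <= 0.05 should sit near 0.05.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_repetitions)
    for k in range(n_repetitions):
        colls = [
            make_cohort(
                "null",
                seed=int(rng.integers(2**31)),
                dataset_id=f"null{k}_{j}",
                n_regions=n_regions,
                n_subjects=n_subjects,
                n_timepoints=n_timepoints,
                n_replicates=1,
            )
            for j in range(2)
        ]
        out[k] = permutation_p(
            colls[0], colls[1], n_perm=n_perm, seed=int(rng.integers(2**31)),
            keep_null=False,
        ).p_perm
    return out


def split_pattern(
    kind: str,
    seed: int,
    n_splits: int = 100,
    n_perm: int = 500,
) -> dict[str, SplitBatchResult]:
    """split_subjects vs split_replicates batches for one cohort kind."""
    collection = make_cohort(kind, seed)
    return {
        mode: split_batch(
            collection, mode, n_splits=n_splits, n_perm=n_perm, seed=seed + offset
        )
        for offset, mode in enumerate(("split_subjects", "split_replicates"))
    }


def transfer_design(
    seed: int,
    shared: bool,
    n_features: int = 10,
    n_subjects: int = 15,
    n_regions: int = 30,
    classifier: Classifier = "linear_svm",
):
    """Cross-dataset transfer: train on a subtype-A cohort, test on either
    another subtype-A cohort (shared effect) or a subtype-B cohort
    (disjoint effect). Effect size 0.8 in z, 30 + 30 scans per dataset."""
    # the datasets describe the same population: share the baseline FC
    common = dict(n_regions=n_regions, n_subjects=n_subjects, base_seed=seed)
    train_cfg = cohort_config("homogeneous", seed, dataset_id="train", **common)
    test_kind = "homogeneous" if shared else "subtype_b"
    test_cfg = cohort_config(test_kind, seed + 1_000_003, dataset_id="test", **common)
    train_cfg.effect_pairs = tuple(
        type(e)(e.pairs, 0.8) for e in train_cfg.effect_pairs
    )
    test_cfg.effect_pairs = tuple(type(e)(e.pairs, 0.8) for e in test_cfg.effect_pairs)
    train, _ = simulate_cohort(train_cfg)
    test, _ = simulate_cohort(test_cfg)
    return evaluate(train, test, classifier=classifier, n_features=n_features)
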