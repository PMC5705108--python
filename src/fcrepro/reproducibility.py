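"""Reproducibility of group-level FC changes across datasets and splits.

The reproducibility of an NC-vs-PD contrast across two datasets i and j is
the Pearson correlation of their per-pair t-vectors,

    R_ij = corr(T_i, T_j),

and its significance is assessed by permuting the group labels
*independently* in the two datasets and recomputing R; the permutation
p-value is the fraction of permutations whose R meets or exceeds the
observed one,

    p_ij = #{sigma : R_ij^(sigma) >= R_ij} / N .

The split engine compares two random halves of a single dataset: either
*split subjects* (disjoint subjects per side, replicates kept together -- a
heterogeneous split sensitive to disease heterogeneity) or *split
replicates* (same subjects on both sides via different replicate scans -- a
homogeneous split that isolates technical noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .connectivity import collection_fc
from .contrast import welch_contrast, welch_t_batch
from .records import ScanRecord, group_labels, subject_index

log = logging.getLogger(__name__)

SplitMode = Literal["split_subjects", "split_replicates"]
PermUnit = Literal["subject", "scan"]


class SplitError(ValueError):
    pass


@dataclass
class ReproResult:
    """Observed reproducibility R, its permutation null and p-value."""

    r_value: float
    p_perm: float
    n_permutations: int
    null_sample: np.ndarray | None = None
    dataset_pair: tuple[str, str] = ("", "")
    t_a: np.ndarray | None = None
    t_b: np.ndarray | None = None

    @property
    def p_perm_corrected(self) -> float:
        """Guaranteed-positive companion (N*p + 1)/(N + 1)."""
        n = self.n_permutations
        return (n * self.p_perm + 1.0) / (n + 1.0)


@dataclass
class SplitBatchResult:
    """Per-split reproducibility over many random splits of one dataset."""

    mode: SplitMode
    r_values: np.ndarray
    p_values: np.ndarray
    seed: int
    n_permutations: int
    alphas: tuple[float, ...] = (0.01, 0.05)

    @property
    def n_splits(self) -> int:
        return self.r_values.size

    @property
    def median_r(self) -> float:
        return float(np.median(self.r_values))

    def fraction_p_above(self, alpha: float) -> float:
        """Fraction of splits that are *non*-reproducible at level alpha."""
        return float(np.mean(self.p_values > alpha))

    def summary(self) -> dict:
        out = {
            "mode": self.mode,
            "n_splits": int(self.n_splits),
            "median_r": self.median_r,
            "n_permutations": int(self.n_permutations),
            "seed": int(self.seed),
        }
        for a in self.alphas:
            out[f"fraction_p_above_{a}"] = self.fraction_p_above(a)
        return out


def reproducibility_r(t_a: np.ndarray, t_b: np.ndarray) -> float:
    """Pearson correlation of two t-vectors over the same pair order."""
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    if t_a.shape != t_b.shape or t_a.ndim != 1 or t_a.size < 3:
        raise ValueError("t-vectors must be 1-D, equal length >= 3")
    if t_a.std() == 0 or t_b.std() == 0:
        raise ValueError("constant t-vector: reproducibility undefined")
    return float(np.corrcoef(t_a, t_b)[0, 1])


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matched rows of two (m, P) arrays."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den == 0, 0.0, r)


def permute_group_labels(
    scans: Sequence[ScanRecord],
    n_perm: int,
    rng: np.random.Generator,
    perm_unit: PermUnit = "subject",
) -> np.ndarray:
    """(n_perm, n_scans) boolean NC-membership matrix under label permutation.

    With ``perm_unit="subject"`` the multiset of subject-level group labels
    is permuted over subjects and scans inherit their subject's permuted
    label (the exchangeable unit when replicate scans exist); with "scan",
    scan labels are permuted directly.
    """
    if perm_unit == "subject":
        _, scan_to_subj, subj_is_nc = subject_index(scans)
        perms = np.empty((n_perm, subj_is_nc.size), dtype=bool)
        for m in range(n_perm):
            perms[m] = rng.permutation(subj_is_nc)
        out = perms[:, scan_to_subj]
    elif perm_unit == "scan":
        is_nc = group_labels(scans)
        out = np.empty((n_perm, is_nc.size), dtype=bool)
        for m in range(n_perm):
            out[m] = rng.permutation(is_nc)
    else:
        raise ValueError(f"unknown perm_unit {perm_unit!r}")
    assert np.all(out.sum(axis=1) == out[0].sum()), "label multiset must be preserved"
    return out


def permutation_p(
    collection_a: Sequence[ScanRecord],
    collection_b: Sequence[ScanRecord],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    perm_unit: PermUnit = "subject",
    keep_null: bool = True,
) -> ReproResult:
    """Observed R between two collections and its permutation p-value.

    Group labels are permuted independently in the two collections; each of
    the ``n_perm`` joint permutations yields one null R. Ties (null R equal
    to the observed R) count toward the numerator, and no +1 correction is
    applied, so p = 0 is attainable; the conservative companion
    (N*p + 1)/(N + 1) is available as ``ReproResult.p_perm_corrected``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fc_a, pidx_a = collection_fc(collection_a)
    fc_b, pidx_b = collection_fc(collection_b)
    if pidx_a.n_pairs != pidx_b.n_pairs:
        raise ValueError("collections have different pair indexings")
    con_a = welch_contrast(collection_a, fc_a, pidx_a)
    con_b = welch_contrast(collection_b, fc_b, pidx_b)
    r_obs = reproducibility_r(con_a.t_values, con_b.t_values)
    lab_a = permute_group_labels(collection_a, n_perm, rng, perm_unit)
    lab_b = permute_group_labels(collection_b, n_perm, rng, perm_unit)
    t_a, _, _ = welch_t_batch(fc_a, lab_a, with_p=False)
    t_b, _, _ = welch_t_batch(fc_b, lab_b, with_p=False)
    null = _rowwise_corr(t_a, t_b)
    p = float(np.mean(null >= r_obs))
    res = ReproResult(
        r_value=r_obs,
        p_perm=p,
        n_permutations=n_perm,
        null_sample=null if keep_null else None,
        dataset_pair=(con_a.dataset_id, con_b.dataset_id),
        t_a=con_a.t_values,
        t_b=con_b.t_values,
    )
    log.debug(
        "R=%.4f p=%.4g (corrected %.4g, N=%d)", r_obs, p, res.p_perm_corrected, n_perm
    )
    return res


def _half_partition(items: list, rng: np.random.Generator) -> tuple[list, list]:
    """Random partition into halves; side 1 gets the extra item when odd."""
    order = rng.permutation(len(items))
    cut = (len(items) + 1) // 2
    side1 = [items[k] for k in order[:cut]]
    side2 = [items[k] for k in order[cut:]]
    return side1, side2


def make_split(
    collection: Sequence[ScanRecord],
    mode: SplitMode,
    seed: int | np.random.Generator = 0,
) -> tuple[list[ScanRecord], list[ScanRecord]]:
    """Split one collection into two halves.

    ``split_subjects``: within each group, subjects are randomly partitioned
    into halves (sizes differing by at most 1) and every scan follows its
    subject -- the two sides contain disjoint subjects.

    ``split_replicates``: every subject appears on both sides, its replicate
    scans randomly divided between them -- the two sides contain the same
    subjects through different scans.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects, scan_to_subj, subj_is_nc = subject_index(collection)
    by_subj: dict[str, list[ScanRecord]] = {s: [] for s in subjects}
    for scan in collection:
        by_subj[scan.subject_id].append(scan)
    side1: list[ScanRecord] = []
    side2: list[ScanRecord] = []
    if mode == "split_subjects":
        for is_nc in (True, False):
            grp = [s for s, g in zip(subjects, subj_is_nc) if g == is_nc]
            if len(grp) < 4:
                raise SplitError(
                    f"split_subjects needs >= 4 subjects per group, got {len(grp)}: {grp}"
                )
            s1, s2 = _half_partition(grp, rng)
            side1.extend(scan for s in s1 for scan in by_subj[s])
            side2.extend(scan for s in s2 for scan in by_subj[s])
    elif mode == "split_replicates":
        short = [s for s in subjects if len(by_subj[s]) < 2]
        if short:
            raise SplitError(f"split_replicates needs >= 2 replicates per subject: {short}")
        for s in subjects:
            s1, s2 = _half_partition(by_subj[s], rng)
            side1.extend(s1)
            side2.extend(s2)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return side1, side2


def split_batch(
    collection: Sequence[ScanRecord],
    mode: SplitMode,
    n_splits: int = 200,
    n_perm: int = 1000,
    seed: int = 0,
    perm_unit: PermUnit = "subject",
) -> SplitBatchResult:
    """Reproducibility over many random splits of one collection.

    For each split, ``permutation_p`` is run between the two halves; the
    batch records each split's (R, p) and summarises the median R and the
    fractions of non-reproducible splits at the usual alpha levels.
    """
    rng = np.random.default_rng(seed)
    r_values = np.empty(n_splits)
    p_values = np.empty(n_splits)
    for k in range(n_splits):
        half1, half2 = make_split(collection, mode, rng)
        res = permutation_p(half1, half2, n_perm, rng, perm_unit, keep_null=False)
        r_values[k], p_values[k] = res.r_value, res.p_perm
    return SplitBatchResult(
        mode=mode,
        r_values=r_values,
        p_values=p_values,
        seed=seed,
        n_permutations=n_perm,
    )


def scatter_frame(result: ReproResult):
    """Per-pair (t_a, t_b) scatter table; its correlation equals R."""
    import pandas as pd

    if result.t_a is None or result.t_b is None:
        raise ValueError("result does not carry its t-vectors")
    return pd.DataFrame({"t_a": result.t_a, "t_b": result.t_b})
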