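"""Mass-univariate NC-vs-PD group contrast on FC vectors.

Each ROI pair gets an unpaired two-sample Welch t-test (unequal sample
sizes, unequal variances) between the NC and PD scans' Fisher-z
connectivities. The sign convention is fixed throughout the package:

    t > 0  <=>  mean FC(NC) > mean FC(PD)

so positive t means FC *decreased* in PD. The per-pair t-vector T_i of a
dataset i is what all reproducibility statistics consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import collection_fc
from .pairs import PairIndex
from .records import ScanRecord, group_labels

log = logging.getLogger(__name__)


class ContrastError(ValueError):
    pass


@dataclass
class ContrastResult:
    """Per-pair Welch t, degrees of freedom and two-sided p for one contrast."""

    t_values: np.ndarray
    df_values: np.ndarray
    p_values: np.ndarray
    n_nc: int
    n_pd: int
    pair_index: PairIndex
    dataset_id: str = ""
    contrast_label: str = "NC-PD"

    def to_frame(self) -> pd.DataFrame:
        i, j = self.pair_index.rows_cols()
        return pd.DataFrame(
            {
                "pair_k": np.arange(self.pair_index.n_pairs),
                "roi_i": i,
                "roi_j": j,
                "t": self.t_values,
                "df": self.df_values,
                "p": self.p_values,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def welch_t_batch(
    fc: np.ndarray, is_nc: np.ndarray, with_p: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Vectorised Welch t-test, NC minus PD, over one or many labelings.

    Parameters
    ----------
    fc : (n_scans, P) Fisher-z connectivity matrix.
    is_nc : (n_scans,) or (m, n_scans) boolean NC membership; a 2-D input
        evaluates m labelings (e.g. label permutations) in one pass.
    with_p : also compute two-sided p from the t distribution.

    Returns (t, df, p) with shape (P,) or (m, P). Pairs with zero variance
    in both groups get t=0, p=1 (and df=1 as a placeholder).
    """
    fc = np.asarray(fc, dtype=float)
    is_nc = np.asarray(is_nc, dtype=bool)
    squeeze = is_nc.ndim == 1
    lab = np.atleast_2d(is_nc).astype(float)  # (m, n)
    n1 = lab.sum(axis=1, keepdims=True)  # NC counts
    n2 = lab.shape[1] - n1
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ContrastError("need at least 2 scans per group")
    if squeeze:
        # accurate two-pass moments for a single labeling
        grp1, grp2 = fc[is_nc], fc[~is_nc]
        m1, m2 = grp1.mean(axis=0, keepdims=True), grp2.mean(axis=0, keepdims=True)
        v1 = ((grp1 - m1) ** 2).sum(axis=0, keepdims=True) / (n1 - 1)
        v2 = ((grp2 - m2) ** 2).sum(axis=0, keepdims=True) / (n2 - 1)
        scale = (fc * fc).mean(axis=0)
    else:
        # one-pass moments via matmuls: evaluates all m labelings at once
        fc2 = fc * fc
        s1, s1sq = lab @ fc, lab @ fc2
        s2, s2sq = fc.sum(axis=0) - s1, fc2.sum(axis=0) - s1sq
        m1, m2 = s1 / n1, s2 / n2
        # clip tiny negative rounding residue
        v1 = np.clip((s1sq - n1 * m1 * m1) / (n1 - 1), 0.0, None)
        v2 = np.clip((s2sq - n2 * m2 * m2) / (n2 - 1), 0.0, None)
        scale = (s1sq + s2sq) / lab.shape[1]
    se2 = v1 / n1 + v2 / n2
    # zero pooled variance up to accumulation error at the data's scale
    degenerate = se2 <= 1e-24 * (scale + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, (m1 - m2) / np.sqrt(np.where(degenerate, 1.0, se2)))
        df = np.where(
            degenerate,
            1.0,
            se2 * se2
            / np.where(
                degenerate,
                1.0,
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1),
            ),
        )
    p = None
    if with_p:
        p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    if squeeze:
        t, df = t[0], df[0]
        p = None if p is None else p[0]
    return t, df, p


def welch_contrast(
    scans: Sequence[ScanRecord],
    fc: np.ndarray | None = None,
    pair_index: PairIndex | None = None,
    sample_unit: Literal["scan", "subject_mean"] = "scan",
    contrast_label: str = "NC-PD",
) -> ContrastResult:
    """NC-vs-PD Welch contrast over all ROI pairs of a collection.

    Samples are scans by default (replicate scans pooled, matching the
    printed per-dataset scan counts of clinical PD cohorts); with
    ``sample_unit="subject_mean"`` each subject contributes the mean of its
    replicate FC vectors instead.
    """
    if fc is None or pair_index is None:
        fc, pair_index = collection_fc(scans)
    is_nc = group_labels(scans)
    if sample_unit == "subject_mean":
        from .records import subject_index

        _, scan_to_subj, subj_is_nc = subject_index(scans)
        n_subj = subj_is_nc.size
        agg = np.zeros((n_subj, fc.shape[1]))
        counts = np.bincount(scan_to_subj, minlength=n_subj).astype(float)
        np.add.at(agg, scan_to_subj, fc)
        fc = agg / counts[:, None]
        is_nc = subj_is_nc
    elif sample_unit != "scan":
        raise ValueError(f"unknown sample_unit {sample_unit!r}")
    if is_nc.sum() < 2 or (~is_nc).sum() < 2:
        raise ContrastError("need at least 2 samples per group")
    t, df, p = welch_t_batch(fc, is_nc, with_p=True)
    n_zero = int(np.count_nonzero((t == 0.0) & (p == 1.0)))
    if n_zero:
        log.info("zero pooled variance at %d pair(s): t=0, p=1", n_zero)
    dataset_ids = {s.dataset_id for s in scans}
    return ContrastResult(
        t_values=t,
        df_values=df,
        p_values=p,
        n_nc=int(is_nc.sum()),
        n_pd=int((~is_nc).sum()),
        pair_index=pair_index,
        dataset_id=dataset_ids.pop() if len(dataset_ids) == 1 else "+".join(sorted(dataset_ids)),
        contrast_label=contrast_label,
    )


def directional_p(
    contrast: ContrastResult, direction: Literal["plus", "minus"]
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p restricted to pairs with the requested t sign.

    ``plus`` keeps pairs with t > 0 (FC decreased in PD, NC > PD), ``minus``
    keeps t < 0. Returns (p, included) where excluded pairs carry p = NaN.
    Pairs with t exactly 0 are excluded from both directions.
    """
    if direction == "plus":
        included = contrast.t_values > 0
    elif direction == "minus":
        included = contrast.t_values < 0
    else:
        raise ValueError(f"direction must be 'plus' or 'minus', got {direction!r}")
    p = np.where(included, contrast.p_values, np.nan)
    return p, included
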