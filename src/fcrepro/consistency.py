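"""Cross-dataset edge consistency: the min(max(p)) statistic.

A single ROI pair may discriminate PD from controls in *every* dataset even
when the global t-vectors do not correlate. For each pair whose t-value has
a consistent sign in all K datasets, max(p) is the largest (least
significant) of its K two-sided p-values; pairs are ranked by ascending
max(p), and min(max(p)) -- the best pair's worst-case significance -- is
tested by permuting disease labels independently within each dataset:

    p(min(max(p))) = #{sigma : min(max(p))^(sigma) <= min(max(p))} / N .

The analysis is run separately for FC increases in NC relative to PD
(direction "plus": t > 0 everywhere, i.e. FC decreases in PD) and for
direction "minus" (t < 0 everywhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .connectivity import collection_fc
from .contrast import ContrastResult, directional_p, welch_contrast, welch_t_batch
from .records import ScanRecord
from .reproducibility import PermUnit, permute_group_labels

log = logging.getLogger(__name__)

Direction = Literal["plus", "minus"]


@dataclass
class ConsistencyResult:
    direction: Direction
    ranked_pairs: pd.DataFrame
    min_max_p: float
    p_of_min_max_p: float
    n_permutations: int
    null_sample: np.ndarray | None = None


def max_p_table(contrasts: Sequence[ContrastResult], direction: Direction) -> pd.DataFrame:
    """Ranked table of sign-consistent pairs by worst-case p.

    Only pairs whose t has the required sign in *every* contrast are
    retained; ``max_p`` is the maximum over contrasts of the directional
    (two-sided) p. Sorted ascending by max_p, ties broken by pair index.
    Columns include each contrast's t and p, labelled by dataset id.
    """
    if len(contrasts) < 2:
        raise ValueError("need at least 2 contrasts")
    pidx = contrasts[0].pair_index
    if any(c.pair_index.n_pairs != pidx.n_pairs for c in contrasts):
        raise ValueError("contrasts use different pair indexings")
    ps, keeps = zip(*(directional_p(c, direction) for c in contrasts))
    keep = np.logical_and.reduce(keeps)
    max_p = np.max(np.vstack(ps), axis=0)  # NaN where any contrast excludes
    i, j = pidx.rows_cols()
    cols: dict[str, np.ndarray] = {
        "pair_k": np.arange(pidx.n_pairs),
        "roi_i": i,
        "roi_j": j,
        "max_p": max_p,
    }
    for k, c in enumerate(contrasts):
        tag = c.dataset_id or f"dataset{k}"
        cols[f"p_{tag}"] = c.p_values
        cols[f"t_{tag}"] = c.t_values
    df = pd.DataFrame(cols)[keep]
    return df.sort_values(["max_p", "pair_k"], kind="mergesort").reset_index(drop=True)


def min_max_p(contrasts: Sequence[ContrastResult], direction: Direction) -> float:
    """min over sign-consistent pairs of the worst-case p; 1.0 if none."""
    table = max_p_table(contrasts, direction)
    if table.empty:
        log.info("no sign-consistent pair for direction %s; min(max(p)) := 1", direction)
        return 1.0
    return float(table["max_p"].iloc[0])


def _min_max_p_batch(
    t_all: np.ndarray, p_all: np.ndarray, sign: float
) -> np.ndarray:
    """min(max(p)) per permutation from stacked per-dataset stats.

    t_all, p_all: (K, m, P) arrays over K datasets, m permutations, P pairs.
    """
    consistent = np.all(sign * t_all > 0, axis=0)  # (m, P)
    worst = np.max(p_all, axis=0)  # (m, P)
    worst = np.where(consistent, worst, np.inf)
    out = worst.min(axis=1)
    return np.where(np.isfinite(out), out, 1.0)


def consistency_permutation_test(
    collections: Sequence[Sequence[ScanRecord]],
    direction: Direction,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    perm_unit: PermUnit = "subject",
    keep_null: bool = False,
) -> ConsistencyResult:
    """Permutation test of the observed min(max(p)).

    Disease labels are permuted independently within each collection
    (subject level by default), contrasts recomputed, and the permuted
    min(max(p)) compared with the observed one; permutations at or below
    the observed value count toward the numerator ("<=", ties included).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sign = 1.0 if direction == "plus" else -1.0
    fcs, contrasts = [], []
    for coll in collections:
        fc, pidx = collection_fc(coll)
        fcs.append(fc)
        contrasts.append(welch_contrast(coll, fc, pidx))
    observed = min_max_p(contrasts, direction)
    t_stack = np.empty((len(collections), n_perm, fcs[0].shape[1]))
    p_stack = np.empty_like(t_stack)
    for k, (coll, fc) in enumerate(zip(collections, fcs)):
        labels = permute_group_labels(coll, n_perm, rng, perm_unit)
        t, df, p = welch_t_batch(fc, labels, with_p=True)
        t_stack[k], p_stack[k] = t, p
    null = _min_max_p_batch(t_stack, p_stack, sign)
    p_val = float(np.mean(null <= observed))
    return ConsistencyResult(
        direction=direction,
        ranked_pairs=max_p_table(contrasts, direction),
        min_max_p=observed,
        p_of_min_max_p=p_val,
        n_permutations=n_perm,
        null_sample=null if keep_null else None,
    )
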