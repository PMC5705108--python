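"""Fisher-z functional connectivity per scan.

FC(ROI_i, ROI_j) = atanh(corr(x_i, x_j)): the Fisher z-transform of the
Pearson correlation between the two regions' mean timecourses. Vectors are
laid out in the canonical pair order of :class:`fcrepro.pairs.PairIndex`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pairs import PairIndex
from .records import ROITimeseries, ScanRecord, validate_collection

# |r| is clipped here before atanh so that degenerate (perfectly correlated)
# pairs yield a large finite z instead of +-inf.
CLIP = 1.0 - 1e-12


class DegenerateRegionError(ValueError):
    """A region's timecourse is constant, so its correlations are undefined."""


@dataclass
class FCVector:
    """Length-P Fisher-z connectivity vector for one scan."""

    values: np.ndarray
    pair_index: PairIndex
    scan_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.pair_index.n_pairs,):
            raise ValueError("FC vector length does not match pair index")


def fc_vector(ts: ROITimeseries, scan_id: str = "") -> FCVector:
    """Fisher-z connectivity of one scan.

    Requires T >= 3 and no constant region (which would make the Pearson
    correlation undefined; the offending regions are named in the error).
    """
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    constant = np.ptp(x, axis=0) == 0
    if np.any(constant):
        bad = [ts.region_ids[k] for k in np.flatnonzero(constant)]
        raise DegenerateRegionError(f"constant timecourse for region id(s) {bad}")
    corr = np.corrcoef(x, rowvar=False)
    pidx = PairIndex(x.shape[1])
    r = np.clip(pidx.condense(corr), -CLIP, CLIP)
    return FCVector(values=np.arctanh(r), pair_index=pidx, scan_id=scan_id)


def collection_fc(scans: Sequence[ScanRecord]) -> tuple[np.ndarray, PairIndex]:
    """Stack per-scan FC vectors into an (n_scans, P) matrix."""
    validate_collection(scans)
    vecs = [fc_vector(s.timeseries, s.scan_id) for s in scans]
    return np.vstack([v.values for v in vecs]), vecs[0].pair_index


def fc_long_frame(vec: FCVector) -> pd.DataFrame:
    """Long-format table (scan_id, pair_k, roi_i, roi_j, z) for one scan."""
    i, j = vec.pair_index.rows_cols()
    return pd.DataFrame(
        {
            "scan_id": vec.scan_id,
            "pair_k": np.arange(vec.pair_index.n_pairs),
            "roi_i": i,
            "roi_j": j,
            "z": vec.values,
        }
    )


def write_fc_long(vec: FCVector, path) -> None:
    fc_long_frame(vec).to_csv(path, sep="\t", index=False)


def read_fc_long(path) -> FCVector:
    df = pd.read_csv(path, sep="\t")
    n_pairs = len(df)
    # recover R from P = R(R-1)/2
    n_regions = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    pidx = PairIndex(n_regions)
    if pidx.n_pairs != n_pairs:
        raise ValueError(f"{n_pairs} rows is not a full upper triangle")
    df = df.sort_values("pair_k")
    scan_id = str(df["scan_id"].iloc[0])
    return FCVector(values=df["z"].to_numpy(), pair_index=pidx, scan_id=scan_id)


def write_fc_wide(scans: Sequence[ScanRecord], path) -> None:
    """Wide matrix (scans x pairs) with scan_id as the row index."""
    fc, pidx = collection_fc(scans)
    cols = [f"pair_{k}" for k in range(pidx.n_pairs)]
    pd.DataFrame(fc, index=[s.scan_id for s in scans], columns=cols).to_csv(
        path, sep="\t", index_label="scan_id"
    )


def read_fc_wide(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="scan_id")
    return df.to_numpy(dtype=float), [str(s) for s in df.index]
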