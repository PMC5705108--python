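"""Core data records: per-scan ROI timeseries and scan metadata.

A *scan* is one resting-state acquisition summarised as a T x R matrix of
mean ROI timecourses. A *collection* is a list of scans belonging to one
dataset (or one split of a dataset); all scans in a collection share the
same parcellation (region ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

GROUPS = ("NC", "PD")


class ValidationError(ValueError):
    """Malformed record or metadata."""


class SchemaError(ValueError):
    """Inconsistent structure across scans in a collection."""


@dataclass
class ROITimeseries:
    """T x R matrix of mean ROI timecourses.

    Parameters
    ----------
    values : (T, R) float array, all finite, T >= 2.
    tr_seconds : repetition time (sampling interval) in seconds.
    region_ids : R unique integer labels, sorted ascending.
    """

    values: np.ndarray
    tr_seconds: float
    region_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("timeseries must be a 2-D (T, R) matrix")
        if self.values.shape[0] < 2:
            raise ValidationError("timeseries needs at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("timeseries contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        self.region_ids = tuple(int(r) for r in self.region_ids)
        if len(self.region_ids) != self.values.shape[1]:
            raise ValidationError("region_ids length must equal number of columns")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValidationError("region_ids must be unique")
        if list(self.region_ids) != sorted(self.region_ids):
            raise ValidationError("region_ids must be sorted ascending")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, tr_seconds: float | None = None) -> "ROITimeseries":
        return ROITimeseries(
            values=values,
            tr_seconds=self.tr_seconds if tr_seconds is None else tr_seconds,
            region_ids=self.region_ids,
        )


@dataclass
class ScanRecord:
    """One scan plus its cohort metadata.

    ``group`` is "NC" (normal control) or "PD"; ``replicate_index`` is
    1-based; ``low_motion`` marks membership in a low in-scanner motion
    subset (a metadata flag only -- no motion estimation is done here).
    """

    scan_id: str
    subject_id: str
    group: str
    dataset_id: str
    replicate_index: int
    timeseries: ROITimeseries
    low_motion: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"scan {self.scan_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.replicate_index < 1:
            raise ValidationError(f"scan {self.scan_id!r}: replicate_index must be >= 1")

    def map_timeseries(self, func) -> "ScanRecord":
        """Return a copy with ``func`` applied to the timeseries."""
        return replace(self, timeseries=func(self.timeseries))


def validate_collection(scans: Sequence[ScanRecord]) -> None:
    """Check cross-scan invariants of a collection.

    Raises SchemaError on duplicate (dataset_id, scan_id) or on region-id
    mismatch across scans.
    """
    if not scans:
        raise SchemaError("empty collection")
    keys = [(s.dataset_id, s.scan_id) for s in scans]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise SchemaError(f"duplicate (dataset_id, scan_id): {dupes}")
    ref = scans[0].timeseries.region_ids
    bad = [s.scan_id for s in scans if s.timeseries.region_ids != ref]
    if bad:
        raise SchemaError(f"region-id mismatch across scans: {bad}")


def group_labels(scans: Sequence[ScanRecord]) -> np.ndarray:
    """Boolean array, True where the scan's group is NC."""
    return np.array([s.group == "NC" for s in scans], dtype=bool)


def subject_index(scans: Sequence[ScanRecord]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Subject bookkeeping for subject-level permutation and splitting.

    Returns (subjects, scan_to_subject, subject_is_nc) where ``subjects``
    lists unique subject ids in first-appearance order, ``scan_to_subject``
    maps each scan to its subject's position, and ``subject_is_nc`` gives
    each subject's group (scans inherit their subject's label, which the
    collection is required to keep consistent).
    """
    subjects: list[str] = []
    pos: dict[str, int] = {}
    is_nc: list[bool] = []
    idx = np.empty(len(scans), dtype=int)
    for i, s in enumerate(scans):
        if s.subject_id not in pos:
            pos[s.subject_id] = len(subjects)
            subjects.append(s.subject_id)
            is_nc.append(s.group == "NC")
        elif is_nc[pos[s.subject_id]] != (s.group == "NC"):
            raise SchemaError(f"subject {s.subject_id!r} has inconsistent group labels")
        idx[i] = pos[s.subject_id]
    return subjects, idx, np.array(is_nc, dtype=bool)
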