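"""Reading and writing scan collections; ROI extraction from volumes.

On-disk layout of a collection directory::

    dir/
      metadata.tsv          scan_id, subject_id, group, dataset_id,
                            replicate_index, tr_seconds, low_motion
      <scan_id>.tsv         T rows x R columns, header row of region ids

The tabular format is deliberately plain TSV: diffable, desk-inspectable,
and lossless to the float precision written (repr-roundtrip).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import (
    GROUPS,
    ROITimeseries,
    ScanRecord,
    SchemaError,
    ValidationError,
    validate_collection,
)

log = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "scan_id",
    "subject_id",
    "group",
    "dataset_id",
    "replicate_index",
    "tr_seconds",
    "low_motion",
]


def extract_roi_timecourses(
    image_4d: np.ndarray, atlas: np.ndarray, tr_seconds: float = 2.0
) -> ROITimeseries:
    """Mean timecourse per atlas region from a 4-D volume series.

    ``atlas`` holds nonnegative integer labels on the same spatial grid as
    the image (label 0 = background). Column k of the result is the spatial
    mean over the voxels of the k-th nonzero label, labels sorted
    ascending. Labels with no voxels simply do not occur; an atlas that is
    all background is an error.
    """
    image_4d = np.asarray(image_4d, dtype=float)
    atlas = np.asarray(atlas)
    if image_4d.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, t)")
    if atlas.shape != image_4d.shape[:3]:
        raise ValueError(
            f"atlas grid {atlas.shape} does not match image grid {image_4d.shape[:3]}"
        )
    if np.any(atlas < 0):
        raise ValueError("atlas labels must be nonnegative integers")
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("atlas contains only background")
    flat_img = image_4d.reshape(-1, image_4d.shape[3])
    flat_atlas = atlas.reshape(-1)
    columns = np.empty((image_4d.shape[3], labels.size))
    for k, lab in enumerate(labels):
        columns[:, k] = flat_img[flat_atlas == lab].mean(axis=0)
    return ROITimeseries(
        values=columns, tr_seconds=tr_seconds, region_ids=tuple(int(x) for x in labels)
    )


def extract_roi_timecourses_nifti(image_path, atlas_path, tr_seconds: float | None = None):
    """NIfTI front-end to :func:`extract_roi_timecourses`."""
    import nibabel as nib

    img = nib.load(str(image_path))
    atl = nib.load(str(atlas_path))
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
    return extract_roi_timecourses(
        np.asanyarray(img.dataobj), np.rint(np.asanyarray(atl.dataobj)).astype(int), tr_seconds
    )


def write_scan_collection(scans: Sequence[ScanRecord], path) -> None:
    """Write a collection to a directory (metadata.tsv + one TSV per scan)."""
    validate_collection(scans)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        [
            {
                "scan_id": s.scan_id,
                "subject_id": s.subject_id,
                "group": s.group,
                "dataset_id": s.dataset_id,
                "replicate_index": s.replicate_index,
                "tr_seconds": s.timeseries.tr_seconds,
                "low_motion": int(s.low_motion),
            }
            for s in scans
        ],
        columns=METADATA_COLUMNS,
    )
    meta.to_csv(path / "metadata.tsv", sep="\t", index=False)
    for s in scans:
        pd.DataFrame(
            s.timeseries.values, columns=[str(r) for r in s.timeseries.region_ids]
        ).to_csv(path / f"{s.scan_id}.tsv", sep="\t", index=False, float_format="%.17g")


def read_scan_collection(path) -> list[ScanRecord]:
    """Read a collection directory written by :func:`write_scan_collection`.

    Metadata rows are validated (group, replicate index, duplicates) and
    all offending scan_ids are reported together; scans must agree on
    region ids.
    """
    path = Path(path)
    meta_path = path / "metadata.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.tsv under {path}")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"scan_id": str, "subject_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata.tsv missing column(s) {missing}")
    bad: list[str] = []
    for _, row in meta.iterrows():
        if row["group"] not in GROUPS or int(row["replicate_index"]) < 1:
            bad.append(str(row["scan_id"]))
    if bad:
        raise ValidationError(f"malformed metadata rows for scan_id(s): {bad}")
    scans: list[ScanRecord] = []
    for _, row in meta.iterrows():
        ts_path = path / f"{row['scan_id']}.tsv"
        if not ts_path.exists():
            raise ValidationError(f"missing timeseries file for scan {row['scan_id']!r}")
        df = pd.read_csv(ts_path, sep="\t")
        scans.append(
            ScanRecord(
                scan_id=str(row["scan_id"]),
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                dataset_id=str(row["dataset_id"]),
                replicate_index=int(row["replicate_index"]),
                low_motion=bool(int(row["low_motion"])),
                timeseries=ROITimeseries(
                    values=df.to_numpy(dtype=float),
                    tr_seconds=float(row["tr_seconds"]),
                    region_ids=tuple(int(c) for c in df.columns),
                ),
            )
        )
    validate_collection(scans)
    n_cols = {s.timeseries.n_regions for s in scans}
    if len(n_cols) > 1:
        raise SchemaError(f"scans have differing region counts: {sorted(n_cols)}")
    return scans
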