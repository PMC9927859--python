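"""On-disk artifacts and in-memory containers for the ISC pipeline.

Images (4D BOLD series, 3D masks, 3D statistic maps) are NIfTI-1 via
nibabel; behavioral data are CSV via pandas; stimulus structure and run
configuration are JSON.  Masked-out voxels are represented as NaN in every
output map so that excluded voxels are unambiguous downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd


class DataError(ValueError):
    """Structural problem in an input artifact (shape/TR mismatch, bad range...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _default_affine(voxel_size_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class TimeSeriesImage:
    """One subject's voxel x time BOLD signal for one condition.

    data has shape (nx, ny, nz, T); tr is the volume repetition time in
    seconds (1.7 s for the narrative acquisition this pipeline targets).
    """

    data: np.ndarray
    tr: float
    subject_id: str
    condition: str
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise DataError(
                f"time series for {self.subject_id}/{self.condition} must be 4D, "
                f"got shape {self.data.shape}"
            )
        if self.data.shape[3] < 2:
            raise DataError(
                f"time series for {self.subject_id}/{self.condition} needs T >= 2"
            )
        if not self.tr > 0:
            raise DataError(f"tr must be positive, got {self.tr}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise DataError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """Boolean analysis mask on the image grid."""

    data: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise DataError("mask must be boolean (values 0/1)")
            arr = arr.astype(bool)
        if arr.ndim != 3:
            raise DataError(f"mask must be 3D, got shape {arr.shape}")
        self.data = arr
        if self.n_voxels < 1:
            raise DataError("mask selects no voxels")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CohortDataset:
    """Aligned subjects x conditions collection of time-series images.

    Subject and condition order is explicit (a manifest), never inherited
    from directory listings, so loading permuted file orderings yields an
    identical dataset.
    """

    images: dict[tuple[str, str], TimeSeriesImage]
    subjects: list[str]
    conditions: list[str]
    mask: BrainMask

    def __post_init__(self) -> None:
        for cond in self.conditions:
            ref: TimeSeriesImage | None = None
            for subj in self.subjects:
                key = (subj, cond)
                if key not in self.images:
                    raise DataError(f"missing image for subject {subj!r}, condition {cond!r}")
                img = self.images[key]
                if img.shape != self.mask.shape:
                    raise DataError(
                        f"image {subj!r}/{cond!r} grid {img.shape} does not match "
                        f"mask grid {self.mask.shape}"
                    )
                if ref is None:
                    ref = img
                else:
                    if img.n_timepoints != ref.n_timepoints:
                        raise DataError(
                            f"image {subj!r}/{cond!r} has T={img.n_timepoints}, "
                            f"expected T={ref.n_timepoints} within condition {cond!r}"
                        )
                    if img.tr != ref.tr:
                        raise DataError(
                            f"image {subj!r}/{cond!r} has tr={img.tr}, "
                            f"expected tr={ref.tr} within condition {cond!r}"
                        )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def get(self, subject: str, condition: str) -> TimeSeriesImage:
        return self.images[(subject, condition)]

    def n_timepoints(self, condition: str) -> int:
        return self.images[(self.subjects[0], condition)].n_timepoints

    def masked_series(self, subject: str, condition: str) -> np.ndarray:
        """Return the (T, n_voxels) matrix of in-mask time courses."""
        img = self.images[(subject, condition)]
        return img.data[self.mask.data, :].T


@dataclass
class StimulusStructure:
    """Silence intervals of the narrative stimulus, in seconds."""

    silences: list[tuple[float, float]]
    duration_s: float

    def __post_init__(self) -> None:
        self.silences = [(float(a), float(b)) for a, b in self.silences]
        prev_end = -np.inf
        for start, end in self.silences:
            if not (0 <= start < end <= self.duration_s):
                raise DataError(f"silence interval ({start}, {end}) outside [0, {self.duration_s}]")
            if start < prev_end:
                raise DataError("silence intervals must be sorted and non-overlapping")
            prev_end = end


@dataclass
class BehavioralTable:
    """Per-subject lipreading score (percent), mean comprehension rating
    (0-1) and presentation-order group (ordinal position of the lipreading
    condition, 1-3)."""

    frame: pd.DataFrame

    REQUIRED = ("subject_id", "lip_score_pct", "mean_rating", "order_group")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DataError(f"behavioral table missing columns: {missing}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise DataError(f"duplicate subject rows: {dup}")
        score = df["lip_score_pct"].to_numpy(dtype=float)
        rating = df["mean_rating"].to_numpy(dtype=float)
        if np.any((score < 0) | (score > 100)):
            raise DataError("lip_score_pct outside [0, 100]")
        if np.any((rating < 0) | (rating > 1)):
            raise DataError("mean_rating outside [0, 1]")
        self.frame = df.reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return self.frame["subject_id"].tolist()

    def value(self, subject: str, column: str) -> float:
        row = self.frame.loc[self.frame["subject_id"] == subject, column]
        if row.empty:
            raise DataError(f"subject {subject!r} not in behavioral table")
        return float(row.iloc[0])

    def aligned(self, subjects: Sequence[str], column: str) -> np.ndarray:
        return np.array([self.value(s, column) for s in subjects], dtype=float)


@dataclass
class StatMap:
    """3D statistic image; NaN outside the mask."""

    data: np.ndarray
    statistic_name: str = "stat"
    metadata: dict = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError(f"stat map must be 3D, got shape {self.data.shape}")
        if self.affine is None:
            self.affine = np.eye(4)


@dataclass
class PValueMap:
    """3D p-value image in (0, 1]; NaN outside the mask."""

    data: np.ndarray
    corrected: bool
    n_perm: int
    metadata: dict = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError(f"p-value map must be 3D, got shape {self.data.shape}")
        inside = np.isfinite(self.data)
        if np.any(self.data[inside] <= 0) or np.any(self.data[inside] > 1):
            raise DataError("p-values must lie in (0, 1]")
        if self.affine is None:
            self.affine = np.eye(4)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_timeseries(img: TimeSeriesImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(img.data, img.affine), str(path))


def load_timeseries(path: str | Path, subject_id: str, condition: str,
                    tr: float | None = None) -> TimeSeriesImage:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=np.float64)
    if tr is None:
        tr = float(nii.header.get_zooms()[3]) if len(nii.header.get_zooms()) > 3 else 1.0
    zooms = nii.header.get_zooms()[:3]
    return TimeSeriesImage(data=data, tr=tr, subject_id=subject_id,
                           condition=condition,
                           voxel_size_mm=tuple(float(z) for z in zooms),
                           affine=np.asarray(nii.affine))


def load_mask(path: str | Path) -> BrainMask:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj)
    return BrainMask(data=data, affine=np.asarray(nii.affine))


def write_mask(mask: BrainMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


def load_cohort(image_paths: Mapping[tuple[str, str], str | Path],
                mask_path: str | Path,
                subjects: Sequence[str] | None = None,
                conditions: Sequence[str] | None = None,
                tr: float | None = None) -> CohortDataset:
    """Load a full cohort from per-(subject, condition) NIfTI paths.

    subjects/conditions are the ordering manifest; when omitted they default
    to the sorted unique tokens of the path mapping, so the result does not
    depend on mapping iteration order.
    """
    if subjects is None:
        subjects = sorted({s for s, _ in image_paths})
    if conditions is None:
        conditions = sorted({c for _, c in image_paths})
    mask = load_mask(mask_path)
    images: dict[tuple[str, str], TimeSeriesImage] = {}
    for subj in subjects:
        for cond in conditions:
            key = (subj, cond)
            if key not in image_paths:
                raise DataError(f"no image path for subject {subj!r}, condition {cond!r}")
            images[key] = load_timeseries(image_paths[key], subj, cond, tr=tr)
    return CohortDataset(images=images, subjects=list(subjects),
                         conditions=list(conditions), mask=mask)


def write_stat_map(m: StatMap | PValueMap, path: str | Path) -> None:
    """Write a statistic/p-value map as NIfTI plus a JSON metadata sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(m.data, m.affine), str(path))
    meta = dict(m.metadata)
    if isinstance(m, StatMap):
        meta["statistic_name"] = m.statistic_name
        meta["kind"] = "stat"
    else:
        meta.update(kind="pvalue", corrected=m.corrected, n_perm=m.n_perm)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=1, default=str))


def load_stat_map(path: str | Path) -> StatMap | PValueMap:
    path = Path(path)
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=np.float64)
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    kind = meta.pop("kind", "stat")
    if kind == "pvalue":
        return PValueMap(data=data, corrected=bool(meta.pop("corrected")),
                         n_perm=int(meta.pop("n_perm")), metadata=meta,
                         affine=np.asarray(nii.affine))
    name = meta.pop("statistic_name", "stat")
    return StatMap(data=data, statistic_name=name, metadata=meta,
                   affine=np.asarray(nii.affine))


def load_behavior(csv_path: str | Path) -> BehavioralTable:
    return BehavioralTable(frame=pd.read_csv(csv_path))


def write_behavior(table: BehavioralTable, csv_path: str | Path) -> None:
    table.frame.to_csv(csv_path, index=False)


def load_stimulus(json_path: str | Path) -> StimulusStructure:
    obj = json.loads(Path(json_path).read_text())
    return StimulusStructure(silences=[tuple(iv) for iv in obj["silences"]],
                             duration_s=float(obj["duration_s"]))


def write_stimulus(stim: StimulusStructure, json_path: str | Path) -> None:
    Path(json_path).write_text(json.dumps(
        {"silences": [list(iv) for iv in stim.silences], "duration_s": stim.duration_s},
        indent=1))
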