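"""Volumetric data model and I/O.

Volumes are 3D scalar derivative maps (e.g. regional homogeneity) stored as
NIfTI-1, typically 61 x 73 x 61 voxels at 3 mm isotropic resolution in MNI152
space. A dataset couples each volume with a subject record carrying a binary
diagnostic label (1 = ASD, 0 = control) and an optional acquisition site,
described by a plain CSV manifest so fixtures stay human-writable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SHAPE = (61, 73, 61)
DEFAULT_VOXEL_SIZE_MM = (3.0, 3.0, 3.0)

MANIFEST_REQUIRED_COLUMNS = ("subject_id", "label", "volume_path")


def _default_affine(voxel_size_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class BrainVolume:
    """One subject's 3D scalar derivative grid plus voxel geometry.

    ``data`` uses 0-based voxel indices with axis order (x, y, z) matching the
    on-disk array layout; ``affine`` maps voxel indices to world mm.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    affine: Optional[np.ndarray] = None
    subject_id: Optional[str] = None
    is_reho: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must be 3D, got shape {self.data.shape}"
            )
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive: {self.voxel_size_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")
        if self.is_reho and self.data.min() < 0:
            raise ValueError("REHO derivative volumes must be non-negative")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "BrainVolume":
        """Copy of this volume with the scalar grid replaced."""
        return BrainVolume(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            affine=None if self.affine is None else self.affine.copy(),
            subject_id=self.subject_id,
            is_reho=False,
        )


@dataclass
class SubjectRecord:
    subject_id: str
    label: int
    site_id: Optional[str] = None
    volume_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.label = int(self.label)
        if self.label not in (0, 1):
            raise ValueError(
                f"label for subject {self.subject_id!r} must be 0 or 1, got {self.label}"
            )


@dataclass
class LabelledDataset:
    """Matched subject records and brain volumes, in manifest order."""

    records: list[SubjectRecord]
    volumes: list[BrainVolume]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.volumes):
            raise ValueError("records and volumes must have equal length")
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id values: {dupes}")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ValueError(f"volumes have inconsistent shapes: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def subset(self, indices: Sequence[int]) -> "LabelledDataset":
        return LabelledDataset(
            records=[self.records[i] for i in indices],
            volumes=[self.volumes[i] for i in indices],
        )

    def to_arrays(self, dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
        """Stack volumes into (n, x, y, z) plus the label vector."""
        X = np.stack([v.data for v in self.volumes]).astype(dtype)
        return X, self.labels


def read_volume(path) -> BrainVolume:
    """Read a single-volume NIfTI-1 file.

    NaN voxels (background outside the brain mask in some derivative
    distributions) are replaced by 0 with a logged warning. 4D input is
    rejected: derivative maps have the time dimension already collapsed.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3D volume, got shape {data.shape} in {path}"
        )
    data = np.asarray(data, dtype=np.float32)
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        logger.warning("replacing %d NaN voxels with 0 in %s", n_nan, path)
        data = np.nan_to_num(data, nan=0.0)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains Inf values")
    zooms = img.header.get_zooms()[:3]
    return BrainVolume(
        data=data,
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=float),
        subject_id=path.name.split(".")[0],
    )


def write_volume(volume: BrainVolume, path) -> Path:
    """Write a volume as NIfTI-1; round-trips bit-compatibly via read_volume."""
    path = Path(path)
    data = np.asarray(volume.data, dtype=np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.voxel_size_mm)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"could not write NIfTI file {path}: {exc}") from exc
    return path


def load_dataset(manifest_path) -> LabelledDataset:
    """Load a dataset from a CSV manifest.

    Columns: subject_id, label, volume_path, optional site_id. Relative
    volume paths are resolved against the manifest's directory. Record
    order is the manifest order.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"manifest {manifest_path} missing columns: {missing}")
    has_site = "site_id" in table.columns

    records: list[SubjectRecord] = []
    volumes: list[BrainVolume] = []
    for row in table.itertuples(index=False):
        sid = str(row.subject_id)
        vpath = Path(str(row.volume_path))
        if not vpath.is_absolute():
            vpath = manifest_path.parent / vpath
        try:
            vol = read_volume(vpath)
        except (IOError, FileNotFoundError) as exc:
            raise IOError(f"subject {sid}: cannot read volume {vpath}: {exc}") from exc
        vol.subject_id = sid
        records.append(
            SubjectRecord(
                subject_id=sid,
                label=int(row.label),
                site_id=str(row.site_id) if has_site and not pd.isna(row.site_id) else None,
                volume_path=str(vpath),
            )
        )
        volumes.append(vol)

    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        offenders = [
            r.subject_id
            for r, v in zip(records, volumes)
            if v.shape != volumes[0].shape
        ]
        raise ValueError(
            f"inconsistent volume shapes across subjects; offenders: {offenders}"
        )
    return LabelledDataset(records=records, volumes=volumes)


def write_manifest(records: Sequence[SubjectRecord], path) -> Path:
    """Write a CSV manifest for a sequence of subject records."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "label": [r.label for r in records],
            "site_id": [r.site_id if r.site_id is not None else "" for r in records],
            "volume_path": [r.volume_path for r in records],
        }
    )
    frame.to_csv(path, index=False)
    return path
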