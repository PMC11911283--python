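"""Brain-volume I/O, intensity masking, and volume <-> row-vector conversion.

FDG-PET analysis operates on a subjects x voxels matrix assembled from
spatially normalized 3D volumes. This module reads and writes NIfTI-1
volumes, builds the percentage-of-maximum analysis mask, and converts
between 3D arrays and the masked row-vector representation, keeping the
column <-> voxel mapping deterministic (C-order scan of the grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BrainVolume",
    "VoxelMask",
    "VoxelMatrix",
    "load_volume",
    "save_volume",
    "build_mask",
    "stack",
    "unstack",
    "read_manifest",
    "write_manifest",
    "load_cohort_volumes",
]

VALID_LABELS = ("PD", "MSA", "PSP", "UD", "unknown")


@dataclass
class BrainVolume:
    """A single subject's spatially normalized metabolic image.

    Intensities are in arbitrary positive units (uptake proxies); the
    affine maps voxel indices to world coordinates.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.data.ndim}D shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"volume {self.subject_id!r} contains non-finite intensities")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VoxelMask:
    """Boolean voxel-inclusion map shared by every volume of an analysis.

    ``threshold_pct`` records the percentage-of-maximum rule used to build
    it (15-45% in routine use).
    """

    included: np.ndarray
    threshold_pct: float

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.ndim != 3:
            raise ValueError("mask must be a 3D boolean map")
        if self.n_voxels < 1:
            raise ValueError("mask includes no voxels")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.included.shape

    @property
    def n_voxels(self) -> int:
        return int(self.included.sum())


@dataclass
class VoxelMatrix:
    """Subjects x masked-voxels intensity matrix with subject bookkeeping.

    Rows follow ``subject_ids`` order; columns follow the C-order scan of
    the grid restricted to ``mask``. All entries must be positive so the
    log transform downstream is defined.
    """

    values: np.ndarray
    mask: VoxelMask
    subject_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (subjects x voxels)")
        m, n = self.values.shape
        if n != self.mask.n_voxels:
            raise ValueError(
                f"matrix has {n} columns but mask includes {self.mask.n_voxels} voxels"
            )
        if m != len(self.subject_ids) or m != len(self.labels):
            raise ValueError("subject_ids/labels length must match row count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def load_volume(path: str | Path, subject_id: str = "", label: str = "unknown") -> BrainVolume:
    """Read a NIfTI-1 file into a :class:`BrainVolume`.

    Raises ``ValueError`` for non-3D images.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    return BrainVolume(
        data=np.asarray(data, dtype=np.float64),
        affine=np.asarray(img.affine),
        subject_id=subject_id or Path(path).stem.replace(".nii", ""),
        label=label,
    )


def save_volume(vol: BrainVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; round trips data and affine losslessly."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    nib.save(img, str(path))


def build_mask(volumes: list[BrainVolume], threshold_pct: float) -> VoxelMask:
    """Build the analysis mask at ``threshold_pct`` % of each image's maximum.

    A voxel is included iff its intensity reaches ``threshold_pct/100`` of
    that image's maximum in *every* volume (intersection over subjects), so
    every matrix entry is above threshold for every subject. Thresholds
    outside the routine 15-45% band warn but do not fail.
    """
    if not volumes:
        raise ValueError("need at least one volume to build a mask")
    if not (15.0 <= threshold_pct <= 45.0):
        warnings.warn(
            f"mask threshold {threshold_pct}% is outside the usual 15-45% range",
            stacklevel=2,
        )
    grid = volumes[0].shape
    included = np.ones(grid, dtype=bool)
    for vol in volumes:
        if vol.shape != grid:
            raise ValueError(
                f"volume {vol.subject_id!r} grid {vol.shape} != {grid}"
            )
        included &= vol.data >= (threshold_pct / 100.0) * vol.data.max()
    if not included.any():
        raise ValueError(f"mask at {threshold_pct}% of maximum excludes every voxel")
    return VoxelMask(included=included, threshold_pct=float(threshold_pct))


def stack(volumes: list[BrainVolume], mask: VoxelMask) -> VoxelMatrix:
    """Assemble masked volumes into the subjects x voxels matrix.

    Column j of the result is the j-th included voxel in C-order scan of
    the grid. Raises if any masked intensity is non-positive (the log
    transform downstream would be undefined).
    """
    rows = []
    for vol in volumes:
        if vol.shape != mask.grid_shape:
            raise ValueError(
                f"volume {vol.subject_id!r} grid {vol.shape} != mask grid {mask.grid_shape}"
            )
        row = vol.data[mask.included]  # C-order scan restricted to mask
        if np.any(row <= 0):
            j = int(np.argmax(row <= 0))
            raise ValueError(
                f"subject {vol.subject_id!r} has non-positive intensity at masked voxel {j}"
            )
        rows.append(row)
    return VoxelMatrix(
        values=np.vstack(rows),
        mask=mask,
        subject_ids=[v.subject_id for v in volumes],
        labels=[v.label for v in volumes],
    )


def unstack(
    row_vector: np.ndarray,
    mask: VoxelMask,
    affine: np.ndarray | None = None,
    subject_id: str = "",
    label: str = "unknown",
    fill: float = 0.0,
) -> BrainVolume:
    """Re-embed a masked row vector into a 3D volume.

    Voxels outside the mask are written as ``fill`` (0 by default, NaN if
    requested). Inverse of :func:`stack` on the masked voxels.
    """
    row_vector = np.asarray(row_vector, dtype=np.float64).ravel()
    if row_vector.size != mask.n_voxels:
        raise ValueError(
            f"row vector length {row_vector.size} != mask voxel count {mask.n_voxels}"
        )
    data = np.full(mask.grid_shape, fill, dtype=np.float64)
    data[mask.included] = row_vector
    vol = BrainVolume.__new__(BrainVolume)
    # bypass the finite check when fill is NaN
    vol.data = data
    vol.affine = np.eye(4) if affine is None else np.asarray(affine, dtype=np.float64)
    vol.subject_id = subject_id
    vol.label = label
    return vol


def write_manifest(entries: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort manifest CSV (subject_id, path, label, split)."""
    required = {"subject_id", "path", "label", "split"}
    missing = required - set(entries.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    entries.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str, "path": str, "label": str, "split": str})
    bad = set(df["label"]) - set(VALID_LABELS)
    if bad:
        raise ValueError(f"manifest contains unknown labels: {sorted(bad)}")
    return df


def load_cohort_volumes(
    manifest: pd.DataFrame | str | Path, split: str | None = None, root: str | Path | None = None
) -> list[BrainVolume]:
    """Load the volumes listed in a manifest, optionally one split only.

    Relative paths are resolved against ``root`` (defaults to the
    manifest's directory when a path is given).
    """
    if not isinstance(manifest, pd.DataFrame):
        if root is None:
            root = Path(manifest).parent
        manifest = read_manifest(manifest)
    if split is not None:
        manifest = manifest[manifest["split"] == split]
    root = Path(root) if root is not None else Path(".")
    volumes = []
    for rec in manifest.itertuples(index=False):
        p = Path(rec.path)
        if not p.is_absolute():
            p = root / p
        volumes.append(load_volume(p, subject_id=rec.subject_id, label=rec.label))
    return volumes
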