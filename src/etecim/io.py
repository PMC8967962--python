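"""Mask volume and cohort manifest I/O.

Coordinate conventions used throughout the package
--------------------------------------------------
* The voxel lattice is indexed ``(z, y, x)``: axis 0 runs cranial-caudal
  (CC), axis 1 anterior-posterior (AP), axis 2 left-right (LR).
* ``spacing`` is given as ``(sx, sy, sz)`` in mm/voxel, i.e. in the *world*
  axis order, not the lattice axis order.
* Physical coordinates are voxel centers: voxel ``(k, j, i)`` sits at
  ``(i * sx, j * sy, k * sz)`` mm.  Indices are 0-based.

On load, NIfTI volumes are reoriented to the closest RAS+ frame so every
downstream metric shares one sign convention regardless of how the file was
stored.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ManifestError, MaskValidationError

__all__ = [
    "MaskVolume",
    "CohortManifest",
    "load_mask",
    "save_mask",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ("patient_id", "predicted_mask_path", "ground_truth_mask_path")


@dataclass(frozen=True)
class MaskVolume:
    """A 3-D binary segmentation mask with physical voxel spacing.

    Parameters
    ----------
    voxels
        ``uint8`` array indexed ``(z, y, x)``; values are exactly 0 or 1.
    spacing
        ``(sx, sy, sz)`` voxel spacing in mm.
    source_path
        Optional provenance label (the file the mask was read from).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    source_path: str | None = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise MaskValidationError(
                f"mask must be 3-D, got {vox.ndim}-D array of shape {vox.shape}"
            )
        if any(s < 1 for s in vox.shape):
            raise MaskValidationError(f"mask needs >=1 voxel per axis, got shape {vox.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise MaskValidationError(f"spacing must have 3 components, got {spacing!r}")
        if not all(np.isfinite(s) and s > 0 for s in spacing):
            raise MaskValidationError(f"spacing components must be positive finite, got {spacing}")
        binary = (vox != 0).astype(np.uint8)
        object.__setattr__(self, "voxels", binary)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def with_voxels(self, voxels: np.ndarray) -> "MaskVolume":
        return replace(self, voxels=voxels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaskVolume):
            return NotImplemented
        return self.spacing == other.spacing and np.array_equal(self.voxels, other.voxels)


@dataclass(frozen=True)
class CohortManifest:
    """Rows of (patient_id, predicted path, ground-truth path, optional fold)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing required column(s): {', '.join(missing)}")
        dupes = df["patient_id"][df["patient_id"].duplicated()].unique().tolist()
        if dupes:
            raise ManifestError(f"duplicate patient_id values: {dupes}")
        same = df[df["predicted_mask_path"] == df["ground_truth_mask_path"]]
        if len(same):
            raise ManifestError(
                "predicted and ground-truth paths must differ per row; offending "
                f"patient_id values: {same['patient_id'].tolist()}"
            )
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return iter(self.frame.itertuples(index=False))

    @property
    def has_folds(self) -> bool:
        return "fold" in self.frame.columns and self.frame["fold"].notna().all()


def load_mask(path: str | os.PathLike) -> MaskVolume:
    """Read a NIfTI-1 volume as a binary mask.

    Any nonzero stored value becomes foreground.  The volume is reoriented
    to the canonical RAS+ frame and transposed to ``(z, y, x)`` lattice
    order; spacing is taken from the (reoriented) header.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(path)
    if img.ndim != 3:
        raise MaskValidationError(f"{path}: expected a 3-D volume, got {img.ndim}-D")
    img = nib.as_closest_canonical(img)
    zooms = img.header.get_zooms()[:3]  # (sx, sy, sz) after canonicalization
    if not all(np.isfinite(z) and z > 0 for z in zooms):
        raise MaskValidationError(f"{path}: header reports non-positive spacing {tuple(zooms)}")
    data = np.asanyarray(img.dataobj)  # (x, y, z)
    voxels = np.transpose(data, (2, 1, 0))
    return MaskVolume(voxels=voxels, spacing=tuple(float(z) for z in zooms), source_path=path)


def save_mask(mask: MaskVolume, path: str | os.PathLike) -> str:
    """Write a mask as NIfTI-1 so that ``load_mask`` reproduces it exactly.

    ``.gz`` output is written with a zeroed gzip timestamp, so saving the
    same mask twice yields byte-identical files.
    """
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    sx, sy, sz = mask.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    data = np.transpose(mask.voxels, (2, 1, 0)).astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    if path.endswith(".gz"):
        payload = gzip.compress(img.to_bytes(), mtime=0)
        with open(path, "wb") as fh:
            fh.write(payload)
    else:
        nib.save(img, path)
    return path


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read and validate a cohort manifest CSV (header row required)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"manifest file not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str})
    return CohortManifest(frame=df)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    manifest.frame.to_csv(path, index=False)
    return path
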