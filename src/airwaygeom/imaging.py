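"""Image containers and file I/O.

All geometry downstream is computed in world (mm) coordinates.  The package
fixes a single convention: voxel arrays are indexed ``[ix, iy, iz]``, voxel
indices are 0-based, and ``world = origin + index * spacing`` componentwise.
The z axis points toward superior, so the top of the trachea is the
foreground region with maximal z.

SimpleITK handles the on-disk formats (NIfTI, NRRD, MetaImage); its arrays
arrive as ``[z, y, x]`` and are transposed at the boundary so nothing else in
the package ever sees index-order ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_feature_table",
    "read_feature_table",
    "write_mesh",
]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".mha", ".mhd")


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing and origin in mm.

    ``voxels[ix, iy, iz]`` maps to world position ``origin + index * spacing``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.voxels.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to mm coordinates."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Map mm coordinates to continuous voxel indices."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class BinaryMask(ImageVolume):
    """A {0,1} labelling on the same grid as its source volume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask voxels must be 0 or 1")
        self.voxels = self.voxels.astype(np.uint8)

    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def foreground_volume(self) -> float:
        """Total foreground volume in mm^3 (count x voxel volume)."""
        return self.foreground_count() * self.voxel_volume()


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported volume format {path.suffix!r}; "
            f"supported: {', '.join(_SUPPORTED_SUFFIXES)}"
        )


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D volume (NIfTI/NRRD/MetaImage) with its spacing and origin.

    Raises if the file is not 3D.  Spacing always comes from the header;
    a missing header spacing is impossible with these formats (SimpleITK
    fills it), but non-positive values are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got {img.GetDimension()}D"
        )
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return ImageVolume(
        voxels=voxels, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin())
    )


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(voxels=(vol.voxels > 0), spacing=vol.spacing, origin=vol.origin)


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(vol), str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    write_volume(ImageVolume(mask.voxels.astype(np.uint8), mask.spacing, mask.origin), path)


def write_mesh(mesh, path: str | Path) -> None:
    """Write a trimesh mesh to PLY/STL (ASCII for text-only pipelines)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))


def write_feature_table(
    rows: list[dict],
    path: str | Path,
    provenance: dict | None = None,
) -> pd.DataFrame:
    """Write per-case feature rows to CSV with a deterministic column order.

    Column order follows first appearance across rows.  Duplicate feature
    names within a row dict are impossible; a duplicate produced upstream
    (e.g. two branches mapped to the same index) raises before writing.
    An optional JSON sidecar records provenance (spacing, seeds, config).
    """
    path = Path(path)
    columns: list[str] = []
    for row in rows:
        keys = list(row)
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate feature names in a row")
        for k in keys:
            if k not in columns:
                columns.append(k)
    df = pd.DataFrame(rows, columns=columns if columns else None)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if provenance is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(provenance, indent=2, sort_keys=True, default=str))
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
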