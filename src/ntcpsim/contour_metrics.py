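"""Geometric agreement and dosimetric parameters from voxel masks.

Dice measures volumetric overlap of two segmentations; surface Dice at a
tolerance measures what fraction of the two segmentation surfaces lie within
a physical distance of each other, which is more sensitive to boundary
placement than volumetric overlap.  Mean dose and VxGy (percentage of the
organ volume receiving at least x Gy) are the dose-volume-histogram
parameters that feed the NTCP simulation.

Conventions
-----------
* Masks and dose grids are 3-D arrays with per-axis physical spacing in mm;
  array axis ``k`` has spacing ``spacing[k]``.  Grids must be co-registered:
  mismatched geometry raises rather than silently resampling.
* The segmentation surface is represented by boundary voxel *faces* (faces
  between a foreground voxel and a background or out-of-grid neighbour),
  and surface-to-surface distances are Euclidean distances between face
  centers in physical coordinates.  Faces are counted unweighted (no area
  weighting); with anisotropic spacing this differs slightly from an
  area-weighted surface integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "VoxelMask",
    "DoseGrid",
    "GeometryMismatchError",
    "dice",
    "surface_dice",
    "mean_dose",
    "vxgy",
    "cohort_metric_table",
    "read_mask",
    "read_dose",
    "write_mask",
    "write_dose",
]


class GeometryMismatchError(ValueError):
    """Raised when two grids are not co-registered (shape/spacing/origin)."""


@dataclass(frozen=True)
class VoxelMask:
    """3-D binary mask with physical spacing (mm per voxel, per array axis)."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


@dataclass(frozen=True)
class DoseGrid:
    """3-D dose array in Gy, geometry-aligned with the masks it is used with."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if grid.ndim != 3:
            raise ValueError("dose grid must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")
        if not np.all(np.isfinite(grid)) or np.any(grid < 0):
            raise ValueError("doses must be finite and non-negative")


def _check_geometry(a, b) -> None:
    if a.grid.shape != b.grid.shape:
        raise GeometryMismatchError(
            f"shape mismatch: {a.grid.shape} vs {b.grid.shape}"
        )
    if not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise GeometryMismatchError(
            "spacing/origin mismatch; grids must be co-registered "
            "(resampling is out of scope)"
        )


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Volumetric Dice coefficient ``2|A∩B| / (|A| + |B|)``."""
    _check_geometry(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("both masks are empty; Dice is undefined")
    inter = int(np.logical_and(a.grid, b.grid).sum())
    return 2.0 * inter / (na + nb)


def _boundary_face_centers(mask: VoxelMask) -> np.ndarray:
    """Physical coordinates (mm) of the centers of all boundary voxel faces.

    A boundary face separates a foreground voxel from a background neighbour;
    neighbours outside the grid count as background.  Voxel centers sit at
    ``origin + (index + 0.5) * spacing``; a face center is displaced by half
    a spacing along its axis.
    """
    grid = mask.grid
    padded = np.pad(grid, 1, constant_values=False)
    centers = []
    for ax in range(3):
        for sign in (-1, +1):
            neighbour = np.roll(padded, -sign, axis=ax)[1:-1, 1:-1, 1:-1]
            faces = grid & ~neighbour
            idx = np.argwhere(faces).astype(float)
            if len(idx) == 0:
                continue
            coords = (idx + 0.5) * np.asarray(mask.spacing) + np.asarray(mask.origin)
            coords[:, ax] += sign * mask.spacing[ax] / 2.0
            centers.append(coords)
    if not centers:
        return np.empty((0, 3))
    return np.vstack(centers)


def surface_dice(a: VoxelMask, b: VoxelMask, tolerance_mm: float) -> float:
    """Surface Dice at a physical tolerance.

    ``(|S_A within tau of S_B| + |S_B within tau of S_A|) / (|S_A| + |S_B|)``
    where the surfaces are boundary voxel faces and distances are Euclidean
    distances between face centers in mm, respecting anisotropic spacing.
    """
    _check_geometry(a, b)
    if tolerance_mm < 0:
        raise ValueError("tolerance must be >= 0")
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise ValueError("surface Dice requires two non-empty masks")
    surf_a = _boundary_face_centers(a)
    surf_b = _boundary_face_centers(b)
    tol = tolerance_mm + 1e-9  # guard against float round-off at exact distances
    d_ab, _ = cKDTree(surf_b).query(surf_a)
    d_ba, _ = cKDTree(surf_a).query(surf_b)
    hits = int(np.sum(d_ab <= tol)) + int(np.sum(d_ba <= tol))
    return hits / (len(surf_a) + len(surf_b))


def mean_dose(dose: DoseGrid, mask: VoxelMask) -> float:
    """Volume-weighted mean dose over the mask (Gy).

    With uniform voxel volume this is the arithmetic mean of the dose over
    foreground voxels.
    """
    _check_geometry(dose, mask)
    if mask.n_voxels == 0:
        raise ValueError("mean dose over an empty mask is undefined")
    return float(dose.grid[mask.grid].mean())


def vxgy(dose: DoseGrid, mask: VoxelMask, x: float) -> float:
    """VxGy: percentage of the mask volume receiving at least ``x`` Gy.

    The threshold is inclusive (dose >= x).
    """
    _check_geometry(dose, mask)
    if mask.n_voxels == 0:
        raise ValueError("VxGy over an empty mask is undefined")
    if x < 0:
        raise ValueError("dose threshold must be >= 0")
    values = dose.grid[mask.grid]
    return float(100.0 * np.mean(values >= x))


def cohort_metric_table(per_patient: list[dict]) -> pd.DataFrame:
    """Aggregate per-patient metric dicts into a mean ± SD table.

    ``per_patient`` is a list of ``{metric_name: value}`` dicts, one per
    patient; the result has one row per metric with columns ``mean``, ``sd``
    and ``n``.
    """
    df = pd.DataFrame(per_patient)
    out = pd.DataFrame(
        {"mean": df.mean(), "sd": df.std(ddof=1), "n": df.count()}
    )
    out.index.name = "metric"
    return out


# ---------------------------------------------------------------------------
# Voxel I/O (NRRD and other ITK-readable formats, spacing-aware)

def _read_image(path):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x); spacing is stored (x, y, z)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin


def read_mask(path) -> VoxelMask:
    arr, spacing, origin = _read_image(path)
    return VoxelMask(grid=arr > 0, spacing=spacing, origin=origin)


def read_dose(path) -> DoseGrid:
    arr, spacing, origin = _read_image(path)
    return DoseGrid(grid=arr.astype(float), spacing=spacing, origin=origin)


def _write_image(arr, spacing, origin, path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(spacing)))
    img.SetOrigin(tuple(reversed(origin)))
    sitk.WriteImage(img, str(path))


def write_mask(mask: VoxelMask, path) -> None:
    _write_image(mask.grid.astype(np.uint8), mask.spacing, mask.origin, path)


def write_dose(dose: DoseGrid, path) -> None:
    _write_image(dose.grid.astype(np.float32), dose.spacing, dose.origin, path)
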