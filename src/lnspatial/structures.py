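"""Labeled 3D binary structure masks with physical geometry.

A :class:`StructureVolume` is the unit of anatomical input: one binary mask
(tumor volume or organ at risk) on a regular voxel grid with per-axis
physical spacing.  All structures belonging to one patient must share the
same grid (shape, spacing, origin); distances and angles are always computed
in physical millimetres, so anisotropic voxels are handled transparently.

Conventions
-----------
* Masks are indexed ``(x, y, z)``; the axial plane is ``(x, y)``.
* Indices are 0-based; the physical coordinate of voxel ``(i, j, k)`` is the
  voxel *center*: ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StructureVolume", "GeometryMismatchError"]


class GeometryMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class StructureVolume:
    """A named binary mask with physical geometry.

    Parameters
    ----------
    name :
        Structure label, e.g. ``"GTVn"`` or ``"SpinalCord"``.
    mask :
        3D boolean (or {0,1}) array indexed ``(x, y, z)``.
    spacing :
        Per-axis voxel size in mm, strictly positive.
    origin :
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    name: str
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"mask for {self.name!r} must be 3D, got {mask.ndim}D")
        if mask.dtype != bool:
            vals = np.unique(mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(
                    f"mask for {self.name!r} is not binary (values {vals[:5]}...)"
                )
            mask = mask.astype(bool)
        object.__setattr__(self, "mask", mask)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or len(origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        """Number of foreground voxels."""
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not self.mask.any()

    def voxel_centers_mm(self) -> np.ndarray:
        """Physical (mm) centers of all foreground voxels, (n, 3), in
        lexicographic index order."""
        idx = np.argwhere(self.mask)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def same_grid(self, other: "StructureVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "StructureVolume") -> None:
        if not self.same_grid(other):
            raise GeometryMismatchError(
                f"structures {self.name!r} and {other.name!r} are on different "
                f"grids: shape {self.shape} vs {other.shape}, spacing "
                f"{self.spacing} vs {other.spacing}, origin {self.origin} vs "
                f"{other.origin}"
            )

    def with_mask(self, mask: np.ndarray, name: str | None = None) -> "StructureVolume":
        """A new volume on the same grid with a different mask."""
        return StructureVolume(
            name=name or self.name, mask=mask, spacing=self.spacing, origin=self.origin
        )


def union(name: str, *volumes: StructureVolume) -> StructureVolume:
    """Voxelwise union of structures on a shared grid (e.g. left + right
    parotid merged into a combined ``Parotids`` structure)."""
    if not volumes:
        raise ValueError("union requires at least one volume")
    first = volumes[0]
    mask = first.mask.copy()
    for v in volumes[1:]:
        first.require_same_grid(v)
        mask |= v.mask
    return first.with_mask(mask, name=name)
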