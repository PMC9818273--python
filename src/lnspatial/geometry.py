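"""Distance and angle descriptors of a nodal tumor volume relative to organs.

Two histograms summarize the spatial configuration of a lymph-node tumor
volume (GTVn) with respect to a surrounding organ at risk (OAR):

* the **overlap volume histogram (OVH)** — the cumulative fraction of OAR
  volume whose signed surface distance to the tumor is at most ``d``, as a
  function of ``d`` in mm.  The surface distance of an OAR voxel is the
  minimum Euclidean distance from the voxel center to the tumor surface,
  negative for voxels inside the tumor and positive outside;

* the **projection overlap volume (POV)** — for each axial angle ``alpha``,
  the fraction of OAR volume whose voxels lie inside the tumor's angular
  "shadow" at that angle.  An OAR voxel contributes at angle ``alpha`` when
  ``alpha`` falls inside the minimal circular arc spanned by the directions
  from every tumor surface point to the voxel center, measured in the axial
  (x, y) plane counterclockwise from +x.

All distances are physical (mm), honoring anisotropic voxel spacing.  The
tumor surface is the set of centers of 6-connectivity boundary voxels; the
distance transform is taken with respect to these surface voxel centers, so
an exhaustive pairwise scan reproduces the fast path exactly.

Angular arcs are closed at both ends, and the seam at 0/360 degrees is
handled by taking the *minimal covering* circular arc (the complement of the
largest angular gap), so a degenerate single-direction arc still matches its
own angle and arcs crossing 0 degrees are counted correctly.  A voxel whose
center coincides axially with some surface point, or whose tumor directions
spread over a half-turn or more, subtends the full circle — below the
half-turn threshold the minimal arc is unique and coverage is monotone in
the surface set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structures import StructureVolume

__all__ = [
    "SurfacePointSet",
    "DistanceMap",
    "OVHCurve",
    "POVCurve",
    "extract_surface",
    "signed_distance_map",
    "signed_distances_at",
    "compute_ovh",
    "compute_pov",
    "ovh",
    "fold_pov",
    "default_ovh_edges",
    "default_pov_angles",
]

# closed-arc membership tolerance in degrees; guards against last-ulp
# differences at arc endpoints that fall exactly on grid angles
ARC_TOL_DEG = 1e-9
# a voxel projecting within this of the nearest surface-point projection is
# treated as level with the tumor, not before it (boundary case is exact
# zero mathematically; the tolerance absorbs summation-order ulps)
BEFORE_TOL_MM = 1e-9

_CROSS_3D = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class EmptyMaskError(ValueError):
    """A structure required to be non-empty has no foreground voxels."""


@dataclass(frozen=True)
class SurfacePointSet:
    """Physical centers (mm) of the tumor's 6-connectivity boundary voxels,
    in lexicographic index order."""

    points: np.ndarray  # (n, 3) float, mm

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def axial(self) -> np.ndarray:
        """(n, 2) projections onto the axial (x, y) plane."""
        return self.points[:, :2]


@dataclass(frozen=True)
class DistanceMap:
    """Signed distance (mm) from every voxel center to the nearest tumor
    surface voxel center: negative inside the tumor, positive outside, zero
    on surface voxels."""

    values: np.ndarray  # 3D float array, mm
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def same_grid(self, vol: StructureVolume, atol: float = 1e-6) -> bool:
        return (
            self.values.shape == vol.shape
            and np.allclose(self.spacing, vol.spacing, atol=atol)
            and np.allclose(self.origin, vol.origin, atol=atol)
        )


@dataclass(frozen=True)
class OVHCurve:
    """Cumulative OAR volume fraction vs signed surface distance."""

    bin_edges: np.ndarray  # (m,) mm, uniform, increasing
    values: np.ndarray  # (m,) in [0, 1], non-decreasing


@dataclass(frozen=True)
class POVCurve:
    """OAR volume fraction covered by the tumor's angular arc vs axial angle."""

    angles: np.ndarray  # (m,) degrees on [0, 360), uniform
    values: np.ndarray  # (m,) in [0, 1]


def default_ovh_edges(lo: float = -10.0, hi: float = 150.0, step: float = 1.0) -> np.ndarray:
    """Uniform 1 mm distance grid on [-10, 150] mm."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def default_pov_angles(step: float = 1.0) -> np.ndarray:
    """Uniform degree grid on [0, 360)."""
    return np.arange(0.0, 360.0, step)


# ---------------------------------------------------------------------------
# surface extraction and signed distances
# ---------------------------------------------------------------------------


def extract_surface(gtv: StructureVolume) -> SurfacePointSet:
    """Centers of all 6-connectivity boundary voxels of the tumor mask.

    A mask voxel is a boundary voxel when at least one of its six
    face-neighbors is background or outside the image.  Points are returned
    in lexicographic index order.
    """
    if gtv.is_empty():
        raise EmptyMaskError(f"structure {gtv.name!r} has no voxels: missing GTVn contour?")
    # border_value=0: outside the image counts as background, so voxels on
    # the image boundary are surface voxels
    interior = ndimage.binary_erosion(gtv.mask, structure=_CROSS_3D, border_value=0)
    boundary = gtv.mask & ~interior
    idx = np.argwhere(boundary)
    pts = idx * np.asarray(gtv.spacing) + np.asarray(gtv.origin)
    return SurfacePointSet(points=pts.astype(float))


def signed_distances_at(
    gtv: StructureVolume,
    points_mm: np.ndarray,
    inside: np.ndarray,
    surface: SurfacePointSet | None = None,
) -> np.ndarray:
    """Signed distance (mm) from arbitrary physical points to the tumor
    surface: ``sign * min_k ||p - s_k||`` with sign -1 where ``inside``."""
    surf = surface if surface is not None else extract_surface(gtv)
    tree = cKDTree(surf.points)
    d, _ = tree.query(points_mm, k=1)
    sign = np.where(inside, -1.0, 1.0)
    return sign * d


def signed_distance_map(gtv: StructureVolume, surface: SurfacePointSet | None = None) -> DistanceMap:
    """Signed Euclidean distance transform with respect to the tumor's
    surface voxel centers, in mm, on the tumor's grid."""
    if gtv.is_empty():
        raise EmptyMaskError(f"structure {gtv.name!r} has no voxels: missing GTVn contour?")
    surf = surface if surface is not None else extract_surface(gtv)
    shape = gtv.shape
    grid = np.indices(shape).reshape(3, -1).T * np.asarray(gtv.spacing) + np.asarray(gtv.origin)
    d = signed_distances_at(gtv, grid, gtv.mask.reshape(-1), surface=surf)
    return DistanceMap(values=d.reshape(shape), spacing=gtv.spacing, origin=gtv.origin)


# ---------------------------------------------------------------------------
# OVH
# ---------------------------------------------------------------------------


def compute_ovh(dist: DistanceMap, oar: StructureVolume, bin_edges: np.ndarray) -> OVHCurve:
    """Cumulative histogram of signed surface distances within the OAR mask.

    ``OVH(d)`` is the fraction of OAR voxels whose signed distance is at most
    ``d``, evaluated at every edge of the (uniform) grid.  Distances outside
    the grid are clipped into the terminal bins, so the curve always ends
    at 1 and starts at the fraction of voxels at or below the lowest edge.
    """
    if oar.is_empty():
        raise EmptyMaskError(f"OAR {oar.name!r} has no voxels")
    if not dist.same_grid(oar):
        raise ValueError(
            f"distance map (shape {dist.values.shape}) and OAR {oar.name!r} "
            f"(shape {oar.shape}) are not on the same grid"
        )
    edges = np.asarray(bin_edges, dtype=float)
    r = dist.values[oar.mask]
    r = np.clip(r, edges[0], edges[-1])
    r.sort()
    counts = np.searchsorted(r, edges, side="right")
    return OVHCurve(bin_edges=edges, values=counts / r.size)


def ovh(
    gtv: StructureVolume,
    oar: StructureVolume,
    bin_edges: np.ndarray,
    surface: SurfacePointSet | None = None,
) -> OVHCurve:
    """OVH computed directly from the two masks, evaluating distances only at
    OAR voxels (equivalent to, and much cheaper than, building the full
    distance map first)."""
    if oar.is_empty():
        raise EmptyMaskError(f"OAR {oar.name!r} has no voxels")
    gtv.require_same_grid(oar)
    surf = surface if surface is not None else extract_surface(gtv)
    pts = oar.voxel_centers_mm()
    inside = gtv.mask[oar.mask]
    r = signed_distances_at(gtv, pts, inside, surface=surf)
    edges = np.asarray(bin_edges, dtype=float)
    r = np.clip(r, edges[0], edges[-1])
    r.sort()
    counts = np.searchsorted(r, edges, side="right")
    return OVHCurve(bin_edges=edges, values=counts / r.size)


# ---------------------------------------------------------------------------
# POV
# ---------------------------------------------------------------------------


def _minimal_arcs(theta: np.ndarray, coincident: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimal covering circular arc per row of ``theta`` (degrees in
    [0, 360)).  Returns (start, span); rows flagged ``coincident`` get the
    full circle (start 0, span 360).

    Once the direction spread reaches a half-turn (span >= 180 degrees)
    the voxel is treated as fully surrounded and gets the full circle:
    in the line-projection reading a projection line through the voxel
    intersects the tumor at every angle, and below 180 degrees the
    largest angular gap (hence the minimal arc) is unique, which keeps
    arc coverage monotone in the surface set.  Ties within tolerance of
    the half-turn threshold are resolved toward the full circle in both
    this implementation and the brute-force oracle.
    """
    srt = np.sort(theta, axis=1)
    n, s = theta.shape
    if s == 1:
        start = srt[:, 0].copy()
        span = np.zeros(n)
    else:
        gaps = np.diff(srt, axis=1)
        wrap = (srt[:, 0] + 360.0 - srt[:, -1])[:, None]
        all_gaps = np.concatenate([gaps, wrap], axis=1)
        imax = np.argmax(all_gaps, axis=1)
        rows = np.arange(n)
        span = 360.0 - all_gaps[rows, imax]
        starts_all = srt[:, (np.arange(s) + 1) % s]
        start = starts_all[rows, imax]
    full = coincident | (span >= 180.0 - ARC_TOL_DEG)
    start = np.where(full, 0.0, start)
    span = np.where(full, 360.0, span)
    return start, span


def compute_pov(
    surface: SurfacePointSet,
    oar: StructureVolume,
    angles: np.ndarray | None = None,
    occlusion: str = "none",
) -> POVCurve:
    """Angular-coverage histogram of the OAR relative to the tumor surface.

    For every OAR voxel center ``v`` the directions (axial-plane ``atan2``,
    degrees in [0, 360)) to all tumor surface points define a minimal
    covering circular arc, closed at both ends; the voxel contributes to
    ``POV(alpha)`` when ``alpha`` lies in its arc.  A voxel axially
    coincident with a surface point, or with tumor directions spreading
    over at least a half-turn, covers the full circle.

    ``occlusion="none"`` counts every such voxel.  ``occlusion="before"``
    additionally requires the voxel to lie upstream of the tumor for the
    projection direction: its axial projection onto the direction of
    ``alpha`` must be strictly smaller than that of every surface point
    (the voxel is "before" the tumor in the projection).
    """
    if oar.is_empty():
        raise EmptyMaskError(f"OAR {oar.name!r} has no voxels")
    if len(surface) == 0:
        raise EmptyMaskError("tumor surface point set is empty")
    if occlusion not in ("none", "before"):
        raise ValueError(f"unknown occlusion mode {occlusion!r}")
    alphas = np.asarray(default_pov_angles() if angles is None else angles, dtype=float)

    pts = oar.voxel_centers_mm()[:, :2]  # (n, 2) axial
    surf = surface.axial  # (s, 2)
    n = pts.shape[0]

    # per-(voxel, surface point) axial displacement angles
    dx = pts[:, 0][:, None] - surf[:, 0][None, :]
    dy = pts[:, 1][:, None] - surf[:, 1][None, :]
    coincident = np.any((dx == 0.0) & (dy == 0.0), axis=1)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    start, span = _minimal_arcs(theta, coincident)

    # closed-arc membership on the angle grid; the wrap-side branch keeps a
    # grid angle sitting one ulp below the arc start inside the closed arc
    rel = (alphas[None, :] - start[:, None]) % 360.0
    member = (rel <= span[:, None] + ARC_TOL_DEG) | (rel >= 360.0 - ARC_TOL_DEG)
    member[coincident, :] = True

    if occlusion == "before":
        rad = np.radians(alphas)
        u = np.stack([np.cos(rad), np.sin(rad)], axis=0)  # (2, m)
        t_vox = pts @ u  # (n, m)
        t_surf_min = (surf @ u).min(axis=0)  # (m,)
        member &= t_vox < t_surf_min[None, :] - BEFORE_TOL_MM

    return POVCurve(angles=alphas, values=member.sum(axis=0) / n)


def fold_pov(curve: POVCurve) -> POVCurve:
    """Fold a [0, 360) directional curve to [0, 180) projection angles by
    taking the maximum of each pair of opposite directions."""
    m = curve.angles.size
    if m % 2 != 0:
        raise ValueError("folding requires an even number of angle samples")
    half = m // 2
    vals = np.maximum(curve.values[:half], curve.values[half:])
    return POVCurve(angles=curve.angles[:half], values=vals)
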