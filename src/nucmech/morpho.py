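"""Nucleus segmentation and 3D shape descriptors.

Shape metrics:

    elongation = 1 - sqrt(intermediate / major)
    flatness   = 1 - sqrt(minor / major)
    sphericity = (36 * pi * V^2)^(1/3) / A

Axis lengths are full extents along the object's principal directions in
physical micrometers; along the minor direction a small quantile fraction
of voxels is clipped from each extreme before taking the extent, which
suppresses single-voxel irregularities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes, mesh_surface_area

from .imgio import VoxelImage


class SegmentationError(RuntimeError):
    pass


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NucleusMorphometry:
    label: int
    major_axis: float
    intermediate_axis: float
    minor_axis: float
    elongation: float
    flatness: float
    sphericity: float
    volume: float
    surface_area: float
    centroid: tuple[float, float, float]  # (z, y, x) um

    @property
    def height(self) -> float:
        return self.minor_axis

    @property
    def equivalent_diameter(self) -> float:
        """Volume-equivalent spherical diameter, (6V/pi)^(1/3)."""
        return float((6.0 * self.volume / np.pi) ** (1.0 / 3.0))


def segment_nucleus(
    img: VoxelImage,
    blur_sigma_um: float = 0.1,
    method: str = "otsu",
    multi_nucleus: bool = False,
    threshold: float | None = None,
) -> np.ndarray:
    """Blur (anisotropy-aware), threshold, and label 26-connected components.

    Returns an integer label volume; by default only the largest component
    is kept (label 1).  ``method='manual'`` uses the explicit ``threshold``.
    """
    if img.is_timeseries:
        raise ValueError("segment_nucleus expects a single-timepoint stack")
    data = img.data.astype(float)
    sigma_vox = blur_sigma_um / np.asarray(img.voxel_size)
    smoothed = ndimage.gaussian_filter(data, sigma=sigma_vox)
    if method == "otsu":
        if smoothed.max() == smoothed.min():
            raise SegmentationError("constant image: no separable foreground")
        thr = threshold_otsu(smoothed)
    elif method == "manual":
        if threshold is None:
            raise ValueError("method='manual' requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    fg = smoothed > thr
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")
    labels, n = ndimage.label(fg, structure=_STRUCT26)
    if n == 0:
        raise SegmentationError("no connected components found")
    if multi_nucleus:
        return labels
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return (labels == keep).astype(np.int32)


def principal_axes(
    nucleus: np.ndarray,
    voxel_size: tuple[float, float, float],
    trim_fraction: float = 0.001,
    label: int = 1,
) -> tuple[float, float, float]:
    """Full extents (um) along the principal directions of one labeled object.

    Voxel centers are mapped to physical coordinates, centered, and rotated
    into the principal frame (eigenvectors of the coordinate covariance).
    Each extent gains the voxel footprint projected on its direction so a
    one-voxel-thick object has a nonzero extent.  Along the minor direction,
    ``trim_fraction`` of voxels is clipped from each extreme first.
    """
    idx = np.argwhere(np.asarray(nucleus) == label)
    if len(idx) < 4:
        raise ValueError("degenerate object: need at least 4 voxels")
    coords = idx.astype(float) * np.asarray(voxel_size)
    coords -= coords.mean(axis=0)
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending: minor first
    extents = np.empty(3)
    for k in range(3):
        proj = coords @ evecs[:, k]
        vox_span = float(np.abs(evecs[:, k]) @ np.asarray(voxel_size))
        if k == 0 and trim_fraction > 0:
            lo, hi = np.quantile(proj, [trim_fraction, 1.0 - trim_fraction])
        else:
            lo, hi = proj.min(), proj.max()
        # centers span underestimates the surface-to-surface extent by up
        # to one voxel footprint; half a footprint is the unbiased midpoint
        extents[k] = (hi - lo) + 0.5 * vox_span
    minor, intermediate, major = extents
    if intermediate > major:  # near-degenerate eigenvalues can swap order
        major, intermediate = intermediate, major
    return float(major), float(intermediate), float(minor)


def volume_surface(
    nucleus: np.ndarray,
    voxel_size: tuple[float, float, float],
    area_method: str = "mesh",
    label: int = 1,
) -> tuple[float, float]:
    """Volume (voxel count x voxel volume) and surface area.

    ``area_method='mesh'`` triangulates the boundary (marching cubes with
    physical spacing); ``'voxel_faces'`` counts exposed voxel faces, which
    overestimates areas of smooth objects by the staircase bias but matches
    a literal voxel-count protocol.
    """
    mask = np.asarray(nucleus) == label
    if not mask.any():
        raise ValueError("empty object")
    vz, vy, vx = voxel_size
    volume = float(mask.sum()) * vz * vy * vx
    if area_method == "mesh":
        # smoothing the binary mask before meshing removes the staircase
        # bias (~9% overestimate raw -> <1% at sigma = 1 voxel)
        padded = np.pad(mask.astype(float), 3)
        smoothed = ndimage.gaussian_filter(padded, 1.0)
        if smoothed.max() <= 0.5:  # very thin objects vanish when smoothed
            smoothed = padded
        verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=voxel_size)
        area = float(mesh_surface_area(verts, faces))
    elif area_method == "voxel_faces":
        area = 0.0
        face_areas = (vy * vx, vz * vx, vz * vy)  # faces normal to z, y, x
        for axis, fa in enumerate(face_areas):
            padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
            diff = np.diff(padded.astype(np.int8), axis=axis)
            area += float(np.abs(diff).sum()) * fa
    else:
        raise ValueError(f"unknown area_method {area_method!r}")
    return volume, area


def shape_metrics(
    axes: tuple[float, float, float],
    volume: float,
    area: float,
    label: int = 1,
    centroid: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> NucleusMorphometry:
    major, intermediate, minor = axes
    if min(axes) <= 0:
        raise ValueError("axis lengths must be positive")
    if not (major >= intermediate >= minor):
        raise ValueError("axes must be ordered major >= intermediate >= minor")
    return NucleusMorphometry(
        label=label,
        major_axis=major,
        intermediate_axis=intermediate,
        minor_axis=minor,
        elongation=1.0 - np.sqrt(intermediate / major),
        flatness=1.0 - np.sqrt(minor / major),
        sphericity=float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area),
        volume=volume,
        surface_area=area,
        centroid=tuple(centroid),
    )


def measure_nucleus(
    img: VoxelImage,
    nucleus: np.ndarray,
    trim_fraction: float = 0.001,
    area_method: str = "mesh",
    label: int = 1,
) -> NucleusMorphometry:
    """Convenience wrapper: principal axes + volume/area + shape metrics."""
    axes = principal_axes(nucleus, img.voxel_size, trim_fraction, label=label)
    volume, area = volume_surface(nucleus, img.voxel_size, area_method, label=label)
    idx = np.argwhere(np.asarray(nucleus) == label)
    centroid = tuple(idx.mean(axis=0) * np.asarray(img.voxel_size))
    return shape_metrics(axes, volume, area, label=label, centroid=centroid)
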