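"""Condensate detection, radial/peripheral statistics and colocalization.

Detection follows an eroded-threshold labeling scheme: blur, Otsu
threshold restricted to the nucleus interior, binary erosion to split
touching objects, 26-connected labeling of the eroded cores, then
constrained re-expansion of each label inside the un-eroded mask (no
label merging).  Radial distances are scaled by the nucleus diameter,
peripheral distances by the nucleus height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .imgio import VoxelImage
from .morpho import NucleusMorphometry

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CondensateRecord:
    id: int
    nucleus_id: int
    center: tuple[float, float, float]  # (z, y, x) um
    volume: float  # um^3
    equivalent_diameter: float  # um
    radial_r: float | None = None
    peripheral_p: float | None = None
    is_control: bool = False
    outside_nucleus: bool = False


@dataclass
class ColocResult:
    nucleus_id: int
    manders_m1: float


def records_to_frame(records: list[CondensateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "nucleus_id": r.nucleus_id,
                "z_um": r.center[0],
                "y_um": r.center[1],
                "x_um": r.center[2],
                "volume_um3": r.volume,
                "equivalent_diameter_um": r.equivalent_diameter,
                "radial_r": r.radial_r,
                "peripheral_p": r.peripheral_p,
                "is_control": r.is_control,
            }
        )
    cols = [
        "id", "nucleus_id", "z_um", "y_um", "x_um", "volume_um3",
        "equivalent_diameter_um", "radial_r", "peripheral_p", "is_control",
    ]
    return pd.DataFrame(rows, columns=cols)


def detect_condensates(
    img: VoxelImage,
    nucleus: np.ndarray,
    blur_sigma_um: float = 0.08,
    n_erosions: int = 2,
    min_voxels: int = 5,
    nucleus_id: int = 1,
    rim_erosions: int = 4,
) -> tuple[np.ndarray, list[CondensateRecord]]:
    """Eroded-Otsu labeling of bright objects inside the nucleus mask.

    Returns the condensate label volume and per-object records.  Empty
    foreground yields an empty result, not an error.
    """
    if nucleus is None:
        raise ValueError("a nucleus mask is required")
    nuc = np.asarray(nucleus) > 0
    if not nuc.any():
        raise ValueError("nucleus mask is empty")
    data = img.data.astype(float)
    sigma_vox = blur_sigma_um / np.asarray(img.voxel_size)
    smoothed = ndimage.gaussian_filter(data, sigma=sigma_vox)
    # estimate the threshold on a rim-eroded interior: the partial-volume
    # rim otherwise dominates the histogram and Otsu splits rim vs core
    # instead of nucleoplasm vs condensates
    core = ndimage.binary_erosion(nuc, iterations=rim_erosions) if rim_erosions else nuc
    if not core.any():
        core = nuc
    inside = smoothed[core]
    if inside.max() == inside.min():
        return np.zeros_like(nuc, dtype=np.int32), []
    thr = threshold_otsu(inside)
    binary = (smoothed > thr) & nuc
    if not binary.any():
        return np.zeros_like(nuc, dtype=np.int32), []
    # bright objects are a small interior subpopulation; if thresholding
    # keeps a large share of the nucleus there is nothing punctate to label
    if binary.sum() > 0.25 * nuc.sum():
        return np.zeros_like(nuc, dtype=np.int32), []
    eroded = binary
    if n_erosions > 0:
        eroded = ndimage.binary_erosion(binary, iterations=n_erosions)
    if not eroded.any():
        return np.zeros_like(nuc, dtype=np.int32), []
    markers, _ = ndimage.label(eroded, structure=_STRUCT26)
    # re-expand each core within the un-eroded mask; watershed on the
    # negative distance transform keeps labels from merging
    edt = ndimage.distance_transform_edt(binary, sampling=img.voxel_size)
    labels = watershed(-edt, markers, mask=binary).astype(np.int32)

    records: list[CondensateRecord] = []
    vz, vy, vx = img.voxel_size
    voxel_vol = vz * vy * vx
    # nucleoplasm floor for half-max sizing: interior signal outside objects
    floor = float(np.median(smoothed[nuc & ~binary]))
    out = np.zeros_like(labels)
    next_id = 1
    for lab in range(1, labels.max() + 1):
        obj = labels == lab
        n_vox = int(obj.sum())
        if n_vox < min_voxels:
            continue
        out[obj] = next_id
        volume = n_vox * voxel_vol
        idx = np.argwhere(obj)
        center = tuple(idx.mean(axis=0) * np.asarray(img.voxel_size))
        # size at half maximum: the threshold-support volume depends on
        # where Otsu lands, the FWHM sub-mask does not
        peak = float(smoothed[obj].max())
        half = 0.5 * (peak + floor)
        v_half = max(int((smoothed[obj] >= half).sum()), 1) * voxel_vol
        records.append(
            CondensateRecord(
                id=next_id,
                nucleus_id=nucleus_id,
                center=center,
                volume=volume,
                equivalent_diameter=float((6.0 * v_half / np.pi) ** (1.0 / 3.0)),
            )
        )
        next_id += 1
    return out, records


def periphery_shell(
    nucleus: np.ndarray,
    voxel_size: tuple[float, float, float],
    fraction: float = 0.05,
) -> np.ndarray:
    """Outer shell of the nucleus: voxels whose distance-to-background
    (physical EDT) is within ``fraction`` of the maximal depth.  The surface
    voxel layer is always included so the fraction->0 limit is the surface."""
    mask = np.asarray(nucleus) > 0
    if not mask.any():
        raise ValueError("empty nucleus mask")
    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    inside = edt[mask]
    cut = max(fraction * float(inside.max()), float(inside.min()))
    return mask & (edt <= cut)


def nucleus_center(nucleus: np.ndarray, voxel_size) -> np.ndarray:
    idx = np.argwhere(np.asarray(nucleus) > 0)
    return idx.mean(axis=0) * np.asarray(voxel_size)


def radial_peripheral_distances(
    records: list[CondensateRecord],
    nucleus: np.ndarray,
    morph: NucleusMorphometry,
    voxel_size: tuple[float, float, float],
    periphery_fraction: float = 0.05,
    diameter_definition: str = "equivalent_sphere",
) -> list[CondensateRecord]:
    """Attach scaled radial (r) and peripheral (p) distances to records.

    r = |condensate center - nucleus center| / nucleus diameter;
    p = min Euclidean distance to a periphery voxel / nucleus height.
    Records whose center falls outside the nucleus mask are flagged and get
    no distances.
    """
    mask = np.asarray(nucleus) > 0
    vs = np.asarray(voxel_size)
    center = nucleus_center(mask, vs)
    if diameter_definition == "equivalent_sphere":
        diameter = morph.equivalent_diameter
    elif diameter_definition == "major_axis":
        diameter = morph.major_axis
    else:
        raise ValueError(f"unknown diameter_definition {diameter_definition!r}")
    height = morph.minor_axis
    shell = periphery_shell(mask, voxel_size, periphery_fraction)
    shell_pts = np.argwhere(shell) * vs
    tree = cKDTree(shell_pts)
    for rec in records:
        c = np.asarray(rec.center)
        vox = np.clip(np.round(c / vs).astype(int), 0, np.array(mask.shape) - 1)
        if not mask[tuple(vox)]:
            rec.outside_nucleus = True
            continue
        rec.radial_r = float(np.linalg.norm(c - center) / diameter)
        rec.peripheral_p = float(tree.query(c)[0] / height)
    return records


def sample_control_points(
    nucleus: np.ndarray,
    records: list[CondensateRecord],
    morph: NucleusMorphometry,
    voxel_size: tuple[float, float, float],
    seed: int = 0,
    periphery_fraction: float = 0.05,
    diameter_definition: str = "equivalent_sphere",
) -> list[CondensateRecord]:
    """Radius-matched random control points.

    For each condensate, the nucleus mask is eroded by that condensate's
    radius (EDT threshold in um) and a single voxel is drawn uniformly from
    the eroded region.  Each condensate uses an independent sub-stream of
    the run seed, so extending the record list never reshuffles earlier
    controls.  If the eroded region is empty the deepest voxel (EDT argmax)
    is used as a documented fallback.
    """
    mask = np.asarray(nucleus) > 0
    vs = np.asarray(voxel_size)
    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    controls: list[CondensateRecord] = []
    for rec in records:
        if rec.is_control:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, rec.id]))
        radius = rec.equivalent_diameter / 2.0
        region = np.argwhere(mask & (edt >= radius))
        if len(region) == 0:
            region = np.argwhere(edt == edt.max())
        pick = region[rng.integers(len(region))]
        center = tuple(pick * vs)
        controls.append(
            CondensateRecord(
                id=rec.id,
                nucleus_id=rec.nucleus_id,
                center=center,
                volume=rec.volume,
                equivalent_diameter=rec.equivalent_diameter,
                is_control=True,
            )
        )
    return radial_peripheral_distances(
        controls, nucleus, morph, voxel_size, periphery_fraction,
        diameter_definition,
    )


def manders_coefficient(
    labels_a: np.ndarray,
    img_a: VoxelImage,
    labels_b: np.ndarray,
    nucleus_id: int = 1,
) -> ColocResult:
    """M1 = sum(A intensity where A- and B-objects overlap) / sum(A intensity
    over A-object voxels)."""
    a = np.asarray(labels_a) > 0
    b = np.asarray(labels_b) > 0
    if not a.any():
        raise ValueError("channel-A object set is empty: M1 undefined")
    inten = img_a.data.astype(float)
    m1 = float(inten[a & b].sum() / inten[a].sum())
    return ColocResult(nucleus_id=nucleus_id, manders_m1=m1)


def scaled_total_volume(records: list[CondensateRecord], morph: NucleusMorphometry) -> float:
    """Total condensate volume divided by nucleus volume."""
    return float(sum(r.volume for r in records if not r.is_control) / morph.volume)
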