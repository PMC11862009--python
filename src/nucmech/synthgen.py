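"""Synthetic input generation with recorded ground truth.

Every generator is a pure function of its parameters and seed, so reruns
are bit-identical.  Axis conventions: volumetric quantities (semi-axes,
voxel sizes, spot centers) are ordered (z, y, x) in micrometers, matching
:class:`nucmech.imgio.VoxelImage`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .imgio import VoxelImage

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma -> FWHM factor


class PackingError(RuntimeError):
    """Spot placement failed under the separation/interior constraints."""


class SizingError(ValueError):
    """The requested ellipsoid does not fit in the voxel grid."""


@dataclass
class NucleusPhantomSpec:
    """Parameters of an ellipsoidal nucleus phantom with bright spots.

    ``semi_axes`` are (z, y, x) semi-axis lengths in um. ``snr`` is
    (post-blur spot peak - interior base) / interior-noise SD; ``np.inf``
    disables noise entirely.
    """

    semi_axes: tuple[float, float, float] = (1.4112, 8.0, 8.0)
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Euler zyx, rad
    n_spots: int = 8
    spot_diameter: float = 0.6
    spot_placement: str = "uniform"  # uniform | central | peripheral
    min_spot_separation: float = 1.5
    snr: float = 10.0
    psf_sigma: tuple[float, float, float] = (0.12, 0.08, 0.08)  # (z,y,x) um
    voxel_size: tuple[float, float, float] = (0.14, 0.08, 0.08)  # (z,y,x) um
    seed: int = 0
    background: float = 10.0
    interior_base: float = 100.0
    margin_um: float = 0.6

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.spot_placement not in ("uniform", "central", "peripheral"):
            raise ValueError(f"unknown spot_placement {self.spot_placement!r}")


@dataclass
class GroundTruth:
    """Exact generating parameters carried alongside every artifact."""

    true_axes: tuple[float, float, float] | None = None
    true_spot_centers: list[tuple[float, float, float]] = field(default_factory=list)
    true_spot_diameter: float | None = None
    true_alpha: float | None = None
    true_frap_params: tuple[float, float, float] | None = None  # (F0, Finf, t1)
    orientation: tuple[float, float, float] | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        raw["true_spot_centers"] = [tuple(c) for c in raw["true_spot_centers"]]
        for key in ("true_axes", "true_frap_params", "orientation"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _rotation(orientation) -> np.ndarray:
    """Rotation matrix acting on (z,y,x) physical offsets."""
    return Rotation.from_euler("zyx", orientation).as_matrix()


def _grid_for(spec: NucleusPhantomSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    rot = _rotation(spec.orientation)
    # extent of rotated ellipsoid along grid axis i: sqrt(sum_j (R_ij a_j)^2)
    half = np.sqrt((rot * np.asarray(spec.semi_axes)) ** 2 @ np.ones(3))
    half = half + spec.margin_um + spec.spot_diameter
    shape = tuple(int(np.ceil(2 * h / v)) + 1 for h, v in zip(half, spec.voxel_size))
    center = (np.array(shape) - 1) / 2.0 * np.asarray(spec.voxel_size)
    for h, c, v in zip(half, center, spec.voxel_size):
        if c < h - v:  # pragma: no cover - defensive
            raise SizingError("ellipsoid exceeds the voxel grid")
    return shape, center


def _ellipsoid_mask(shape, center, semi_axes, rot, voxel_size) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * v - c for n, v, c in zip(shape, voxel_size, center)],
        indexing="ij",
    )
    pts = np.stack([g.ravel() for g in grids])
    local = rot.T @ pts
    q = (local / np.asarray(semi_axes)[:, None]) ** 2
    return (q.sum(axis=0) <= 1.0).reshape(shape)


def _sample_spot_centers(spec: NucleusPhantomSpec, rng: np.random.Generator,
                         extra_exclude: np.ndarray | None = None) -> np.ndarray:
    """Rejection-sample spot centers strictly inside the ellipsoid (local
    frame, um, z,y,x) with pairwise separation >= min_spot_separation."""
    axes = np.asarray(spec.semi_axes)
    r_spot = spec.spot_diameter / 2.0
    eff = axes - r_spot - 0.05
    if np.any(eff <= 0):
        raise PackingError("spot diameter exceeds the ellipsoid interior")
    lo, hi = {
        "uniform": (0.0, 1.0),
        "central": (0.0, 0.5),
        "peripheral": (0.7, 1.0),
    }[spec.spot_placement]
    centers: list[np.ndarray] = []
    existing = [] if extra_exclude is None else [np.asarray(p) for p in extra_exclude]
    attempts = 0
    while len(centers) < spec.n_spots:
        attempts += 1
        if attempts > 10_000:
            raise PackingError(
                f"could not place {spec.n_spots} spots with separation "
                f">= {spec.min_spot_separation} um in 10000 attempts"
            )
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        # radius with uniform-in-ellipsoid density restricted to [lo, hi]
        rad = (lo**3 + (hi**3 - lo**3) * rng.random()) ** (1.0 / 3.0)
        cand = u * rad * eff
        ok = all(
            np.linalg.norm(cand - p) >= spec.min_spot_separation
            for p in centers + existing
        )
        if ok:
            centers.append(cand)
    return np.array(centers).reshape(len(centers), 3)


def _psf_attenuation(spot_sigma: float, psf_sigma) -> float:
    psf = np.asarray(psf_sigma)
    return float(np.prod(spot_sigma / np.sqrt(spot_sigma**2 + psf**2)))


def _render(spec: NucleusPhantomSpec, centers_global: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    shape, center = _grid_for(spec)
    rot = _rotation(spec.orientation)
    mask = _ellipsoid_mask(shape, center, spec.semi_axes, rot, spec.voxel_size)
    clean = np.where(mask, spec.interior_base, spec.background).astype(float)

    read_sd = 2.0
    interior_sd = np.sqrt(spec.interior_base + read_sd**2)
    snr = spec.snr
    amp_post = (20.0 if not np.isfinite(snr) else snr) * interior_sd
    spot_sigma = spec.spot_diameter / _FWHM
    amp_pre = amp_post / _psf_attenuation(spot_sigma, spec.psf_sigma)

    # render each spot only inside a +-5 sigma crop for speed
    for c in centers_global:
        los, his, axes_1d = [], [], []
        for n, v, ci in zip(shape, spec.voxel_size, c):
            lo = max(0, int((ci - 5 * spot_sigma) / v))
            hi = min(n, int((ci + 5 * spot_sigma) / v) + 2)
            los.append(lo)
            his.append(hi)
            axes_1d.append(np.arange(lo, hi) * v - ci)
        d2 = (
            axes_1d[0][:, None, None] ** 2
            + axes_1d[1][None, :, None] ** 2
            + axes_1d[2][None, None, :] ** 2
        )
        clean[los[0]:his[0], los[1]:his[1], los[2]:his[2]] += amp_pre * np.exp(
            -0.5 * d2 / spot_sigma**2
        )

    sigma_vox = np.asarray(spec.psf_sigma) / np.asarray(spec.voxel_size)
    blurred = gaussian_filter(clean, sigma=sigma_vox)
    if not np.isfinite(snr):
        return blurred
    noisy = rng.poisson(np.clip(blurred, 0, None)).astype(float)
    noisy += rng.normal(0.0, read_sd, size=noisy.shape)
    return noisy


def gen_nucleus_stack(spec: NucleusPhantomSpec) -> tuple[VoxelImage, GroundTruth]:
    """Render an ellipsoidal nucleus with Gaussian spots, anisotropic PSF
    blur and Poisson-Gaussian noise; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    shape, grid_center = _grid_for(spec)
    rot = _rotation(spec.orientation)
    local = _sample_spot_centers(spec, rng)
    centers_global = (rot @ local.T).T + grid_center if len(local) else local
    data = _render(spec, centers_global, rng)
    truth = GroundTruth(
        true_axes=tuple(spec.semi_axes),
        true_spot_centers=[tuple(c) for c in centers_global],
        true_spot_diameter=spec.spot_diameter,
        orientation=tuple(spec.orientation),
        extras={"grid_center_um": list(grid_center)},
    )
    return VoxelImage(data, spec.voxel_size), truth


def gen_two_channel(
    spec: NucleusPhantomSpec, overlap_fraction: float
) -> tuple[VoxelImage, VoxelImage, GroundTruth]:
    """Two co-registered channels whose spot sets overlap by the requested
    fraction: round(f*n) channel-B spots coincide with channel-A spots, the
    rest are placed disjointly (separation >= 2 spot diameters)."""
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    shape, grid_center = _grid_for(spec)
    rot = _rotation(spec.orientation)
    sep = max(spec.min_spot_separation, 2.0 * spec.spot_diameter)
    spec_a = dataclasses.replace(spec, min_spot_separation=sep)
    local_a = _sample_spot_centers(spec_a, rng)
    n_shared = int(round(overlap_fraction * spec.n_spots))
    n_new = spec.n_spots - n_shared
    spec_b = dataclasses.replace(spec_a, n_spots=n_new)
    local_b_new = _sample_spot_centers(spec_b, rng, extra_exclude=local_a)
    local_b = np.vstack([local_a[:n_shared], local_b_new.reshape(-1, 3)])

    glob_a = (rot @ local_a.T).T + grid_center if len(local_a) else local_a
    glob_b = (rot @ local_b.T).T + grid_center if len(local_b) else local_b
    img_a = VoxelImage(_render(spec, glob_a, rng), spec.voxel_size, channel="A")
    img_b = VoxelImage(_render(spec, glob_b, rng), spec.voxel_size, channel="B")
    truth = GroundTruth(
        true_axes=tuple(spec.semi_axes),
        true_spot_centers=[tuple(c) for c in glob_a],
        true_spot_diameter=spec.spot_diameter,
        extras={
            "overlap_fraction": overlap_fraction,
            "n_shared": n_shared,
            "channel_b_centers": [list(c) for c in glob_b],
        },
    )
    return img_a, img_b, truth


# ---------------------------------------------------------------------------
# fractional Brownian motion tracks


def _fgn_cholesky(n: int, hurst: float) -> np.ndarray:
    """Lower Cholesky factor of the unit fractional-Gaussian-noise covariance."""
    k = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    cov = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    # tiny jitter guards against numerical loss of positive definiteness
    return np.linalg.cholesky(cov + 1e-12 * np.eye(n))


def gen_tracks_fbm(
    n_tracks: int,
    hurst: float,
    n_steps: int,
    dt: float = 30.0,
    step_scale: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """2D fractional-Brownian tracks with exact increment covariance
    (Cholesky synthesis per axis); E[MSD(t)] ~ t^(2*hurst).

    Returns a long-format track table with columns
    (track_id, frame, t_min, x_um, y_um).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    chol = _fgn_cholesky(n_steps, hurst)
    rows = []
    t = np.arange(n_steps + 1) * dt
    for tid in range(n_tracks):
        incr = step_scale * (chol @ rng.standard_normal((n_steps, 2)))
        pos = np.vstack([np.zeros(2), np.cumsum(incr, axis=0)])
        for f in range(n_steps + 1):
            rows.append((tid, f, t[f], pos[f, 0], pos[f, 1]))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "t_min", "x_um", "y_um"])
    truth = GroundTruth(true_alpha=2.0 * hurst, extras={"hurst": hurst, "dt_min": dt})
    return df, truth


# ---------------------------------------------------------------------------
# FRAP curves


def frap_model(t: np.ndarray, f0: float, finf: float, t1: float) -> np.ndarray:
    """Single-diffusion recovery: F(t) = (F0 + Finf*(t/t1)/2) / (1 + (t/t1)/2)."""
    x = (np.asarray(t, dtype=float) / t1) / 2.0
    return (f0 + finf * x) / (1.0 + x)


def gen_frap_curve(
    f0: float,
    finf: float,
    t1: float,
    n_points: int = 600,
    dt: float = 0.1,
    noise_sd: float = 0.0,
    bleach_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample the recovery model, apply exponential acquisition bleaching
    and Gaussian noise.  Returns (curve table with time_s/intensity, truth)."""
    if not (0.0 <= f0 <= finf <= 1.0):
        raise ValueError("require 0 <= F0 <= Finf <= 1")
    if t1 <= 0:
        raise ValueError("t1 must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt
    f = frap_model(t, f0, finf, t1) * np.exp(-bleach_rate * t)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    df = pd.DataFrame({"time_s": t, "intensity": f})
    truth = GroundTruth(
        true_frap_params=(f0, finf, t1),
        extras={"noise_sd": noise_sd, "bleach_rate": bleach_rate},
    )
    return df, truth


# ---------------------------------------------------------------------------
# blocky ChIP-like 1-Mb signal

#: default chromosome-arm bin counts (Mb); chosen to total 258 bins
DEFAULT_ARM_LENGTHS: dict[str, int] = {
    "chr8p": 40,
    "chr13q": 85,
    "chr14q": 78,
    "chr19p": 23,
    "chr22q": 32,
}


def gen_chip_track(
    arm_lengths_mb: dict[str, int] | None = None,
    domain_mean_len_mb: float = 3.0,
    off_mean_len_mb: float = 7.0,
    lognorm_mu: float = 0.0,
    lognorm_sigma: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-arm 1-Mb binned nonnegative signal with contiguous on/off domains.

    Domain lengths follow a two-state Markov chain (geometric lengths with
    the given means); on-bins draw log-normal intensities; off-bins are
    exactly zero and mark non-bound monomers downstream.
    """
    if arm_lengths_mb is None:
        arm_lengths_mb = dict(DEFAULT_ARM_LENGTHS)
    if not arm_lengths_mb:
        raise ValueError("arm_lengths_mb must not be empty")
    if any(n < 1 for n in arm_lengths_mb.values()):
        raise ValueError("every arm must span at least 1 Mb")
    rng = np.random.default_rng(seed)
    p_leave_on = 0.0 if domain_mean_len_mb <= 0 else min(1.0, 1.0 / domain_mean_len_mb)
    p_leave_off = min(1.0, 1.0 / off_mean_len_mb)
    all_off = domain_mean_len_mb <= 0
    rows = []
    for arm, n_bins in arm_lengths_mb.items():
        state = (not all_off) and rng.random() < 0.5
        for i in range(n_bins):
            value = (
                float(rng.lognormal(lognorm_mu, lognorm_sigma)) if state else 0.0
            )
            rows.append((arm, i * 1_000_000, (i + 1) * 1_000_000, value))
            if not all_off:
                flip = rng.random() < (p_leave_on if state else p_leave_off)
                state = state ^ flip
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
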