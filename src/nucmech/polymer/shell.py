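"""Rigid confinement shells: sizing and static wall-monomer placement.

The shell volume is fixed by the monomer volume fraction:
V_shell = n_monomers * (pi/6) sigma^3 / phi.  Shapes are a sphere and two
oblate spheroids with aspect ratios c/a = 1/2 and 1/3, all at equal
volume.  Wall monomers sit on the surface on an area-weighted Fibonacci
lattice and never move.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

SHAPE_ASPECTS: dict[str, float] = {"sphere": 1.0, "oblate_0.5": 0.5, "oblate_0.33": 1.0 / 3.0}


class WallSpacingError(RuntimeError):
    """Wall monomers are spaced too far apart to guarantee confinement."""


@dataclass
class ShellSpec:
    shape: str
    a: float  # equatorial semi-axis, sigma
    c: float  # polar semi-axis, sigma
    phi: float
    n_monomers: int
    wall: np.ndarray = field(repr=False)  # (n_wall, 3) static coordinates

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.a**2 * self.c

    @property
    def achieved_phi(self) -> float:
        return self.n_monomers * (np.pi / 6.0) / self.volume

    def normalized_radius(self, pos: np.ndarray) -> np.ndarray:
        """Ellipsoidal coordinate: <1 inside, 1 on the surface."""
        p = np.atleast_2d(pos)
        return np.sqrt(
            (p[:, 0] / self.a) ** 2 + (p[:, 1] / self.a) ** 2 + (p[:, 2] / self.c) ** 2
        )

    def signed_distance(self, pos: np.ndarray) -> np.ndarray:
        """Euclidean distance to the surface, negative inside."""
        p = np.atleast_2d(pos)
        inside = self.normalized_radius(p) < 1.0
        d = np.array(
            [ellipsoid_surface_distance(pt, self.a, self.c) for pt in p]
        )
        return np.where(inside, -d, d)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "shape": self.shape,
                    "a": self.a,
                    "c": self.c,
                    "phi": self.phi,
                    "n_monomers": self.n_monomers,
                    "wall": self.wall.tolist(),
                }
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ShellSpec":
        raw = json.loads(Path(path).read_text())
        raw["wall"] = np.asarray(raw["wall"], dtype=float)
        return cls(**raw)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi_ang = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi_ang), r * np.sin(phi_ang), z])


def oblate_area(a: float, c: float) -> float:
    if np.isclose(a, c):
        return 4.0 * np.pi * a**2
    e = np.sqrt(1.0 - (c / a) ** 2)
    return 2.0 * np.pi * a**2 * (1.0 + (c**2 / (a**2 * e)) * np.arctanh(e))


def build_shell(
    shape: str,
    n_monomers: int = 258,
    phi: float = 0.10,
    n_wall: int | None = None,
    max_gap: float = 1.0,
) -> ShellSpec:
    """Size the shell for the target volume fraction and tile its surface
    with static wall monomers.

    Raises :class:`WallSpacingError` if the largest nearest-neighbor wall
    gap cannot be brought below ``max_gap`` sigma (a leaky wall).
    """
    if shape not in SHAPE_ASPECTS:
        raise ValueError(f"unknown shape {shape!r}; expected one of {sorted(SHAPE_ASPECTS)}")
    if not 0.0 < phi < 0.4:
        raise ValueError("phi must lie in (0, 0.4)")
    aspect = SHAPE_ASPECTS[shape]
    volume = n_monomers * (np.pi / 6.0) / phi
    # (4/3) pi a^3 (c/a) = volume
    a = (3.0 * volume / (4.0 * np.pi * aspect)) ** (1.0 / 3.0)
    c = aspect * a
    if n_wall is None:
        n_wall = int(np.ceil(1.6 * oblate_area(a, c)))
    for _ in range(5):
        unit = _fibonacci_sphere(n_wall)
        wall = unit * np.array([a, a, c])
        tree = cKDTree(wall)
        dists, _ = tree.query(wall, k=2)
        gap = float(dists[:, 1].max())
        if gap <= max_gap:
            return ShellSpec(
                shape=shape, a=float(a), c=float(c), phi=phi,
                n_monomers=n_monomers, wall=wall,
            )
        n_wall = int(np.ceil(n_wall * 1.4))
    raise WallSpacingError(
        f"wall gap {gap:.3f} sigma > {max_gap}; increase n_wall beyond {n_wall}"
    )


def ellipsoid_surface_distance(point, a: float, c: float) -> float:
    """Euclidean distance from a point to the surface of the axisymmetric
    ellipsoid x^2/a^2 + y^2/a^2 + z^2/c^2 = 1 (valid inside and outside).

    Reduces to the point-to-ellipse problem in the (rho, z) half-plane and
    solves the Lagrange condition by bisection, which is robust for all
    point positions including the center and the axes.
    """
    x, y, z = (float(v) for v in np.asarray(point, dtype=float))
    rho = float(np.hypot(x, y))
    e0, e1 = float(a), float(c)
    y0 = max(rho, 1e-12)
    y1 = max(abs(z), 1e-12)
    gap = e0**2 - e1**2  # >= 0 for oblate/spherical shells

    # Lagrange condition in u = t + e1^2 (avoids cancellation near the
    # center where the root sits at u ~ e1*y1)
    def f(u: float) -> float:
        return (e0 * y0 / (u + gap)) ** 2 + (e1 * y1 / u) ** 2 - 1.0

    lo = e1 * y1  # f(lo) >= 0 always
    hi = max(e0 * y0, e1 * y1) + y0**2 + y1**2 + 1.0
    while f(hi) > 0:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    u = 0.5 * (lo + hi)
    cx = e0**2 * y0 / (u + gap)
    cz = e1**2 * y1 / u
    return float(np.hypot(y0 - cx, y1 - cz))
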