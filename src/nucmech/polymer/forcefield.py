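"""Bonded and non-bonded potentials in reduced units (sigma = kBT = 1).

    U_FENE(r)  = -0.5 k R0^2 ln(1 - (r/R0)^2),  r < R0
    U_bend(th) = k_theta (1 - cos th)
    U_LJ(r)    = 4 eps [(sigma/r)^12 - (sigma/r)^6]

Attractive pairs truncate the LJ at ``lj_cutoff`` (default 2.5 sigma);
pairs with zero attraction use the purely repulsive WCA form (truncated at
2^(1/6) sigma and shifted so the energy is continuous at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass
class ForceField:
    fene_k: float = 30.0
    fene_r0: float = 1.5
    bend_k: float = 1.0
    lj_cutoff: float = 2.5
    sigma: float = 1.0
    # phantom-chain mode: disables all non-bonded monomer-monomer terms
    # (bond FENE+WCA and bending stay); walls still repel
    excluded_volume: bool = True
    # wall attraction depth for bound monomers (eps_iw = sqrt(eps_i * wall_eps));
    # 0 = purely repulsive WCA walls
    wall_eps: float = 0.0


class FeneOverstretchError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension R0."""


def fene_energy(r, k: float = 30.0, r0: float = 1.5):
    r = np.asarray(r, dtype=float)
    if np.any(r >= r0):
        raise FeneOverstretchError(f"bond length >= R0={r0}")
    return -0.5 * k * r0**2 * np.log(1.0 - (r / r0) ** 2)


def fene_force_mag(r, k: float = 30.0, r0: float = 1.5):
    """Magnitude of -dU/dr (positive = attractive restoring force)."""
    r = np.asarray(r, dtype=float)
    return -k * r / (1.0 - (r / r0) ** 2)


def bend_energy(theta, k_theta: float = 1.0):
    return k_theta * (1.0 - np.cos(np.asarray(theta, dtype=float)))


def lj_energy(r, eps: float, sigma: float = 1.0, cutoff: float = 2.5):
    """Truncated (unshifted) Lennard-Jones; zero beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6**2 - sr6)
    return np.where(r < cutoff, u, 0.0)


def wca_energy(r, eps: float = 1.0, sigma: float = 1.0):
    """Purely repulsive cut-and-shifted LJ (zero at and beyond 2^(1/6) sigma)."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6**2 - sr6) + eps
    return np.where(r < WCA_CUTOFF * sigma, u, 0.0)


def pair_energy(r, eps_ij: float, sigma: float = 1.0, cutoff: float = 2.5):
    """Dispatch rule: attractive pairs (eps_ij > 0) use truncated LJ with
    well depth eps_ij; non-attractive pairs use unit-strength WCA."""
    if eps_ij > 0.0:
        return lj_energy(r, eps_ij, sigma, cutoff)
    return wca_energy(r, 1.0, sigma)


def equilibrium_bond_length(k: float = 30.0, r0: float = 1.5) -> float:
    """Minimizer of U_FENE + U_WCA, the expected mean bond length (~0.97)."""
    from scipy.optimize import minimize_scalar

    def u(r):
        return float(fene_energy(r, k, r0) + wca_energy(r, 1.0))

    res = minimize_scalar(u, bounds=(0.5, r0 - 1e-9), method="bounded")
    return float(res.x)
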