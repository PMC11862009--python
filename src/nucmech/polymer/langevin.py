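"""Langevin dynamics of the confined bead-spring model.

BAOAB splitting at kBT = 1 and unit mass; forces are evaluated over a
Verlet neighbor list (skin 0.3 sigma) rebuilt whenever any particle has
moved half the skin since the last build.  Noise is pre-generated per
sampling chunk from a NumPy generator, so identical config + seed gives
bit-identical trajectories.  An exact all-pairs energy routine is kept in
plain NumPy for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .forcefield import WCA_CUTOFF, FeneOverstretchError, ForceField
from .shell import ShellSpec
from .system import PolymerSystem


@njit(cache=True)
def _build_pairs(pos, wall, r_list2, pairs_mm, pairs_mw):
    n = pos.shape[0]
    nw = wall.shape[0]
    n_mm = 0
    cap_mm = pairs_mm.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < r_list2:
                if n_mm < cap_mm:
                    pairs_mm[n_mm, 0] = i
                    pairs_mm[n_mm, 1] = j
                n_mm += 1
    n_mw = 0
    cap_mw = pairs_mw.shape[0]
    r_wca2 = r_list2  # same list cutoff; wall LJ may extend to lj_cut
    for i in range(n):
        for j in range(nw):
            dx = pos[i, 0] - wall[j, 0]
            dy = pos[i, 1] - wall[j, 1]
            dz = pos[i, 2] - wall[j, 2]
            if dx * dx + dy * dy + dz * dz < r_wca2:
                if n_mw < cap_mw:
                    pairs_mw[n_mw, 0] = i
                    pairs_mw[n_mw, 1] = j
                n_mw += 1
    return n_mm, n_mw


@njit(cache=True)
def _forces(pos, wall, bonds, angles, chain_id, eps, pairs_mm, n_mm,
            pairs_mw, n_mw, fene_k, fene_r0, bend_k, lj_cut, force_cap,
            pair_on, wall_eps, out):
    n = pos.shape[0]
    for i in range(n):
        out[i, 0] = 0.0
        out[i, 1] = 0.0
        out[i, 2] = 0.0
    r02 = fene_r0 * fene_r0
    wca2 = WCA_CUTOFF * WCA_CUTOFF
    lj2 = lj_cut * lj_cut
    # non-bonded monomer-monomer (1-2 and 1-3 along a chain excluded)
    for p in range(n_mm * pair_on):
        i = pairs_mm[p, 0]
        j = pairs_mm[p, 1]
        if chain_id[i] == chain_id[j] and j - i <= 2:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if eps[i] > 0.0 and eps[j] > 0.0:
            e = np.sqrt(eps[i] * eps[j])
            cut2 = lj2
        else:
            e = 1.0
            cut2 = wca2
        if r2 >= cut2 or r2 <= 0.0:
            continue
        inv2 = 1.0 / r2
        sr6 = inv2 * inv2 * inv2
        fr = 24.0 * e * (2.0 * sr6 * sr6 - sr6) * inv2
        out[i, 0] += fr * dx
        out[i, 1] += fr * dy
        out[i, 2] += fr * dz
        out[j, 0] -= fr * dx
        out[j, 1] -= fr * dy
        out[j, 2] -= fr * dz
    # monomer-wall: WCA by default; bound monomers feel LJ attraction when
    # wall_eps > 0 (same geometric mixing as monomer pairs)
    for p in range(n_mw):
        i = pairs_mw[p, 0]
        j = pairs_mw[p, 1]
        dx = pos[i, 0] - wall[j, 0]
        dy = pos[i, 1] - wall[j, 1]
        dz = pos[i, 2] - wall[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if wall_eps > 0.0 and eps[i] > 0.0:
            e = np.sqrt(eps[i] * wall_eps)
            cut2 = lj2
        else:
            e = 1.0
            cut2 = wca2
        if r2 >= cut2 or r2 <= 0.0:
            continue
        inv2 = 1.0 / r2
        sr6 = inv2 * inv2 * inv2
        fr = 24.0 * e * (2.0 * sr6 * sr6 - sr6) * inv2
        out[i, 0] += fr * dx
        out[i, 1] += fr * dy
        out[i, 2] += fr * dz
    if force_cap > 0.0:  # cap only non-bonded forces; bonds must always restore
        for i in range(n):
            fn = np.sqrt(out[i, 0] ** 2 + out[i, 1] ** 2 + out[i, 2] ** 2)
            if fn > force_cap:
                s = force_cap / fn
                out[i, 0] *= s
                out[i, 1] *= s
                out[i, 2] *= s
    # bonds: FENE + WCA (the pair loop excludes 1-2 and 1-3 neighbors so
    # the bending term alone controls chain stiffness)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return 1  # overstretch -> abort
        g = -fene_k / (1.0 - r2 / r02)
        if r2 < wca2:
            inv2 = 1.0 / r2
            sr6 = inv2 * inv2 * inv2
            g += 24.0 * (2.0 * sr6 * sr6 - sr6) * inv2
        out[i, 0] += g * dx
        out[i, 1] += g * dy
        out[i, 2] += g * dz
        out[j, 0] -= g * dx
        out[j, 1] -= g * dy
        out[j, 2] -= g * dz
    # bending: U = k (1 - cos theta), theta between consecutive bond vectors
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        inv12 = 1.0 / (n1 * n2)
        dot = b1x * b2x + b1y * b2y + b1z * b2z
        cth = dot * inv12
        # g1 = d cos/d b1, g2 = d cos/d b2
        g1x = b2x * inv12 - cth * b1x / (n1 * n1)
        g1y = b2y * inv12 - cth * b1y / (n1 * n1)
        g1z = b2z * inv12 - cth * b1z / (n1 * n1)
        g2x = b1x * inv12 - cth * b2x / (n2 * n2)
        g2y = b1y * inv12 - cth * b2y / (n2 * n2)
        g2z = b1z * inv12 - cth * b2z / (n2 * n2)
        out[i, 0] -= bend_k * g1x
        out[i, 1] -= bend_k * g1y
        out[i, 2] -= bend_k * g1z
        out[j, 0] += bend_k * (g1x - g2x)
        out[j, 1] += bend_k * (g1y - g2y)
        out[j, 2] += bend_k * (g1z - g2z)
        out[k, 0] += bend_k * g2x
        out[k, 1] += bend_k * g2y
        out[k, 2] += bend_k * g2z
    for i in range(n):
        if not (np.isfinite(out[i, 0]) and np.isfinite(out[i, 1]) and np.isfinite(out[i, 2])):
            return 2
    return 0


@njit(cache=True)
def _run_chunk(pos, vel, forces, wall, bonds, angles, chain_id, eps, noise,
               dt, c1, c2, fene_k, fene_r0, bend_k, lj_cut, force_cap, pair_on,
               wall_eps, r_list2, skin_half2, pairs_mm, pairs_mw, counts, pos_at_build):
    n_steps = noise.shape[0]
    n = pos.shape[0]
    n_mm = counts[0]
    n_mw = counts[1]
    for s in range(n_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
        for i in range(n):
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * noise[s, i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
        # neighbor-list validity
        max_d2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - pos_at_build[i, 0]
            dy = pos[i, 1] - pos_at_build[i, 1]
            dz = pos[i, 2] - pos_at_build[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_d2:
                max_d2 = d2
        if max_d2 > skin_half2:
            n_mm, n_mw = _build_pairs(pos, wall, r_list2, pairs_mm, pairs_mw)
            if n_mm > pairs_mm.shape[0] or n_mw > pairs_mw.shape[0]:
                counts[0] = n_mm
                counts[1] = n_mw
                return 3  # capacity overflow; caller reallocates
            for i in range(n):
                for d in range(3):
                    pos_at_build[i, d] = pos[i, d]
        status = _forces(pos, wall, bonds, angles, chain_id, eps, pairs_mm,
                         n_mm, pairs_mw, n_mw, fene_k, fene_r0, bend_k,
                         lj_cut, force_cap, pair_on, wall_eps, forces)
        if status != 0:
            counts[0] = n_mm
            counts[1] = n_mw
            return status
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d]
    counts[0] = n_mm
    counts[1] = n_mw
    return 0


@dataclass
class Trajectory:
    frames: list[np.ndarray]
    times: list[float]
    energies: pd.DataFrame
    system: PolymerSystem = field(repr=False)


def potential_energy(system: PolymerSystem, pos: np.ndarray | None = None) -> float:
    """Exact all-pairs potential energy in plain NumPy (oracle route)."""
    from . import forcefield as ff

    pos = system.positions if pos is None else pos
    f = system.forcefield
    total = 0.0
    bonds = system.bonds
    if len(bonds):
        d = np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)
        total += float(np.sum(ff.fene_energy(d, f.fene_k, f.fene_r0)))
        total += float(np.sum(ff.wca_energy(d, 1.0)))
    angles = system.angles
    if len(angles):
        b1 = pos[angles[:, 1]] - pos[angles[:, 0]]
        b2 = pos[angles[:, 2]] - pos[angles[:, 1]]
        cth = np.sum(b1 * b2, axis=1) / (
            np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1)
        )
        total += float(np.sum(f.bend_k * (1.0 - cth)))
    n = len(pos)
    if n > 1 and f.excluded_volume:
        chain_id = system.chain_id
        diff = pos[:, None, :] - pos[None, :, :]
        r = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(n, k=1)
        eps_ij = np.sqrt(np.outer(system.eps, system.eps))
        for i, j in zip(*iu):
            if chain_id[i] == chain_id[j] and j - i <= 2:
                continue
            total += float(ff.pair_energy(r[i, j], eps_ij[i, j], cutoff=f.lj_cutoff))
    if system.shell is not None and len(system.shell.wall):
        dw = np.linalg.norm(pos[:, None, :] - system.shell.wall[None, :, :], axis=2)
        for i in range(n):
            if f.wall_eps > 0.0 and system.eps[i] > 0.0:
                e_iw = float(np.sqrt(system.eps[i] * f.wall_eps))
                total += float(np.sum(ff.lj_energy(dw[i], e_iw, cutoff=f.lj_cutoff)))
            else:
                close = dw[i] < WCA_CUTOFF
                if close.any():
                    total += float(np.sum(ff.wca_energy(dw[i][close], 1.0)))
    return total


def run_langevin(
    system: PolymerSystem,
    n_steps: int,
    dt: float = 0.01,
    gamma: float = 1.0,
    sample_every: int = 1000,
    seed: int | None = None,
    force_cap: float = 0.0,
    skin: float = 0.3,
) -> Trajectory:
    """Integrate and sample frames every ``sample_every`` steps.

    ``force_cap > 0`` clips per-particle force norms (used for the initial
    push-off after growth); leave at 0 for production.  Aborts with the
    last good frame attached on FENE overstretch or non-finite forces.
    """
    f = system.forcefield
    pos = system.positions.astype(np.float64).copy()
    vel = system.velocities.astype(np.float64).copy()
    wall = (
        system.shell.wall.astype(np.float64)
        if system.shell is not None
        else np.zeros((0, 3))
    )
    bonds = system.bonds
    angles = system.angles
    chain_id = system.chain_id
    eps = system.eps.astype(np.float64)
    rng = np.random.default_rng(system.seed + 7_919 if seed is None else seed)

    r_list = f.lj_cutoff + skin
    cap_mm, cap_mw = max(64, system.n * 120), max(64, system.n * 80)
    while True:
        pairs_mm = np.zeros((cap_mm, 2), dtype=np.int64)
        pairs_mw = np.zeros((cap_mw, 2), dtype=np.int64)
        n_mm, n_mw = _build_pairs(pos, wall, r_list**2, pairs_mm, pairs_mw)
        if n_mm <= cap_mm and n_mw <= cap_mw:
            break
        cap_mm, cap_mw = 2 * max(cap_mm, n_mm), 2 * max(cap_mw, n_mw)
    counts = np.array([n_mm, n_mw], dtype=np.int64)
    pos_at_build = pos.copy()
    forces = np.zeros_like(pos)
    pair_on = 1 if f.excluded_volume else 0
    status = _forces(pos, wall, bonds, angles, chain_id, eps, pairs_mm,
                     counts[0], pairs_mw, counts[1], f.fene_k, f.fene_r0,
                     f.bend_k, f.lj_cutoff, force_cap, pair_on, f.wall_eps, forces)
    if status != 0:
        raise FeneOverstretchError("initial configuration has an invalid bond")

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)  # kBT = 1, m = 1
    frames: list[np.ndarray] = []
    times: list[float] = []
    erows: list[tuple] = []

    def record(t_now: float) -> None:
        frames.append(pos.copy())
        times.append(t_now)
        bl = (
            np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)
            if len(bonds)
            else np.array([np.nan])
        )
        kin = 0.5 * float((vel**2).sum())
        max_q = (
            float(system.shell.normalized_radius(pos).max())
            if system.shell is not None
            else np.nan
        )
        erows.append((t_now, kin, float(bl.mean()), float(bl.max()), max_q))

    record(0.0)
    done = 0
    while done < n_steps:
        chunk = min(sample_every, n_steps - done)
        noise = rng.standard_normal((chunk, system.n, 3))
        status = _run_chunk(
            pos, vel, forces, wall, bonds, angles, chain_id, eps, noise, dt, c1, c2,
            f.fene_k, f.fene_r0, f.bend_k, f.lj_cutoff, force_cap, pair_on,
            f.wall_eps, r_list**2, (skin / 2.0) ** 2, pairs_mm, pairs_mw, counts,
            pos_at_build,
        )
        if status == 3:  # neighbor capacity overflow: grow and rebuild
            cap_mm = 2 * max(cap_mm, int(counts[0]))
            cap_mw = 2 * max(cap_mw, int(counts[1]))
            pairs_mm = np.zeros((cap_mm, 2), dtype=np.int64)
            pairs_mw = np.zeros((cap_mw, 2), dtype=np.int64)
            n_mm, n_mw = _build_pairs(pos, wall, r_list**2, pairs_mm, pairs_mw)
            counts[0], counts[1] = n_mm, n_mw
            pos_at_build[:] = pos
            _forces(pos, wall, bonds, angles, chain_id, eps, pairs_mm,
                    counts[0], pairs_mw, counts[1], f.fene_k, f.fene_r0,
                    f.bend_k, f.lj_cutoff, force_cap, pair_on, f.wall_eps, forces)
            continue
        if status != 0:
            raise FeneOverstretchError(
                f"dynamics aborted at step {done} (status {status}); "
                f"last good frame at t={times[-1]:.3f}"
            )
        done += chunk
        record(done * dt)

    system.positions = pos.copy()
    system.velocities = vel.copy()
    return _finish(frames, times, erows, system)


def _finish(frames, times, erows, system) -> Trajectory:
    energies = pd.DataFrame(
        erows, columns=["t", "kinetic", "mean_bond", "max_bond", "max_norm_radius"]
    )
    return Trajectory(frames=frames, times=times, energies=energies, system=system)


def pushoff(system: PolymerSystem, n_steps: int = 2000, dt: float = 0.005,
            seed: int | None = None) -> PolymerSystem:
    """Relax grown-chain overlaps with capped forces before production."""
    run_langevin(
        system, n_steps, dt=dt, gamma=5.0, sample_every=n_steps,
        seed=(system.seed + 13 if seed is None else seed), force_cap=50.0,
    )
    return system


def chain_diagnostics(traj: Trajectory, discard_fraction: float = 0.0) -> dict:
    """Bond statistics, mean bond-angle cosine, Kuhn length estimate
    l_k = l_b (1+<cos>)/(1-<cos>), and achieved volume fraction."""
    frames = traj.frames[int(len(traj.frames) * discard_fraction):]
    if len(frames) < 10:
        raise ValueError("need at least 10 sampled frames for diagnostics")
    system = traj.system
    bonds, angles = system.bonds, system.angles
    bl, cth = [], []
    for pos in frames:
        if len(bonds):
            bl.append(np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1))
        if len(angles):
            b1 = pos[angles[:, 1]] - pos[angles[:, 0]]
            b2 = pos[angles[:, 2]] - pos[angles[:, 1]]
            cth.append(
                np.sum(b1 * b2, axis=1)
                / (np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1))
            )
    mean_bond = float(np.mean(np.concatenate(bl))) if bl else np.nan
    mean_cos = float(np.mean(np.concatenate(cth))) if cth else np.nan
    kuhn = mean_bond * (1.0 + mean_cos) / (1.0 - mean_cos) if cth else np.nan
    return {
        "mean_bond": mean_bond,
        "sd_bond": float(np.std(np.concatenate(bl))) if bl else np.nan,
        "mean_cos_theta": mean_cos,
        "kuhn_length": float(kuhn),
        "achieved_phi": (
            float(system.shell.achieved_phi) if system.shell is not None else np.nan
        ),
    }
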