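"""System construction: chain growth inside the shell and overlap relief."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epsilon import EpsilonTrack
from .forcefield import ForceField
from .shell import ShellSpec


class GrowthError(RuntimeError):
    """Self-avoiding chain growth failed; the shell is likely too dense."""


@dataclass
class PolymerSystem:
    positions: np.ndarray  # (N, 3) sigma
    velocities: np.ndarray  # (N, 3)
    chain_lengths: list[int]
    eps: np.ndarray  # per-monomer attraction, kBT
    shell: ShellSpec | None
    seed: int
    forcefield: ForceField = field(default_factory=ForceField)

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def bonds(self) -> np.ndarray:
        """(B, 2) bonded index pairs; chains are never bonded across ends."""
        pairs = []
        start = 0
        for length in self.chain_lengths:
            for i in range(start, start + length - 1):
                pairs.append((i, i + 1))
            start += length
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    @property
    def chain_id(self) -> np.ndarray:
        """Per-monomer chain index (used for bonded-neighbor exclusions)."""
        out = np.empty(self.n, dtype=np.int64)
        start = 0
        for c, length in enumerate(self.chain_lengths):
            out[start:start + length] = c
            start += length
        return out

    @property
    def angles(self) -> np.ndarray:
        """(A, 3) consecutive monomer triplets within chains."""
        triplets = []
        start = 0
        for length in self.chain_lengths:
            for i in range(start, start + length - 2):
                triplets.append((i, i + 1, i + 2))
            start += length
        return np.asarray(triplets, dtype=np.int64).reshape(-1, 3)


def init_system(
    chain_lengths: list[int],
    eps: EpsilonTrack | np.ndarray,
    shell: ShellSpec | None,
    seed: int = 0,
    bond_length: float = 0.97,
    forcefield: ForceField | None = None,
) -> PolymerSystem:
    """Grow each chain as a self-avoiding random walk inside the shell
    (wall clearance ~1 sigma), with bounded retries.  Overlap relief is the
    caller's job via a short capped-force run (see ``run_langevin`` with
    ``force_cap``).
    """
    eps_arr = eps.eps if isinstance(eps, EpsilonTrack) else np.asarray(eps, float)
    if sum(chain_lengths) != len(eps_arr):
        raise ValueError(
            f"chain lengths sum to {sum(chain_lengths)} but eps has {len(eps_arr)} entries"
        )
    rng = np.random.default_rng(seed)
    min_sep = 0.85

    def inside(p: np.ndarray) -> bool:
        if shell is None:
            return True
        q = np.sqrt(
            (p[0] / (shell.a - 1.0)) ** 2
            + (p[1] / (shell.a - 1.0)) ** 2
            + (p[2] / (shell.c - 1.0)) ** 2
        )
        return bool(q < 1.0)

    for _attempt in range(30):
        placed: list[np.ndarray] = []
        ok = True
        for length in chain_lengths:
            grown = _grow_chain(length, placed, rng, inside, bond_length, min_sep, shell)
            if grown is None:
                ok = False
                break
            placed.extend(grown)
        if ok:
            positions = np.asarray(placed)
            velocities = rng.standard_normal(positions.shape)  # kBT=1, m=1
            return PolymerSystem(
                positions=positions,
                velocities=velocities,
                chain_lengths=list(chain_lengths),
                eps=eps_arr.copy(),
                shell=shell,
                seed=seed,
                forcefield=forcefield or ForceField(),
            )
    raise GrowthError(
        "self-avoiding growth failed after 30 restarts; lower phi or chain count"
    )


def _grow_chain(length, placed, rng, inside, bond_length, min_sep, shell):
    existing = np.asarray(placed) if placed else np.zeros((0, 3))

    def clash(p, chain):
        pts = [existing] + ([np.asarray(chain)] if chain else [])
        for block in pts:
            if len(block) and np.min(np.linalg.norm(block - p, axis=1)) < min_sep:
                return True
        return False

    for _ in range(200):
        if shell is None:
            start = rng.standard_normal(3) * 0.5
        else:
            while True:
                start = (rng.random(3) * 2.0 - 1.0) * np.array(
                    [shell.a, shell.a, shell.c]
                )
                if inside(start):
                    break
        chain = [start]
        failed = False
        while len(chain) < length:
            for _try in range(60):
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                cand = chain[-1] + bond_length * d
                if inside(cand) and not clash(cand, chain[:-1]):
                    chain.append(cand)
                    break
            else:
                failed = True
                break
        if not failed:
            return chain
    return None
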