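"""Map a 1-Mb binned occupancy signal to per-monomer attraction strengths.

The signal fixes only the *ratios* of the attraction between bound
segments; the interaction level (E1..E4) sets the absolute scale:

    eps_i = level_scale * signal_i / mean(signal over positive bins)

Zero-signal bins mark unbound monomers (eps_i = 0, repulsive-only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_LEVEL_SCALES: dict[str, float] = {"E1": 0.5, "E2": 1.0, "E3": 1.5, "E4": 2.0}


@dataclass
class EpsilonTrack:
    eps: np.ndarray  # per-monomer attraction, kBT
    level: str
    signal: np.ndarray  # source bin values

    @property
    def bound_mask(self) -> np.ndarray:
        return self.eps > 0.0

    def __len__(self) -> int:
        return len(self.eps)


def chip_to_epsilon(
    signal,
    level: str = "E2",
    level_scales: dict[str, float] | None = None,
) -> EpsilonTrack:
    """Convert one bin value per monomer into an attraction track.

    ``signal`` may be a 1D array or a bedGraph-style DataFrame with a
    ``value`` column (one row per 1-Mb bin / monomer).
    """
    if isinstance(signal, pd.DataFrame):
        values = signal["value"].to_numpy(dtype=float)
    else:
        values = np.asarray(signal, dtype=float)
    if values.ndim != 1:
        raise ValueError("signal must be one value per monomer")
    if np.any(values < 0):
        raise ValueError("signal values must be nonnegative")
    scales = DEFAULT_LEVEL_SCALES if level_scales is None else level_scales
    if level not in scales:
        raise ValueError(f"unknown level {level!r}; expected one of {sorted(scales)}")
    positive = values[values > 0]
    eps = np.zeros_like(values)
    if len(positive):
        eps = scales[level] * values / positive.mean()
    return EpsilonTrack(eps=eps, level=level, signal=values)


def chain_lengths_from_signal(signal: pd.DataFrame) -> list[int]:
    """Per-arm monomer counts from a bedGraph-style table, preserving the
    arm order of first appearance."""
    order = signal["chrom"].drop_duplicates().tolist()
    counts = signal["chrom"].value_counts()
    return [int(counts[c]) for c in order]
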