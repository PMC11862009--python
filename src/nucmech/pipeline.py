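"""End-to-end orchestration with a provenance manifest.

Two composed flows: the imaging flow (generate phantoms -> segment ->
morphometry -> condensates -> distances -> controls -> comparisons) and the
simulation flow (signal -> epsilon track -> shell -> init -> dynamics ->
clusters -> normalized positions -> comparisons).  Seeds for every stage
derive from one master seed through a counter scheme, so extending a grid
never reshuffles existing runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as cl
from . import condensates as cond
from . import morpho, stats_report, synthgen
from .imgio import RunConfig, write_table
from .polymer import (
    build_shell,
    chip_to_epsilon,
    init_system,
)
from .polymer.epsilon import chain_lengths_from_signal
from .polymer.langevin import pushoff, run_langevin


def derive_seed(master: int, *path: int | str) -> int:
    """Stable per-stage seed from a (master, stage-path) tuple.

    String components are digested with SHA-256 (never ``hash()``, which is
    salted per process and would break cross-run reproducibility).
    """
    ints = []
    for p in path:
        if isinstance(p, str):
            digest = hashlib.sha256(p.encode()).digest()
            ints.append(int.from_bytes(digest[:4], "little"))
        else:
            ints.append(int(p))
    ss = np.random.SeedSequence([master] + ints)
    return int(ss.generate_state(1)[0])


@dataclass
class PipelineManifest:
    config_hash: str
    master_seed: int
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, started: float, **info) -> None:
        self.stages.append(
            {"stage": name, "wall_s": round(time.time() - started, 3), **info}
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "master_seed": self.master_seed,
                    "stages": self.stages,
                },
                indent=1,
            )
        )
        return path


def run_imaging_pipeline(
    config: RunConfig,
    conditions: dict[str, synthgen.NucleusPhantomSpec] | None = None,
    n_per_condition: int = 3,
    out_dir: str | Path | None = None,
) -> tuple[PipelineManifest, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full imaging analysis on synthetic conditions.

    Default conditions emulate non-confined, moderately and strongly
    flattened nuclei.  Returns (manifest, nucleus table, condensate table,
    comparison report).
    """
    if conditions is None:
        conditions = {
            "non_confined": synthgen.NucleusPhantomSpec(
                semi_axes=(3.0, 5.0, 5.5), n_spots=12, min_spot_separation=1.2
            ),
            "confined_3to5": synthgen.NucleusPhantomSpec(
                semi_axes=(1.9, 6.0, 6.5), n_spots=10, min_spot_separation=1.2
            ),
            "confined_lt3": synthgen.NucleusPhantomSpec(
                semi_axes=(1.3, 7.0, 7.5), n_spots=8, min_spot_separation=1.2
            ),
        }
    manifest = PipelineManifest(config.config_hash(), config.seed)
    nuc_rows, cond_frames = [], []
    t0 = time.time()
    for label, base_spec in conditions.items():
        for rep in range(n_per_condition):
            seed = derive_seed(config.seed, label, rep)
            spec = _respec(base_spec, seed)
            img, truth = synthgen.gen_nucleus_stack(spec)
            nucleus = morpho.segment_nucleus(
                img, config.blur_sigma_um, config.threshold_method
            )
            m = morpho.measure_nucleus(
                img, nucleus, config.trim_fraction, config.area_method
            )
            labels, records = cond.detect_condensates(
                img,
                nucleus,
                config.condensate_blur_sigma_um,
                config.n_erosions,
                config.min_voxels,
            )
            records = cond.radial_peripheral_distances(
                records, nucleus, m, img.voxel_size, config.periphery_fraction,
                config.diameter_definition,
            )
            controls = cond.sample_control_points(
                nucleus, records, m, img.voxel_size,
                seed=derive_seed(config.seed, label, rep, "controls"),
                periphery_fraction=config.periphery_fraction,
                diameter_definition=config.diameter_definition,
            )
            nuc_rows.append(
                {
                    "condition": label,
                    "replicate": rep,
                    "height_um": m.minor_axis,
                    "major_um": m.major_axis,
                    "intermediate_um": m.intermediate_axis,
                    "elongation": m.elongation,
                    "flatness": m.flatness,
                    "sphericity": m.sphericity,
                    "volume_um3": m.volume,
                    "area_um2": m.surface_area,
                    "n_condensates": len(records),
                    "scaled_total_volume": cond.scaled_total_volume(records, m),
                }
            )
            df = cond.records_to_frame(records + controls)
            df.insert(0, "condition", label)
            df.insert(1, "replicate", rep)
            cond_frames.append(df)
    nuclei = pd.DataFrame(nuc_rows)
    condensates = (
        pd.concat(cond_frames, ignore_index=True) if cond_frames else pd.DataFrame()
    )
    manifest.add("imaging", t0, n_nuclei=len(nuclei), n_condensates=len(condensates))

    t0 = time.time()
    report = stats_report.compare_groups(nuclei, "flatness", "condition")
    manifest.add("stats", t0, comparisons=len(report))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(nuclei, out_dir / "nuclei.csv")
        write_table(condensates, out_dir / "condensates.csv")
        write_table(report, out_dir / "comparisons.csv")
        manifest.write(out_dir / "manifest.json")
    return manifest, nuclei, condensates, report


def _respec(base: synthgen.NucleusPhantomSpec, seed: int) -> synthgen.NucleusPhantomSpec:
    import dataclasses

    return dataclasses.replace(base, seed=seed)


def run_simulation_pipeline(
    config: RunConfig,
    shapes: list[str] = ("sphere", "oblate_0.33"),
    levels: list[str] = ("E1", "E4"),
    seeds: list[int] = (0, 1),
    n_steps: int = 50_000,
    equilibration: int | None = None,
    sample_every: int = 5_000,
    signal: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> tuple[PipelineManifest, pd.DataFrame]:
    """Simulate the shape x level x seed grid and cluster every run.

    Returns (manifest, long-format condensate table with columns shape,
    level, seed, frame, cluster, size, R, P).
    """
    for shape in shapes:
        if shape not in ("sphere", "oblate_0.5", "oblate_0.33"):
            raise ValueError(f"invalid shape {shape!r}")
    manifest = PipelineManifest(config.config_hash(), config.seed)
    if signal is None:
        signal = synthgen.gen_chip_track(seed=derive_seed(config.seed, "chip"))
    chain_lengths = chain_lengths_from_signal(signal)
    equil = config.equilibration_steps if equilibration is None else equilibration
    tables = []
    for shape in shapes:
        shell = build_shell(shape, n_monomers=int(signal.shape[0]), phi=config.phi)
        for level in levels:
            eps = chip_to_epsilon(signal, level, config.level_scales)
            for run_seed in seeds:
                t0 = time.time()
                sys_seed = derive_seed(config.seed, shape, level, run_seed)
                system = init_system(chain_lengths, eps, shell, seed=sys_seed)
                pushoff(system)
                run_langevin(
                    system, equil, dt=config.dt, gamma=config.gamma,
                    sample_every=max(equil, 1),
                    seed=derive_seed(config.seed, shape, level, run_seed, "equil"),
                )
                traj = run_langevin(
                    system, n_steps, dt=config.dt, gamma=config.gamma,
                    sample_every=sample_every,
                    seed=derive_seed(config.seed, shape, level, run_seed, "prod"),
                )
                table = cl.cluster_trajectory(
                    traj.frames[1:], eps.bound_mask, shell,
                    min_size=config.cluster_min_size,
                )
                table.insert(0, "shape", shape)
                table.insert(1, "level", level)
                table.insert(2, "seed", run_seed)
                tables.append(table)
                manifest.add(
                    f"run:{shape}:{level}:{run_seed}", t0,
                    frames=len(traj.frames) - 1, n_condensates=len(table),
                )
    nonempty = [t for t in tables if len(t)]
    table = (
        pd.concat(nonempty or tables[:1], ignore_index=True)
        if tables
        else pd.DataFrame()
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(table, out_dir / "clusters.csv")
        manifest.write(out_dir / "manifest.json")
    return manifest, table
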