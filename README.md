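# nucmech

Analysis pipeline for nuclear mechano-confinement studies: 3D nucleus and
condensate morphometry, condensate spatial statistics with radius-matched
random controls, condensate tracking with anomalous-diffusion analysis,
FRAP recovery fitting, and a confined bead-spring polymer simulator whose
monomer attractions are weighted by a 1-Mb binned occupancy signal.
Every stage is driven by a synthetic-data generator with recorded ground
truth, so the full pipeline is testable offline.

## Modules

| module | contents |
| --- | --- |
| `nucmech.synthgen` | phantoms (ellipsoidal nuclei + Gaussian spots, PSF blur, Poisson-Gaussian noise), fractional-Brownian tracks, FRAP curves, blocky 1-Mb signal tracks |
| `nucmech.imgio` | OME-TIFF/CSV/bedGraph/XYZ I/O, `VoxelImage`, `RunConfig` (TOML) |
| `nucmech.morpho` | nucleus segmentation; principal-axis extents with minor-axis trimming; elongation / flatness / sphericity; volume and surface area (mesh or voxel-face) |
| `nucmech.condensates` | eroded-Otsu condensate labeling, periphery shell, scaled radial/peripheral distances, radius-matched control points, Mander's M1 |
| `nucmech.dynamics` | LAP track linking with gating and splitting costs, nucleus-motion correction, reference-point MSD, log-log alpha fit, displacement stats |
| `nucmech.frap` | double normalization and the single-diffusion recovery fit (`t_half = 2*t1`) |
| `nucmech.polymer` | FENE + bending + Lennard-Jones force field, rigid shells (sphere / oblate 0.5 / oblate 0.33) tiled with static wall monomers, signal-to-epsilon mapping (E1-E4), BAOAB Langevin dynamics (numba) |
| `nucmech.clusters` | single-linkage clustering with silhouette-selected cut, normalized radial (R) and peripheral (P) condensate positions |
| `nucmech.stats_report` | Mann-Whitney with star notation, boxplot summaries, KDE, Pearson |
| `nucmech.pipeline` | end-to-end imaging and simulation flows with provenance manifests |

## CLI

One entry point with per-stage subcommands:

```sh
nucmech simulate-images --n-spots 8 --seed 1 --out nucleus.ome.tif
nucmech morpho --in nucleus.ome.tif --out morpho.csv
nucmech condensates --in nucleus.ome.tif --out condensates.csv --controls controls.csv
nucmech track --detections det.csv --cutoff 16900 --split 100 --out tracks.csv
nucmech msd --tracks tracks.csv --window-hours 7 --out msd.csv
nucmech frap-fit --curve curve.csv --out fit.json
nucmech chip2eps --level E4 --out eps.csv
nucmech polymer-run --shape oblate_0.33 --level E4 --steps 100000 --seed 7 --out runs/
nucmech clusters --traj runs/trajectory.xyz --shell runs/shell.json --eps runs/eps.csv --out clusters.csv
nucmech report --table clusters.csv --value-col R --group-col shape --out report.csv
nucmech pipeline --mode imaging --out out/
```

Any tunable can also be set in a TOML config (`--config run.toml`); CLI
flags override config keys, and every run embeds its config hash in the
outputs.

## Conventions

- Volumetric axis order is (t, z, y, x); voxel sizes are (z, y, x) in um;
  physical positions are voxel centers; bedGraph intervals are 0-based
  half-open.
- Polymer simulations use reduced units (sigma = kBT = tau = 1) and are
  bit-identical for a fixed seed.
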