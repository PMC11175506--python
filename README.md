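# histomech

Mechanics of buckling epithelial cell junctions, as in the *Drosophila*
histoblast shape transition: cell boundaries are spring chains (point
masses joined by linear springs with angular springs for bending) growing
on a shrinking rectangular template, restrained by a plastically relaxing
elastic foundation and kept from self-crossing by transient
compression-only penalty springs. Alongside the simulator, the package
implements the morphometric statistics (area, perimeter, circularity,
junction straightness, drift-corrected vertex fluctuation RMS,
morphospace tables), the image quantifications (junction/cytosol
enrichment ratio, double-Gaussian membrane thickness mapping), in-silico
physics experiments (laser-ablation recoil, Euler critical-load scaling,
Winkler-foundation mode selection), and synthetic-data generators with
known ground truth for every analysis path.

Units: lengths in micrometres; stiffnesses (`k_b`, `k_bend`, `k_connect`,
`k_foundation`) are dimensionless model constants, so forces and energies
are in model units.

## Library quick start

```python
import histomech as hm

mesh = hm.make_cell_grid(50.0, 50.0, n_cells=16, seed=0)   # CellMaker-style nest
mesh = hm.init_rest_state(hm.subdivide_long_edges(mesh, 1.0))
snapshots, log = hm.run_simulation(mesh, hm.SimParams(), n_steps=100)
print(log[["step", "mean_circularity", "n_connections"]].tail())
```

`SimParams()` defaults reproduce the published simulation parameter table
(subdivision threshold 1 um, boundary stiffness 0.2, bending stiffness
5e-4, connection stiffness 0.1, shrink rate 0.6 along x, boundary growth
rate 1.0, dt 0.005, foundation stiffness 0.1, foundation step 0.01).

## Command line

```sh
histomech init --width 50 --height 50 --n-cells 16 --seed 0 --out mesh.txt
histomech simulate --mesh mesh.txt --steps 100 --snapshot-every 25 --out run/
histomech stats --mesh run/snapshot_000100.txt --out stats.csv
histomech ablate --mesh run/snapshot_000100.txt --edges 120:122 --out recoil.csv
histomech scan-euler --out euler.csv          # critical load ~ L^-2
histomech scan-foundation --out winkler.csv   # wavelength ~ k^-1/4
histomech synth zstack --thickness-um 6 --snr 20 --out stack.tif
histomech thickness --stack stack.tif --dz 1.0 --out map.tif
histomech synth enrichment --ratio 1.5 --snr 10 --out enr.tif
histomech enrich --image enr.tif --junction-mask enr_junction.tif \
    --cytosol-mask enr_cytosol.tif --out ratio.csv
histomech synth tracks --seed 1 --out tracks.csv
histomech fluctuations --tracks tracks.csv --out rms.csv
```

Every command writes a `manifest.json` (config hash, seed, versions)
beside its outputs; identical config + seed gives identical manifests.
Mesh files are a plain-text format with `VERTICES` / `EDGES` / `ANGLES` /
`FACES` sections; tabular outputs are CSV.

## Module map

| Module | Contents |
| --- | --- |
| `histomech.core` | `SimParams`, `TissueMesh`, `ConnectionSet`, validation, mesh text I/O |
| `histomech.initializer` | shortest-wall cell grid, edge subdivision, rest-state init |
| `histomech.mechanics` | force laws, energy, L-BFGS/Newton quasi-static solvers |
| `histomech.growth_loop` | connection placement, growth/shrink/foundation updates, run driver |
| `histomech.experiments` | ablation recoil, Euler scan, Winkler mode scan |
| `histomech.morphometrics` | polygon stats, straightness, fluctuation RMS, morphospaces |
| `histomech.imagequant` | enrichment ratio, double-Gaussian thickness map |
| `histomech.synthetic` | label images, membrane z-stacks, tracks, enrichment images |
| `histomech.cli` | `histomech` entry point |
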