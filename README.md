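# clampmf

A tested, reusable pipeline from biased sampling to ligand-binding free
energies for a two-domain ("clamshell") ligand-binding domain:

- **structio** — PDB and plain-text trajectory I/O, residue selections,
  center of mass, Kabsch superposition, RMSD/RMSF (all coordinates in nm).
- **colvars** — reaction coordinates: pairwise COM distance, plane-projected
  site–ligand distance, interdomain angle/torsion at the hinge, PCA-mode
  projections.
- **rigidpca** — rigid-body PCA: strip internal domain motion by per-domain
  superposition, diagonalize the interdomain covariance, expose the leading
  modes (clamshell / twisting / rocking) as collective variables.
- **toysystems** — the synthetic stand-in for an MD engine: analytic
  potentials (harmonic, asymmetric double well, calibrated triple well with
  minima near 0.53/0.76/1.12 nm), an overdamped Langevin integrator with
  pluggable bias forces, umbrella-window generation, and a toy clamshell
  trajectory generator with planted bend/twist/rock modes.
- **wham** — umbrella-sampling estimator: shared-grid histograms, log-space
  WHAM self-consistency, PMF assembly, histogram-overlap and sequential-batch
  convergence diagnostics.
- **metad** — plain metadynamics with a staged hill schedule, HILLS-style
  ledger I/O, free-energy-surface reconstruction (with trailing-window
  averaging to damp deposition ripple), basin ΔG analysis.
- **statemodel** — PMF feature finding (minima/barriers/plateaus), RMSD-based
  closed/half-closed/open state assignment, and the two-substep binding
  free-energy combination (receptor opening + ligand dissociation).
- **cli** — `clampmf simulate | colvar | pca | wham | metad | report`.

Units: nm, ps, kcal/mol, degrees. kT = 0.596 kcal/mol at 300 K.

## CLI

Every subcommand takes a YAML config, rejects unknown keys, requires explicit
seeds for stochastic stages, and writes a `manifest.json` with content hashes
so deterministic stages reproduce bit for bit. Example — generate umbrella
windows and estimate the PMF:

```yaml
# sim.yaml
kind: umbrella
output_dir: data
potential: {kind: double_well, x1: 0.4, x2: 1.0, barrier: 4.0, delta: 1.19}
centers: [0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0, 1.05, 1.1]
force_constant: 500.0
langevin: {timestep: 0.0001, n_steps: 400000, seed: 11, save_stride: 4, n_equil: 4000}
```

```yaml
# wham.yaml
windows: data/windows.meta
bin_width: 0.01
range: [0.28, 1.12]
output_dir: out
n_batches: 4
endpoints: [0.4, 1.0]
```

```sh
clampmf simulate sim.yaml
clampmf wham wham.yaml        # writes out/pmf.dat, overlap.dat, batch curves
```

`clampmf report` combines per-substep free energies into the final
binding-free-energy table (US Step1 / US Step2 / US Σ / Metadynamics /
Combined rows, one column per ligand).

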