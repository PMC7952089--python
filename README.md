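# magicratio

Desk-scale tools for two-component associative-polymer phase separation:

* **`magicratio.simulate`** — coarse-grained Langevin dynamics (BAOAB) of
  bead-spring sticker polymers.  Opposite species attract through a
  short-ranged well of depth `U0` (binding = overlap), identical species
  repel over twice the binding range, which enforces one-to-one binding
  geometrically.
* **`magicratio.analysis`** — bond detection, polymer-level cluster
  statistics, slab density profiles, dilute/dense coexistence
  extraction, and the fully-bonded-oligomer combinatorics.
* **`magicratio.theory`** — the mean-field dimer-gel free energy: ideal,
  specific (minimised over the dimer / independent-bond association
  state) and nonspecific components, the strong-binding limiting forms,
  the dimer/gel crossover concentrations `c0` and `c_s`, effective
  valence rescaling, and the well-depth → dissociation-constant
  conversion.
* **`magicratio.phase`** — free-energy landscapes on a `(c1, c2)` grid
  and convex-hull binodal/tie-line extraction, including the dilute
  branch scan that exhibits the magic-ratio effect: at strong binding
  the dilute boundary peaks at equal *polymer* stoichiometry
  (`c1/c2 = L1/L2`) and the peak disappears at weak binding.
* **`magicratio.fixtures`** — planted profiles, clusters, and dilute
  gases with exact ground truth for testing the analysis chain.
* **`magicratio.io` / `magicratio.cli`** — LAMMPS-dump / XYZ trajectory
  text I/O, flat key-value configs, JSON run manifests.

Units: lengths nm, energies k_BT (T = 1), concentrations mM, reduced time.

## CLI

```bash
magicratio simulate     --config sim.cfg --steps 100000 --seed 1 --out traj.dump
magicratio analyze      --traj traj.dump --cutoff 1.83 --out results/
magicratio theory       --params theory.cfg --c1 3.0 --c2 3.0
magicratio phasediagram --params theory.cfg --grid 200 --cmax 30 --out pd.json
magicratio fixtures     --kind profile --out profile.csv
```

Config files are flat `key = value` text mirroring the
`SimulationSpec` / `TheoryParams` fields.  Every invocation writes a
JSON manifest (parameters, seeds, file digests) next to its outputs.
Exit codes: 0 success, 2 usage error, 3 numerical failure.

## Notes on conventions

* The attraction range (1.83 nm) is the one free geometric parameter;
  it is frozen by requiring the bound-state integral of a 9 k_BT well
  to give K_d = 0.40 mM, and is used consistently by the simulator, the
  bond-detection cutoff, and the theory helpers.
* Whole-polymer dimer dissociation constants `Kd` are valence-dependent
  inputs.  `theory.dimer_kd_from_crossover` generates stand-ins by
  placing the equal-stoichiometry dimer/gel crossover at a chosen
  concentration.
* Hull defaults: uniform grid, `n_grid = 200`, `c_max = 30` mM,
  facet-area threshold 1.5 grid cells; all recorded in output metadata.
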