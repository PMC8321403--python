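# memlip

Analysis toolkit for membrane-protein/lipid interactions in coarse-grained
and atomistic MD trajectories, with a synthetic membrane/trajectory
generator that provides exact ground truth for every estimator.

## The problem

Receptors such as the T-cell receptor complex sit in an asymmetric
bilayer whose inner leaflet carries low-abundance anionic lipids (PIP2,
PIP3). Simulation studies of such systems keep asking the same
quantitative questions: which residues contact which lipid species, and
how strongly once corrected for abundance? How long does a lipid stay
bound? Where around the protein do lipids accumulate? How tilted are the
transmembrane helices, and how coiled are the cytoplasmic tails? Which
cytoplasmic conformation dominates? `memlip` implements this analysis
pipeline as a tested library plus CLI:

* **Contact fingerprints** — a residue and a lipid are in contact when any
  particle pair is within a cutoff (0.55 nm coarse-grained, 0.4 nm
  atomistic) under the minimum-image convention. The per-residue,
  per-species fingerprint is normalized as

  `N = n1 / (n2 · n3)`

  where `n1` counts residue-lipid contact frames, `n2` is the number of
  lipids of that species in the bilayer and `n3` the number of frames.
  Variants: acyl-chain (membrane-penetration) profiles normalized by the
  *total* lipid count, nitrogen-atom contacts per species, inter-chain
  profiles with per-dimer max normalization, and 0-1 min-max scaling.
* **Residence times** — dual-cutoff bound intervals (enter below 0.55 nm,
  leave above 1.0 nm, optional gap bridging), censoring at trajectory
  ends, mean residence time and a single-exponential rate fitted to the
  survival curve S(t).
* **Density and enrichment maps** — frames are translated and z-rotated so
  the protein is fixed at the box center, then lipid headgroups are binned
  laterally per species and leaflet; dividing by the bulk areal density
  gives an enrichment ratio map.
* **Geometry** — mass-weighted COM distances along z, radius of gyration,
  Kabsch superposition with RMSD/RMSF, helix tilt from the principal axis
  (arccos|u·ẑ| in [0°, 90°]), lateral radial distribution functions,
  nitrogen relative-height maps, polynomial smoothing (cubic for binding
  time series, degree 10 for long distance traces).
* **Conformational clustering** — single-linkage clustering of strided
  frames (default every 10th) under backbone RMSD with a 0.35 nm cutoff,
  computed as connected components of the threshold graph.
* **Synthetic generator** — deterministic membranes with a prescribed
  per-leaflet headgroup composition (largest-remainder apportionment),
  an idealized multi-chain protein with ECD/TMR/CYR regions and exact
  helix tilts, and a toy simulator with lateral lipid diffusion and
  per-species binding kinetics whose every binding interval is logged.

## Worked example

```python
import memlip as ml

membrane = ml.build_membrane(
    ml.MembraneSpec(lx=25.0, ly=25.0, protein_exclusion_radius=3.5), 150, seed=7)
protein = ml.build_protein(ml.ProteinSpec(tilt_deg=[0, 10, 20, 30]))
topo, frame0 = ml.combine_systems(membrane, protein)
sites = ml.pick_binding_sites(topo, frame0, z=3.0, n_sites=6)

kin = ml.BindingKineticsSpec(kon={"PIP2": 1.0, "PIP3": 1.0},
                             koff={"PIP2": 0.2, "PIP3": 0.3},
                             site_indices=sites)
traj, log = ml.simulate_trajectory(topo, frame0, kin, n_frames=400, dt=0.2, seed=8)

fp = ml.fingerprint(traj, cutoff=0.55)
print(fp.normalized.sum(axis=0).sort_values(ascending=False).round(4))
```

prints the abundance-corrected contact totals per species:

```
PIP2    4.1440
PIP3    3.4075
DPSM    0.0702
CHOL    0.0407
POPC    0.0125
POPE    0.0000
POPS    0.0000
```

Only PIP2/PIP3 were given binding sites, and the fingerprint ranks them
far above the bulk species even though they are only 8% and 2% of the
inner leaflet — the normalization by `n2` is what makes the low-abundance
binders stand out. Continuing,

```python
ivs = ml.binding_intervals(traj, "PIP2", lower_cutoff=0.55, upper_cutoff=1.0)
print(ml.residence_summary(ivs, dt=0.2, species="PIP2").mean)
```

reports a mean PIP2 proximity time of `7.56` ns against a kinetic
ground-truth bound time of 1/koff = 5 ns: with diffusion enabled, lipids
released near the protein linger inside the contact shell, so
whole-protein proximity exceeds the kinetic bound time (see
`docs/methods.md` for the clean parameter-recovery protocol). Finally,

```python
tilt = ml.helix_tilt_series(traj, ml.Selection(chain_id="D", region="TMR"))
print(tilt.values.mean())   # 30.0 — chain D was built at 30 degrees
```

The same analyses are available from the shell via
`memlip simulate | fingerprint | acyl-profile | nitrogen-contacts |
pip-series | interchain | residence | geometry | density | cluster`; every
run writes TSV artifacts plus a `manifest.yaml` recording all parameters
and input checksums.

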