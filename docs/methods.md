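# Methods

## System model

Every system is a particle table (`ParticleTopology`) plus frames of 3D
coordinates in an orthorhombic periodic box. Units are nm and ns
throughout; PDB Angstroms are converted on read. Each particle carries a
molecule id, residue, chain, a protein region label (ECD — extracellular,
TMR — transmembrane, CYR — cytoplasmic), a lipid species and leaflet, and
a coarse role (backbone, headgroup, phosphate, nitrogen, acyl, sterol).
Standard coordinate formats carry none of these labels, so they come from
a sidecar TSV keyed by (chain, residue range) for protein rows and by
residue name for lipid rows. When leaflet labels are absent they are
assigned once from the first frame: a lipid whose phosphate (sterol for
cholesterol) sits above the phosphate-z midplane is "outer". This is valid
for planar, non-flipping membranes, which is the regime the whole pipeline
assumes. Masses default to 72 amu per coarse-grained bead; all COM and Rg
quantities are mass-weighted. Triclinic boxes are rejected rather than
approximated.

Only GRO/PDB (via MDAnalysis) and a plain-text `frames_txt` dialect are
supported for fixtures; binary trajectories (XTC/TRR/DCD) are read through
MDAnalysis against a known topology. `frames_txt` floats are written with
17 significant digits so round trips are bitwise exact. GRO files carry no
chain identity; when chain-resolved analyses are needed, use PDB (the CLI
writes both).

## Contacts

A residue and a lipid are in contact in a frame when any particle of the
residue is within the cutoff of any particle of the lipid under the
minimum-image convention (cell-list search via a periodic KD-tree; tests
hold it to exact agreement with the all-pairs oracle). Default cutoffs are
0.55 nm for coarse-grained and 0.4 nm for atomistic inputs, selected by a
resolution flag and overridable. Cutoffs above half the smallest box edge
are an error because the minimum image is then ambiguous.

The fingerprint is N = n1/(n2·n3). By default a residue contacting k
lipids of one species in one frame adds k to n1 (the "number of lipid
contacts" reading); a once-per-frame variant is available because the
alternative reading is also defensible. The raw n1, n2, n3 are always
retained. Two distinct normalizers exist by design and are not
interchangeable: the per-species fingerprint divides by that species'
lipid count, while the acyl-chain (membrane-penetration) profile divides
by the total lipid count — each matches its figure convention in the
literature this pipeline serves. The PIP time series counts distinct
bound lipids of a species per frame over the species count and smooths
with a least-squares cubic; inter-chain profiles are normalized by the
per-dimer maximum; min-max scaling maps the maximum to 1 and preserves
zeros, per species or globally.

## Residence times

Bound intervals use a dual cutoff: a lipid enters the bound state below
the lower cutoff (default 0.55 nm, the contact cutoff) and remains bound
while within the upper cutoff (default 1.0 nm); interruptions up to a gap
tolerance (default 0) are bridged. The hysteresis prevents boundary
rattling from fragmenting one visit into many short events. Durations are
(frames bound) × dt; intervals clipped by either trajectory end are
censored and excluded from the mean, because including them biases it
downward by an amount that depends on trajectory length. The survival
curve S(t) is evaluated at the completed durations and log S is fitted by
unweighted least squares over points with S ≥ 0.05 (the sparse tail is
uninformative and would dominate an unweighted fit); the negated slope is
the reported rate. The fit needs at least 5 completed events; the mean
needs at least one.

Residence is lipid-to-whole-protein by default; a `protein_sel` argument
restricts the protein side (e.g. to known binding sites), which is what
the parameter-recovery protocol uses.

## Geometry

Kabsch superposition is the standard weighted SVD construction with the
determinant correction, so the rotation is always proper; for collinear
inputs the rotation about the degenerate axis is arbitrary but the RMSD is
still unique. RMSF superposes frames to the time-mean structure (two
alignment passes) and averages per-particle fluctuations within residues.
Helix tilt is the angle between the principal axis of the centered
backbone coordinates and the membrane normal, folded into [0°, 90°] via
|cos|; a signed tilt is deliberately not reported. The lateral RDF is 2D
and per leaflet — the membrane is quasi-planar, so a 3D RDF of the same
system would not be comparable — and normalizes annulus counts by the
species' uniform areal density over the box. Nitrogen height maps
reference each nitrogen to the per-frame mean phosphate z of its leaflet.
COM is computed on wrapped coordinates without unwrapping; analyses
require the selected group not to straddle a periodic boundary, which the
protein-centering alignment guarantees for the protein.

## Alignment and density maps

Each frame is translated laterally so the reference selection's COM (TMR
backbone by default) sits at the box center, then rotated about z by the
closed-form 2D-Kabsch angle minimizing the selection's XY RMSD to the
reference frame. Rotation is restricted to z so the membrane normal — and
therefore leaflet assignment — is preserved; z coordinates are untouched.
Aligned coordinates are not re-wrapped; grid accumulation simply drops the
rare rotated-out observations. Density maps bin the headgroup reference
bead (phosphate, or the sterol bead for cholesterol) per species and
leaflet; enrichment divides the per-bin mean number density by the
species' bulk areal density, so 1 means bulk-like.

## Clustering

Pairwise superposed backbone RMSDs between strided frames (default every
10th) feed single-linkage clustering with a 0.35 nm cutoff, implemented as
connected components of the strictly-below-cutoff threshold graph — the
same partition a dendrogram cut yields, at O(n²) cost. Clusters are
ordered by size (ties to the smallest member frame). The representative is
the member with minimal mean RMSD to its cluster; a most-neighbors variant
exists behind a flag since common tooling differs here.

## Synthetic generator

The generator is a statistical stand-in, not an MD engine: no forces, no
bonded terms, no thermostats. It exists so that every estimator above can
be validated against known truth.

*Membrane.* Species counts per leaflet come from largest-remainder
apportionment of the composition percentages (deterministic, ties broken
by declared species order), so at n=500 the default composition reproduces
its percentages exactly. Exact per-build lipid counts are
builder-dependent in real tools, so compositional fractions, not absolute
counts, are the contract. Lipids sit on a jittered square grid (the grid
suppresses density clumping, the jitter removes lattice artifacts) at
phosphate planes z = 3.0 (inner) and 7.0 nm (outer) in a 10 nm box, with
small fixed vertical bead stacks per lipid (nitrogen only for PC/PE/SM;
sterol+acyl for cholesterol). An optional keep-out radius at the patch
center models the hole a membrane-insertion tool carves for the protein.

*Protein.* Each chain is an ideal α-helix trace (rise 0.15 nm/residue,
3.6 residues/turn, radius 0.23 nm) with an ECD bead stack above and a
linear CYR tail below, chains arranged on a ring. A finite helix's
principal axis deviates slightly from its geometric axis, so the builder
measures the actual principal axis and rotates the trace onto the
requested tilt — the constructed tilt is then exact ground truth, and the
tilt analysis recovers it to machine precision.

*Kinetics.* Binding is whole-lipid: one site (a designated protein bead)
holds at most one lipid, so residence truth is unambiguous. Per step,
bound lipids unbind with probability 1−exp(−koff·dt); free lipids of a
species fire with 1−exp(−kon·dt) and compete for free sites in random
order (so build order carries no priority); a firing lipid with no free
site stays free. Only lipids of the sites' leaflet may bind (inner by
default — sites are cytoplasmic in the motivating system). Binding places
the lipid's reference bead uniformly within the placement radius (0.3 nm)
of the site; unbinding displaces it to the release radius (2.0 nm, outside
the residence upper cutoff) in a random direction, and a lipid released in
step t may not rebind before t+1 — both choices ensure every kinetic
transition is visible in at least one frame, which is what makes the
logged intervals a usable ground truth. Free lipids do a lateral Gaussian
random walk with per-axis step variance 2·D·dt and periodic wrap; D
defaults to 0.05 nm²/ns, the upper range of coarse-grained lipid
diffusion. Random streams are split per purpose (build, diffusion,
kinetics), so the built system does not depend on the number of frames
simulated. Every binding interval is logged (species, lipid, site, start,
end, censoring) and the log is emitted alongside the trajectory.

## What the generator does and does not emulate

It reproduces the features the estimators measure: abundance-weighted
composition, leaflet asymmetry, region-labelled protein geometry with
known tilts, lateral diffusion with known variance, and two-state binding
with known rates. It does not model membrane elasticity, curvature,
lipid flip-flop, protein conformational change, acyl-chain order or any
energetics — so green tests demonstrate that the estimators are correct,
not that the biology of any particular receptor is reproduced.

One interaction deserves emphasis: a distance-threshold detector cannot
distinguish "kinetically bound" from "parked next to a site". With
diffusion enabled, free lipids occasionally linger inside the contact
shell, and these ambient passages lengthen whole-protein proximity times
relative to 1/koff (visible in the README example). The parameter-recovery
protocol therefore runs the kinetics with diffusion disabled, where
proximity and kinetic state coincide exactly and the recovered intervals
equal the log frame-for-frame; diffusion statistics are validated by their
own variance test. Frame quantization biases the mean duration by +dt/2,
so recovery fixtures use dt = 0.05/koff, keeping that bias at 2.5%
against a 10% acceptance band.

## Problem sizes

Fixtures use 150–625 lipids per leaflet, 8 binding sites, and 150–2500
frames per run; the oracle-equivalence sweeps use 50 random systems of
200–2000 particles and 200-frame RMSD matrices. These sizes give ≥500
completed binding events per rate, ≥10⁴ density observations per map, and
sampling errors a factor 2–3 below each stated tolerance, while the full
test suite and the acceptance script each run in well under a minute.

## Known limitations

* Orthorhombic boxes only; no triclinic support anywhere.
* COM/Rg do not unwrap molecules across the boundary; center first.
* The enrichment normalizer uses the full box area, not the
  protein-excluded accessible area; for large proteins in small boxes the
  bulk reference is slightly underestimated.
* The survival-rate fit is a single exponential; multi-exponential
  residence (distinct site classes) is summarized by an effective rate.
* Helix tilt assumes the helix is the dominant principal component of its
  selection; heavily kinked helices should be split before analysis.
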