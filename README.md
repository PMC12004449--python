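# lipidsites

Lipid–protein binding-site and residence-time analysis for coarse-grained
molecular dynamics trajectories.

Specific lipids — cardiolipin in particular — bind membrane proteins at
discrete sites and can dwell there for microseconds, far longer than the
bulk lipids that exchange on the tens-of-nanoseconds scale. Coarse-grained
(CG) simulations reach those time scales, but turning a raw trajectory into
"this protein has a binding site at these residues with residence time τ"
takes a chain of careful steps. `lipidsites` implements that chain for
structural biologists and simulators working with CG bilayer systems:

1. **Dual-cutoff contact detection.** A lipid–residue contact *starts* when
   the minimum bead–bead distance (minimum image) drops below 5 Å and *ends*
   only when it exceeds 7 Å. The hysteresis suppresses boundary rattling
   that a single cutoff would split into spurious short events.
2. **Survival-function kinetics.** Pooled contact events give the survival
   time correlation function

   σ(t) = [ Σ_j Σ_v ñ_j(v, v+t) ] / [ N (T − t) ],   normalized so σ(0) = 1,

   where ñ_j(v, v+t) = 1 iff lipid j's contact persists over every frame in
   [v, v+t], T is the analyzed length and N the contact count. σ(t) is fit
   with a biexponential A e^(−k₁t) + B e^(−k₂t), k₁ ≤ k₂; the slow rate is
   the dissociation rate k_off and the residence time is reported as
   τ = 1/k_off in microseconds, with R² alongside.
3. **Binding sites by community detection.** Residues are nodes of a
   co-contact network (edge weight = number of (frame, lipid) pairs in which
   one lipid touches both residues); Louvain modularity maximization
   partitions the network into sites, each with union-occupancy kinetics,
   occupancy fraction and an approximate bead-sphere surface area.
4. **Bilayer descriptors.** Leaflet assignment, membrane thickness
   (head-plane separation), area per lipid (periodic Voronoi tessellation
   with protein beads as excluded seeds) and P2 bond order parameters, with
   block-averaged means and SDs.

Because real μs-scale trajectories are bulky and rarely shared, the package
also ships a **synthetic-data generator**: a rigid 7-helix bundle in a
two-species background bilayer (3:1 mole ratio, emulating POPE:POPG) plus a
minority lipid at 0/5/10 mol %, with binding sites planted at known
k_on/k_off. Every stage of the pipeline is validated against this ground
truth and against independent brute-force oracles.

## Worked example

`examples/03_binding_sites.py` plants two sites (τ = 1 and 2 μs) on helices
0 and 3, generates 20 μs of trajectory at a 10 ns stride, and runs contact
detection plus site identification:

```
planted ground truth:
  residues [4, 5, 6, 7]  tau_true = 1.0 us
  residues [25, 26, 27, 28]  tau_true = 2.0 us

recovered sites (ranked by occupancy):
  BS0: residues [25, 26, 27, 28]  tau = 1.75 us  R^2 = 0.979  area = 7.2 nm^2  occupancy = 0.97
  BS1: residues [4, 5, 6, 7]  tau = 1.07 us  R^2 = 0.999  area = 7.2 nm^2  occupancy = 0.92
```

Both planted residue sets are recovered exactly; the residence times agree
with the planted values within the statistical error of ~10–20 binding
events per site. Site labels BS0, BS1, … are assigned by descending
occupancy. The other example scripts cover contact detection
(`01`), survival-function fitting on raw Markov kinetics (`02`, ~500
events recover τ to a few percent), membrane properties (`04` prints
`thickness: 39.90 +/- 0.01 A`, the generator's constructed 40 Å bilayer),
and the full file-based pipeline (`05`).

A thin CLI mirrors the library: `lipidsites simulate|contacts|kinetics|`
`sites|membrane|run` (see `lipidsites --help`); `run` takes a flat key-value
YAML config and writes a report bundle (events.csv, residence_times.csv,
sites.json, membrane.csv, manifest.json) that fully records config, seed and
package version.

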