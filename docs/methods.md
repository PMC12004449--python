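# Methods

This note records the models, estimators and numerical choices behind
`lipidsites`, and what the synthetic validation does and does not establish
about real data.

## Contact model

Contacts are defined between one lipid *molecule* (any of its beads) and one
protein *residue* (any of its beads, backbone included). Per frame, the
minimum-image minimum bead–bead distance feeds a dual-cutoff hysteresis: a
contact starts strictly below the lower cutoff (default 5 Å), survives while
the distance stays below the upper cutoff (default 7 Å), and ends at the
first frame at or above it. With equal cutoffs the scheme reduces exactly to
a single-cutoff definition. Distances are evaluated only at saved frames —
no interpolation — so the frame stride is the kinetic time resolution and
dwells shorter than one stride are unresolvable. A contact still open at the
last frame is kept as a right-censored event: it enters the survival
function up to its observed length, which avoids the downward residence-time
bias that discarding such events would cause for μs-scale sites.

Whether "residue" should include backbone beads is a modeling choice; the
default is all beads, configurable at the selection level.

## Survival function and residence time

For pooled contact events the survival time correlation function is

    σ(t) = [ Σ_j Σ_v ñ_j(v, v+t) ] / [ N (T − t) ],

with ñ_j(v, v+t) = 1 iff the contact of lipid j covers every frame in
[v, v+t], N the total number of contact events and T the number of analyzed
frames; the curve is renormalized so σ(0) = 1. An event occupying L
consecutive frames contributes max(L − t, 0) start positions, so the
implementation evaluates σ exactly from the event list in O(events × lags);
tests verify bit-level agreement with a direct window-count evaluation.
Normalization by total contacts (rather than per-lipid) is immaterial after
the σ(0) = 1 renormalization.

σ(t) is fit by least squares with σ(t) ≈ A e^(−k₁t) + B e^(−k₂t), rates
ordered k₁ ≤ k₂. The slow rate is identified with the lipid dissociation
rate k_off and the residence time reported as τ = 1/k₁ (microseconds); the
fast component absorbs frame-discretization rattle and brief brushing
contacts. R² is computed on the fitted lag range.

Numerical choices that matter:

* **Lag range.** The (T − t) denominator makes long lags statistically poor:
  the tail of σ is carried by the handful of longest events, and a free
  4-parameter fit will happily track that correlated noise with a spuriously
  slow component. The default fitting range is 3× the lag at which σ first
  crosses 1/e, further capped at the lag where fewer than 4 events are still
  alive (but never below 2× the 1/e crossing), and always within
  [50, T/2] frames.
* **Initialization and multi-start.** A single-exponential fit provides the
  rate scale k̂; three biexponential starts at (k̂/10, k̂), (k̂/3, 3k̂) and
  (k̂, 1.5k̂) are tried and the best R² wins. The third start's fast rate
  carries a small seeded perturbation; the seed is exposed.
* **Identifiability floor.** If either fitted amplitude is below 10% of the
  total, the second component is declared unidentifiable and a
  single-exponential refit is reported with a degenerate second component
  (B = 0, k₂ = k₁). Noiseless biexponential curves with both amplitudes
  above the floor are still recovered to ≤ 1e−6.
* **Rate lower bound.** Rates are bounded below by 1/(2 T_total): a decay
  slower than the observation window cannot be distinguished from no decay,
  and an unbounded fit would otherwise occasionally report effectively
  infinite residence times.
* **Failure is explicit.** Non-convergence returns `converged=False` with a
  message, never a silent number.

Estimator precision: for exponential ground truth with T = 20 τ and ~500
events, the median relative error of τ across seeded replicates is ~4–6%
(the acceptance script measures it); single replicates can still err by
50–100% when one very long event dominates the tail — an information limit,
not a bug. Per-residue tables therefore omit residues with fewer than
`min_events` (default 5) events rather than reporting a meaningless number,
and residues never contacted are missing, not zero. Residue indices are
0-based internally and 1-based in every report.

## Binding sites

The residue co-contact network has edge weight(r, s) = number of
(frame, lipid) pairs in which one lipid simultaneously touches r and s —
the simplest frame-resolved definition consistent with reading communities
as binding sites; event-level correlation measures were deliberately not
used. Residues whose occupancy fraction is below `min_occupancy` (default
2%) never enter the network: a residue brushed only in passing is not part
of a site, and including such residues would surround genuine sites with a
halo of noise nodes. Louvain modularity maximization (networkx
implementation, fixed seed, resolution 1.0) partitions the network;
communities below `min_size` (default 3) residues are merged into the
community they share the most edge weight with, or dropped if they have no
outside connection. Sites are labeled BS0, BS1, … by descending occupancy so
labels are stable across reruns.

Per-site kinetics use union occupancy: a lipid is at the site while touching
*any* member residue, with per-lipid intervals merged before event
extraction. Site surface area is a Shrake–Rupley sphere-sampling SASA over
the site's beads (default bead radius 2.64 Å, probe 1.85 Å — typical CG
values, made explicit because no standard exists), averaged over ~10 frames;
coincident beads are deduplicated so degenerate geometries count once.

## Membrane descriptors

The bilayer normal is fixed to z (the target systems are semi-isotropic with
the membrane in the xy plane; no local-normal estimation). Leaflets are
assigned per frame by head-bead height against the instantaneous mean z of
all lipid beads, ties broken by tail direction. Thickness is the separation
of the two leaflets' mean head-bead planes — a head-plane definition, not a
density-profile peak distance. Area per lipid is a 2D periodic Voronoi
tessellation of head beads (implemented by 3×3 image replication, taking the
central cells, which tiles the box exactly); protein beads within 10 Å of
the leaflet plane are included as seeds and excluded from the lipid mean,
since a transmembrane protein occupies leaflet area and the naive box/N
estimate would be biased upward. P2 = ½(3⟨cos²θ⟩ − 1) is computed per
consecutive bead–bead bond against z, averaged over lipids and frames.
Means and SDs of frame series use block averaging (configurable block size)
to respect autocorrelation.

## Synthetic ground truth

Two generator levels:

* **Markov contact series** — independent two-state telegraph channels with
  dissociation rate k_off and effective association rate k_on, sampled in
  continuous time and discretized by reading the state at frame instants.
  Bound dwells are exactly exponential with mean 1/k_off (verified by KS
  test); sub-frame dwells can vanish in discretization, the same
  undersampling real saved frames impose.
* **3D toy system** — a rigid bundle of 7 bead columns (49 residues)
  spanning a bilayer of two background species in a 3:1 mole ratio plus a
  minority species at 0/5/10 mol %, 128 background lipids in a
  70×70×100 Å box, frames every 10 ns, 20 μs total (≥10× the longest
  planted residence time). Lipids are 3-bead chains (head + two tails) doing
  2D periodic Brownian motion (D = 5 Å²/ns) in their leaflet, reflected off
  a 16 Å exclusion disk around the protein. Binding sites (default: two
  4-residue sites on helices 0 and 3, τ = 1 and 2 μs, k_on = 2×10⁻³/ns per
  free lipid) are simulated exactly by a Gillespie chain over a shared free
  pool per leaflet; while bound, the designated lipid is held at the site
  with 0.4 Å jitter. Fixed seeds give bit-identical trajectories; files are
  written as GRO + XTC and read back through the normal I/O path.

What the toy system deliberately omits: protein dynamics (the bundle is
rigid — the analysis layer, not conformational sampling, is under test),
realistic lipid conformations (bonds are built along the normal, so P2 = 1
by construction), force-field energetics, membrane undulations and
flip-flop, and multi-lipid occupancy of one site. Passing the validation
therefore shows the *estimators* are correct and unbiased under known
kinetics; it says nothing about whether any particular force field or
system exhibits those kinetics, and absolute thickness/APL values of real
mixtures are out of scope.

## Problem sizes in the validation suite

The acceptance script and tests use 100 random event sets for the
survival-function oracle, 50 replicates × 4 time scales (1000 frames, 50
channels each) for residence-time recovery, 100 seeded toy-system replicates
(2000 frames each) for site recovery, and 100 planted-partition graphs for
Louvain — sizes at which the checked statistics are stable while the whole
suite runs in minutes on one CPU.

## Known limitations

* Only orthorhombic boxes; no triclinic support, no trajectory alignment.
* Kinetics below one frame stride are invisible; choose the stride
  accordingly.
* The biexponential model cannot separate a genuine slow component with
  amplitude under the 10% identifiability floor from noise.
* The surface-area estimate treats all beads with one radius; no
  per-bead-type radii.
* Louvain on a near-clique network can in principle split or merge sites at
  non-default resolutions; the resolution is exposed but untested away
  from 1.0.
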