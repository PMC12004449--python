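"""Recover planted binding sites by Louvain community detection.

The toy system plants two sites on helices 0 and 3 with residence times of
1 and 2 us. The residue co-contact network is partitioned into communities;
each community is one binding site with pooled kinetics and an approximate
bead-sphere surface area.
"""

from lipidsites import Selection, detect_contacts, identify_binding_sites
from lipidsites.synthetic import build_toy_system, default_config

cfg = default_config(mole_fraction_minority=0.10, seed=5)
toy = build_toy_system(cfg)
series = detect_contacts(
    toy.system, Selection(tuple(range(cfg.n_protein_residues)), "CL")
)
sites = identify_binding_sites(series, system=toy.system, seed=7)

print("planted ground truth:")
for s in cfg.sites:
    print(f"  residues {sorted(r + 1 for r in s.residue_ids)}  "
          f"tau_true = {s.tau_true_ns / 1000:.1f} us")

print("\nrecovered sites (ranked by occupancy):")
for s in sites:
    print(
        f"  BS{s.site_id}: residues {s.residues_1based()}  "
        f"tau = {s.residence_time:.2f} us  R^2 = {s.r_squared:.3f}  "
        f"area = {s.surface_area:.1f} nm^2  occupancy = {s.occupancy_fraction:.2f}"
    )
print(
    "\nResidue numbers are 1-based. tau is the slow biexponential component of\n"
    "the site's union-occupancy survival curve; with ~10-20 binding events per\n"
    "site, single-replicate tau estimates carry ~25% statistical error."
)
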