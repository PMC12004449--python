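"""Bilayer descriptors: thickness, area per lipid, order parameters.

Runs the membrane module on the toy system: leaflet assignment by head-bead
height, thickness as the phosphate-plane separation, area per lipid by
periodic Voronoi tessellation with protein beads as excluded seeds, and the
P2 order parameter for each consecutive lipid bond.
"""

import numpy as np

from lipidsites.membrane import block_mean_sd, membrane_profile
from lipidsites.synthetic import build_toy_system, default_config

toy = build_toy_system(default_config(0.10, seed=2, n_frames=200))
profile = membrane_profile(toy.system)

t_mean, t_sd = block_mean_sd(profile.thickness_series, block_size=10)
apl = (profile.apl_upper + profile.apl_lower) / 2.0
a_mean, a_sd = block_mean_sd(apl, block_size=10)

print(f"thickness:      {t_mean:.2f} +/- {t_sd:.2f} A")
print(f"area per lipid: {a_mean:.1f} +/- {a_sd:.1f} A^2 (protein-corrected)")
for sp, p2 in profile.order_params.items():
    print(f"P2 per bond, {sp}: {np.round(p2, 3)}")
print(
    "\nThe generator builds lipids with bonds along the bilayer normal, so\n"
    "P2 = 1 by construction; thickness is the head-plane separation (40 A)\n"
    "and APL reflects the box area minus the protein footprint. SDs use\n"
    "10-frame block averaging to respect frame autocorrelation."
)
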