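"""Detect dual-cutoff lipid-protein contacts on a synthetic system.

Builds a small toy trajectory (7-helix bundle in a POPE/POPG-like bilayer
with a cardiolipin-like minority species and two planted binding sites),
then extracts per-(lipid, residue) contact events with the 5/7 A
dual-cutoff hysteresis scheme.
"""

import numpy as np

from lipidsites import Selection, detect_contacts, events_from_series
from lipidsites.contacts import events_to_dataframe
from lipidsites.synthetic import build_toy_system, default_config

cfg = default_config(mole_fraction_minority=0.10, seed=1, n_frames=800)
toy = build_toy_system(cfg)

selection = Selection(
    protein_residues=tuple(range(cfg.n_protein_residues)),
    lipid_species_of_interest="CL",
)
series = detect_contacts(toy.system, selection, cutoff_lower=5.0, cutoff_upper=7.0)
events = events_from_series(series)
df = events_to_dataframe(events, series.frame_dt)

print(f"{len(events)} contact events between CL lipids and protein residues")
print(df.head(8).to_string(index=False))
lengths = df.end_ns - df.start_ns
print(f"\nlongest contact: {lengths.max():.0f} ns; median: {lengths.median():.0f} ns")
print(
    "Long events come from the planted binding sites; the short ones are\n"
    "diffusive brushes of free lipids passing the protein surface."
)
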