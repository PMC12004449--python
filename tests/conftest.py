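import numpy as np
import pytest

from lipidsites import CGSystem, Selection, detect_contacts
from lipidsites.synthetic import build_toy_system, default_config


@pytest.fixture(scope="session")
def toy():
    """One reference toy system: 10 mol % minority lipid, two planted sites
    with residence times of 1 and 2 us, 20 us at 10 ns stride."""
    return build_toy_system(default_config(0.10, seed=3))


@pytest.fixture(scope="session")
def toy_series(toy):
    sel = Selection(
        protein_residues=tuple(range(toy.config.n_protein_residues)),
        lipid_species_of_interest="CL",
        background_species=("POPE", "POPG"),
    )
    return detect_contacts(toy.system, sel)


def make_flat_bilayer(
    n_side=8,
    box_xy=80.0,
    head_z=20.0,
    species="POPE",
    n_frames=1,
    box_z=100.0,
    jitter=0.0,
    seed=0,
):
    """Protein-free lattice bilayer: n_side^2 lipids per leaflet, 3 beads each
    (head first), heads at +/- head_z around the box midplane."""
    rng = np.random.default_rng(seed)
    spacing = box_xy / n_side
    xs = (np.arange(n_side) + 0.5) * spacing
    xy = np.array([(x, y) for x in xs for y in xs])
    n_per_leaf = len(xy)
    mid = box_z / 2.0
    coords = []
    for leaf, sign in ((0, 1.0), (1, -1.0)):
        for x, y in xy:
            for k in range(3):
                coords.append((x, y, mid + sign * (head_z - 7.0 * k)))
    coords = np.asarray(coords)
    n_lipids = 2 * n_per_leaf
    frames = np.tile(coords, (n_frames, 1, 1))
    if jitter:
        frames = frames + rng.normal(0, jitter, size=frames.shape)
    return CGSystem(
        coords=frames,
        box=np.tile([box_xy, box_xy, box_z], (n_frames, 1)),
        frame_times=np.arange(n_frames, dtype=float),
        bead_residue=np.repeat(np.arange(n_lipids), 3),
        bead_molecule=np.repeat(np.arange(n_lipids), 3),
        molecule_species=[species] * n_lipids,
    )
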