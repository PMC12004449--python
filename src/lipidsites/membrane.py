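"""Bilayer descriptors: thickness, area per lipid, and bond order parameters.

The bilayer normal is taken as the z axis (the semi-isotropic setups this
package targets keep the membrane in the xy plane). Thickness is the
separation of the mean head-bead planes of the two leaflets; area per lipid
is a periodic 2D Voronoi tessellation of head beads with transmembrane
protein beads included as seeds but excluded from the lipid mean; the P2
order parameter is 1/2 (3<cos^2 theta> - 1) per consecutive bead-bead bond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

from .trajectory_io import CGSystem

__all__ = [
    "MembraneProfile",
    "assign_leaflets",
    "membrane_thickness",
    "area_per_lipid",
    "periodic_voronoi_areas",
    "order_parameters",
    "block_mean_sd",
]


@dataclass
class MembraneProfile:
    """Per-frame bilayer metrics; summarize with :func:`block_mean_sd`."""

    thickness_series: np.ndarray  # (n_frames,), A
    apl_upper: np.ndarray  # (n_frames,), A^2
    apl_lower: np.ndarray  # (n_frames,), A^2
    order_params: dict[str, np.ndarray]  # species -> P2 per bond
    leaflets: np.ndarray  # (n_frames, n_lipids), 0 upper / 1 lower


def _lipid_head_beads(system: CGSystem) -> tuple[np.ndarray, np.ndarray]:
    """(lipid molecule indices, head-bead index per lipid).

    The head bead of each lipid is its first bead (construction convention
    of both the synthetic generator and typical CG topologies, where the
    headgroup bead leads the residue).
    """
    species = np.asarray(system.molecule_species)
    lipid_mols = np.flatnonzero(species != "protein")
    heads = np.array(
        [system.beads_of_molecule(m)[0] for m in lipid_mols], dtype=np.int64
    )
    return lipid_mols, heads


def assign_leaflets(system: CGSystem) -> np.ndarray:
    """Per-frame leaflet label for each lipid: 0 = upper, 1 = lower.

    A lipid is in the upper leaflet when its head bead sits above the
    instantaneous midplane (mean z of all lipid beads). A head exactly at the
    midplane is classified by where its tail points: tail below head = upper.
    """
    lipid_mols, heads = _lipid_head_beads(system)
    lipid_bead_mask = np.isin(system.bead_molecule, lipid_mols)
    labels = np.empty((system.n_frames, lipid_mols.size), dtype=np.int64)
    for f in range(system.n_frames):
        z = system.coords[f, :, 2]
        midplane = z[lipid_bead_mask].mean()
        head_z = z[heads]
        lab = (head_z < midplane).astype(np.int64)
        ties = np.flatnonzero(head_z == midplane)
        for t in ties:
            beads = system.beads_of_molecule(lipid_mols[t])
            tail_z = z[beads[-1]]
            lab[t] = 0 if tail_z < head_z[t] else 1
        labels[f] = lab
    return labels


def membrane_thickness(
    system: CGSystem, leaflets: np.ndarray | None = None
) -> np.ndarray:
    """Per-frame thickness (A): |mean upper head z - mean lower head z|."""
    lipid_mols, heads = _lipid_head_beads(system)
    if leaflets is None:
        leaflets = assign_leaflets(system)
    thickness = np.empty(system.n_frames)
    for f in range(system.n_frames):
        hz = system.coords[f, heads, 2]
        up, lo = hz[leaflets[f] == 0], hz[leaflets[f] == 1]
        if up.size == 0 or lo.size == 0:
            raise ValueError(f"frame {f}: one leaflet is empty")
        thickness[f] = abs(up.mean() - lo.mean())
    return thickness


def periodic_voronoi_areas(points_xy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Voronoi cell area of each point under 2D periodic boundaries.

    The points are wrapped into the box and replicated into the 8 surrounding
    periodic images; the Voronoi cells of the central copies are then finite
    and exactly the periodic cells. Cell areas are computed with the shoelace
    formula; they sum to the box area.
    """
    pts = np.mod(points_xy, box_xy)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 seeds for a Voronoi tessellation")
    shifts = [
        (dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)
    ]
    tiled = np.vstack([pts] + [pts + np.asarray(s) * box_xy for s in shifts])
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise ValueError("unbounded Voronoi cell for a central point")
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    return areas


def area_per_lipid(
    system: CGSystem,
    leaflets: np.ndarray | None = None,
    protein_z_tolerance: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean Voronoi area per lipid (A^2) for (upper, lower) leaflets.

    Protein beads within ``protein_z_tolerance`` (A) of a leaflet's mean head
    plane are included as Voronoi seeds — a transmembrane protein occupies
    leaflet area — but their cells are excluded from the lipid average.
    """
    lipid_mols, heads = _lipid_head_beads(system)
    if leaflets is None:
        leaflets = assign_leaflets(system)
    species = np.asarray(system.molecule_species)
    prot_mols = np.flatnonzero(species == "protein")
    prot_beads = (
        np.flatnonzero(np.isin(system.bead_molecule, prot_mols))
        if prot_mols.size
        else np.array([], dtype=np.int64)
    )

    apl = np.empty((system.n_frames, 2))
    for f in range(system.n_frames):
        box_xy = system.box[f, :2]
        for side in (0, 1):
            sel = heads[leaflets[f] == side]
            if sel.size < 3:
                raise ValueError(f"frame {f}: fewer than 3 lipids in a leaflet")
            lipid_xy = system.coords[f, sel, :2]
            plane_z = system.coords[f, sel, 2].mean()
            seeds = [lipid_xy]
            n_lip = len(lipid_xy)
            if prot_beads.size:
                near = prot_beads[
                    np.abs(system.coords[f, prot_beads, 2] - plane_z)
                    < protein_z_tolerance
                ]
                if near.size:
                    seeds.append(system.coords[f, near, :2])
            areas = periodic_voronoi_areas(np.vstack(seeds), box_xy)
            apl[f, side] = areas[:n_lip].mean()
    return apl[:, 0], apl[:, 1]


def order_parameters(system: CGSystem, species: str) -> np.ndarray:
    """P2 order parameter per consecutive bead-bead bond of one lipid species.

    P2 = 1/2 (3 <cos^2 theta> - 1), theta against the z axis, averaged over
    all lipids of the species and all frames. Ranges from 1 (parallel to the
    normal) through 0 (isotropic) to -0.5 (in-plane).
    """
    mols = system.molecules_of_species(species)
    if mols.size == 0:
        raise ValueError(f"no molecules of species {species!r}")
    bead_lists = [system.beads_of_molecule(m) for m in mols]
    n_bonds = len(bead_lists[0]) - 1
    if n_bonds < 1:
        raise ValueError("species has fewer than 2 beads per molecule")
    cos2 = np.zeros(n_bonds)
    count = 0
    for f in range(system.n_frames):
        box = system.box[f]
        for beads in bead_lists:
            vec = system.coords[f, beads[1:]] - system.coords[f, beads[:-1]]
            vec -= box * np.round(vec / box)  # minimum-image bond vectors
            norm = np.linalg.norm(vec, axis=1)
            cos2 += (vec[:, 2] / norm) ** 2
        count += len(bead_lists)
    cos2 /= count
    return 0.5 * (3.0 * cos2 - 1.0)


def bond_order_parameter(vectors: np.ndarray) -> float:
    """P2 of a set of bond vectors against z; used for closed-form checks."""
    v = np.asarray(vectors, dtype=np.float64)
    cos2 = (v[:, 2] / np.linalg.norm(v, axis=1)) ** 2
    return float(0.5 * (3.0 * cos2.mean() - 1.0))


def block_mean_sd(series: np.ndarray, block_size: int = 1) -> tuple[float, float]:
    """Mean and SD of a frame series using block averaging.

    Frames within a block are averaged first, and the SD is taken over block
    means, which respects frame-to-frame autocorrelation. Trailing frames
    that do not fill a block are dropped.
    """
    x = np.asarray(series, dtype=np.float64)
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n_blocks = len(x) // block_size
    if n_blocks < 1:
        raise ValueError("series shorter than one block")
    blocks = x[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=1)) if n_blocks > 1 else 0.0


def membrane_profile(
    system: CGSystem, species: list[str] | None = None
) -> MembraneProfile:
    """Convenience wrapper computing all bilayer descriptors at once."""
    leaflets = assign_leaflets(system)
    thickness = membrane_thickness(system, leaflets)
    apl_u, apl_l = area_per_lipid(system, leaflets)
    if species is None:
        species = sorted(
            {s for s in system.molecule_species if s != "protein"}
        )
    order = {sp: order_parameters(system, sp) for sp in species}
    return MembraneProfile(
        thickness_series=thickness,
        apl_upper=apl_u,
        apl_lower=apl_l,
        order_params=order,
        leaflets=leaflets,
    )
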