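"""Dual-cutoff lipid-protein contact detection.

A contact between a lipid molecule and a protein residue STARTS at the first
frame where the minimum bead-bead distance drops below the lower cutoff
(default 5 A), PERSISTS through every subsequent frame where it stays below
the upper cutoff (default 7 A), and ENDS at the first frame at or above the
upper cutoff. The hysteresis suppresses rattling at the contact boundary that
a single cutoff would chop into many spurious short events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import CGSystem, Selection

__all__ = [
    "ContactSeries",
    "ContactEvent",
    "detect_contacts",
    "events_from_series",
    "occupancy_from_distances",
]

DEFAULT_CUTOFF_LOWER = 5.0  # A
DEFAULT_CUTOFF_UPPER = 7.0  # A


@dataclass
class ContactSeries:
    """Boolean occupancy over (lipid molecule, protein residue, frame).

    ``occupancy[i, r, f]`` is True while lipid ``lipid_ids[i]`` is in dual-cutoff
    contact with residue ``residue_ids[r]`` at frame ``f``. Contact is
    molecule-level for the lipid (any of its beads) and residue-level for the
    protein (any bead of the residue).
    """

    occupancy: np.ndarray  # bool (n_lipids, n_residues, n_frames)
    lipid_ids: np.ndarray  # molecule indices, (n_lipids,)
    residue_ids: np.ndarray  # residue indices, (n_residues,)
    frame_dt: float  # ns
    cutoff_lower: float = DEFAULT_CUTOFF_LOWER
    cutoff_upper: float = DEFAULT_CUTOFF_UPPER

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=np.int64)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be (n_lipids, n_residues, n_frames)")
        if self.cutoff_lower > self.cutoff_upper:
            raise ValueError("cutoff_lower must be <= cutoff_upper")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.occupancy.shape[2]

    def residue_slice(self, residue_id: int) -> np.ndarray:
        """(n_lipids, n_frames) occupancy for one residue."""
        (idx,) = np.nonzero(self.residue_ids == residue_id)
        if idx.size == 0:
            raise KeyError(f"residue {residue_id} not in series")
        return self.occupancy[:, idx[0], :]


@dataclass(frozen=True)
class ContactEvent:
    """A maximal run of occupied frames, half-open ``[start_frame, end_frame)``.

    ``censored`` marks events still open at the last frame: their true duration
    exceeds the observed one, so they enter the survival function only up to
    the observed length.
    """

    lipid_id: int
    residue_id: int
    start_frame: int
    end_frame: int
    censored: bool = False

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def occupancy_from_distances(
    min_dist: np.ndarray, cutoff_lower: float, cutoff_upper: float
) -> np.ndarray:
    """Apply dual-cutoff hysteresis along the last (frame) axis.

    ``min_dist`` holds per-frame minimum bead-bead distances for any number of
    leading channel axes. Occupied at frame f iff dist < lower, or
    (occupied at f-1 and dist < upper).
    """
    if cutoff_lower > cutoff_upper:
        raise ValueError("cutoff_lower must be <= cutoff_upper")
    below_lo = min_dist < cutoff_lower
    below_hi = min_dist < cutoff_upper
    occ = np.zeros_like(below_lo, dtype=bool)
    occ[..., 0] = below_lo[..., 0]
    for f in range(1, min_dist.shape[-1]):
        occ[..., f] = below_lo[..., f] | (occ[..., f - 1] & below_hi[..., f])
    return occ


def detect_contacts(
    system: CGSystem,
    selection: Selection,
    cutoff_lower: float = DEFAULT_CUTOFF_LOWER,
    cutoff_upper: float = DEFAULT_CUTOFF_UPPER,
) -> ContactSeries:
    """Build the dual-cutoff :class:`ContactSeries` for one lipid species.

    Per frame, the minimum-image minimum bead-bead distance is computed
    between every bead of each lipid of ``selection.lipid_species_of_interest``
    and every bead of each selected protein residue, using a periodic KD-tree
    restricted to pairs within ``cutoff_upper``; anything farther never
    matters to the hysteresis.
    """
    if not (0 < cutoff_lower < cutoff_upper) and cutoff_lower != cutoff_upper:
        raise ValueError("need 0 < cutoff_lower <= cutoff_upper")
    lipid_mols = system.molecules_of_species(selection.lipid_species_of_interest)
    if lipid_mols.size == 0:
        raise ValueError(
            f"no molecules of species {selection.lipid_species_of_interest!r}"
        )
    residues = np.asarray(sorted(selection.protein_residues), dtype=np.int64)
    if residues.size == 0:
        raise ValueError("empty protein residue selection")

    prot_mask = np.isin(system.bead_residue, residues)
    prot_beads = np.flatnonzero(prot_mask)
    if prot_beads.size == 0:
        raise ValueError("selected residues have no beads in the system")
    # channel index maps
    res_pos = {r: i for i, r in enumerate(residues)}
    prot_channel = np.array(
        [res_pos[r] for r in system.bead_residue[prot_beads]], dtype=np.int64
    )
    lip_mask = np.isin(system.bead_molecule, lipid_mols)
    lip_beads = np.flatnonzero(lip_mask)
    mol_pos = {m: i for i, m in enumerate(lipid_mols)}
    lip_channel = np.array(
        [mol_pos[m] for m in system.bead_molecule[lip_beads]], dtype=np.int64
    )

    n_lip, n_res, n_frames = lipid_mols.size, residues.size, system.n_frames
    big = np.inf
    min_dist = np.full((n_lip, n_res, n_frames), big)

    for f in range(n_frames):
        box = system.box[f]
        ppos = np.mod(system.coords[f, prot_beads], box)
        lpos = np.mod(system.coords[f, lip_beads], box)
        tree_p = cKDTree(ppos, boxsize=box)
        tree_l = cKDTree(lpos, boxsize=box)
        dmat = tree_l.sparse_distance_matrix(
            tree_p, max_distance=cutoff_upper, output_type="coo_matrix"
        )
        if dmat.nnz == 0:
            continue
        li = lip_channel[dmat.row]
        ri = prot_channel[dmat.col]
        np.minimum.at(min_dist[:, :, f], (li, ri), dmat.data)

    occ = occupancy_from_distances(min_dist, cutoff_lower, cutoff_upper)
    return ContactSeries(
        occupancy=occ,
        lipid_ids=lipid_mols,
        residue_ids=residues,
        frame_dt=system.frame_dt if n_frames > 1 else 1.0,
        cutoff_lower=cutoff_lower,
        cutoff_upper=cutoff_upper,
    )


def _runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) pairs."""
    padded = np.concatenate(([False], row, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def events_from_series(series: ContactSeries) -> list[ContactEvent]:
    """Extract maximal contact events from a :class:`ContactSeries`.

    Events still occupied at the final frame are flagged ``censored``.
    """
    n_frames = series.n_frames
    events: list[ContactEvent] = []
    for i, lip in enumerate(series.lipid_ids):
        for r, res in enumerate(series.residue_ids):
            for s, e in _runs(series.occupancy[i, r]):
                events.append(
                    ContactEvent(
                        lipid_id=int(lip),
                        residue_id=int(res),
                        start_frame=int(s),
                        end_frame=int(e),
                        censored=bool(e == n_frames),
                    )
                )
    return events


def events_to_dataframe(events: list[ContactEvent], frame_dt: float):
    """Tabulate events as (lipid_id, residue, start_ns, end_ns, censored)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "lipid_id": [e.lipid_id for e in events],
            "residue": [e.residue_id + 1 for e in events],  # 1-based in reports
            "start_ns": [e.start_frame * frame_dt for e in events],
            "end_ns": [e.end_frame * frame_dt for e in events],
            "censored": [e.censored for e in events],
        }
    )
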