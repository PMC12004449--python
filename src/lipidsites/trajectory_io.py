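"""Topology/trajectory loading into the common coarse-grained system container.

Internal units are Angstrom for lengths and nanoseconds for times; all unit
conversion happens at the I/O boundary (GRO files store nm, MDAnalysis hands
back Angstrom and ps). Only orthorhombic periodic boxes are supported, which
matches the semi-isotropic bilayer setups this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CGSystem",
    "Selection",
    "FormatError",
    "EmptyTrajectoryError",
    "load_system",
    "write_system",
    "trim_trajectory",
    "minimum_image_distance",
]


class FormatError(ValueError):
    """Topology/trajectory inconsistency or unsupported box geometry."""


class EmptyTrajectoryError(ValueError):
    """An operation removed every frame."""


@dataclass
class CGSystem:
    """In-memory frame stream of a coarse-grained protein + bilayer system.

    Attributes
    ----------
    coords : (n_frames, n_beads, 3) float array, Angstrom.
    box : (n_frames, 3) float array, orthorhombic box lengths in Angstrom.
    frame_times : (n_frames,) float array, ns, strictly increasing.
    bead_residue : (n_beads,) int array, residue index per bead (0-based).
    bead_molecule : (n_beads,) int array, molecule index per bead.
    molecule_species : list of str, species label per molecule
        ("protein" or a lipid species name such as "POPE", "CL").
    """

    coords: np.ndarray
    box: np.ndarray
    frame_times: np.ndarray
    bead_residue: np.ndarray
    bead_molecule: np.ndarray
    molecule_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        self.bead_residue = np.asarray(self.bead_residue, dtype=np.int64)
        self.bead_molecule = np.asarray(self.bead_molecule, dtype=np.int64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_beads, 3)")
        n_frames, n_beads = self.coords.shape[:2]
        if self.box.shape != (n_frames, 3):
            raise FormatError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise FormatError("box lengths must be positive")
        if self.frame_times.shape != (n_frames,):
            raise FormatError("frame_times must have one entry per frame")
        if n_frames > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise FormatError("frame_times must be strictly increasing")
        if self.bead_residue.shape != (n_beads,) or self.bead_molecule.shape != (n_beads,):
            raise FormatError("per-bead maps must have one entry per bead")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_dt(self) -> float:
        """Frame spacing in ns (assumes a uniform stride)."""
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames to define a stride")
        return float(self.frame_times[1] - self.frame_times[0])

    def molecules_of_species(self, species: str) -> np.ndarray:
        """Molecule indices whose species label equals ``species``."""
        return np.flatnonzero(np.asarray(self.molecule_species) == np.str_(species))

    def beads_of_molecule(self, molecule: int) -> np.ndarray:
        return np.flatnonzero(self.bead_molecule == molecule)

    def protein_residues(self) -> np.ndarray:
        """Sorted residue indices belonging to protein molecules."""
        prot_mols = {m for m, s in enumerate(self.molecule_species) if s == "protein"}
        mask = np.isin(self.bead_molecule, list(prot_mols))
        return np.unique(self.bead_residue[mask])


@dataclass(frozen=True)
class Selection:
    """What to analyze: which residues are protein, which lipid species matters.

    ``lipid_species_of_interest`` names the species whose binding kinetics are
    under study (e.g. the cardiolipin analog); ``background_species`` are the
    bulk bilayer lipids used only for membrane-level metrics.
    """

    protein_residues: tuple[int, ...]
    lipid_species_of_interest: str
    background_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.protein_residues) == 0:
            raise ValueError("protein_residues must be non-empty")


def load_system(
    topology_path,
    trajectory_path,
    protein_resnames: tuple[str, ...] = ("PRO",),
) -> CGSystem:
    """Read a topology + trajectory pair into a :class:`CGSystem`.

    Coordinates come back in Angstrom and times in ns regardless of on-disk
    units (MDAnalysis normalizes GRO/XTC nm -> Angstrom, ps internally).
    Every residue whose resname is in ``protein_resnames`` is grouped into a
    single protein molecule; every other residue is one lipid molecule whose
    species label is its resname.

    Raises
    ------
    FormatError
        If the trajectory bead count disagrees with the topology, or any
        frame's box is non-orthorhombic.
    """
    import MDAnalysis as mda
    from MDAnalysis.exceptions import NoDataError

    try:
        u = mda.Universe(str(topology_path), str(trajectory_path))
    except (ValueError, OSError, NoDataError) as exc:
        raise FormatError(f"cannot load {topology_path} + {trajectory_path}: {exc}") from exc

    n_beads = len(u.atoms)
    resids = u.atoms.resindices  # 0-based contiguous residue indices
    resnames = [u.residues.resnames[i] for i in range(len(u.residues))]

    bead_residue = np.asarray(resids, dtype=np.int64)
    molecule_species: list[str] = []
    residue_molecule = np.empty(len(u.residues), dtype=np.int64)
    protein_mol: int | None = None
    for ri, rn in enumerate(resnames):
        if rn in protein_resnames:
            if protein_mol is None:
                protein_mol = len(molecule_species)
                molecule_species.append("protein")
            residue_molecule[ri] = protein_mol
        else:
            residue_molecule[ri] = len(molecule_species)
            molecule_species.append(rn)
    bead_molecule = residue_molecule[bead_residue]

    coords, boxes, times = [], [], []
    for ts in u.trajectory:
        if ts.n_atoms != n_beads:
            raise FormatError(
                f"trajectory frame has {ts.n_atoms} beads, topology has {n_beads}"
            )
        dims = ts.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise FormatError("frame lacks box dimensions")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise FormatError("only orthorhombic boxes are supported")
        coords.append(ts.positions.astype(np.float64).copy())
        boxes.append(dims[:3].astype(np.float64).copy())
        times.append(ts.time / 1000.0)  # ps -> ns

    return CGSystem(
        coords=np.stack(coords),
        box=np.stack(boxes),
        frame_times=np.asarray(times),
        bead_residue=bead_residue,
        bead_molecule=bead_molecule,
        molecule_species=molecule_species,
    )


def write_system(system: CGSystem, topology_path, trajectory_path) -> None:
    """Write a :class:`CGSystem` as a GRO topology + XTC trajectory.

    Protein residues get resname "PRO" and bead name "BB"; lipid residues get
    their species label as resname and bead names B1, B2, ... XTC stores
    positions at 1e-3 nm precision, so a round-trip through
    :func:`load_system` reproduces coordinates to ~1e-2 A.
    """
    import MDAnalysis as mda

    n_beads = system.n_beads
    n_res = int(system.bead_residue.max()) + 1
    u = mda.Universe.empty(
        n_beads,
        n_residues=n_res,
        atom_resindex=system.bead_residue,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    resnames = []
    names = np.empty(n_beads, dtype=object)
    species = np.asarray(system.molecule_species)
    for ri in range(n_res):
        beads = np.flatnonzero(system.bead_residue == ri)
        mol = system.bead_molecule[beads[0]]
        if species[mol] == "protein":
            resnames.append("PRO")
            names[beads] = "BB"
        else:
            resnames.append(str(species[mol])[:5])
            for k, b in enumerate(beads):
                names[b] = f"B{k + 1}"
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("names", list(names))
    u.add_TopologyAttr("resids", list(range(1, n_res + 1)))

    u.atoms.positions = system.coords[0]
    u.dimensions = np.concatenate([system.box[0], [90.0, 90.0, 90.0]])
    u.atoms.write(str(topology_path))

    with mda.Writer(str(trajectory_path), n_beads) as w:
        for f in range(system.n_frames):
            u.atoms.positions = system.coords[f]
            u.dimensions = np.concatenate([system.box[f], [90.0, 90.0, 90.0]])
            u.trajectory.ts.time = system.frame_times[f] * 1000.0  # ns -> ps
            u.trajectory.ts.frame = f
            w.write(u.atoms)


def trim_trajectory(system: CGSystem, t_discard: float) -> CGSystem:
    """Drop all frames with time < ``t_discard`` (ns) and re-origin time to 0.

    Discarding an initial decorrelation window (2 us is the conventional
    choice for us-scale CG production runs) removes memory of the starting
    configuration before kinetics are measured.

    Raises
    ------
    EmptyTrajectoryError
        If no frame survives the trim.
    """
    if t_discard < 0:
        raise ValueError("t_discard must be >= 0")
    keep = system.frame_times >= t_discard
    if not keep.any():
        raise EmptyTrajectoryError(
            f"t_discard={t_discard} ns removes all {system.n_frames} frames"
        )
    times = system.frame_times[keep]
    return replace(
        system,
        coords=system.coords[keep],
        box=system.box[keep],
        frame_times=times - times[0],
    )


def minimum_image_distance(a, b, box) -> np.ndarray:
    """Minimum-image Euclidean distance under an orthorhombic box.

    ``a`` and ``b`` broadcast against each other over the last axis (length 3);
    ``box`` is the 3 box lengths. Returns a scalar for single points.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    d = a - b
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))
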