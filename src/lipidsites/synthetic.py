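"""Synthetic ground-truth systems for validating the analysis pipeline.

Two levels of realism are provided:

* :func:`simulate_contact_series` draws raw boolean lipid-residue contact
  series from a continuous-time two-state (bound/unbound) Markov telegraph
  process, discretized to frames. This is the direct ground truth for
  survival-function and k_off-recovery checks: bound dwells are exponential
  with mean 1/k_off by construction.

* :func:`build_toy_system` emits full 3D coordinates of a rigid 7-helix
  transmembrane bead bundle in a two-species background bilayer (3:1 mole
  ratio, emulating a POPE:POPG mixture) plus a minority lipid species (a
  cardiolipin analog) at a configurable mole fraction. Binding sites are
  planted on the protein: a site binds a free minority lipid with rate
  k_on per free lipid and releases it with rate k_off_true (Gillespie
  simulation in continuous time); while bound, the lipid is held within the
  capture radius of the site's residues, otherwise lipids perform 2D
  periodic Brownian motion in their leaflet.

The toy lipid has 3 beads (head + two tail beads): contact detection only
needs any-bead distances, so the full multi-tail lipid topology is not
modeled. The protein is rigid because the analysis layer, not protein
dynamics, is under test. Dwell times are sampled in continuous time and then
binned to frames, so a dwell shorter than the frame stride can vanish --
the same undersampling bias real saved MD frames impose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactSeries
from .trajectory_io import CGSystem

__all__ = [
    "PlantedSite",
    "SyntheticConfig",
    "ToySystem",
    "sample_telegraph",
    "simulate_contact_series",
    "build_toy_system",
    "default_config",
]

N_HELICES = 7
HELIX_RING_RADIUS = 12.0  # A, helix axes on a ring around the box center
EXCLUSION_RADIUS = 16.0  # A, free lipids reflected off this disk
LEAFLET_HEAD_Z = 20.0  # A above/below the bilayer midplane
LIPID_BEAD_DZ = 7.0  # A spacing between the 3 lipid beads
BOUND_LATERAL_OFFSET = 3.2  # A, bound lipid held this far outside its helix
BOUND_JITTER_SD = 0.4  # A, positional jitter of the bound lipid per frame


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one binding site.

    ``k_on`` is the association rate per free minority lipid (1/ns);
    ``k_off_true`` the dissociation rate (1/ns), so the true residence
    time is 1/k_off_true. ``residue_ids`` must be disjoint across sites.
    """

    residue_ids: frozenset[int]
    k_on: float
    k_off_true: float
    capture_radius: float = 5.0

    def __post_init__(self) -> None:
        if not self.residue_ids:
            raise ValueError("residue_ids must be non-empty")
        if self.k_off_true <= 0 or self.k_on <= 0:
            raise ValueError("rates must be positive")

    @property
    def tau_true_ns(self) -> float:
        return 1.0 / self.k_off_true


@dataclass
class SyntheticConfig:
    """Study conditions for the toy system.

    Defaults emulate the reference conditions: two background species in a
    3:1 mole ratio plus a minority species at 10 mol %, frames every 10 ns,
    20 us total -- at least 10x the longest planted residence time.
    """

    n_lipids_by_species: dict[str, int] = field(
        default_factory=lambda: {"POPE": 96, "POPG": 32, "CL": 14}
    )
    minority_species: str = "CL"
    box: tuple[float, float, float] = (70.0, 70.0, 100.0)
    n_frames: int = 2000
    frame_dt: float = 10.0  # ns
    diffusion_coeff: float = 5.0  # A^2/ns, lateral
    seed: int = 0
    sites: list[PlantedSite] = field(default_factory=list)
    n_protein_residues: int = 49

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if any(n < 0 for n in self.n_lipids_by_species.values()):
            raise ValueError("lipid counts must be non-negative")
        if self.minority_species not in self.n_lipids_by_species:
            raise ValueError("minority species missing from composition")
        used: set[int] = set()
        for s in self.sites:
            if used & s.residue_ids:
                raise ValueError("planted sites must have disjoint residues")
            used |= s.residue_ids
            if max(s.residue_ids) >= self.n_protein_residues:
                raise ValueError("site residue outside protein")

    @property
    def mole_fraction_minority(self) -> float:
        total = sum(self.n_lipids_by_species.values())
        return self.n_lipids_by_species[self.minority_species] / total if total else 0.0

    @property
    def t_total(self) -> float:
        return self.n_frames * self.frame_dt


@dataclass
class ToySystem:
    """A generated system plus its ground truth."""

    system: CGSystem
    config: SyntheticConfig
    # bound_site[f, i] = site index occupying minority lipid i at frame f, or -1
    bound_site: np.ndarray


def default_config(
    mole_fraction_minority: float = 0.10,
    seed: int = 0,
    n_frames: int = 2000,
    frame_dt: float = 10.0,
    tau_true_ns: tuple[float, ...] = (1000.0, 2000.0),
) -> SyntheticConfig:
    """Reference conditions: 3:1 background mixture, minority at 0/5/10 mol %,
    two planted 4-residue sites with residence times of 1 and 2 us."""
    n_bg = 128
    if not 0 <= mole_fraction_minority < 1:
        raise ValueError("mole fraction must be in [0, 1)")
    n_min = int(round(mole_fraction_minority / (1 - mole_fraction_minority) * n_bg))
    per_helix = 7
    # sites on helices 0 and 3 (well separated), upper-leaflet half of the helix
    site_helices = (0, 3)
    sites = []
    if n_min > 0:
        for h, tau in zip(site_helices, tau_true_ns):
            residues = frozenset(h * per_helix + lvl for lvl in (3, 4, 5, 6))
            sites.append(
                PlantedSite(residue_ids=residues, k_on=2e-3, k_off_true=1.0 / tau)
            )
    return SyntheticConfig(
        n_lipids_by_species={"POPE": 96, "POPG": 32, "CL": n_min},
        minority_species="CL",
        n_frames=n_frames,
        frame_dt=frame_dt,
        seed=seed,
        sites=sites,
    )


# ---------------------------------------------------------------------------
# level 1: Markov contact series


def sample_telegraph(
    k_off: float,
    k_on: float,
    t_total: float,
    rng: np.random.Generator,
    start_bound: bool | None = None,
) -> tuple[bool, np.ndarray]:
    """Sample one continuous-time bound/unbound telegraph realization.

    Returns ``(initial_bound, transition_times)`` where transition times are
    strictly increasing and < t_total; the state flips at each. If
    ``start_bound`` is None the initial state is drawn from the stationary
    distribution k_on / (k_on + k_off).
    """
    if k_off <= 0 or k_on <= 0:
        raise ValueError("rates must be positive")
    if t_total <= 0:
        raise ValueError("t_total must be positive")
    if start_bound is None:
        start_bound = bool(rng.random() < k_on / (k_on + k_off))
    times = []
    t = 0.0
    bound = start_bound
    while True:
        rate = k_off if bound else k_on
        t += rng.exponential(1.0 / rate)
        if t >= t_total:
            break
        times.append(t)
        bound = not bound
    return bool(start_bound), np.asarray(times)


def telegraph_to_frames(
    initial_bound: bool, transitions: np.ndarray, n_frames: int, frame_dt: float
) -> np.ndarray:
    """State at each frame instant f * frame_dt (True = bound)."""
    frame_times = np.arange(n_frames) * frame_dt
    n_before = np.searchsorted(transitions, frame_times, side="right")
    return (n_before % 2 == 1) != initial_bound  # XOR of parity with initial


def simulate_contact_series(
    k_off: float,
    k_on_eff: float,
    n_frames: int,
    frame_dt: float,
    n_lipids: int,
    seed: int,
    start_bound: bool | None = None,
) -> ContactSeries:
    """Raw contact series of ``n_lipids`` independent telegraph channels
    against a single nominal residue.

    Rates are per unit of ``frame_dt``'s time unit. Bound dwell times are
    exponential with mean 1/k_off in continuous time, then discretized by
    sampling the state at frame instants, so sub-frame dwells may vanish.
    """
    if n_lipids < 1 or n_frames < 2:
        raise ValueError("need n_lipids >= 1 and n_frames >= 2")
    rng = np.random.default_rng(seed)
    t_total = n_frames * frame_dt
    occ = np.zeros((n_lipids, 1, n_frames), dtype=bool)
    for i in range(n_lipids):
        init, trans = sample_telegraph(k_off, k_on_eff, t_total, rng, start_bound)
        occ[i, 0] = telegraph_to_frames(init, trans, n_frames, frame_dt)
    return ContactSeries(
        occupancy=occ,
        lipid_ids=np.arange(n_lipids),
        residue_ids=np.array([0]),
        frame_dt=frame_dt,
        cutoff_lower=0.0,
        cutoff_upper=0.0,
    )


# ---------------------------------------------------------------------------
# level 2: 3D toy trajectory


def _protein_layout(n_residues: int, box: np.ndarray) -> np.ndarray:
    """(n_residues, 3) bead coordinates of the rigid 7-column bundle."""
    per_helix = int(np.ceil(n_residues / N_HELICES))
    center = box / 2.0
    zs = np.linspace(-16.5, 16.5, per_helix)
    coords = np.empty((n_residues, 3))
    for i in range(n_residues):
        h, lvl = divmod(i, per_helix)
        ang = 2.0 * np.pi * h / N_HELICES
        coords[i] = (
            center[0] + HELIX_RING_RADIUS * np.cos(ang),
            center[1] + HELIX_RING_RADIUS * np.sin(ang),
            center[2] + zs[lvl],
        )
    return coords


def _site_anchor(site_residues: np.ndarray, prot_xyz: np.ndarray, box: np.ndarray):
    """Bound-pose template: (anchor_xy, bead_zs) for a planted site."""
    center = box[:2] / 2.0
    res_xyz = prot_xyz[site_residues]
    helix_xy = res_xyz[:, :2].mean(axis=0)
    radial = helix_xy - center
    radial /= np.linalg.norm(radial)
    anchor_xy = helix_xy + BOUND_LATERAL_OFFSET * radial
    z_lo, z_hi = res_xyz[:, 2].min(), res_xyz[:, 2].max()
    if z_hi - z_lo < 1e-9:
        z_hi = z_lo + 1.0
    bead_zs = np.linspace(z_lo, z_hi, 3)
    return anchor_xy, bead_zs


def _gillespie_binding(
    sites: list[PlantedSite],
    site_leaflet: np.ndarray,
    lipid_leaflet: np.ndarray,
    t_total: float,
    rng: np.random.Generator,
) -> list[tuple[int, int, float, float]]:
    """Exact stochastic simulation of site occupancy with a shared free pool.

    Returns bound intervals (site, minority lipid index, t_start, t_end).
    """
    n_sites = len(sites)
    free: dict[int, list[int]] = {
        0: sorted(np.flatnonzero(lipid_leaflet == 0).tolist()),
        1: sorted(np.flatnonzero(lipid_leaflet == 1).tolist()),
    }
    bound_lipid = [-1] * n_sites
    start_time = [0.0] * n_sites
    intervals: list[tuple[int, int, float, float]] = []
    t = 0.0
    while True:
        rates = np.array(
            [
                s.k_off_true
                if bound_lipid[i] >= 0
                else s.k_on * len(free[site_leaflet[i]])
                for i, s in enumerate(sites)
            ]
        )
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_total:
            break
        i = int(rng.choice(n_sites, p=rates / total))
        if bound_lipid[i] >= 0:
            intervals.append((i, bound_lipid[i], start_time[i], t))
            free[site_leaflet[i]].append(bound_lipid[i])
            bound_lipid[i] = -1
        else:
            pool = free[site_leaflet[i]]
            j = pool.pop(int(rng.integers(len(pool))))
            bound_lipid[i] = j
            start_time[i] = t
    for i in range(n_sites):
        if bound_lipid[i] >= 0:  # censored at trajectory end
            intervals.append((i, bound_lipid[i], start_time[i], t_total))
    return intervals


def build_toy_system(config: SyntheticConfig) -> ToySystem:
    """Generate the toy protein + bilayer trajectory with planted kinetics.

    Raises a packing error if the box cannot hold the requested lipid count
    at a plausible area per lipid.
    """
    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box, dtype=np.float64)
    center = box / 2.0

    species_order = list(config.n_lipids_by_species)
    lipid_species: list[str] = []
    for sp in species_order:
        lipid_species += [sp] * config.n_lipids_by_species[sp]
    n_lipids = len(lipid_species)
    # alternate leaflets within each species so compositions match per leaflet
    leaflet = np.empty(n_lipids, dtype=np.int64)
    pos = 0
    for sp in species_order:
        n = config.n_lipids_by_species[sp]
        leaflet[pos : pos + n] = np.arange(n) % 2
        pos += n

    usable = box[0] * box[1] - np.pi * EXCLUSION_RADIUS**2
    for lf in (0, 1):
        n_lf = int((leaflet == lf).sum())
        if n_lf and usable / n_lf < 40.0:  # ~ smallest physical area per lipid
            raise ValueError(
                f"box too small: {usable:.0f} A^2 for {n_lf} lipids in one leaflet"
            )

    prot_xyz = _protein_layout(config.n_protein_residues, box)

    minority_idx = np.flatnonzero(np.asarray(lipid_species) == config.minority_species)
    min_leaflet = leaflet[minority_idx]

    site_res = [np.asarray(sorted(s.residue_ids)) for s in config.sites]
    anchors = [_site_anchor(r, prot_xyz, box) for r in site_res]
    site_leaflet = np.array(
        [0 if prot_xyz[r][:, 2].mean() >= center[2] else 1 for r in site_res],
        dtype=np.int64,
    )  # 0 = upper
    for i, s in enumerate(config.sites):
        if not (min_leaflet == site_leaflet[i]).any():
            raise ValueError("no minority lipid available in the site's leaflet")

    intervals = _gillespie_binding(
        config.sites, site_leaflet, min_leaflet, config.t_total, rng
    ) if config.sites else []

    # per-frame bound-site map for minority lipids (-1 = free)
    bound_site = np.full((config.n_frames, minority_idx.size), -1, dtype=np.int64)
    frame_times = np.arange(config.n_frames) * config.frame_dt
    for site_i, lip_i, t0, t1 in intervals:  # lip_i indexes the minority pool
        f0 = int(np.searchsorted(frame_times, t0, side="left"))
        f1 = int(np.searchsorted(frame_times, t1, side="left"))
        bound_site[f0:f1, lip_i] = site_i

    # initial head positions: uniform outside the exclusion disk
    head_xy = np.empty((n_lipids, 2))
    n_placed = 0
    while n_placed < n_lipids:
        cand = rng.uniform(0, 1, size=(n_lipids, 2)) * box[:2]
        ok = np.linalg.norm(cand - center[:2], axis=1) >= EXCLUSION_RADIUS
        take = min(int(ok.sum()), n_lipids - n_placed)
        head_xy[n_placed : n_placed + take] = cand[ok][:take]
        n_placed += take

    step_sd = np.sqrt(2.0 * config.diffusion_coeff * config.frame_dt)
    head_z = np.where(leaflet == 0, center[2] + LEAFLET_HEAD_Z, center[2] - LEAFLET_HEAD_Z)
    tail_sign = np.where(leaflet == 0, -1.0, 1.0)  # tails point to the midplane

    n_prot = config.n_protein_residues
    n_beads = n_prot + 3 * n_lipids
    coords = np.empty((config.n_frames, n_beads, 3))
    coords[:, :n_prot, :] = prot_xyz[None, :, :]

    lipid_bead0 = n_prot + 3 * np.arange(n_lipids)
    for f in range(config.n_frames):
        if f > 0:
            head_xy += rng.normal(0.0, step_sd, size=head_xy.shape)
            # reflect off the protein exclusion disk, then wrap
            d = head_xy - center[:2]
            r = np.linalg.norm(d, axis=1)
            inside = r < EXCLUSION_RADIUS
            if inside.any():
                safe_r = np.where(r[inside] < 1e-9, 1e-9, r[inside])
                head_xy[inside] = center[:2] + d[inside] / safe_r[:, None] * (
                    2 * EXCLUSION_RADIUS - safe_r
                )[:, None]
            head_xy %= box[:2]

        frame_xy = head_xy.copy()
        frame_zs = np.stack(
            [head_z, head_z + tail_sign * LIPID_BEAD_DZ, head_z + 2 * tail_sign * LIPID_BEAD_DZ],
            axis=1,
        )
        if config.sites:
            for mpos, lip in enumerate(minority_idx):
                s = bound_site[f, mpos]
                if s >= 0:
                    anchor_xy, bead_zs = anchors[s]
                    jxy = anchor_xy + rng.normal(0.0, BOUND_JITTER_SD, size=2)
                    frame_xy[lip] = jxy
                    head_xy[lip] = jxy  # release continues from the site
                    # head bead farthest from the midplane
                    frame_zs[lip] = bead_zs[::-1] if site_leaflet[s] == 0 else bead_zs
        for b in range(3):
            coords[f, lipid_bead0 + b, 0] = frame_xy[:, 0]
            coords[f, lipid_bead0 + b, 1] = frame_xy[:, 1]
            coords[f, lipid_bead0 + b, 2] = frame_zs[:, b]

    bead_residue = np.concatenate(
        [np.arange(n_prot), n_prot + np.repeat(np.arange(n_lipids), 3)]
    )
    bead_molecule = np.concatenate(
        [np.zeros(n_prot, dtype=np.int64), 1 + np.repeat(np.arange(n_lipids), 3)]
    )
    molecule_species = ["protein"] + lipid_species

    system = CGSystem(
        coords=coords,
        box=np.tile(box, (config.n_frames, 1)),
        frame_times=frame_times.astype(np.float64),
        bead_residue=bead_residue,
        bead_molecule=bead_molecule,
        molecule_species=molecule_species,
    )
    return ToySystem(system=system, config=config, bound_site=bound_site)
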