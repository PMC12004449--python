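"""Binding-site identification by community detection on a residue network.

Residues that the lipid species of interest contacts are nodes; the edge
weight between residues r and s counts the (frame, lipid) pairs in which the
same lipid molecule simultaneously contacts both. Louvain modularity
maximization then partitions the network into communities, each read as one
binding site. Per-site kinetics treat a lipid as "at the site" while it
touches any site residue (union occupancy), and an approximate
solvent-accessible surface area is computed over the site's beads.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .contacts import ContactEvent, ContactSeries, events_from_series
from .kinetics import (
    KineticFit,
    default_lag_range,
    fit_biexponential,
    survival_function,
)
from .trajectory_io import CGSystem

__all__ = [
    "ResidueGraph",
    "BindingSite",
    "build_residue_graph",
    "louvain_partition",
    "site_union_events",
    "site_kinetics",
    "site_surface_area",
    "identify_binding_sites",
]

DEFAULT_BEAD_RADIUS = 2.64  # A, typical CG bead van der Waals radius
DEFAULT_PROBE_RADIUS = 1.85  # A, CG water half-bead


@dataclass
class ResidueGraph:
    """Symmetric non-negative co-contact weights between contacted residues."""

    graph: nx.Graph

    def weight(self, r: int, s: int) -> float:
        return self.graph[r][s]["weight"] if self.graph.has_edge(r, s) else 0.0

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)


@dataclass
class BindingSite:
    """One community of residues with aggregated kinetics.

    ``occupancy_fraction`` is the fraction of frames in which at least one
    lipid of the species of interest touches the site.
    """

    site_id: int
    residues: frozenset[int]
    residence_time: float = np.nan  # us
    r_squared: float = np.nan
    surface_area: float = np.nan  # nm^2
    occupancy_fraction: float = np.nan
    n_events: int = 0
    fit: KineticFit | None = None

    def residues_1based(self) -> list[int]:
        return sorted(r + 1 for r in self.residues)


def build_residue_graph(
    series: ContactSeries, min_occupancy: float = 0.0
) -> ResidueGraph:
    """Co-contact network from a contact series.

    weight(r, s) = number of (frame, lipid) pairs where one lipid touches r
    and s simultaneously. Residues whose own occupancy fraction (any lipid)
    falls below ``min_occupancy`` are excluded: residues brushed only in
    passing are not part of any binding site.
    """
    occ = series.occupancy  # (lipids, residues, frames)
    n_frames = occ.shape[2]
    res_occ_frac = occ.any(axis=0).mean(axis=1)  # per-residue occupancy
    contacted = np.flatnonzero((res_occ_frac > 0) & (res_occ_frac >= min_occupancy))

    g = nx.Graph()
    for r in contacted:
        g.add_node(int(series.residue_ids[r]))
    sub = occ[:, contacted, :].astype(np.float64)
    # co-contact count: sum over lipids and frames of occ_r * occ_s
    w = np.einsum("lrf,lsf->rs", sub, sub)
    for a in range(len(contacted)):
        for b in range(a + 1, len(contacted)):
            if w[a, b] > 0:
                g.add_edge(
                    int(series.residue_ids[contacted[a]]),
                    int(series.residue_ids[contacted[b]]),
                    weight=float(w[a, b]),
                )
    return ResidueGraph(graph=g)


def louvain_partition(
    graph: ResidueGraph,
    resolution: float = 1.0,
    seed: int = 7,
    min_size: int = 3,
) -> list[set[int]]:
    """Louvain communities of the residue network, deterministic per seed.

    Communities smaller than ``min_size`` are merged into the community they
    share the most total edge weight with; small communities with no outside
    connection are dropped (an isolated brush of < min_size residues is not a
    binding site).
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        return []
    comms = [set(c) for c in nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )]
    comms.sort(key=lambda c: (-len(c), min(c)))

    def external_weight(small: set[int], other: set[int]) -> float:
        return sum(
            g[u][v]["weight"] for u in small for v in g.neighbors(u) if v in other
        )

    changed = True
    while changed:
        changed = False
        for i, c in enumerate(comms):
            if len(c) >= min_size or len(comms) == 1:
                continue
            weights = [
                external_weight(c, other) if j != i else -1.0
                for j, other in enumerate(comms)
            ]
            best = int(np.argmax(weights))
            comms.pop(i)
            if weights[best] > 0:
                target = best if best < i else best - 1
                comms[target] |= c
            changed = True
            break
    return comms


def site_union_events(residues: set[int], series: ContactSeries) -> list[ContactEvent]:
    """Contact events of lipids with the site as a whole (any member residue)."""
    idx = np.flatnonzero(np.isin(series.residue_ids, sorted(residues)))
    if idx.size == 0:
        return []
    union_occ = series.occupancy[:, idx, :].any(axis=1, keepdims=True)
    sub = ContactSeries(
        occupancy=union_occ,
        lipid_ids=series.lipid_ids,
        residue_ids=np.array([min(residues)]),
        frame_dt=series.frame_dt,
        cutoff_lower=series.cutoff_lower,
        cutoff_upper=series.cutoff_upper,
    )
    return events_from_series(sub)


def site_kinetics(
    residues: set[int],
    series: ContactSeries,
    t_max_frames: int | None = None,
    seed: int = 0,
) -> KineticFit:
    """Residence-time fit for the union occupancy of a residue set."""
    events = site_union_events(residues, series)
    if t_max_frames is None:
        t_max_frames = default_lag_range(events, series.n_frames)
    curve = survival_function(
        events, series.n_frames, t_max_frames=t_max_frames, frame_dt=series.frame_dt
    )
    return fit_biexponential(curve, time_unit_us=1e-3, seed=seed)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit sphere points (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_area(
    centers: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 512,
) -> float:
    """Solvent-accessible surface area (A^2) of a set of spheres.

    Classic sphere-sampling: for each bead, points on the expanded sphere of
    radius r_i + probe are kept if outside every other expanded sphere; the
    accessible fraction scales the analytic sphere area.
    """
    centers = np.asarray(centers, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    # coincident identical spheres contribute one surface, not two
    keep = []
    for i in range(len(centers)):
        if not any(
            np.allclose(centers[i], centers[j], atol=1e-9) and radii[i] == radii[j]
            for j in keep
        ):
            keep.append(i)
    centers, radii = centers[keep], radii[keep]
    sphere = _fibonacci_sphere(n_points)
    expanded = radii + probe_radius
    total = 0.0
    for i in range(len(centers)):
        pts = centers[i] + expanded[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(centers)):
            if j == i:
                continue
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2 - 1e-9
        total += 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return float(total)


def site_surface_area(
    residues: set[int],
    system: CGSystem,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
    frame_stride: int = 0,
    n_points: int = 512,
) -> float:
    """Approximate SASA of a site's beads in nm^2, averaged over frames.

    ``frame_stride = 0`` picks ~10 evenly spaced frames; the protein in the
    systems this targets is near-rigid, so a sparse subsample suffices.
    """
    bead_idx = np.flatnonzero(np.isin(system.bead_residue, sorted(residues)))
    if bead_idx.size == 0:
        raise ValueError("site residues have no beads in the system")
    if frame_stride <= 0:
        frame_stride = max(1, system.n_frames // 10)
    frames = range(0, system.n_frames, frame_stride)
    radii = np.full(bead_idx.size, bead_radius)
    areas = [
        shrake_rupley_area(system.coords[f, bead_idx], radii, probe_radius, n_points)
        for f in frames
    ]
    return float(np.mean(areas)) / 100.0  # A^2 -> nm^2


def identify_binding_sites(
    series: ContactSeries,
    system: CGSystem | None = None,
    resolution: float = 1.0,
    seed: int = 7,
    min_size: int = 3,
    min_occupancy: float = 0.02,
    t_max_frames: int | None = None,
) -> list[BindingSite]:
    """Full binding-site analysis: graph -> Louvain -> per-site kinetics/area.

    Sites are numbered BS0, BS1, ... by descending occupancy fraction, which
    makes labels stable across reruns of the same system.
    """
    graph = build_residue_graph(series, min_occupancy=min_occupancy)
    comms = louvain_partition(graph, resolution=resolution, seed=seed, min_size=min_size)

    sites: list[BindingSite] = []
    for residues in comms:
        idx = np.flatnonzero(np.isin(series.residue_ids, sorted(residues)))
        site_occ = series.occupancy[:, idx, :].any(axis=(0, 1))
        events = site_union_events(residues, series)
        fit = None
        tau = r2 = np.nan
        if len(events) >= 3:
            try:
                fit = site_kinetics(residues, series, t_max_frames=t_max_frames, seed=seed)
                if fit.converged:
                    tau, r2 = fit.residence_time, fit.r_squared
            except ValueError:
                fit = None
        area = np.nan
        if system is not None:
            area = site_surface_area(residues, system)
        sites.append(
            BindingSite(
                site_id=-1,
                residues=frozenset(int(r) for r in residues),
                residence_time=tau,
                r_squared=r2,
                surface_area=area,
                occupancy_fraction=float(site_occ.mean()),
                n_events=len(events),
                fit=fit,
            )
        )
    sites.sort(key=lambda s: (-s.occupancy_fraction, min(s.residues)))
    for i, s in enumerate(sites):
        s.site_id = i
    return sites
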