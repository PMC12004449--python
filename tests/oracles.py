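"""Independent brute-force reference implementations used only by tests.

Each oracle evaluates a quantity by direct enumeration, without sharing code
paths with the package's optimized implementations.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def survival_bruteforce(occupancy: np.ndarray, t_max: int) -> np.ndarray:
    """Direct double-loop evaluation of the survival correlation function.

    ``occupancy`` is (n_channels, n_frames) boolean. For every lag t and every
    start frame v the window [v, v+t] is checked for full occupancy; the count
    is divided by N (T - t) with N the number of contact events, then
    normalized to 1 at t = 0.
    """
    occ = np.asarray(occupancy, dtype=bool)
    n_channels, T = occ.shape
    n_events = 0
    for ch in range(n_channels):
        padded = np.concatenate(([False], occ[ch], [False]))
        n_events += int(np.sum(~padded[:-1] & padded[1:]))
    raw = np.empty(t_max + 1)
    for t in range(t_max + 1):
        # every start position v: window of t+1 frames fully occupied
        windows = sliding_window_view(occ, t + 1, axis=1)
        raw[t] = windows.all(axis=2).sum() / (n_events * (T - t))
    return raw / raw[0]


def run_length_events(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector by linear scan."""
    events = []
    start = None
    for i, v in enumerate(row):
        if v and start is None:
            start = i
        elif not v and start is not None:
            events.append((start, i))
            start = None
    if start is not None:
        events.append((start, len(row)))
    return events


def min_image_distance_27(a, b, box) -> float:
    """Minimum distance over explicit enumeration of the 27 periodic images."""
    a, b, box = map(np.asarray, (a, b, box))
    best = np.inf
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                shift = np.array([dx, dy, dz]) * box
                best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best


def cocontact_weights_tripleloop(occupancy: np.ndarray) -> np.ndarray:
    """Edge weights by explicit (lipid, frame, residue-pair) enumeration."""
    n_lip, n_res, n_frames = occupancy.shape
    w = np.zeros((n_res, n_res))
    for lip in range(n_lip):
        for f in range(n_frames):
            touched = np.flatnonzero(occupancy[lip, :, f])
            for i in range(len(touched)):
                for j in range(i + 1, len(touched)):
                    w[touched[i], touched[j]] += 1
                    w[touched[j], touched[i]] += 1
    return w


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open integer intervals."""
    if not intervals:
        return []
    srt = sorted(intervals)
    out = [list(srt[0])]
    for s, e in srt[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def sphere_area_grid(centers, radii, probe, spacing=0.15) -> float:
    """Surface area of a union of spheres by dense-grid surface counting.

    Counts grid cells whose center lies within half a spacing of the union
    surface is unreliable; instead integrate each sphere's surface by a fine
    latitude-longitude quadrature and keep points outside all other spheres.
    """
    centers = np.asarray(centers, float)
    radii = np.asarray(radii, float) + probe
    total = 0.0
    n_theta = 400
    for i, (c, r) in enumerate(zip(centers, radii)):
        theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
        d_theta = np.pi / n_theta
        for th, sin_th in zip(theta, np.sin(theta)):
            n_phi = max(8, int(round(2 * np.pi * sin_th / d_theta)))
            phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
            pts = c + r * np.column_stack(
                [
                    sin_th * np.cos(phi),
                    sin_th * np.sin(phi),
                    np.full(n_phi, np.cos(th)),
                ]
            )
            keep = np.ones(n_phi, dtype=bool)
            for j, (c2, r2) in enumerate(zip(centers, radii)):
                if j == i:
                    continue
                keep &= np.sum((pts - c2) ** 2, axis=1) > r2**2
            total += keep.sum() * r * r * sin_th * d_theta * (2 * np.pi / n_phi)
    return total
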