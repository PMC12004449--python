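"""Residence-time kinetics from contact events.

The survival time correlation function sigma(t) is the fraction of observed
lipid contacts that persist continuously over a lag t, averaged over all
admissible start times:

    sigma(t) = [ sum_j sum_v n~_j(v, v+t) ] / [ N (T - t) ],

where n~_j(v, v+t) = 1 iff lipid j's contact covers every frame in
[v, v+t], T is the number of analyzed frames and N the total contact count;
the curve is renormalized so sigma(0) = 1. For a contact event occupying L
consecutive frames the inner sum contributes max(L - t, 0) start positions,
which makes the event-list evaluation exact and O(n_events) per lag.

sigma(t) is then fit with a biexponential

    sigma(t) ~ A exp(-k1 t) + B exp(-k2 t),    k1 <= k2,

whose slow rate k1 is identified with the lipid dissociation rate k_off, and
the residence time is reported as tau = 1/k1. The fast component absorbs
short boundary rattling; R^2 on the fitted lag range is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .contacts import ContactEvent, ContactSeries, events_from_series

__all__ = [
    "SurvivalCurve",
    "KineticFit",
    "NoBindingError",
    "survival_function",
    "default_lag_range",
    "fit_biexponential",
    "residence_time",
    "per_residue_residence_times",
]


class NoBindingError(ValueError):
    """No contact events: the survival curve is undefined."""


@dataclass
class SurvivalCurve:
    """sigma(t) over lag times, normalized so sigma(0) = 1.

    ``lag_times`` are in the unit implied by ``frame_dt`` at construction
    (ns by convention); ``n_contacts`` is the pooled event count N and
    ``t_total`` the analyzed duration in the same unit.
    """

    lag_times: np.ndarray
    sigma: np.ndarray
    n_contacts: int
    t_total: float

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.lag_times.shape != self.sigma.shape:
            raise ValueError("lag_times and sigma must align")
        if self.sigma.size and not np.isclose(self.sigma[0], 1.0):
            raise ValueError("sigma must be normalized to sigma(0)=1")


@dataclass
class KineticFit:
    """Biexponential fit parameters; rates in 1/us, residence time in us."""

    amplitude_slow: float
    rate_slow: float  # k1, identified with k_off
    amplitude_fast: float
    rate_fast: float  # k2 >= k1
    residence_time: float  # 1/k1, us
    r_squared: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if self.rate_slow > self.rate_fast * (1 + 1e-12):
                raise ValueError("rate_slow must not exceed rate_fast")
            if self.amplitude_slow < 0 or self.amplitude_fast < 0:
                raise ValueError("amplitudes must be non-negative")


def survival_function(
    events: list[ContactEvent],
    n_frames: int,
    t_max_frames: int | None = None,
    frame_dt: float = 1.0,
) -> SurvivalCurve:
    """Evaluate sigma(t) from a pooled contact-event list.

    Parameters
    ----------
    events : pooled contact events (censored ones contribute up to their
        observed length, which avoids the downward tau bias that dropping
        them would cause for us-scale sites).
    n_frames : total analyzed frames T.
    t_max_frames : largest lag evaluated; defaults to ``n_frames // 2``
        because the (T - t) start-count denominator makes long lags noisy.
    frame_dt : time per frame; lag_times = frame_dt * (0..t_max).
    """
    if not events:
        raise NoBindingError("no contact events; survival curve undefined")
    if t_max_frames is None:
        t_max_frames = n_frames // 2
    if not 0 < t_max_frames < n_frames:
        raise ValueError("need 0 < t_max_frames < n_frames")

    lengths = np.array([e.n_frames for e in events], dtype=np.int64)
    t = np.arange(t_max_frames + 1, dtype=np.int64)
    # sum_events max(L - t, 0), exact
    counts = np.clip(lengths[None, :] - t[:, None], 0, None).sum(axis=1).astype(float)
    n_contacts = len(events)
    raw = counts / (n_contacts * (n_frames - t).astype(float))
    sigma = raw / raw[0]
    return SurvivalCurve(
        lag_times=t * frame_dt,
        sigma=sigma,
        n_contacts=n_contacts,
        t_total=n_frames * frame_dt,
    )


def default_lag_range(events: list[ContactEvent], n_frames: int) -> int:
    """Adaptive fitting lag range: 3x the 1/e crossing of a provisional sigma.

    The (T - t) start-count denominator makes long lags statistically poor
    (the tail of sigma is carried by a handful of long events), so fitting is
    restricted to lags where the curve is still well sampled. Clipped to
    [50, n_frames // 2] frames.
    """
    cap = n_frames // 2
    provisional = survival_function(events, n_frames, t_max_frames=cap)
    below = np.nonzero(provisional.sigma < np.exp(-1.0))[0]
    t_e = int(below[0]) if below.size else cap
    # beyond the lag where fewer than ~4 events are still alive the curve is
    # carried by individual events, but never cut before 2x the 1/e crossing
    lengths = np.array([e.n_frames for e in events])
    alive = (lengths[None, :] > np.arange(cap + 1)[:, None]).sum(axis=1)
    starved = np.nonzero(alive < 4)[0]
    t_alive = int(starved[0]) if starved.size else cap
    t_max = min(3 * t_e, max(t_alive, 2 * t_e))
    return int(np.clip(t_max, min(50, cap), cap))


def _biexp(t, a, k1, b, k2):
    return a * np.exp(-k1 * t) + b * np.exp(-k2 * t)


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-30 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_biexponential(
    curve: SurvivalCurve,
    time_unit_us: float = 1e-3,
    seed: int = 0,
    amplitude_floor: float = 0.1,
) -> KineticFit:
    """Least-squares biexponential fit of a survival curve.

    ``time_unit_us`` converts the curve's lag-time unit to microseconds
    (1e-3 for ns lags); rates are reported in 1/us and tau in us. Three
    starts spread around an initial single-exponential rate estimate are
    tried and the best R^2 wins. If either fitted amplitude falls below
    ``amplitude_floor`` of the total, that component is not identifiable:
    a biexponential fit to a noisy single-exponential curve routinely parks
    a few-percent amplitude on a spuriously slow rate, which would corrupt
    tau = 1/k1. The fit then falls back to a single exponential with a
    degenerate second component (B = 0, k2 = k1).
    """
    if curve.lag_times.size < 10:
        raise ValueError("need >= 10 lag points to fit")
    t_us = curve.lag_times * time_unit_us
    y = curve.sigma
    span = float(t_us[-1] - t_us[0])
    if span <= 0:
        raise ValueError("degenerate lag range")

    # crude decay-scale guess from where sigma falls below 1/e
    below = np.nonzero(y < np.exp(-1.0))[0]
    t_e = t_us[below[0]] if below.size else span
    k_0 = 1.0 / max(t_e, 1e-9)
    # identifiability bound: a rate slower than 1/(2 T_total) cannot be
    # distinguished from no decay over the observation window
    t_total_us = curve.t_total * time_unit_us
    k_min = 1.0 / (2.0 * t_total_us) if t_total_us > 0 else 1e-9 / span
    k_0 = max(k_0, k_min)

    # single-exponential reference fit; also refines the rate scale
    single = None
    try:
        popt1, _ = curve_fit(
            lambda t, a, k: a * np.exp(-k * t),
            t_us,
            y,
            p0=(1.0, k_0),
            bounds=([0.0, k_min], [10.0, np.inf]),
            maxfev=20000,
        )
        single = (popt1, _r_squared(y, popt1[0] * np.exp(-popt1[1] * t_us)))
        k_0 = float(popt1[1])
    except (RuntimeError, ValueError):
        pass

    rng = np.random.default_rng(seed)
    starts = [
        (0.5, max(k_0 / 10.0, k_min), 0.5, k_0),
        (0.5, max(k_0 / 3.0, k_min), 0.5, 3.0 * k_0),
        (0.5, k_0, 0.5, 1.5 * k_0 * float(rng.uniform(0.8, 1.2))),
    ]
    lo = [0.0, k_min, 0.0, k_min]
    hi = [10.0, np.inf, 10.0, np.inf]

    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _biexp, t_us, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        r2 = _r_squared(y, _biexp(t_us, *popt))
        if best is None or r2 > best[1]:
            best = (popt, r2)

    if best is None and single is None:
        return KineticFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False,
                          "no fit converged")

    use_single = False
    if best is None:
        use_single = True
    else:
        a, k1, b, k2 = best[0]
        if k1 > k2:
            a, k1, b, k2 = b, k2, a, k1
        total = a + b
        degenerate = total <= 0 or min(a, b) < amplitude_floor * total
        if degenerate and single is not None:
            use_single = True
        elif single is not None and single[1] >= best[1] - 1e-12:
            # the extra component buys nothing; prefer the simpler model
            use_single = True

    if use_single:
        (a1, k), r2 = single
        return KineticFit(
            amplitude_slow=float(a1),
            rate_slow=float(k),
            amplitude_fast=0.0,
            rate_fast=float(k),
            residence_time=1.0 / float(k),
            r_squared=float(r2),
            converged=True,
            message="single-exponential (degenerate fast component)",
        )

    return KineticFit(
        amplitude_slow=float(a),
        rate_slow=float(k1),
        amplitude_fast=float(b),
        rate_fast=float(k2),
        residence_time=1.0 / float(k1),
        r_squared=float(best[1]),
        converged=True,
    )


def residence_time(k_off_per_us: float) -> float:
    """Reporting convention: residence time tau (us) = 1 / k_off (1/us)."""
    if k_off_per_us <= 0:
        raise ValueError("k_off must be positive")
    return 1.0 / k_off_per_us


def pooled_events_for_residue(
    series: ContactSeries, residue_id: int
) -> list[ContactEvent]:
    """Contact events of every lipid of the series' species with one residue."""
    return [e for e in events_from_series(series) if e.residue_id == residue_id]


def per_residue_residence_times(
    series: ContactSeries,
    t_max_frames: int | None = None,
    min_events: int = 5,
    seed: int = 0,
):
    """Per-residue residence-time table (residue, time_us, r_squared).

    For each residue, events are pooled across all lipid molecules of the
    species, sigma(t) is evaluated and the biexponential fit gives
    tau = 1/k1. Residues with fewer than ``min_events`` events are omitted
    (missing, not zero). Residue numbers in the table are 1-based.
    """
    import pandas as pd

    n_frames = series.n_frames
    all_events = events_from_series(series)
    by_res: dict[int, list[ContactEvent]] = {}
    for e in all_events:
        by_res.setdefault(e.residue_id, []).append(e)

    rows = []
    for res in sorted(by_res):
        events = by_res[res]
        if len(events) < min_events:
            continue
        t_max = t_max_frames if t_max_frames is not None else default_lag_range(
            events, n_frames
        )
        curve = survival_function(
            events, n_frames, t_max_frames=t_max, frame_dt=series.frame_dt
        )
        fit = fit_biexponential(curve, time_unit_us=1e-3, seed=seed)
        if not fit.converged:
            continue
        rows.append(
            {
                "residue": res + 1,
                "time_us": fit.residence_time,
                "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(rows, columns=["residue", "time_us", "r_squared"])
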