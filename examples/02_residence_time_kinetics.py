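"""Estimate a lipid residence time from planted Markov contact kinetics.

Simulates 50 independent lipid channels that bind and unbind a residue as a
two-state telegraph process with a known dissociation rate, evaluates the
survival time correlation function sigma(t) of the pooled contact events,
and fits the biexponential model whose slow rate k1 is read as k_off.
"""

import numpy as np

from lipidsites import (
    events_from_series,
    fit_biexponential,
    simulate_contact_series,
    survival_function,
)
from lipidsites.kinetics import default_lag_range

TAU_TRUE_NS = 1000.0  # 1 us residence time
FRAME_DT_NS = 10.0
N_FRAMES = 2000  # 20 us trajectory

series = simulate_contact_series(
    k_off=1.0 / TAU_TRUE_NS,
    k_on_eff=1.0 / TAU_TRUE_NS,
    n_frames=N_FRAMES,
    frame_dt=FRAME_DT_NS,
    n_lipids=50,
    seed=11,
)
events = events_from_series(series)
t_max = default_lag_range(events, N_FRAMES)
curve = survival_function(events, N_FRAMES, t_max, frame_dt=FRAME_DT_NS)
fit = fit_biexponential(curve, time_unit_us=1e-3)

print(f"{len(events)} contact events pooled; sigma(t) fitted over {t_max} lags")
print(f"slow rate k1 = {fit.rate_slow:.3f} /us  ->  tau = 1/k1 = "
      f"{fit.residence_time:.2f} us (true: {TAU_TRUE_NS / 1000:.2f} us)")
print(f"fast rate k2 = {fit.rate_fast:.3f} /us (frame-discretization rattle)")
print(f"R^2 = {fit.r_squared:.4f}")
print(
    "\nThe slow biexponential component is the dissociation rate k_off; the\n"
    "residence time is reported as 1/k_off in microseconds."
)
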