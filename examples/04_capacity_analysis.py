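"""Analytic working-memory capacity and volley-train readouts.

Computes the maximal limit-cycle period T_max across facilitation time
constants, then demonstrates the population-spike detector and the
held-item counter on a constructed raster of three alternating populations.
"""

import numpy as np

from synwm import (
    PSDetectionParams, STPParams, capacity_estimate, count_held_items,
    detect_population_spikes, median_ps_spacing, tmax_estimate,
)

print("tau_f (ms)   T_max (ms)   N_c at t_s = 160 ms")
for tau_f in (1500.0, 2000.0, 3000.0):
    p = STPParams(U=0.19, tau_f=tau_f, tau_d=200.0)
    T_max = tmax_estimate(p)
    print(f"{tau_f:9.0f} {T_max:12.1f} {capacity_estimate(T_max, 160.0):12.2f}")
print("-> longer facilitation stretches the limit cycle, so more items "
      "can alternate their refresh volleys.\n")

# constructed raster: 3 populations of 100 neurons alternating volleys
# every 160 ms on a 1 Hz background
rng = np.random.default_rng(0)
times, ids = [], []
for p in range(3):
    members = np.arange(100) + 100 * p
    bg = rng.uniform(0, 5000, size=rng.poisson(5.0 * 100))
    times.append(bg)
    ids.append(rng.integers(0, 100, size=len(bg)) + 100 * p)
    for t in np.arange(1000.0 + 160.0 * p, 5000.0, 480.0):
        times.append(t + rng.uniform(-3, 3, size=100))
        ids.append(members)
times = np.concatenate(times)
ids = np.concatenate(ids)

trains = [
    detect_population_spikes(times, ids, np.arange(100) + 100 * p, p,
                             800.0, 5000.0, (0.0, 800.0),
                             PSDetectionParams())
    for p in range(3)
]
T_max = tmax_estimate(STPParams())
held = count_held_items(trains, (1000.0, 5000.0), T_max)
t_s = median_ps_spacing(trains, (1000.0, 5000.0))
print(f"detected volleys per population: {[len(t.times) for t in trains]}")
print(f"held items: {held}, pooled volley spacing t_s = {t_s:.0f} ms")
print(f"empirical capacity ratio T_max/t_s = {T_max / t_s:.2f}")
print("-> with three populations alternating every 160 ms the ratio is "
      "~2.8: the analytic bound explains why about three items fit.")
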