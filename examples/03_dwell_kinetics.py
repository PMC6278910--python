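"""Dwell-time kinetics: detect binding events, fit survival curves.

Bound dwells follow f(t) = A exp(-k t) giving the dissociation rate
k_off; waiting times between events follow the double-exponential
f(t) = A1 exp(-k1 t) + A2 exp(-k2 t) giving k_on,fast and k_on,slow.
"""

from fretkin import (
    collect_dwells,
    compute_fret,
    correct_leakage,
    detect_events,
    fit_double_exp,
    fit_single_exp,
    simulate_dataset,
    survival_curve,
)
from fretkin.presets import get_preset

cfg, n_events = get_preset("wt-gddc")  # k_off 0.20, k_on 0.8/0.030
traces, _ = simulate_dataset(cfg, n_events, events_per_trace=10, seed=11)

per_trace = []
for tr in traces:
    ft = compute_fret(correct_leakage(tr, cfg.leakage))
    per_trace.append(detect_events(ft, threshold=0.25, min_frames=2))
bound, unbound = collect_dwells(per_trace)

off = fit_single_exp(survival_curve(bound), n_dwells=bound.durations.size)
on = fit_double_exp(survival_curve(unbound), n_dwells=unbound.durations.size)

print(f"uncensored dwells:  {bound.durations.size} bound, {unbound.durations.size} unbound")
print(f"k_off      = {off.rates[0]:.3f} s^-1   (generated 0.20)")
print(f"k_on,fast  = {on.rates[0]:.3f} s^-1   (generated 0.80)")
print(f"k_on,slow  = {on.rates[1]:.4f} s^-1  (generated 0.030)")
# Single-dataset fits scatter by 10-20% at ~100 events; the recovery
# harness (fretkin.recovery) pools replicates for tighter estimates.
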