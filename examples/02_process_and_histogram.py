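"""Convert raw intensities to apparent FRET and summarize the population.

Processing chain: subtract 10% donor leakage from the acceptor channel,
compute E = I_A/(I_D + I_A), seven-point moving average, then pool all
frames into a FRET histogram with a single-Gaussian summary (center X0,
width sigma).
"""

import numpy as np

from fretkin import (
    FretTrace,
    SimConfig,
    build_histogram,
    compute_fret,
    correct_leakage,
    detect_events,
    simulate_dataset,
    smooth,
)

cfg = SimConfig(seed=2)
traces, _ = simulate_dataset(cfg, n_events=40, events_per_trace=10, seed=2)

# pool smoothed FRET from frames inside binding events; the unbound
# baseline (E ~ 0) would otherwise dominate the histogram
bound_frames = []
for tr in traces:
    ft = compute_fret(correct_leakage(tr, leakage=0.10))
    sm = smooth(ft, window=7)
    events, _ = detect_events(ft, threshold=0.25, min_frames=2)
    for ev in events:
        chunk = sm.efficiency[ev.start_frame:ev.end_frame]
        bound_frames.append(FretTrace(
            time=sm.time[ev.start_frame:ev.end_frame],
            efficiency=chunk,
            frame_time=sm.frame_time,
        ))

hist = build_histogram(bound_frames, bins=40, range=(0.0, 1.0))
centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
print(f"pooled frames in range: {hist.counts.sum()}")
print(f"histogram mode:         {centers[np.argmax(hist.counts)]:.2f}")
print(f"Gaussian center X0:     {hist.gaussian_center:.3f}")
print(f"Gaussian width sigma:   {hist.gaussian_width:.3f}")
# X0 sits mid-way through the occupied 0.2-0.8 FRET band; sigma reflects
# both state heterogeneity and detector noise.
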