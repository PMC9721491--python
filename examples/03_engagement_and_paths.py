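"""Feedback-engagement points and two-reporter path geometry.

The slope of a differentiating cell's PPARG trajectory steps up at each
positive-feedback engagement. A +/-4 h sliding-window OLS slope plus a
2x-over-baseline persistence rule estimates the engagement hour per cell.
The (PPARG, FABP4) plane, min-max normalized per cell to the unit square,
shows that PPARG rises before FABP4 (mean path below the diagonal).
"""

import numpy as np

from fatecommit import (
    SimConfig, canonical_trace, detect_engagement, fold_change,
    simulate_population, sliding_window_slope, unit_square_normalize,
)

# noise-free canonical cell: engagement detected shortly after tau_A = 17 h
canon = canonical_trace()
e = detect_engagement(sliding_window_slope(canon))
print(f"canonical cell: first sustained slope increase at {e:.1f} h")
print(f"canonical fold changes: PPARG {fold_change(canon, 'PPARG'):.1f}x, "
      f"FABP4 {fold_change(canon, 'FABP4'):.0f}x")

# noisy population: per-cell engagement estimates of differentiating cells
ts = simulate_population(SimConfig(n_cells=200, seed=2))
est = []
for tr in ts.traces:
    if (ts.truth[tr.cell_id].fate == "differentiated"
            and tr.times[0] < 1.0 and tr.times[-1] > 90.0):
        e = detect_engagement(sliding_window_slope(tr))
        if e is not None:
            est.append(e)
print(f"population: median engagement {np.median(est):.1f} h "
      f"(n={len(est)} cells; true CEBPA engagement 17 h +/- 3 h jitter)")

diff = [c for c, t in ts.truth.items() if t.fate == "differentiated"]
paths = unit_square_normalize(ts, cells=diff)
print(f"unit-square path asymmetry {paths.asymmetry:+.2f} "
      "(positive: PPARG leads FABP4)")
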