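"""Calibrate the jitter-suppressing delta threshold by directional parity.

Simulates a speed-characterization trial (direction alternating every 10 s),
then scans tau = 1..55 for the threshold maximizing the ratio of
stimulus-aligned to misaligned eye-angle deltas.
"""

from okrloop import VirtualLarvaParams, build_schedule, optimal_threshold, simulate_trace

schedule = build_schedule("speed")
trace = simulate_trace(VirtualLarvaParams(seed=2), schedule)
curves = optimal_threshold(trace.series, schedule)
for eye in ("left", "right"):
    c = curves[eye]
    s_opt = c.S[list(c.tau_grid).index(c.tau_opt)]
    print(f"{eye:>5} eye: tau_opt = {c.tau_opt:g} deg/frame, parity ratio S = {s_opt:.2f} "
          f"(S at largest tau = {c.S[-1]:.2f})")
print("-> the optimizer keeps the threshold just above the camera-jitter floor,")
print("   where stimulus-aligned deltas dominate the surviving samples.")
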