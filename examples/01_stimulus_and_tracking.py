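"""Render grating frames, then recover eye angles from synthetic eye images.

Builds a rotating-grating frame, simulates a short stimulus-following eye
trace, renders it as camera frames (two dark ellipses on white) and re-tracks
the frames with the median-blur/threshold/ellipse-fit pipeline.
"""

import numpy as np

from okrloop import (
    GratingParams,
    RoiSpec,
    TimeBin,
    VirtualLarvaParams,
    render_eye_frames,
    render_frame,
    simulate_trace,
    track_series,
)

frame = render_frame(GratingParams(omega=30.0, n_gratings=5, spacing=20.0), phase=0.0, size=(200, 200))
dark = np.mean(frame.image < 128)
print(f"stimulus frame: {frame.image.shape}, {dark:.0%} dark pixels")

schedule = [
    TimeBin(0.0, 3.0, GratingParams(omega=30.0), label="ccw"),
    TimeBin(3.0, 6.0, GratingParams(omega=-30.0), label="cw"),
]
trace = simulate_trace(VirtualLarvaParams(seed=1, latency=0.0), schedule)
frames = render_eye_frames(trace)
series = track_series(
    frames,
    RoiSpec(0, 0, 120, 120, "left"),
    RoiSpec(120, 0, 120, 120, "right"),
)
rms = np.sqrt(np.nanmean((series.theta_left - trace.series.theta_left) ** 2))
print(f"re-tracked {len(series)} frames; left-eye RMS error {rms:.2f} deg")
print("-> the image pipeline recovers the simulated eye angles to well under a degree.")
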