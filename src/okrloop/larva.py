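"""Virtual larva: synthetic OKR eye-angle traces and synthetic eye images.

The simulated optokinetic response is a minimal slow-phase/saccade mechanism:
each eye integrates the grating rotation with a proportional gain
(``theta += gain * omega * dt`` per frame, gain possibly different for CCW
and CW stimulation to model an intrinsic directional preference), plus
independent per-frame Gaussian jitter standing in for camera noise.  When an
eye's excursion exceeds ``saccade_trigger`` it snaps back by ``saccade_size``
toward center -- a hard reset recorded as a ground-truth saccade -- which
yields the characteristic sawtooth of stimulus-following eye traces.  Blank
stimulus periods produce jitter only.  Direction changes reach the larva
after a pure delay ``latency``.

The same mechanism is exposed two ways: :func:`simulate_trace` runs a fixed
stimulus schedule and returns the full trace with ground truth, while
:class:`VirtualLarva` is a steppable online source for the closed loop, where
the stimulus each tick depends on the robot.  ``render_eye_frames`` converts
a trace into synthetic camera frames (two dark ellipses on a bright
background) for exercising the image-tracking pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .analytics import TimeBin
from .eyetrack import EyeAngleSeries
from .stimulus import GratingParams

__all__ = [
    "VirtualLarvaParams",
    "SyntheticTrace",
    "VirtualLarva",
    "EyeGeometry",
    "simulate_trace",
    "render_eye_frames",
]


@dataclass(frozen=True)
class VirtualLarvaParams:
    """Behavioral parameters of the simulated larva.

    ``gain_ccw``/``gain_cw`` are slow-phase gains (eye deg per stimulus deg)
    for counterclockwise and clockwise rotation; equal gains give an unbiased
    larva.  The effective stimulus velocity saturates at ``omega_sat``
    (deg/s): slow-phase eye velocity is ``gain * min(|omega|, omega_sat)``,
    mirroring the well-known saturation of larval OKR slow-phase velocity at
    high stimulus speeds.  ``saccade_trigger`` (deg) is the excursion at
    which a resetting saccade of ``saccade_size`` (deg) fires.  ``jitter_sd``
    (deg/frame) emulates camera jitter; ``latency`` (s) delays stimulus
    changes.
    """

    gain_ccw: float = 0.8
    gain_cw: float = 0.8
    omega_sat: float = 15.0
    saccade_trigger: float = 20.0
    saccade_size: float = 15.0
    jitter_sd: float = 0.3
    latency: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_ccw < 0 or self.gain_cw < 0:
            raise ValueError("gains must be >= 0")
        if self.omega_sat <= 0:
            raise ValueError("omega_sat must be > 0")
        if self.saccade_trigger <= 0:
            raise ValueError("saccade_trigger must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")


@dataclass
class SyntheticTrace:
    """Simulated eye-angle series plus ground truth it was built from."""

    series: EyeAngleSeries
    saccade_times_left: np.ndarray
    saccade_times_right: np.ndarray
    omega: np.ndarray  # stimulus omega effective at each frame (0 when blank)
    blank: np.ndarray  # boolean per frame

    def saccade_times(self, eye: str) -> np.ndarray:
        return self.saccade_times_left if eye == "left" else self.saccade_times_right


class VirtualLarva:
    """Steppable virtual larva for closed-loop use.

    Each :meth:`step` receives the stimulus currently on the display and
    returns the new (theta_left, theta_right) after one frame of simulated
    OKR.  Determinism: the same params (including seed) and stimulus stream
    give a bit-identical angle stream.
    """

    def __init__(self, params: VirtualLarvaParams, dt: float = 0.1):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.params = params
        self.dt = dt
        self.rng = np.random.default_rng(params.seed)
        self.theta = {"left": 0.0, "right": 0.0}
        self._saccades = {"left": [], "right": []}
        self._delay_buf: list[tuple[float, bool]] = []
        self._delay_steps = int(round(params.latency / dt))
        self.t = 0.0

    def _effective_stimulus(self, omega: float, blank: bool) -> tuple[float, bool]:
        """Pure delay of `latency` on the stimulus the larva perceives."""
        if self._delay_steps == 0:
            return omega, blank
        self._delay_buf.append((omega, blank))
        if len(self._delay_buf) <= self._delay_steps:
            return 0.0, True  # nothing perceived yet
        return self._delay_buf.pop(0)

    def step(self, stim: GratingParams | None, dt: float | None = None) -> tuple[float, float]:
        dt = self.dt if dt is None else dt
        p = self.params
        omega = 0.0 if stim is None else stim.omega
        blank = True if stim is None else stim.blank
        omega, blank = self._effective_stimulus(omega, blank)
        for eye in ("left", "right"):
            drift = 0.0
            if not blank and omega != 0.0:
                gain = p.gain_ccw if omega > 0 else p.gain_cw
                # slow-phase response saturates above omega_sat (deg/s)
                v = np.sign(omega) * gain * min(abs(omega), p.omega_sat)
                drift = v * dt
            jitter = self.rng.normal(0.0, p.jitter_sd) if p.jitter_sd > 0 else 0.0
            theta = self.theta[eye] + drift + jitter
            if abs(theta) > p.saccade_trigger:
                theta -= np.sign(theta) * p.saccade_size
                self._saccades[eye].append(self.t + dt)
            self.theta[eye] = theta
        self.t += dt
        return self.theta["left"], self.theta["right"]

    def saccade_times(self, eye: str) -> np.ndarray:
        return np.asarray(self._saccades[eye], dtype=float)


def simulate_trace(
    params: VirtualLarvaParams,
    schedule: Sequence[TimeBin],
    dt: float = 0.1,
) -> SyntheticTrace:
    """Simulate both eyes over a fixed stimulus schedule.

    The schedule's bins must tile a contiguous span; frames are laid on a
    uniform ``dt`` grid from the first bin's start to the last bin's end.
    Frame 0 is the initial resting state (theta = 0).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not schedule:
        raise ValueError("schedule must be non-empty")
    bins = sorted(schedule, key=lambda b: b.tb)
    t0, t1 = bins[0].tb, bins[-1].tbn
    n = int(round((t1 - t0) / dt))
    t = t0 + dt * np.arange(n + 1)

    def stim_at(time: float) -> GratingParams | None:
        for b in bins:
            if b.tb <= time < b.tbn:
                return b.stimulus
        return None

    larva = VirtualLarva(params, dt=dt)
    larva.t = t0
    th_l = np.empty(n + 1)
    th_r = np.empty(n + 1)
    omega_arr = np.zeros(n + 1)
    blank_arr = np.ones(n + 1, dtype=bool)
    th_l[0] = th_r[0] = 0.0
    for i in range(1, n + 1):
        stim = stim_at(t[i - 1])
        if stim is not None:
            omega_arr[i] = 0.0 if stim.blank else stim.omega
            blank_arr[i] = stim.blank
        th_l[i], th_r[i] = larva.step(stim)
    series = EyeAngleSeries(t=t, theta_left=th_l, theta_right=th_r)
    return SyntheticTrace(
        series=series,
        saccade_times_left=larva.saccade_times("left"),
        saccade_times_right=larva.saccade_times("right"),
        omega=omega_arr,
        blank=blank_arr,
    )


@dataclass(frozen=True)
class EyeGeometry:
    """Placement and shape of the two synthetic eyes in a rendered frame."""

    frame_size: tuple[int, int] = (120, 240)  # (height, width)
    center_left: tuple[float, float] = (60.0, 60.0)  # (x, y) px
    center_right: tuple[float, float] = (180.0, 60.0)
    semi_major: float = 22.0
    semi_minor: float = 11.0
    foreground: int = 30
    background: int = 255

    def __post_init__(self) -> None:
        h, w = self.frame_size
        for cx, cy in (self.center_left, self.center_right):
            if not (
                self.semi_major <= cx <= w - 1 - self.semi_major
                and self.semi_major <= cy <= h - 1 - self.semi_major
            ):
                raise ValueError("eye ellipse would overflow the frame")


def _draw_ellipse(img: np.ndarray, center: tuple[float, float], a: float, b: float,
                  theta_world: float, value: int) -> None:
    """Draw a filled ellipse whose *minor* axis sits at `theta_world` deg.

    World angles are CCW-positive; image rows grow downward, so the
    image-frame major-axis angle is the negated world angle of (theta+90).
    """
    phi = np.deg2rad(-(theta_world + 90.0))
    h, w = img.shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = value


def render_eye_frames(trace: SyntheticTrace, geometry: EyeGeometry | None = None) -> list[np.ndarray]:
    """Render a trace as synthetic camera frames (two dark eyes on white)."""
    geometry = geometry or EyeGeometry()
    s = trace.series
    frames: list[np.ndarray] = []
    for i in range(len(s)):
        img = np.full(geometry.frame_size, geometry.background, dtype=np.uint8)
        _draw_ellipse(img, geometry.center_left, geometry.semi_major, geometry.semi_minor,
                      s.theta_left[i], geometry.foreground)
        _draw_ellipse(img, geometry.center_right, geometry.semi_major, geometry.semi_minor,
                      s.theta_right[i], geometry.foreground)
        frames.append(img)
    return frames
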