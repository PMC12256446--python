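"""Virtual line-following robot, arena, line sensor and overhead tracker.

The arena reproduces the physical track: a 55 x 55 cm white sheet with a
2.54 cm wide yellow tape line running along the y-axis at x = 0.  The robot
is a planar unicycle (two driven wheels + castor): ``Forward`` advances
``speed * dt`` along the heading, ``Left``/``Right`` rotate the heading by
``turn_rate * dt`` in place (an arc-turn mode that also translates is
available), and an optional constant castor-drag heading drift models the
mechanical bias of the castor wheel.

Line sensing has two equivalent routes:

* :func:`observe_line` -- geometric default used in the loop: the line is
  projected into a forward-looking trapezoidal sensor footprint (mimicking
  the robot's tilted onboard camera, which sees the floor roughly 10-30 cm
  ahead) and the lateral center of mass of the visible line classifies the
  robot as left of / on / right of the line.  Because the footprint looks
  *ahead*, this is effectively a lookahead sensor, which is what lets the
  sign-only display feedback steer the robot smoothly onto the line.
* :func:`detect_line_com` -- image route: HSV filtering isolates the yellow
  line in a synthetic onboard render and its pixel center of mass gives the
  same offset; the two routes are equivalence-tested.

The overhead tracker rectifies an oblique camera view with an exact
four-point homography and locates the robot's rear marker by color center
of mass in the top-down image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.transform import ProjectiveTransform, warp

from .loop_types import Command

__all__ = [
    "RobotState",
    "LineObservation",
    "WorldConfig",
    "WorldError",
    "step",
    "observe_line",
    "detect_line_com",
    "render_onboard",
    "render_overhead",
    "rectify",
    "apply_homography",
    "track_marker",
    "YELLOW_HSV_RANGE",
    "MARKER_HSV_RANGE",
]

#: HSV in-range bounds (h, s, v in [0,1]) for the yellow painter's tape
YELLOW_HSV_RANGE = ((0.10, 0.35, 0.35), (0.22, 1.0, 1.0))
#: bounds for the red rear marker used by the overhead tracker
MARKER_HSV_RANGE = ((0.95, 0.35, 0.35), (1.0001, 1.0, 1.0))


class WorldError(RuntimeError):
    """Raised for degenerate geometry (e.g. collinear calibration points)."""


@dataclass(frozen=True)
class RobotState:
    """Planar robot pose in the track frame (cm, deg CCW from +x)."""

    x: float
    y: float
    heading: float
    speed: float = 5.0


@dataclass(frozen=True)
class LineObservation:
    """Result of one line-sensor reading.

    ``line_side`` is the side of the line the *robot* reports itself on
    ('left', 'on', 'right'), ``com_offset`` the lateral offset (cm, positive
    = line appears to the robot's left) of the visible line's center of
    mass, and ``lost`` marks a reading where no line was visible (the side
    is then carried from the previous observation).
    """

    line_side: str
    com_offset: float
    lost: bool = False


@dataclass(frozen=True)
class WorldConfig:
    """Arena, line, sensor and kinematic parameters (cm, s, deg)."""

    arena_size: float = 55.0
    line_x: float = 0.0
    tape_width: float = 2.54
    deadband: float = 1.27  # half the tape width
    lookahead_near: float = 10.0
    lookahead_far: float = 30.0
    halfwidth_near: float = 5.0  # sensor footprint half-width at the near edge
    halfwidth_far: float = 15.0
    turn_rate: float = 45.0  # deg/s
    turn_mode: str = "in_place"  # or "arc"
    castor_bias: float = 0.0  # deg/s constant heading drift


def step(state: RobotState, cmd: Command, dt: float, cfg: WorldConfig | None = None) -> RobotState:
    """Advance the robot pose by one command tick (exact Euler kinematics)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    cfg = cfg or WorldConfig()
    x, y, h = state.x, state.y, state.heading
    if cmd is Command.FORWARD:
        x += state.speed * dt * np.cos(np.deg2rad(h))
        y += state.speed * dt * np.sin(np.deg2rad(h))
    else:
        sign = 1.0 if cmd is Command.LEFT else -1.0
        h += sign * cfg.turn_rate * dt
        if cfg.turn_mode == "arc":
            x += state.speed * dt * np.cos(np.deg2rad(h))
            y += state.speed * dt * np.sin(np.deg2rad(h))
    h += cfg.castor_bias * dt
    h = (h + 180.0) % 360.0 - 180.0
    return replace(state, x=x, y=y, heading=h)


def _footprint_halfwidth(u: np.ndarray, cfg: WorldConfig) -> np.ndarray:
    """Half-width of the trapezoidal sensor footprint at forward distance u."""
    frac = (u - cfg.lookahead_near) / (cfg.lookahead_far - cfg.lookahead_near)
    return cfg.halfwidth_near + frac * (cfg.halfwidth_far - cfg.halfwidth_near)


def observe_line(
    state: RobotState,
    cfg: WorldConfig | None = None,
    last_side: str | None = None,
    n_samples: int = 201,
) -> LineObservation:
    """Geometric line sensor.

    Points of the line inside the forward footprint are expressed in the
    robot frame (u forward, w lateral with left positive); the mean lateral
    offset classifies the side: the line appearing to the *right* of the
    sensor axis (w < -deadband) means the robot sits on the *left* side of
    the line, and vice versa; |offset| <= deadband reads as 'on'.  An empty
    footprint yields a 'line lost' observation carrying ``last_side``.
    """
    cfg = cfg or WorldConfig()
    h = np.deg2rad(state.heading)
    f = np.array([np.cos(h), np.sin(h)])
    l = np.array([-np.sin(h), np.cos(h)])
    # sample the line densely around the robot; footprint reach bounds the span
    reach = cfg.lookahead_far + cfg.halfwidth_far
    s = np.linspace(state.y - reach, state.y + reach, n_samples)
    qx = cfg.line_x - state.x
    qy = s - state.y
    u = qx * f[0] + qy * f[1]
    w = qx * l[0] + qy * l[1]
    visible = (u >= cfg.lookahead_near) & (u <= cfg.lookahead_far)
    visible &= np.abs(w) <= _footprint_halfwidth(u, cfg)
    if not visible.any():
        return LineObservation(line_side=last_side or "on", com_offset=np.nan, lost=True)
    com = float(np.mean(w[visible]))
    if abs(com) <= cfg.deadband:
        side = "on"
    elif com < 0:
        side = "left"  # line appears right of the sensor axis
    else:
        side = "right"
    return LineObservation(line_side=side, com_offset=com, lost=False)


# ---------------------------------------------------------------------------
# image route: synthetic renders + HSV center-of-mass detection

_WHITE_RGB = np.array([1.0, 1.0, 1.0])
_YELLOW_RGB = np.array([1.0, 0.9, 0.1])
_MARKER_RGB = np.array([0.9, 0.05, 0.05])


def render_onboard(
    state: RobotState,
    cfg: WorldConfig | None = None,
    size: tuple[int, int] = (60, 120),
) -> np.ndarray:
    """Synthetic rectified onboard-camera view of the sensor footprint.

    Rows map to forward distance (near edge at the bottom), columns to
    lateral offset with the robot's left on the *left* of the image reversed
    into screen convention: image columns grow to the robot's right.  Pixels
    over the tape are yellow, the rest white.  Float RGB in [0, 1].
    """
    cfg = cfg or WorldConfig()
    hpx, wpx = size
    img = np.ones((hpx, wpx, 3), dtype=float) * _WHITE_RGB
    h = np.deg2rad(state.heading)
    f = np.array([np.cos(h), np.sin(h)])
    l = np.array([-np.sin(h), np.cos(h)])
    rows, cols = np.mgrid[0:hpx, 0:wpx]
    u = cfg.lookahead_far - (rows + 0.5) / hpx * (cfg.lookahead_far - cfg.lookahead_near)
    half_span = cfg.halfwidth_far  # fixed image span; outside-footprint px stay white
    w = -((cols + 0.5) / wpx * 2.0 - 1.0) * half_span  # left-positive lateral coord
    in_fp = np.abs(w) <= _footprint_halfwidth(u, cfg)
    gx = state.x + u * f[0] + w * l[0]
    on_tape = np.abs(gx - cfg.line_x) <= cfg.tape_width / 2.0
    img[in_fp & on_tape] = _YELLOW_RGB
    return img


def detect_line_com(
    image: np.ndarray,
    hsv_range: tuple = YELLOW_HSV_RANGE,
) -> float | None:
    """Center-of-mass column offset of the HSV-isolated line, in px.

    Positive offsets are to the right of the image center.  Returns None
    when no in-range pixel exists (line lost).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    hsv = rgb2hsv(image)
    (h0, s0, v0), (h1, s1, v1) = hsv_range
    mask = (
        (hsv[..., 0] >= h0) & (hsv[..., 0] < h1)
        & (hsv[..., 1] >= s0) & (hsv[..., 1] <= s1)
        & (hsv[..., 2] >= v0) & (hsv[..., 2] <= v1)
    )
    if not mask.any():
        return None
    cols = np.nonzero(mask)[1]
    center = (image.shape[1] - 1) / 2.0
    return float(cols.mean() - center)


def line_side_from_image(
    image: np.ndarray,
    cfg: WorldConfig | None = None,
    last_side: str | None = None,
    hsv_range: tuple = YELLOW_HSV_RANGE,
) -> LineObservation:
    """Classify the robot's side of the line from an onboard render.

    The px offset from :func:`detect_line_com` is converted to the lateral
    cm offset of :func:`observe_line` (image columns grow to the robot's
    right, so the sign flips) and classified with the same deadband.
    """
    cfg = cfg or WorldConfig()
    off_px = detect_line_com(image, hsv_range)
    if off_px is None:
        return LineObservation(line_side=last_side or "on", com_offset=np.nan, lost=True)
    wpx = np.asarray(image).shape[1]
    cm_per_px = 2.0 * cfg.halfwidth_far / wpx
    com = -off_px * cm_per_px
    if abs(com) <= cfg.deadband:
        side = "on"
    elif com < 0:
        side = "left"
    else:
        side = "right"
    return LineObservation(line_side=side, com_offset=com, lost=False)


# ---------------------------------------------------------------------------
# overhead tracker: homography rectification + marker center of mass


def rectify(src: np.ndarray, dst: np.ndarray) -> ProjectiveTransform:
    """Exact 4-point direct-linear-transform homography, src -> dst (px)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (4, 2) or dst.shape != (4, 2):
        raise WorldError("need exactly 4 source and 4 target points")
    for pts in (src, dst):
        for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            a, b, c = pts[list(idx)]
            det = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if abs(det) < 1e-9:
                raise WorldError("three calibration points are collinear")
    tf = ProjectiveTransform.from_estimate(src, dst)
    if not tf:
        raise WorldError("homography estimation failed")
    return tf


def apply_homography(
    tf: ProjectiveTransform,
    image: np.ndarray,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Warp an image with the (forward) homography to the top-down view."""
    return warp(
        np.asarray(image, dtype=float),
        inverse_map=tf.inverse,
        output_shape=output_shape,
        order=1,
        mode="constant",
        cval=1.0,
    )


def render_overhead(
    state: RobotState,
    cfg: WorldConfig | None = None,
    px_per_cm: float = 4.0,
    marker_radius_cm: float = 1.5,
) -> np.ndarray:
    """Synthetic top-down arena view: white sheet, yellow line, red marker.

    Pixel (0, 0) is the arena corner at (-arena/2, +arena/2); columns grow
    with x, rows with -y.  Float RGB in [0, 1].
    """
    cfg = cfg or WorldConfig()
    n = int(round(cfg.arena_size * px_per_cm))
    img = np.ones((n, n, 3), dtype=float) * _WHITE_RGB
    half = cfg.arena_size / 2.0
    rows, cols = np.mgrid[0:n, 0:n]
    gx = (cols + 0.5) / px_per_cm - half
    gy = half - (rows + 0.5) / px_per_cm
    img[np.abs(gx - cfg.line_x) <= cfg.tape_width / 2.0] = _YELLOW_RGB
    img[(gx - state.x) ** 2 + (gy - state.y) ** 2 <= marker_radius_cm**2] = _MARKER_RGB
    return img


def track_marker(
    topdown: np.ndarray,
    cfg: WorldConfig | None = None,
    px_per_cm: float = 4.0,
    hsv_range: tuple = MARKER_HSV_RANGE,
) -> tuple[float, float] | None:
    """Locate the robot's rear marker in a rectified top-down image (cm).

    Returns None when no marker-colored pixel is present (tracking lost).
    """
    cfg = cfg or WorldConfig()
    image = np.asarray(topdown, dtype=float)
    hsv = rgb2hsv(image)
    (h0, s0, v0), (h1, s1, v1) = hsv_range
    hue = hsv[..., 0]
    hue_ok = (hue >= h0) & (hue < h1) if h0 <= h1 else (hue >= h0) | (hue < h1 - 1.0)
    # red sits at the hue wrap; accept hues near 0 as well
    if h0 > 0.5:
        hue_ok |= hue <= (h1 - 1.0 if h1 > 1.0 else 0.05)
    mask = hue_ok & (hsv[..., 1] >= s0) & (hsv[..., 2] >= v0)
    if not mask.any():
        return None
    r, c = np.nonzero(mask)
    half = cfg.arena_size / 2.0
    x = (c.mean() + 0.5) / px_per_cm - half
    y = half - (r.mean() + 0.5) / px_per_cm
    return float(x), float(y)
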