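"""Rotating concentric-grating stimulus.

The stimulus shown beneath the larva is a disc of alternating black and white
angular sectors ("gratings") arranged in concentric annular rings around a
central white contrast circle, rotating at angular velocity ``omega`` (deg/s,
counterclockwise positive as seen by the camera).  Rendering is a pure function
of (parameters, phase, raster size) and uses nearest-neighbour sector
assignment so repeated calls are bit-identical.

The module also implements the closed-loop display rule: the rotation sense of
the grating is chosen from which side of the taped line the robot reports
itself to be on, and the pattern is hidden entirely while the robot sits on
the line.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "GratingParams",
    "StimulusFrame",
    "ParameterError",
    "render_frame",
    "advance_phase",
    "display_logic",
]

#: rendered intensity of dark sectors / white background
_DARK = 0
_WHITE = 255


class ParameterError(ValueError):
    """Invalid stimulus parameters."""


@dataclass(frozen=True)
class GratingParams:
    """Parameter vector of the rotating grating animation.

    Parameters
    ----------
    omega:
        Angular velocity in deg/s, signed; positive is counterclockwise when
        viewed from the camera.
    n_gratings:
        Number of dark angular sectors (>= 1 unless blank).
    spacing:
        Radial gap between consecutive grating rings, in percent of the
        radial extent available for the pattern (0..100).
    thickness:
        Radial thickness of each grating ring in px; ``None`` is the
        "maximum" preset: a single ring tiling the whole annulus between the
        central circle and the raster edge.
    center_radius:
        Radius of the central white contrast circle, px.
    blank:
        If true no pattern is shown; the frame is uniform white.
    """

    omega: float = 30.0
    n_gratings: int = 5
    spacing: float = 20.0
    thickness: float | None = None
    center_radius: float = 20.0
    blank: bool = False

    def __post_init__(self) -> None:
        if not self.blank and self.n_gratings < 1:
            raise ParameterError("n_gratings must be >= 1 when not blank")
        if not 0.0 <= self.spacing <= 100.0:
            raise ParameterError("spacing must be in [0, 100] percent")
        if self.thickness is not None and self.thickness < 1:
            raise ParameterError("thickness must be >= 1 px")
        if self.center_radius < 0:
            raise ParameterError("center_radius must be >= 0")


@dataclass(frozen=True)
class StimulusFrame:
    """One rendered animation frame plus the state that produced it."""

    image: np.ndarray  # 2-D uint8 raster
    phase: float  # deg in [0, 360)
    params: GratingParams
    t: float = 0.0


def advance_phase(phase: float, omega: float, dt: float) -> float:
    """Advance the rotation phase by ``omega * dt`` and wrap to [0, 360)."""
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    out = float(np.mod(phase + omega * dt, 360.0))
    return 0.0 if out == 360.0 else out  # float rounding at the wrap point


def render_frame(
    params: GratingParams,
    phase: float = 0.0,
    size: Tuple[int, int] = (200, 200),
    t: float = 0.0,
) -> StimulusFrame:
    """Render one frame of the grating animation.

    ``size`` is (height, width) in px, minimum 32x32.  Dark sectors are drawn
    where the polar angle (measured counterclockwise, i.e. with the image
    y-axis flipped) falls in the dark half of a grating period, offset by
    ``phase``; the pattern only covers the annular rings defined by
    ``thickness`` and ``spacing``, and everything inside ``center_radius`` or
    beyond the disc stays white.
    """
    h, w = int(size[0]), int(size[1])
    if h < 32 or w < 32:
        raise ParameterError("raster must be at least 32x32")
    phase = float(np.mod(phase, 360.0))
    img = np.full((h, w), _WHITE, dtype=np.uint8)
    if params.blank:
        return StimulusFrame(image=img, phase=phase, params=params, t=t)

    cy = (h - 1) / 2.0
    cx = (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    r = np.hypot(dx, dy)
    # polar angle, CCW-positive: image rows grow downward, hence -dy
    ang = np.degrees(np.arctan2(-dy, dx))

    outer = min(cx, cy)
    extent = outer - params.center_radius
    if extent <= 0:
        return StimulusFrame(image=img, phase=phase, params=params, t=t)

    thickness = extent if params.thickness is None else float(params.thickness)
    gap = extent * params.spacing / 100.0
    in_ring = np.zeros_like(r, dtype=bool)
    r0 = params.center_radius
    while r0 < outer:
        in_ring |= (r >= r0) & (r < min(r0 + thickness, outer))
        if thickness + gap <= 0:
            break
        r0 += thickness + gap

    period = 360.0 / params.n_gratings
    sector = np.mod(ang - phase, period)
    dark = sector < period / 2.0

    img[in_ring & dark & (r >= params.center_radius)] = _DARK
    return StimulusFrame(image=img, phase=phase, params=params, t=t)


def display_logic(line_side: str, base: GratingParams) -> GratingParams:
    """Closed-loop display rule mapping the robot's line side to the stimulus.

    ``left``  -> clockwise rotation (negative omega), pattern shown;
    ``on``    -> pattern hidden (blank);
    ``right`` -> counterclockwise rotation (positive omega), pattern shown.

    The rotation magnitude is taken from ``base`` (the trial configuration).
    """
    mag = abs(base.omega)
    if line_side == "left":
        return replace(base, omega=-mag, blank=False)
    if line_side == "right":
        return replace(base, omega=+mag, blank=False)
    if line_side == "on":
        return replace(base, blank=True)
    raise ParameterError(f"unknown line side {line_side!r}")
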