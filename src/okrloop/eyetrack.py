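"""Ellipse-fit eye tracking.

The tracking pipeline crops each frame to a per-eye region of interest,
median-blurs it, thresholds dark (pigmented) pixels, keeps the largest
connected component, extracts its boundary and fits a least-squares ellipse.
The eye angle theta is the angle of the fitted ellipse's *minor* axis relative
to the image horizontal.

Sign convention (single site for the whole package): angles are
counterclockwise-positive as seen by the camera.  Image row indices grow
downward, so an angle measured in raw (col, row) coordinates is negated once,
here, to obtain the CCW-positive value; everything downstream (stimulus omega,
deltas, the virtual larva) shares this convention.  Because an ellipse axis is
undirected, theta lives on the half-open interval (-90, 90].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import EllipseModel, find_contours

__all__ = [
    "RoiSpec",
    "EllipseFit",
    "EyeAngleSeries",
    "EyeTrackError",
    "segment_eye",
    "fit_eye_angle",
    "track_series",
    "wrap_axial",
    "axial_difference",
]

#: minimum major/minor ratio below which the orientation is meaningless
_MIN_AXIS_RATIO = 1.05


class EyeTrackError(RuntimeError):
    """Raised when no eye can be extracted from a frame or series."""


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest, 0-based half-open pixel coordinates."""

    x0: int
    y0: int
    width: int
    height: int
    eye_label: str = "left"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be > 0")

    def crop(self, frame: np.ndarray) -> np.ndarray:
        if (
            self.x0 < 0
            or self.y0 < 0
            or self.x0 + self.width > frame.shape[1]
            or self.y0 + self.height > frame.shape[0]
        ):
            raise ValueError("ROI extends outside the frame")
        return frame[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width]


@dataclass(frozen=True)
class EllipseFit:
    """Least-squares ellipse fitted to an eye contour.

    ``theta`` is the minor-axis angle in degrees, CCW-positive, in (-90, 90].
    ``reliable`` is false for near-circular fits whose orientation is
    ill-defined.
    """

    cx: float
    cy: float
    major: float
    minor: float
    theta: float
    reliable: bool = True


@dataclass
class EyeAngleSeries:
    """Timestamped left/right eye angles on a uniform (default 10 Hz) grid."""

    t: np.ndarray
    theta_left: np.ndarray
    theta_right: np.ndarray
    valid_left: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid_right: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta_left = np.asarray(self.theta_left, dtype=float)
        self.theta_right = np.asarray(self.theta_right, dtype=float)
        n = len(self.t)
        if self.valid_left is None:
            self.valid_left = np.isfinite(self.theta_left)
        if self.valid_right is None:
            self.valid_right = np.isfinite(self.theta_right)
        self.valid_left = np.asarray(self.valid_left, dtype=bool)
        self.valid_right = np.asarray(self.valid_right, dtype=bool)
        if not (
            len(self.theta_left) == len(self.theta_right) == n
            and len(self.valid_left) == len(self.valid_right) == n
        ):
            raise ValueError("series arrays must share one length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise ValueError("need >= 2 samples for a sampling period")
        return float(np.median(np.diff(self.t)))

    def theta(self, eye: str) -> np.ndarray:
        return self.theta_left if eye == "left" else self.theta_right

    def valid(self, eye: str) -> np.ndarray:
        return self.valid_left if eye == "left" else self.valid_right

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "theta_left": self.theta_left,
                "theta_right": self.theta_right,
                "valid_left": self.valid_left.astype(int),
                "valid_right": self.valid_right.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EyeAngleSeries":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(),
            theta_left=df["theta_left"].to_numpy(),
            theta_right=df["theta_right"].to_numpy(),
            valid_left=df["valid_left"].to_numpy().astype(bool),
            valid_right=df["valid_right"].to_numpy().astype(bool),
        )


def wrap_axial(theta_deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an undirected-axis angle into (-90, 90]."""
    w = -(np.mod(-np.asarray(theta_deg, dtype=float) + 90.0, 180.0) - 90.0)
    return float(w) if np.isscalar(theta_deg) else w


def axial_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest signed difference a - b between two axis angles, in (-90, 90]."""
    return wrap_axial(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def segment_eye(
    frame: np.ndarray,
    roi: RoiSpec,
    blur_k: int = 5,
    thresh: float = 100.0,
    dark_on_light: bool = True,
) -> np.ndarray:
    """Segment one eye inside its ROI.

    Median-blurs the cropped ROI, thresholds (pixels darker than ``thresh``
    by default) and keeps the largest connected component.  Returns a boolean
    mask with the ROI's shape; an all-false mask signals "no eye found".
    """
    if blur_k < 1 or blur_k % 2 == 0:
        raise ValueError("blur_k must be an odd integer >= 1")
    patch = roi.crop(np.asarray(frame))
    if patch.ndim == 3:  # color -> luminance
        patch = patch.mean(axis=2)
    patch = patch.astype(float)
    if blur_k > 1:
        patch = ndimage.median_filter(patch, size=blur_k)
    mask = patch < thresh if dark_on_light else patch > thresh
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def fit_eye_angle(mask: np.ndarray) -> EllipseFit:
    """Fit a least-squares ellipse to the boundary of a binary eye mask.

    The contour of the (single) component is extracted at sub-pixel
    resolution and an algebraic least-squares ellipse is fitted to it.
    Raises :class:`EyeTrackError` for empty masks or degenerate contours;
    near-circular fits are returned with ``reliable=False``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EyeTrackError("empty mask: no eye found")
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise EyeTrackError("no closed contour in mask")
    contour = max(contours, key=len)
    if len(contour) - 1 < 5:  # closed contours repeat their first point
        raise EyeTrackError("fewer than 5 boundary points")
    pts = np.column_stack([contour[:, 1], contour[:, 0]])  # (x=col, y=row)
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise EyeTrackError("ellipse fit failed")
    cx, cy = (float(v) for v in model.center)
    major, minor = (float(v) for v in model.axis_lengths)
    major_img_deg = np.rad2deg(float(model.theta))  # major axis, image frame
    # minor axis is orthogonal; negate once for the CCW-positive convention
    theta = wrap_axial(-(major_img_deg + 90.0))
    reliable = minor > 0 and (major / minor) >= _MIN_AXIS_RATIO
    return EllipseFit(cx=cx, cy=cy, major=major, minor=minor, theta=float(theta), reliable=reliable)


def _track_one(frame, roi, blur_k, thresh, dark_on_light) -> float:
    mask = segment_eye(frame, roi, blur_k=blur_k, thresh=thresh, dark_on_light=dark_on_light)
    fit = fit_eye_angle(mask)
    return fit.theta


def track_series(
    frames: Iterable[np.ndarray],
    roi_left: RoiSpec,
    roi_right: RoiSpec,
    blur_k: int = 5,
    thresh: float = 100.0,
    dark_on_light: bool = True,
    dt: float = 0.1,
    t0: float = 0.0,
) -> EyeAngleSeries:
    """Track both eyes over an ordered frame sequence.

    Frames where segmentation or fitting fails are carried as invalid samples
    (NaN angle), never interpolated.  Frame-to-frame jumps larger than 90 deg
    are unwrapped by axial equivalence (theta and theta+180 describe the same
    ellipse axis), so slow rotations through +/-90 stay continuous.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise EyeTrackError("need at least 2 frames")
    cols: dict[str, list[float]] = {"left": [], "right": []}
    for frame in frames:
        for eye, roi in (("left", roi_left), ("right", roi_right)):
            try:
                cols[eye].append(_track_one(frame, roi, blur_k, thresh, dark_on_light))
            except EyeTrackError:
                cols[eye].append(np.nan)
    out = {}
    for eye in ("left", "right"):
        theta = np.array(cols[eye], dtype=float)
        out[eye] = _unwrap_axial_series(theta)
    t = t0 + dt * np.arange(len(frames))
    series = EyeAngleSeries(t=t, theta_left=out["left"], theta_right=out["right"])
    if not (series.valid_left.any() or series.valid_right.any()):
        raise EyeTrackError("all samples invalid")
    return series


def _unwrap_axial_series(theta: np.ndarray) -> np.ndarray:
    """Make a wrapped (-90, 90] axis-angle series continuous across samples.

    Consecutive valid samples never move by more than 90 deg in one frame for
    a physical eye, so any larger apparent jump is a wrap artifact and is
    folded back by 180 deg.
    """
    out = theta.copy()
    prev = None
    for i, v in enumerate(theta):
        if not np.isfinite(v):
            continue
        if prev is None:
            prev = v
            out[i] = v
            continue
        step = wrap_axial(v - wrap_axial(prev))
        out[i] = prev + step
        prev = out[i]
    return out
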