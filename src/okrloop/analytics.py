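"""Eye-trace analytics: delta thresholding, directional parity, NEA, saccades.

All quantities here operate on the 10 Hz eye-angle series produced by
``okrloop.eyetrack`` (or simulated by ``okrloop.larva``).  The central ideas:

* **Delta series** -- frame-to-frame eye-angle changes ``delta(t) =
  theta(t) - theta(t - dt)``, first defined at the second frame,
  CCW-positive.  Camera jitter contaminates small deltas, so deltas are
  passed through a magnitude threshold tau: a sample is kept when
  ``|delta| > tau`` and set to 0 otherwise.

* **Directional parity** -- during proper stimulus following, the sign of
  each kept delta should agree with the grating rotation sense.  The parity
  ratio S(tau) is (#frames whose kept delta agrees with the stimulus
  direction) / (#frames that disagree), counts pooled across all directed
  time bins; zeros count on neither side.  The optimal tau is the smallest
  grid value maximizing S (a zero disagreement count yields an infinite S
  which beats any finite one).

* **Normalized eye activity (NEA)** -- for each time bin b the summed
  absolute delta B_b, normalized to the most active bin of that larva/trial,
  so NEA is in [0, 1] with the max bin exactly 1.

* **Saccades** -- fast resetting eye movements, detected either by an
  angular-velocity threshold (default +/-3 deg/s) or by the
  stimulus-disagreement threshold search (saccades oppose the slow-phase
  direction, so the delta threshold maximizing the disagreement/agreement
  ratio separates them from slow-phase frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .eyetrack import EyeAngleSeries
from .stimulus import GratingParams

__all__ = [
    "TimeBin",
    "ParityCurve",
    "SaccadeEvents",
    "AnalyticsError",
    "default_tau_grid",
    "delta_series",
    "threshold_filter",
    "parity_ratio",
    "optimal_threshold",
    "nea",
    "detect_saccades_velocity",
    "detect_saccades_disagreement",
    "bins_to_frame",
    "bins_from_frame",
]


class AnalyticsError(RuntimeError):
    """Raised for schedule/series mismatches (e.g. no directed bins)."""


@dataclass(frozen=True)
class TimeBin:
    """Half-open trial time bin [tb, tbn) with the stimulus active in it."""

    tb: float
    tbn: float
    stimulus: GratingParams
    label: str = ""

    def __post_init__(self) -> None:
        if not self.tb < self.tbn:
            raise ValueError("bin start must precede bin end")

    @property
    def directed(self) -> bool:
        return (not self.stimulus.blank) and self.stimulus.omega != 0

    @property
    def direction(self) -> int:
        """+1 for CCW rotation, -1 for CW, 0 for blank/static."""
        if not self.directed:
            return 0
        return 1 if self.stimulus.omega > 0 else -1


@dataclass
class ParityCurve:
    """Parity ratio S as a function of the candidate threshold grid."""

    tau_grid: np.ndarray
    S: np.ndarray
    tau_opt: float
    eye: str = ""

    def __post_init__(self) -> None:
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        self.S = np.asarray(self.S, dtype=float)


@dataclass
class SaccadeEvents:
    """Detected saccade events of one eye."""

    times: np.ndarray
    frame_mask: np.ndarray  # boolean, aligned with the series samples
    detector: str
    threshold: float
    eye: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frame_mask = np.asarray(self.frame_mask, dtype=bool)

    @property
    def count(self) -> int:
        return len(self.times)


def default_tau_grid() -> np.ndarray:
    """Integer threshold grid tau = 1..55 (trace units, deg/frame at 10 Hz)."""
    return np.arange(1.0, 56.0)


def delta_series(series: EyeAngleSeries, eye: str) -> tuple[np.ndarray, np.ndarray]:
    """Frame-to-frame deltas of one eye, aligned to the *later* frame's time.

    Deltas spanning an invalid sample are NaN; they are excluded from every
    count downstream rather than zero-filled (zero-filling would inflate the
    parity denominators).
    Returns ``(t, delta)`` with length ``len(series) - 1``.
    """
    theta = series.theta(eye).copy()
    valid = series.valid(eye)
    theta[~valid] = np.nan
    d = np.diff(theta)
    return series.t[1:], d


def threshold_filter(delta: np.ndarray, tau: float) -> np.ndarray:
    """Suppress small deltas: keep delta where ``|delta| > tau``, else 0.

    NaN samples (gaps) stay NaN.  Idempotent for fixed tau and monotone in
    tau: a larger threshold never increases the number of kept samples.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    delta = np.asarray(delta, dtype=float)
    out = np.where(np.abs(delta) > tau, delta, 0.0)
    out[np.isnan(delta)] = np.nan
    return out


def _pos_neg_counts(filtered: np.ndarray) -> tuple[int, int]:
    p = int(np.nansum(filtered > 0))
    n = int(np.nansum(filtered < 0))
    return p, n


def _ratio(num: int, den: int) -> float:
    if den == 0:
        return np.nan if num == 0 else np.inf
    return num / den


def parity_ratio(
    filtered: np.ndarray,
    t: np.ndarray,
    bin: TimeBin,
    stim_direction: int | None = None,
) -> float:
    """Parity ratio S of a thresholded delta series within one time bin.

    For a CCW (+) stimulus S = (#positive kept deltas)/(#negative kept
    deltas) over frames in [tb, tbn); for CW (-) the reciprocal counting.
    Zeros count on neither side.  A zero denominator with a nonzero
    numerator returns +inf; 0/0 returns NaN (undefined).
    """
    direction = bin.direction if stim_direction is None else int(stim_direction)
    if direction == 0:
        raise AnalyticsError("parity ratio requires a directed stimulus")
    sel = (np.asarray(t) >= bin.tb) & (np.asarray(t) < bin.tbn)
    p, n = _pos_neg_counts(np.asarray(filtered)[sel])
    return _ratio(p, n) if direction > 0 else _ratio(n, p)


def _pooled_parity(
    t_prev: np.ndarray,
    delta: np.ndarray,
    bins: Sequence[TimeBin],
    tau: float,
) -> float:
    """S(tau) with aligned/misaligned counts pooled across all directed bins.

    Each delta is attributed to the bin containing its *earlier* frame --
    the stimulus that was actually on the display while the eye moved --
    so bin-boundary deltas never leak into the following bin.
    """
    filt = threshold_filter(delta, tau)
    aligned = 0
    misaligned = 0
    for b in bins:
        if not b.directed:
            continue
        sel = (t_prev >= b.tb) & (t_prev < b.tbn)
        p, n = _pos_neg_counts(filt[sel])
        if b.direction > 0:
            aligned += p
            misaligned += n
        else:
            aligned += n
            misaligned += p
    return _ratio(aligned, misaligned)


def _argmax_tau(tau_grid: np.ndarray, S: np.ndarray) -> float:
    """Smallest tau attaining the maximum S; +inf beats any finite S.

    All-NaN curves (no kept deltas anywhere) fall back to the smallest tau.
    """
    if np.all(np.isnan(S)):
        return float(tau_grid[0])
    best = np.nanmax(S)
    if np.isposinf(best):
        idx = int(np.argmax(np.isposinf(S)))
    else:
        idx = int(np.nanargmax(S))  # nanargmax returns the first maximizer
    return float(tau_grid[idx])


def optimal_threshold(
    series: EyeAngleSeries,
    bins: Sequence[TimeBin],
    tau_grid: np.ndarray | None = None,
    eyes: Iterable[str] = ("left", "right"),
) -> dict[str, ParityCurve]:
    """Grid-search the delta threshold maximizing directional parity, per eye."""
    tau_grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, dtype=float)
    if not any(b.directed for b in bins):
        raise AnalyticsError("schedule contains no directed bins")
    out: dict[str, ParityCurve] = {}
    for eye in eyes:
        _, delta = delta_series(series, eye)
        t_prev = series.t[:-1]
        S = np.array([_pooled_parity(t_prev, delta, bins, tau) for tau in tau_grid])
        out[eye] = ParityCurve(tau_grid=tau_grid, S=S, tau_opt=_argmax_tau(tau_grid, S), eye=eye)
    return out


def nea(
    series: EyeAngleSeries,
    bins: Sequence[TimeBin],
    larva_id: str = "larva0",
    trial_id: str = "trial0",
    eye: str = "left",
) -> pd.DataFrame:
    """Normalized eye activity per time bin.

    ``B`` is the sum of |frame-to-frame delta| over frames whose *both*
    endpoints fall in the bin; bins sharing a label (e.g. the two blank
    segments labelled "B") are summed together.  ``NEA = B / max_b B`` over
    all bins of this larva/trial, blank bins included in the max.  If every
    B is 0 the NEA column is NaN and the rows are flagged.
    """
    if not bins:
        raise AnalyticsError("need at least one bin")
    theta = series.theta(eye).copy()
    theta[~series.valid(eye)] = np.nan
    absd = np.abs(np.diff(theta))
    # delta f -> f+1 belongs to a bin iff both endpoint times are inside it
    t0, t1 = series.t[:-1], series.t[1:]
    sums: dict[str, float] = {}
    order: list[str] = []
    for i, b in enumerate(bins):
        label = b.label or f"bin{i}"
        sel = (t0 >= b.tb) & (t1 < b.tbn)
        val = float(np.nansum(absd[sel]))
        if label not in sums:
            sums[label] = 0.0
            order.append(label)
        sums[label] += val
    bmax = max(sums.values())
    flagged = bmax == 0
    rows = [
        {
            "larva": larva_id,
            "trial": trial_id,
            "bin": label,
            "B": sums[label],
            "NEA": (sums[label] / bmax) if not flagged else np.nan,
            "flagged": flagged,
        }
        for label in order
    ]
    return pd.DataFrame(rows)


def detect_saccades_velocity(
    series: EyeAngleSeries,
    eye: str = "left",
    v_thresh: float = 3.0,
) -> SaccadeEvents:
    """Velocity-threshold saccade detector.

    Eye angular velocity is the central difference of theta over the uniform
    sampling grid; frames with ``|v| > v_thresh`` (deg/s) are saccadic, and
    consecutive supra-threshold frames merge into a single event timestamped
    at the velocity peak.
    """
    theta = series.theta(eye).copy()
    theta[~series.valid(eye)] = np.nan
    v = np.gradient(theta, series.t)
    supra = np.abs(v) > v_thresh
    supra &= np.isfinite(v)
    times, mask = _merge_events(series.t, np.abs(v), supra)
    return SaccadeEvents(times=times, frame_mask=mask, detector="velocity", threshold=v_thresh, eye=eye)


def _merge_events(t: np.ndarray, strength: np.ndarray, supra: np.ndarray):
    """Merge runs of supra-threshold frames into single peak-located events."""
    mask = np.zeros_like(supra)
    times = []
    i = 0
    n = len(supra)
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1]:
                j += 1
            peak = i + int(np.nanargmax(strength[i : j + 1]))
            times.append(t[peak])
            mask[peak] = True
            i = j + 1
        else:
            i += 1
    return np.asarray(times, dtype=float), mask


def disagreement_curve(
    series: EyeAngleSeries,
    bins: Sequence[TimeBin],
    eye: str = "left",
    tau_grid: np.ndarray | None = None,
) -> ParityCurve:
    """Disagreement/agreement ratio vs tau, pooled across directed bins.

    For each candidate tau, only deltas with ``|delta| > tau`` are counted;
    the curve value is (#deltas whose sign opposes the stimulus direction) /
    (#deltas that agree).  The maximizing tau separates saccades (which
    oppose the slow phase) from stimulus-following frames.
    """
    tau_grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, dtype=float)
    if not any(b.directed for b in bins):
        raise AnalyticsError("schedule contains no directed bins")
    _, delta = delta_series(series, eye)
    t_prev = series.t[:-1]
    ratios = np.empty(len(tau_grid))
    for k, tau in enumerate(tau_grid):
        filt = threshold_filter(delta, tau)
        agree = 0
        disagree = 0
        for b in bins:
            if not b.directed:
                continue
            sel = (t_prev >= b.tb) & (t_prev < b.tbn)
            p, n = _pos_neg_counts(filt[sel])
            if b.direction > 0:
                agree += p
                disagree += n
            else:
                agree += n
                disagree += p
        ratios[k] = _ratio(disagree, agree)
    return ParityCurve(tau_grid=tau_grid, S=ratios, tau_opt=_argmax_tau(tau_grid, ratios), eye=eye)


def detect_saccades_disagreement(
    series: EyeAngleSeries,
    bins: Sequence[TimeBin],
    eye: str = "left",
    tau_grid: np.ndarray | None = None,
) -> SaccadeEvents:
    """Disagreement-threshold saccade detector.

    The delta threshold is chosen by :func:`disagreement_curve`; saccades
    are all frames whose |delta| exceeds it.  If even the best threshold
    leaves disagreement below agreement (max ratio < 1 with no infinite
    value), saccades and slow phase are not separable -- the trace is
    treated as saccade-free.
    """
    curve = disagreement_curve(series, bins, eye=eye, tau_grid=tau_grid)
    t, delta = delta_series(series, eye)
    separable = np.any(np.isposinf(curve.S)) or (
        not np.all(np.isnan(curve.S)) and np.nanmax(curve.S[np.isfinite(curve.S)], initial=0.0) >= 1.0
    )
    if not separable:
        mask = np.zeros(len(series), dtype=bool)
        return SaccadeEvents(
            times=np.array([]), frame_mask=mask, detector="disagreement",
            threshold=np.inf, eye=eye,
        )
    supra = np.abs(delta) > curve.tau_opt
    supra &= np.isfinite(delta)
    mask = np.concatenate([[False], supra])  # align to series samples
    times = series.t[mask]
    return SaccadeEvents(
        times=times, frame_mask=mask, detector="disagreement", threshold=curve.tau_opt, eye=eye
    )


def bins_to_frame(bins: Sequence[TimeBin]) -> pd.DataFrame:
    """Serialize bins to the `tb,tbn,omega,blank,label` CSV schema."""
    return pd.DataFrame(
        {
            "tb": [b.tb for b in bins],
            "tbn": [b.tbn for b in bins],
            "omega": [b.stimulus.omega for b in bins],
            "blank": [int(b.stimulus.blank) for b in bins],
            "label": [b.label for b in bins],
        }
    )


def bins_from_frame(df: pd.DataFrame, base: GratingParams | None = None) -> list[TimeBin]:
    base = base or GratingParams()
    from dataclasses import replace

    return [
        TimeBin(
            tb=float(r.tb),
            tbn=float(r.tbn),
            stimulus=replace(base, omega=float(r.omega), blank=bool(r.blank)),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]
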