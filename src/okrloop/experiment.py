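"""Trial protocols, trial metrics and NEA statistics.

Characterization protocol: a 2-minute trial per stimulus parameter
(rotational speed, grating spacing, grating count, grating thickness).  The
varied parameter changes level at t = 10, 30, 50, 70 and 90 s (five 20 s
levels), the rotation direction alternates every 10 s, and the first and
last 10 s show a blank screen.  Parameters not being varied stay at the
defaults: omega 30 deg/s, spacing 20 %, thickness maximum, 5 gratings.  The
two blank segments share the label "B", so normalized-eye-activity tables
group into six bins: five levels plus blank.

Driving protocol: after a speed-characterization calibration fixes the
per-eye delta thresholds, each larva runs 8 closed-loop line-following
trials (4 grating speeds x 2 starting sides, 45 s each, logged at 10 Hz).
Trial performance is the absolute x-error |robot_x - line_x| over time,
summarized by the intersection time (first sign change of the signed
error), the cumulative error (trapezoidal time integral), and mean errors
over the whole trial and over the post-intersection region t > 20 s.

NEA statistics: Kruskal-Wallis H across the six bins pooled over larvae,
followed (when significant) by Dunn's pairwise z-tests on pooled ranks with
Bonferroni adjustment, keeping the family-wise error rate at alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analytics import TimeBin, nea, optimal_threshold
from .larva import VirtualLarva, VirtualLarvaParams, simulate_trace
from .loop import LoopConfig, TrialLog, run_loop
from .stimulus import GratingParams
from .world import RobotState, WorldConfig

__all__ = [
    "CHARACTERIZATION_KINDS",
    "ScheduleError",
    "TrialMetrics",
    "NeaStatsResult",
    "build_schedule",
    "compute_metrics",
    "nea_stats",
    "dunn_posthoc",
    "run_driving_set",
    "DRIVING_OMEGAS",
    "START_SIDES",
]

#: parameter levels per characterization kind (five 20-s levels each)
CHARACTERIZATION_KINDS: dict[str, tuple[str, tuple[float, ...]]] = {
    "speed": ("omega", (15.0, 30.0, 45.0, 60.0, 75.0)),
    "spacing": ("spacing", (10.0, 20.0, 30.0, 40.0, 50.0)),
    "count": ("n_gratings", (1, 2, 3, 4, 5)),
    "thickness": ("thickness", (20.0, 40.0, 60.0, 80.0, 100.0)),
}

DRIVING_OMEGAS = (15.0, 30.0, 45.0, 60.0)
START_SIDES = ("left", "right")

_TRIAL_LEN = 120.0
_LEVEL_LEN = 20.0
_ALTERNATE = 10.0
_BLANK_LEN = 10.0


class ScheduleError(ValueError):
    """Unknown characterization kind or malformed schedule."""


def build_schedule(kind: str, **overrides) -> list[TimeBin]:
    """Deterministic characterization schedule for one stimulus parameter.

    Returns 12 half-open bins tiling [0, 120) s: a leading and trailing
    10 s blank bin (both labelled "B") and ten 10 s directed bins -- five
    parameter levels of 20 s each, split in two by the direction
    alternation (CCW first).  ``overrides`` replace the non-varied defaults
    (e.g. ``omega=45``).
    """
    if kind not in CHARACTERIZATION_KINDS:
        raise ScheduleError(f"unknown characterization kind {kind!r}")
    field_name, levels = CHARACTERIZATION_KINDS[kind]
    base = GratingParams(**overrides)
    bins: list[TimeBin] = [
        TimeBin(0.0, _BLANK_LEN, replace(base, blank=True), label="B")
    ]
    t = _BLANK_LEN
    direction = +1
    for level in levels:
        for _ in range(int(_LEVEL_LEN / _ALTERNATE)):
            params = replace(base, **{field_name: level}) if field_name != "omega" else base
            omega_mag = abs(level if field_name == "omega" else params.omega)
            params = replace(params, omega=direction * omega_mag)
            label = f"{level:g}" if field_name != "n_gratings" else str(int(level))
            bins.append(TimeBin(t, t + _ALTERNATE, params, label=label))
            t += _ALTERNATE
            direction = -direction
    bins.append(TimeBin(t, t + _BLANK_LEN, replace(base, blank=True), label="B"))
    assert bins[-1].tbn == _TRIAL_LEN
    return bins


@dataclass(frozen=True)
class TrialMetrics:
    """Performance summary of one driving trial (cm, s)."""

    mean_total_error: float
    mean_error_post20: float
    cumulative_error: float
    intersection_time: float | None
    max_error_post_intersection: float | None
    initial_error: float


def compute_metrics(
    log: TrialLog | pd.DataFrame,
    line_x: float = 0.0,
    intersection_cutoff: float = 20.0,
) -> TrialMetrics:
    """Compute line-following error metrics from a trial log.

    The absolute x-error is |robot_x - line_x| per row; the intersection
    time is the first time the signed error changes sign (None if the robot
    never crosses); the cumulative error is the trapezoidal time integral
    of the absolute error (cm s).
    """
    df = log.frame if isinstance(log, TrialLog) else log
    if "robot_x" not in df or "t" not in df:
        raise KeyError("log lacks robot position columns")
    if len(df) == 0:
        raise ValueError("empty trial log")
    t = df["t"].to_numpy(dtype=float)
    err_signed = df["robot_x"].to_numpy(dtype=float) - line_x
    err = np.abs(err_signed)

    sign0 = np.sign(err_signed[0])
    intersection = None
    if sign0 == 0:
        intersection = float(t[0])
    else:
        crossed = np.nonzero(np.sign(err_signed) != sign0)[0]
        if crossed.size:
            intersection = float(t[crossed[0]])
    max_post = None
    if intersection is not None:
        post = err[t >= intersection]
        max_post = float(post.max()) if post.size else None

    late = t > intersection_cutoff
    return TrialMetrics(
        mean_total_error=float(err.mean()),
        mean_error_post20=float(err[late].mean()) if late.any() else np.nan,
        cumulative_error=float(np.trapezoid(err, t)) if len(t) > 1 else 0.0,
        intersection_time=intersection,
        max_error_post_intersection=max_post,
        initial_error=float(err[0]),
    )


@dataclass
class NeaStatsResult:
    """Kruskal-Wallis omnibus result plus (optional) Dunn post-hoc table."""

    H: float
    p: float
    n_groups: int
    pairwise: pd.DataFrame | None  # None unless the omnibus test rejects
    degenerate: bool = False


def dunn_posthoc(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with Bonferroni adjustment.

    For groups i, j with pooled mean ranks Rbar_i, Rbar_j over N total
    observations, z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with the tie correction T = sum(t^3 - t) / (12 (N - 1)).  Two-sided
    normal p-values are adjusted as min(1, p * m), m = k(k-1)/2.
    """
    labels = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    N = len(values)
    ranks = stats.rankdata(values)
    offsets = np.cumsum([0] + [sizes[g] for g in labels])
    mean_rank = {
        g: float(ranks[offsets[i] : offsets[i + 1]].mean()) for i, g in enumerate(labels)
    }
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": p_raw,
                "p_adj": min(1.0, p_raw * m),
                "significant": min(1.0, p_raw * m) < alpha,
            }
        )
    return pd.DataFrame(rows)


def nea_stats(table: pd.DataFrame, alpha: float = 0.05) -> NeaStatsResult:
    """Kruskal-Wallis H across bins (pooled over larvae) + Dunn post-hoc.

    ``table`` follows the NEA schema (columns ``bin`` and ``NEA``, one row
    per larva/trial/bin).  Constant data cannot be ranked informatively and
    returns a degenerate flag with H = 0.
    """
    groups = {
        str(label): sub["NEA"].to_numpy(dtype=float)
        for label, sub in table.groupby("bin", sort=False)
    }
    if len(groups) < 2:
        raise ValueError("need >= 2 bins for the omnibus test")
    if min(len(v) for v in groups.values()) < 2:
        raise ValueError("need >= 2 observations per bin")
    pooled = np.concatenate(list(groups.values()))
    if np.allclose(pooled, pooled[0]):
        return NeaStatsResult(H=0.0, p=1.0, n_groups=len(groups), pairwise=None, degenerate=True)
    H, p = stats.kruskal(*groups.values())
    pairwise = dunn_posthoc(groups, alpha=alpha) if p < alpha else None
    return NeaStatsResult(H=float(H), p=float(p), n_groups=len(groups), pairwise=pairwise)


def _start_state(side: str, world_cfg: WorldConfig, offset: float, oblique_deg: float, speed: float) -> RobotState:
    """Initial pose: offset to one side, oblique (tilted toward the line)."""
    if side == "left":
        return RobotState(x=-offset, y=-world_cfg.arena_size * 0.35, heading=90.0 - oblique_deg, speed=speed)
    if side == "right":
        return RobotState(x=+offset, y=-world_cfg.arena_size * 0.35, heading=90.0 + oblique_deg, speed=speed)
    raise ValueError(f"unknown start side {side!r}")


def calibrate_thresholds(
    larva_params: VirtualLarvaParams,
    dt: float = 0.1,
) -> dict[str, float]:
    """Initial speed-characterization trial -> per-eye optimal thresholds."""
    schedule = build_schedule("speed")
    trace = simulate_trace(larva_params, schedule, dt=dt)
    curves = optimal_threshold(trace.series, schedule)
    return {eye: curves[eye].tau_opt for eye in ("left", "right")}


def run_driving_set(
    larva_params: Sequence[VirtualLarvaParams],
    world_cfg: WorldConfig | None = None,
    omegas: Sequence[float] = DRIVING_OMEGAS,
    start_sides: Sequence[str] = START_SIDES,
    trial_duration: float = 45.0,
    start_offset: float = 12.0,
    oblique_deg: float = 60.0,
    speed: float = 5.0,
    keep_logs: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, list[TrialLog]]:
    """Full driving protocol: calibration then the 4 x 2 trial array per larva.

    For each virtual larva: run the speed-characterization calibration to
    fix tau_left/tau_right, then one 45 s closed-loop trial per
    (omega, start side) combination.  Each trial reseeds the larva with a
    distinct sub-seed so trials are independent but reproducible.

    Returns ``(metrics, summary, logs)``: per-trial metric rows, the
    (omega, side) group means of the post-20 s error, and (optionally) the
    raw logs.
    """
    world_cfg = world_cfg or WorldConfig()
    rows = []
    logs: list[TrialLog] = []
    for li, lp in enumerate(larva_params):
        taus = calibrate_thresholds(lp)
        for ti, (omega, side) in enumerate(itertools.product(omegas, start_sides)):
            trial_seed = (lp.seed * 1009 + ti * 101 + 7) % (2**31 - 1)
            larva = VirtualLarva(replace(lp, seed=trial_seed), dt=0.1)
            cfg = LoopConfig(
                tau_left=taus["left"],
                tau_right=taus["right"],
                omega_magnitude=omega,
                trial_duration=trial_duration,
            )
            state = _start_state(side, world_cfg, start_offset, oblique_deg, speed)
            log = run_loop(larva, state, GratingParams(), cfg, world_cfg)
            m = compute_metrics(log)
            rows.append(
                {
                    "larva": li,
                    "seed": lp.seed,
                    "omega": omega,
                    "start_side": side,
                    "tau_left": taus["left"],
                    "tau_right": taus["right"],
                    "initial_error": m.initial_error,
                    "mean_total_error": m.mean_total_error,
                    "mean_error_post20": m.mean_error_post20,
                    "cumulative_error": m.cumulative_error,
                    "intersection_time": m.intersection_time,
                    "max_error_post_intersection": m.max_error_post_intersection,
                }
            )
            if keep_logs:
                logs.append(log)
    metrics = pd.DataFrame(rows)
    summary = (
        metrics.groupby(["omega", "start_side"], sort=True)["mean_error_post20"]
        .mean()
        .reset_index()
    )
    return metrics, summary, logs
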