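"""Closed loop: eye deltas -> movement decision -> robot -> stimulus.

Each 0.1 s control tick reads the larva's eye angles under the stimulus
currently displayed, computes the frame-to-frame deltas, applies the two-eye
movement rule, steps the robot, reads the line sensor, and updates the
stimulus through the display logic -- producing one synchronized log row.

The movement rule is deliberately conservative: a turn is commanded only
when *both* eyes cross their calibrated thresholds in the same direction
(both deltas above +tau -> Left, both below -tau -> Right); any
disagreement, sub-threshold movement, or missing sample means Forward.
Because the two-eye consensus gates out single-eye noise and saccades, the
per-eye thresholds from the parity calibration are what make the loop
robust to camera jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd

from . import world as world_mod
from .loop_types import Command, LoopConfig
from .stimulus import GratingParams, display_logic
from .world import RobotState, WorldConfig

__all__ = ["Command", "LoopConfig", "TrialLog", "decide", "run_loop"]

#: bit-exact column order of the synchronized trial log
LOG_COLUMNS = [
    "t",
    "theta_left",
    "theta_right",
    "delta_left",
    "delta_right",
    "command",
    "omega",
    "blank",
    "robot_x",
    "robot_y",
    "heading",
    "line_side",
]


class EyeAngleSource(Protocol):
    """Anything able to produce one (theta_left, theta_right) pair per tick."""

    def step(self, stim: GratingParams | None, dt: float | None = None) -> tuple[float, float]:
        ...


@dataclass
class TrialLog:
    """Synchronized 10 Hz record of one closed-loop trial."""

    frame: pd.DataFrame
    config: LoopConfig
    aborted: bool = False

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: LoopConfig | None = None) -> "TrialLog":
        return cls(frame=pd.read_csv(path), config=config or LoopConfig())


def decide(
    delta_left: float,
    delta_right: float,
    tau_left: float,
    tau_right: float,
) -> Command:
    """Two-eye movement rule.

    Left iff delta_left > tau_left and delta_right > tau_right;
    Right iff delta_left < -tau_left and delta_right < -tau_right;
    Forward otherwise (including ties at the thresholds, disagreement
    between the eyes, and NaN deltas from invalid samples).
    """
    if tau_left < 0 or tau_right < 0:
        raise ValueError("thresholds must be >= 0")
    if np.isnan(delta_left) or np.isnan(delta_right):
        return Command.FORWARD
    if delta_left > tau_left and delta_right > tau_right:
        return Command.LEFT
    if delta_left < -tau_left and delta_right < -tau_right:
        return Command.RIGHT
    return Command.FORWARD


def run_loop(
    larva: EyeAngleSource,
    robot: RobotState,
    base_stim: GratingParams,
    cfg: LoopConfig | None = None,
    world_cfg: WorldConfig | None = None,
) -> TrialLog:
    """Run one synchronized closed-loop trial.

    Per tick: read eye angles -> compute deltas -> decide -> command robot
    -> read line side -> display logic updates the stimulus for the next
    tick -> append one log row.  Deterministic for a seeded larva.
    """
    cfg = cfg or LoopConfig()
    world_cfg = world_cfg or WorldConfig()
    base = GratingParams(
        omega=cfg.omega_magnitude,
        n_gratings=base_stim.n_gratings,
        spacing=base_stim.spacing,
        thickness=base_stim.thickness,
        center_radius=base_stim.center_radius,
    )
    n_ticks = int(round(cfg.trial_duration / cfg.tick))

    obs = world_mod.observe_line(robot, world_cfg, last_side="on")
    last_side = obs.line_side
    stim = display_logic(last_side, base)

    prev_l: float | None = None
    prev_r: float | None = None
    rows = []
    for i in range(n_ticks):
        t = i * cfg.tick
        th_l, th_r = larva.step(stim, cfg.tick)
        d_l = np.nan if prev_l is None else th_l - prev_l
        d_r = np.nan if prev_r is None else th_r - prev_r
        prev_l, prev_r = th_l, th_r
        cmd = decide(d_l, d_r, cfg.tau_left, cfg.tau_right)
        robot = world_mod.step(robot, cmd, cfg.tick, world_cfg)
        obs = world_mod.observe_line(robot, world_cfg, last_side=last_side)
        last_side = obs.line_side
        stim = display_logic(last_side, base)
        rows.append(
            {
                "t": round(t, 6),
                "theta_left": th_l,
                "theta_right": th_r,
                "delta_left": d_l,
                "delta_right": d_r,
                "command": str(cmd),
                "omega": stim.omega if not stim.blank else 0.0,
                "blank": int(stim.blank),
                "robot_x": robot.x,
                "robot_y": robot.y,
                "heading": robot.heading,
                "line_side": obs.line_side,
            }
        )
    return TrialLog(frame=pd.DataFrame(rows, columns=LOG_COLUMNS), config=cfg)
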