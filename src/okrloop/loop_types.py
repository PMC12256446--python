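"""Shared closed-loop types (kept dependency-free to avoid import cycles)."""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = ["Command", "LoopConfig"]


class Command(enum.Enum):
    """Discrete movement command sent to the robot each control tick."""

    LEFT = "left"
    RIGHT = "right"
    FORWARD = "forward"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


@dataclass(frozen=True)
class LoopConfig:
    """Closed-loop timing and per-eye delta thresholds.

    ``tick`` is the control period in seconds (10 Hz default, matching the
    logging rate); ``tau_left``/``tau_right`` the calibrated per-eye delta
    thresholds (deg/frame); ``omega_magnitude`` the grating speed magnitude
    for the trial (deg/s); ``trial_duration`` the trial length in seconds.
    """

    tick: float = 0.1
    tau_left: float = 1.0
    tau_right: float = 1.0
    omega_magnitude: float = 30.0
    trial_duration: float = 45.0

    def __post_init__(self) -> None:
        if self.tick <= 0:
            raise ValueError("tick must be > 0")
        if self.tau_left < 0 or self.tau_right < 0:
            raise ValueError("thresholds must be >= 0")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be > 0")
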