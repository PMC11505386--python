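"""Two-loop sweep-gas controller.

The outer loop is a velocity-form PI that converts the EGCO2 error into
the next sweep-flow command: a positive error (measured EGCO2 above
target) increases sweep to remove more CO2.  Writing the PI in velocity
form means the clamp to ``[min_sweep, max_sweep]`` doubles as anti-windup
-- no integral state can run away while the command is saturated.  The
floor (250 mL/min by default) keeps gas moving past the CO2 sensor and
bounds the transport delay.

The inner loop drives blower duty so the measured sweep flow tracks the
commanded flow; it is an integral-only velocity update, fast enough that a
0.25 -> 4.0 L/min step enters the +-0.1 L/min band in under 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum


class ControlMode(str, Enum):
    fixed_egco2 = "fixed_egco2"
    fixed_sweep = "fixed_sweep"


@dataclass(frozen=True)
class ControllerConfig:
    """Outer- and inner-loop controller parameters.

    ``kp``/``ki`` were calibrated on the reference water scenario so that
    settling after each simulated metabolic step stays under 1 min and the
    target is held within +-5 mmHg; the dominant constraint is stability at
    the flow floor, where the plant gain |dEGCO2/dQ| and the transport
    delay are both largest.  ``egco2_filter_s`` low-passes the sensed
    EGCO2 before the PI law; it damps the post-step ringing that the raw
    1 Hz readings otherwise excite through the loop delay.
    """

    mode: ControlMode = ControlMode.fixed_egco2
    target_egco2: float = 20.0      # mmHg
    fixed_sweep_flow: float = 1.0   # L/min
    kp: float = 0.02                # (L/min)/mmHg
    ki: float = 0.008               # (L/min)/(mmHg*s)
    min_sweep: float = 0.25         # L/min flow floor
    max_sweep: float = 7.0          # L/min, tall-lung blower limit
    update_period: float = 1.0      # s, outer-loop tick
    egco2_filter_s: float = 3.0     # s, EMA on the sensed EGCO2 (0 = off)
    inner_ff: float = 10.0 / 70.0   # duty per (L/min), calibrated feedforward
    inner_ki: float = 0.1           # duty/(L/min * s), integral trim
    kd: float = 0.0                 # derivative stub, unused by default

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ControlMode(self.mode))
        if self.kp < 0 or self.ki < 0:
            raise ValueError("kp and ki must be >= 0")
        if self.update_period <= 0:
            raise ValueError("update_period must be > 0")
        if self.mode is ControlMode.fixed_egco2 and self.min_sweep < 0.25:
            raise ValueError("min_sweep must be >= 0.25 L/min in feedback mode")
        if self.min_sweep > self.max_sweep:
            raise ValueError("min_sweep must not exceed max_sweep")


@dataclass
class ControllerState:
    """PI memory: previous error and previous (clamped) command."""

    last_error: float = 0.0
    last_command: float = 0.25   # L/min
    saturated: bool = False


def pi_update(egco2_measured: float, cfg: ControllerConfig,
              state: ControllerState) -> tuple[float, ControllerState]:
    """One outer-loop update; returns ``(command, new_state)``.

    Velocity form:
    ``u = clamp(u_prev + kp*(e - e_prev) + ki*T*e, min_sweep, max_sweep)``
    with ``e = EGCO2 - target``.
    """
    if cfg.mode is not ControlMode.fixed_egco2:
        raise ValueError("pi_update requires fixed_egco2 mode")
    e = egco2_measured - cfg.target_egco2
    u = (state.last_command
         + cfg.kp * (e - state.last_error)
         + cfg.ki * cfg.update_period * e)
    clamped = min(max(u, cfg.min_sweep), cfg.max_sweep)
    new = ControllerState(last_error=e, last_command=clamped,
                          saturated=clamped != u)
    return clamped, new


def fixed_sweep_command(cfg: ControllerConfig) -> float:
    """Open-loop command: the pre-set fixed sweep flow, feedback ignored."""
    if cfg.mode is not ControlMode.fixed_sweep:
        raise ValueError("fixed_sweep_command requires fixed_sweep mode")
    return cfg.fixed_sweep_flow


def inner_flow_loop(command: float, measured_flow: float, duty: float,
                    dt: float, cfg: ControllerConfig | None = None,
                    prev_command: float | None = None) -> tuple[float, bool]:
    """One inner-loop step: adjust blower duty toward the flow command.

    Velocity update combining a calibrated feedforward with an integral
    trim on the measured flow error,

    ``duty += inner_ff * (command - prev_command) + inner_ki * dt * e``.

    The feedforward (duty per L/min, from the blower pressure/resistance
    calibration) moves the duty to the right neighborhood within one tick
    of a setpoint change; the slow integral absorbs calibration error and
    sensor bias without fighting the flow-reading noise.  The integral is
    gated off while the flow error exceeds 0.5 L/min (integral
    separation), so it does not wind up during the blower's own transient
    after a large setpoint step.  Returns ``(duty', saturated)`` where
    ``saturated`` flags a command beyond the blower's reach (duty pinned
    at 1 while the flow error is still large).
    """
    if cfg is None:
        cfg = ControllerConfig()
    if prev_command is None:
        prev_command = command
    e = command - measured_flow
    integ = cfg.inner_ki * dt * e if abs(e) <= 0.5 else 0.0
    duty_new = duty + cfg.inner_ff * (command - prev_command) + integ
    clamped = min(max(duty_new, 0.0), 1.0)
    saturated = clamped >= 1.0 and e > 0.1
    return clamped, saturated


def tune_gains(aggressiveness: float, cfg: ControllerConfig
               ) -> ControllerConfig:
    """Scale the proportional gain by ``aggressiveness``.

    Reducing the proportional term trades overshoot after a metabolic step
    against initial response time.
    """
    if aggressiveness <= 0:
        raise ValueError("aggressiveness must be > 0")
    return replace(cfg, kp=cfg.kp * aggressiveness)
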