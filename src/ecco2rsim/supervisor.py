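"""Blower-module safety logic.

The exhaust module computes the feedback law and only *suggests* a sweep
flow; the blower module validates that suggestion against a set of fault
heuristics (frozen or out-of-range EGCO2 or suggestion, a patient-operated
switch) and, on any fault, latches into a pre-specified fixed-sweep
fallback -- the behavior of a conventional, non-feedback sweep controller.
A pressure guard additionally caps sweep flow so the AL gas-side inlet
pressure cannot exceed a configured margin above ambient (gas-embolism
protection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class FaultKind(str, Enum):
    suggestion_frozen = "suggestion_frozen"
    egco2_frozen = "egco2_frozen"
    egco2_out_of_range = "egco2_out_of_range"
    suggestion_out_of_range = "suggestion_out_of_range"
    patient_switch = "patient_switch"
    overpressure = "overpressure"


class SupervisorMode(str, Enum):
    feedback = "feedback"
    fallback_fixed = "fallback_fixed"


@dataclass(frozen=True)
class SupervisorConfig:
    """Fault-detection thresholds and the fallback sweep setting.

    Freeze windows are chosen longer than the worst-case EGCO2 transport
    delay at the flow floor (12 s) so a slow but live signal is never
    mistaken for a dead one.
    """

    default_sweep: float = 1.0            # L/min fallback
    suggestion_window_s: float = 30.0
    suggestion_eps: float = 0.01          # L/min
    egco2_window_s: float = 60.0
    egco2_eps: float = 0.1                # mmHg
    egco2_bounds: tuple[float, float] = (1.0, 100.0)
    suggestion_bounds: tuple[float, float] = (0.0, 10.0)
    pressure_limit: float = 80.0          # mmHg above ambient

    def __post_init__(self) -> None:
        if self.default_sweep < 0.25:
            raise ValueError("default_sweep must be >= 0.25 L/min")
        if self.suggestion_window_s <= 0 or self.egco2_window_s <= 0:
            raise ValueError("detection windows must be > 0")


@dataclass
class SupervisorStatus:
    """Operating mode, active fault flags and the pressure-guard cap."""

    mode: SupervisorMode = SupervisorMode.feedback
    faults: set[FaultKind] = field(default_factory=set)
    pressure_capped: bool = False
    flow_cap: float = float("inf")        # L/min while overpressure active


def check_faults(times: Sequence[float], suggested: Sequence[float],
                 egco2: Sequence[float], status: SupervisorStatus,
                 cfg: SupervisorConfig,
                 clamp_bounds: tuple[float, float] | None = None
                 ) -> SupervisorStatus:
    """Apply the fault heuristics to recent history and update the flags.

    Freeze detection is conservative: a window shorter than the configured
    duration raises no new flags.  A suggestion pinned at the controller
    clamp (``clamp_bounds``) is exempt from freeze detection -- a
    saturated command is legitimately constant, e.g. during floor-pinned
    operation at an unachievably high target.
    """
    faults = set(status.faults)
    if times:
        t_now = times[-1]
        # Out-of-range checks act on the latest sample alone.
        lo, hi = cfg.egco2_bounds
        if not lo <= egco2[-1] <= hi:
            faults.add(FaultKind.egco2_out_of_range)
        slo, shi = cfg.suggestion_bounds
        if not slo <= suggested[-1] <= shi:
            faults.add(FaultKind.suggestion_out_of_range)

        def _frozen(series: Sequence[float], window: float, eps: float,
                    exempt: tuple[float, float] | None) -> bool:
            idx = [i for i, t in enumerate(times) if t >= t_now - window]
            if not idx or times[idx[0]] > t_now - window + 1e-9:
                return False     # insufficient history
            vals = [series[i] for i in idx]
            if exempt is not None and any(
                    abs(v - b) < 1e-9 for v in vals for b in exempt):
                # A window containing clamp-saturated samples is not
                # evidence of a dead module: a pinned command is
                # legitimately constant (e.g. an unachievably high target).
                return False
            return max(vals) - min(vals) < eps

        if _frozen(suggested, cfg.suggestion_window_s, cfg.suggestion_eps,
                   clamp_bounds):
            faults.add(FaultKind.suggestion_frozen)
        if _frozen(egco2, cfg.egco2_window_s, cfg.egco2_eps, None):
            faults.add(FaultKind.egco2_frozen)
    out = SupervisorStatus(mode=status.mode, faults=faults,
                           pressure_capped=status.pressure_capped,
                           flow_cap=status.flow_cap)
    return out


def arbitrate(suggested: float, status: SupervisorStatus,
              cfg: SupervisorConfig) -> tuple[float, SupervisorStatus]:
    """Pass the suggestion through, or override with the fixed fallback.

    Any active fault (other than pure overpressure, which caps rather than
    overrides) latches the fallback mode; the latch persists until the
    faults clear *and* :func:`re_arm` is called.
    """
    trip = {f for f in status.faults if f is not FaultKind.overpressure}
    mode = status.mode
    if trip:
        mode = SupervisorMode.fallback_fixed
    command = (cfg.default_sweep if mode is SupervisorMode.fallback_fixed
               else suggested)
    if status.pressure_capped:
        command = min(command, status.flow_cap)
    out = SupervisorStatus(mode=mode, faults=set(status.faults),
                           pressure_capped=status.pressure_capped,
                           flow_cap=status.flow_cap)
    return command, out


def re_arm(status: SupervisorStatus) -> SupervisorStatus:
    """Manual re-arm: return to feedback mode if no faults remain."""
    faults = set(status.faults)
    mode = status.mode
    if not faults:
        mode = SupervisorMode.feedback
    return SupervisorStatus(mode=mode, faults=faults,
                            pressure_capped=status.pressure_capped,
                            flow_cap=status.flow_cap)


def pressure_guard(gas_inlet_pressure: float, ambient: float,
                   status: SupervisorStatus, cfg: SupervisorConfig,
                   gas_resistance: float) -> SupervisorStatus:
    """Gas-embolism guard on the AL inlet pressure.

    Flags ``overpressure`` when the inlet exceeds ambient by more than
    ``pressure_limit`` and, while flagged, caps the sweep command at the
    flow whose modelled inlet pressure equals the limit
    (``limit / gas_resistance`` for the linear pressure model).
    """
    over = (gas_inlet_pressure - ambient) > cfg.pressure_limit
    faults = set(status.faults)
    if over:
        faults.add(FaultKind.overpressure)
    else:
        faults.discard(FaultKind.overpressure)
    cap = (cfg.pressure_limit / gas_resistance) if over else float("inf")
    return SupervisorStatus(mode=status.mode, faults=faults,
                            pressure_capped=over, flow_cap=cap)
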