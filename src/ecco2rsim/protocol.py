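"""Scenario definitions and the end-to-end simulation runner.

A :class:`Scenario` describes one benchtop experiment: the carrier fluid,
liquid flow, a schedule of conditioning-lung CO2 feed levels (the
simulated metabolic challenge), the controller configuration, and any
injected faults.  :func:`run` integrates the full closed loop --
conditioning lung, AL gas exchange, transport delay, sensors, outer PI /
fixed-sweep command, supervisor arbitration, blower dynamics, reservoir
balance -- with a fixed step and emits a decimated trace.

:func:`reference_scenarios` reproduces the benchtop protocol: water at
1.0 L/min with CO2 stepped 0.1/0.2/0.4/0.8 L/min at 4 min per level under
targets of 10-40 mmHg, fixed-sweep control arms at 1.0 and 2.0 L/min,
water-flow variations at 0.5-2.0 L/min (0.8 level omitted), and a blood
run.  Schedules step up and then back down so both overshoot (after a
metabolic increase) and undershoot (after a decrease) are exercised.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import exchange as ex
from . import hardware as hw
from .config import SimSetup, setup_to_dict
from .control import (ControlMode, ControllerConfig, ControllerState,
                      fixed_sweep_command, inner_flow_loop, pi_update)
from .exchange import Fluid, LiquidState, ReservoirState
from .supervisor import (FaultKind, SupervisorStatus, arbitrate, check_faults,
                         pressure_guard)

TRACE_COLUMNS = [
    "time_s", "egco2_true_mmHg", "egco2_sensed_mmHg", "sweep_cmd_lpm",
    "sweep_act_lpm", "pco2_pre_mmHg", "pco2_post_mmHg", "pco2_res_mmHg",
    "mode", "faults",
]

#: Conditioning-lung CO2 feed levels (L/min) of the metabolic challenge,
#: stepped up and back down; each level held 4 min.
FULL_STEPS = (0.1, 0.2, 0.4, 0.8, 0.4, 0.2, 0.1)
REDUCED_STEPS = (0.1, 0.2, 0.4, 0.2, 0.1)   # 0.8 level omitted
STEP_DURATION_S = 240.0


@dataclass(frozen=True)
class FaultInjection:
    """Exhaust-module misbehavior injected at ``time_s``.

    Kinds: ``egco2_freeze`` and ``suggestion_freeze`` hold the respective
    exhaust-module output at its last value; ``egco2_out_of_range`` forces
    the reported EGCO2 to ``value`` (default 150 mmHg); ``patient_switch``
    raises the patient-operated fault switch; ``blower_failure`` drops one
    of the two blowers.
    """

    time_s: float
    kind: str
    value: float = 150.0

    _KINDS = ("egco2_freeze", "suggestion_freeze", "egco2_out_of_range",
              "patient_switch", "blower_failure")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown fault kind {self.kind!r}; "
                             f"supported: {self._KINDS}")


@dataclass(frozen=True)
class Scenario:
    """One benchtop experiment definition."""

    name: str = "custom"
    fluid: Fluid = Fluid.water
    liquid_flow: float = 1.0                     # L/min
    schedule: tuple[tuple[float, float], ...] = tuple(
        (STEP_DURATION_S, lvl) for lvl in FULL_STEPS)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    fault_injections: tuple[FaultInjection, ...] = ()
    seed: int = 0
    initial_reservoir_pco2: float = 20.0         # mmHg
    warmup_s: float = 300.0                      # hold at first level

    def __post_init__(self) -> None:
        object.__setattr__(self, "fluid", Fluid(self.fluid))
        if self.liquid_flow <= 0:
            raise ValueError("liquid_flow must be > 0")
        for dur, lvl in self.schedule:
            if dur <= 0 or lvl < 0:
                raise ValueError("schedule durations must be > 0 and "
                                 "CO2 levels >= 0")

    @property
    def duration_s(self) -> float:
        return self.warmup_s + sum(d for d, _ in self.schedule)

    def change_times(self) -> list[float]:
        """Times of the metabolic steps (level boundaries after warm-up)."""
        out, t = [], self.warmup_s
        prev = self.schedule[0][1] if self.schedule else None
        for dur, lvl in self.schedule:
            if prev is not None and lvl != prev:
                out.append(t)
            prev = lvl
            t += dur
        # first boundary is warm-up -> level 0 only if levels differ; they
        # never do (warm-up holds the first level), so boundaries are the
        # in-schedule changes computed above, offset by one segment.
        out = []
        t = self.warmup_s
        for i, (dur, lvl) in enumerate(self.schedule):
            if i > 0 and lvl != self.schedule[i - 1][1]:
                out.append(t)
            t += dur
        return out

    def segment_bounds(self) -> list[tuple[float, float]]:
        """(start, end) of each schedule segment, warm-up excluded."""
        out, t = [], self.warmup_s
        for dur, _ in self.schedule:
            out.append((t, t + dur))
            t += dur
        return out


def inject_fault(scenario: Scenario, kind: str, time_s: float,
                 value: float = 150.0) -> Scenario:
    """Return a copy of ``scenario`` with one more fault injection."""
    inj = FaultInjection(time_s=time_s, kind=kind, value=value)
    return replace(scenario,
                   fault_injections=scenario.fault_injections + (inj,))


def reference_scenarios(seed: int = 0) -> dict[str, Scenario]:
    """The named benchtop protocol scenarios."""
    full = tuple((STEP_DURATION_S, l) for l in FULL_STEPS)
    reduced = tuple((STEP_DURATION_S, l) for l in REDUCED_STEPS)
    out: dict[str, Scenario] = {}
    for tgt in (10.0, 20.0, 30.0, 40.0):
        out[f"target_{int(tgt)}"] = Scenario(
            name=f"target_{int(tgt)}", liquid_flow=1.0, schedule=full,
            controller=ControllerConfig(mode=ControlMode.fixed_egco2,
                                        target_egco2=tgt),
            seed=seed)
    for fs in (1.0, 2.0):
        out[f"fixed_{fs:.1f}"] = Scenario(
            name=f"fixed_{fs:.1f}", liquid_flow=1.0, schedule=full,
            controller=ControllerConfig(mode=ControlMode.fixed_sweep,
                                        fixed_sweep_flow=fs),
            seed=seed)
    for q in (0.5, 1.0, 1.5, 2.0):
        out[f"flow_{q:.1f}"] = Scenario(
            name=f"flow_{q:.1f}", liquid_flow=q, schedule=reduced,
            controller=ControllerConfig(mode=ControlMode.fixed_egco2,
                                        target_egco2=20.0),
            seed=seed)
    out["blood"] = Scenario(
        name="blood", fluid=Fluid.blood, liquid_flow=1.0, schedule=reduced,
        controller=ControllerConfig(mode=ControlMode.fixed_egco2,
                                    target_egco2=20.0),
        seed=seed)
    return out


@dataclass
class TraceRecord:
    """Per-tick logged signals (one row of the trace CSV)."""

    time_s: float
    egco2_true_mmHg: float
    egco2_sensed_mmHg: float
    sweep_cmd_lpm: float
    sweep_act_lpm: float
    pco2_pre_mmHg: float
    pco2_post_mmHg: float
    pco2_res_mmHg: float
    mode: str
    faults: str


@dataclass
class RunResult:
    """Trace plus the metadata needed to interpret it."""

    scenario: Scenario
    setup: SimSetup
    records: list[TraceRecord]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records],
                            columns=TRACE_COLUMNS)

    @property
    def change_times(self) -> list[float]:
        return self.scenario.change_times()

    def to_csv(self, path: str | Path) -> None:
        """Write the trace CSV plus a JSON sidecar of the resolved config."""
        path = Path(path)
        self.frame().to_csv(path, index=False)
        sidecar = {
            "scenario": {
                **{k: (v.value if hasattr(v, "value") else v)
                   for k, v in asdict(self.scenario).items()
                   if k not in ("controller", "fault_injections", "schedule")},
                "schedule": [list(s) for s in self.scenario.schedule],
                "fault_injections": [asdict(f)
                                     for f in self.scenario.fault_injections],
            },
            **setup_to_dict(self.setup, self.scenario.controller),
        }
        path.with_suffix(".config.json").write_text(
            json.dumps(sidecar, indent=2, default=str))


def run(scenario: Scenario, setup: SimSetup | None = None,
        decimation_hz: float = 1.0) -> RunResult:
    """Integrate the closed loop for the full scenario duration.

    Fixed-step explicit integration at ``setup.plant.dt_s``; deterministic
    for a given ``scenario.seed``.  Raises ``RuntimeError`` with a
    diagnostic if any state goes non-finite.
    """
    setup = setup or SimSetup()
    plant, blower, sensor, sup_cfg = (setup.plant, setup.blower,
                                      setup.sensor, setup.supervisor)
    ctrl_cfg = scenario.controller
    chem = plant.chem()
    lung = plant.lung()
    fluid = scenario.fluid
    dt = plant.dt_s
    feedback = ctrl_cfg.mode is ControlMode.fixed_egco2

    rng = np.random.default_rng(scenario.seed)

    # Bench calibration before the run: the CO2 sensor is compared against
    # a reference analyzer at 20 mmHg (noise-free averaged bench reading).
    observed = sensor.co2_gain_error * 20.0 + sensor.co2_offset_error
    cal = hw.calibrate_one_point(observed, reference=20.0)

    # Schedule lookup table including warm-up at the first level.
    bounds: list[float] = [0.0]
    levels: list[float] = []
    if scenario.warmup_s > 0:
        levels.append(scenario.schedule[0][1])
        bounds.append(scenario.warmup_s)
    for dur, lvl in scenario.schedule:
        levels.append(lvl)
        bounds.append(bounds[-1] + dur)
    total_s = bounds[-1]

    # Initial conditions.
    res = ReservoirState.from_pco2(scenario.initial_reservoir_pco2,
                                   volume=plant.volume_l, fluid=fluid,
                                   chem=chem)
    command = (ctrl_cfg.fixed_sweep_flow if not feedback
               else ctrl_cfg.min_sweep)
    flow_act = command
    r_series = (lung.gas_resistance
                + blower.internal_resistance / max(blower.count_active, 1))
    duty = min(max(flow_act * r_series / blower.max_pressure, 0.0), 1.0)
    flow_ema = flow_act
    ema_tau = 0.5   # s, flow-reading smoothing for the inner loop
    prev_command = command
    ctrl_state = ControllerState(last_error=0.0, last_command=command)
    status = SupervisorStatus()
    plug = hw.PlugFlowBuffer(lung.dead_volume)
    latency = hw.DelayLine(sensor.latency_s, dt, initial=math.nan)
    sensed: float | None = None
    eg_filt: float | None = None    # EMA of sensed EGCO2 fed to the PI law
    suggested = command

    # Fault-injection bookkeeping.
    injections = sorted(scenario.fault_injections, key=lambda f: f.time_s)
    egco2_frozen_at: float | None = None
    sugg_frozen_at: float | None = None
    egco2_forced: float | None = None
    blower_cfg = blower
    pending = list(injections)

    # Supervisor history at the outer-loop cadence.
    hist_len = int(max(sup_cfg.suggestion_window_s, sup_cfg.egco2_window_s)
                   / ctrl_cfg.update_period) + 5
    h_t: deque[float] = deque(maxlen=hist_len)
    h_sugg: deque[float] = deque(maxlen=hist_len)
    h_eg: deque[float] = deque(maxlen=hist_len)

    records: list[TraceRecord] = []
    rec_period = 1.0 / decimation_hz
    next_rec = 0.0
    next_sample = 0.0
    next_ctrl = 0.0
    eps = dt * 1e-3

    n_ticks = int(round(total_s / dt))
    seg_idx = 0
    for i in range(n_ticks):
        t = i * dt
        while seg_idx + 1 < len(bounds) - 1 and t >= bounds[seg_idx + 1] - eps:
            seg_idx += 1
        co2_level = levels[seg_idx]

        # Activate any pending fault injections.
        while pending and t >= pending[0].time_s - eps:
            inj = pending.pop(0)
            if inj.kind == "egco2_freeze":
                egco2_frozen_at = sensed if sensed is not None else 0.0
            elif inj.kind == "suggestion_freeze":
                sugg_frozen_at = suggested
            elif inj.kind == "egco2_out_of_range":
                egco2_forced = inj.value
            elif inj.kind == "patient_switch":
                status.faults.add(FaultKind.patient_switch)
            elif inj.kind == "blower_failure":
                blower_cfg = replace(blower_cfg, count_active=max(
                    blower_cfg.count_active - 1, 0))

        # Liquid loop: reservoir -> conditioning lung -> AL.
        liquid = LiquidState.from_content(scenario.liquid_flow, res.content,
                                          fluid, chem)
        cond = ex.ConditioningConfig(
            air_flow=2.0, co2_flow=co2_level,
            efficiency=plant.efficiency_conditioning)
        liquid_pre = ex.conditioning_pass(liquid, cond, plant.ambient_mmhg,
                                          chem)
        egco2_true, removal, liquid_post = ex.al_exchange(
            liquid_pre, flow_act, lung, plant.ambient_mmhg, plant.temp_k,
            chem)

        # Gas path to the sensor: plug-flow dead volume + side-stream lag.
        buffered = plug.push(flow_act, dt, egco2_true)
        at_sensor = latency.push(buffered)
        if math.isnan(at_sensor):
            at_sensor = buffered

        # 1 Hz CO2 sensor sample (with fault overrides).
        if t >= next_sample - eps:
            stream = ex.GasStream(flow=flow_act, pco2=max(at_sensor, 0.0),
                                  pressure=plant.ambient_mmhg)
            raw = hw.sense_egco2(stream, plant.ambient_mmhg, cal, sensor, rng)
            if egco2_forced is not None:
                raw = egco2_forced
            elif egco2_frozen_at is not None:
                raw = egco2_frozen_at
            sensed = raw
            next_sample += sensor.co2_sample_period
        assert sensed is not None

        # Outer loop + supervisor at the update period.
        if t >= next_ctrl - eps:
            if feedback:
                tau = ctrl_cfg.egco2_filter_s
                if tau > 0:
                    if eg_filt is None:
                        eg_filt = sensed
                    else:
                        eg_filt += ((sensed - eg_filt)
                                    * ctrl_cfg.update_period / tau)
                else:
                    eg_filt = sensed
                suggested, ctrl_state = pi_update(eg_filt, ctrl_cfg,
                                                  ctrl_state)
                if sugg_frozen_at is not None:
                    suggested = sugg_frozen_at
                h_t.append(t)
                h_sugg.append(suggested)
                h_eg.append(sensed)
                status = check_faults(
                    list(h_t), list(h_sugg), list(h_eg), status, sup_cfg,
                    clamp_bounds=(ctrl_cfg.min_sweep, ctrl_cfg.max_sweep))
                status = pressure_guard(
                    hw.inlet_pressure(flow_act, blower_cfg, lung,
                                      plant.ambient_mmhg),
                    plant.ambient_mmhg, status, sup_cfg, lung.gas_resistance)
                command, status = arbitrate(suggested, status, sup_cfg)
            else:
                command = fixed_sweep_command(ctrl_cfg)
            next_ctrl += ctrl_cfg.update_period

        # Inner flow loop on a smoothed noisy flow reading, every tick.
        reading = hw.read_flow(flow_act, sensor, rng)
        flow_ema += (reading - flow_ema) * dt / ema_tau
        duty, _sat = inner_flow_loop(command, flow_ema, duty, dt, ctrl_cfg,
                                     prev_command=prev_command)
        prev_command = command
        flow_act = hw.blower_flow(duty, blower_cfg, lung, dt, flow_act)

        # Reservoir mass balance with the returned liquid.
        res = ex.reservoir_step(res, liquid_post, dt, fluid, chem)

        if t >= next_rec - eps:
            if not all(map(math.isfinite,
                           (egco2_true, sensed, command, flow_act,
                            res.content))):
                raise RuntimeError(
                    f"non-finite state at t={t:.1f}s: egco2={egco2_true}, "
                    f"sensed={sensed}, cmd={command}, flow={flow_act}, "
                    f"reservoir={res.content}")
            records.append(TraceRecord(
                time_s=round(t, 6),
                egco2_true_mmHg=egco2_true,
                egco2_sensed_mmHg=sensed,
                sweep_cmd_lpm=command,
                sweep_act_lpm=flow_act,
                pco2_pre_mmHg=liquid_pre.pco2,
                pco2_post_mmHg=liquid_post.pco2,
                pco2_res_mmHg=res.pco2,
                mode=status.mode.value if feedback else "fixed_sweep",
                faults="|".join(sorted(f.value for f in status.faults)),
            ))
            next_rec += rec_period

    return RunResult(scenario=scenario, setup=setup, records=records)
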