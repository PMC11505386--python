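"""Actuator and sensor models.

Covers the twin centrifugal blowers feeding the AL through a check-valve
manifold, the noisy mass-flow sensor, the side-stream EGCO2 sensor with its
pressure normalization, transport delay and one-point calibration, and the
plug-flow buffer that delays the EGCO2 signal between the AL fibers and the
sensing chamber.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, asdict

import numpy as np

from .exchange import GasStream, LungConfig


@dataclass(frozen=True)
class BlowerConfig:
    """Blower pair modelled as a duty-proportional constant-pressure source.

    Steady flow into a series gas-path resistance is
    ``duty * max_pressure / (gas_resistance + internal_resistance/count_active)``.
    ``max_pressure`` is calibrated so both blowers at full duty drive
    7.0 L/min through the tall lung; with ``internal_resistance = 0`` the
    short lung (half the resistance) then reaches 14 L/min.
    """

    max_pressure: float = 70.0          # mmHg at 100% duty
    internal_resistance: float = 0.0    # mmHg per (L/min), shared by pair
    count_active: int = 2
    time_constant: float = 0.3          # s, first-order flow dynamics

    def __post_init__(self) -> None:
        if self.max_pressure <= 0 or self.time_constant <= 0:
            raise ValueError("max_pressure and time_constant must be > 0")
        if self.count_active not in (0, 1, 2):
            raise ValueError("count_active must be 0, 1 or 2")


def steady_flow(duty: float, cfg: BlowerConfig, lung: LungConfig) -> float:
    """Steady-state sweep flow (L/min) at the given blower duty."""
    if not 0 <= duty <= 1:
        raise ValueError("duty must be within [0, 1]")
    if cfg.count_active == 0:
        return 0.0
    r = lung.gas_resistance + cfg.internal_resistance / cfg.count_active
    return duty * cfg.max_pressure / r


def blower_flow(duty: float, cfg: BlowerConfig, lung: LungConfig,
                dt: float, prev_flow: float) -> float:
    """Advance the blower flow one step of ``dt`` seconds.

    First-order relaxation of the actual flow toward the steady-state flow
    at the commanded duty.
    """
    target = steady_flow(duty, cfg, lung)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = 1.0 - math.exp(-dt / cfg.time_constant)
    return prev_flow + (target - prev_flow) * a


def inlet_pressure(flow: float, cfg: BlowerConfig, lung: LungConfig,
                   ambient: float = 760.0) -> float:
    """Absolute gas pressure (mmHg) at the AL inlet for a given sweep flow."""
    return ambient + lung.gas_resistance * flow


@dataclass(frozen=True)
class SensorConfig:
    """Noise, error and timing model for the flow and CO2 sensors.

    The raw mass-flow readings are noisy (SD 0.25 L/min by default) but a
    10 s average at 100 Hz reduces the mean-estimate SD to
    ``0.25/sqrt(1000) ~ 0.008 L/min``.  The CO2 sensor reads a molar
    fraction that is normalized by the sensing-chamber pressure, carries a
    multiplicative gain error plus a small offset, updates at 1 Hz, and is
    fed through a side-stream path that adds a fixed latency on top of the
    flow-dependent plug-flow delay.
    """

    co2_noise_sd: float = 0.3        # mmHg
    co2_gain_error: float = 1.03     # dimensionless
    co2_offset_error: float = 0.1    # mmHg
    flow_noise_sd: float = 0.25      # L/min
    co2_sample_period: float = 1.0   # s
    flow_sample_rate: float = 100.0  # Hz
    latency_s: float = 1.0           # s, side-stream sampling-pump lag
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.co2_noise_sd, self.flow_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.co2_sample_period <= 0 or self.flow_sample_rate <= 0:
            raise ValueError("sample period/rate must be > 0")


def read_flow(true_flow: float, cfg: SensorConfig,
              rng: np.random.Generator) -> float:
    """One raw mass-flow-sensor reading: truth plus Gaussian noise."""
    if true_flow < 0:
        raise ValueError("true_flow must be >= 0")
    if cfg.flow_noise_sd == 0:
        return true_flow
    return true_flow + rng.normal(0.0, cfg.flow_noise_sd)


@dataclass
class CalibrationState:
    """Correction applied to the CO2 sensor after bench calibration."""

    gain_correction: float = 1.0
    offset_correction: float = 0.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.gain_correction <= 0:
            raise ValueError("gain_correction must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CalibrationState":
        return cls(**json.loads(s))


def sense_egco2(exhaust: GasStream, chamber_pressure: float,
                cal: CalibrationState, cfg: SensorConfig,
                rng: np.random.Generator | None = None) -> float:
    """One EGCO2 sensor reading (mmHg).

    The sensor reports a CO2 molar fraction; multiplying by the measured
    sensing-chamber pressure normalizes it back to a partial pressure.
    Gain error, offset and Gaussian noise act on the raw reading before
    the calibration correction is applied.  Clipped at zero.
    """
    if chamber_pressure <= 0:
        raise ValueError("chamber_pressure must be > 0")
    raw = cfg.co2_gain_error * exhaust.pco2 + cfg.co2_offset_error
    if cfg.co2_noise_sd > 0 and rng is not None:
        raw += rng.normal(0.0, cfg.co2_noise_sd)
    fraction = raw / exhaust.pressure
    reading = fraction * chamber_pressure
    if cal.calibrated:
        reading = cal.gain_correction * reading + cal.offset_correction
    return max(reading, 0.0)


def calibrate_one_point(observed: float, reference: float = 20.0
                        ) -> CalibrationState:
    """One-point calibration against a benchtop blood-gas analyzer.

    A pure multiplicative gain error is assumed (the default sensor error
    model is gain-dominated), so a single reference point at 20 mmHg fixes
    the correction ``gain = reference/observed``.
    """
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return CalibrationState(gain_correction=reference / observed,
                            offset_correction=0.0, calibrated=True)


def calibrate_two_point(observed_lo: float, observed_hi: float,
                        reference_lo: float, reference_hi: float
                        ) -> CalibrationState:
    """Two-point calibration correcting both gain and offset."""
    if observed_hi == observed_lo:
        raise ValueError("calibration points must differ")
    gain = (reference_hi - reference_lo) / (observed_hi - observed_lo)
    if gain <= 0:
        raise ValueError("calibration points must be monotone")
    offset = reference_lo - gain * observed_lo
    return CalibrationState(gain_correction=gain, offset_correction=offset,
                            calibrated=True)


def transport_delay(sweep: float, lung: LungConfig) -> float:
    """Gas transit time (s) from the AL fibers to the CO2 sensor.

    Plug flow through the dead volume: ``60 * dead_volume / sweep``.
    At the 0.25 L/min flow floor with the default 0.05 L dead volume this
    is 12 s, which is why the control loop slows at low sweep.  Zero sweep
    means the signal never arrives (infinite delay); the flow floor
    prevents that while the controller runs.
    """
    if sweep < 0:
        raise ValueError("sweep must be >= 0")
    if sweep == 0:
        return math.inf
    return 60.0 * lung.dead_volume / sweep


class PlugFlowBuffer:
    """Volume-tracked plug-flow delay line for the EGCO2 signal.

    Gas parcels are pushed in at the AL outlet; the sensor sees the parcel
    currently leaving the dead volume.  With constant sweep this reproduces
    a pure delay of ``transport_delay(sweep)`` to within one tick; with
    varying sweep the delay is flow-weighted, as in the physical duct.
    """

    def __init__(self, dead_volume: float):
        if dead_volume <= 0:
            raise ValueError("dead_volume must be > 0")
        self.dead_volume = dead_volume
        self._parcels: deque[list[float]] = deque()   # [volume_l, pco2]
        self._held = 0.0
        self._outlet: float | None = None

    def push(self, sweep: float, dt: float, pco2: float) -> float:
        """Advance by ``dt`` s at flow ``sweep`` L/min; return outlet pCO2."""
        if self._outlet is None:
            # Start with the dead volume filled with gas at the first value.
            self._parcels.append([self.dead_volume, pco2])
            self._held = self.dead_volume
            self._outlet = pco2
        vol = sweep * dt / 60.0
        if vol > 0:
            self._parcels.append([vol, pco2])
            self._held += vol
        expelled_vol = self._held - self.dead_volume
        if expelled_vol > 0:
            acc = 0.0
            acc_vol = 0.0
            while acc_vol < expelled_vol and self._parcels:
                head = self._parcels[0]
                take = min(head[0], expelled_vol - acc_vol)
                acc += take * head[1]
                acc_vol += take
                head[0] -= take
                if head[0] <= 1e-15:
                    self._parcels.popleft()
            self._held -= acc_vol
            if acc_vol > 0:
                self._outlet = acc / acc_vol
        return self._outlet


class DelayLine:
    """Fixed-latency buffer (the side-stream sampling-pump lag)."""

    def __init__(self, latency_s: float, dt: float, initial: float = 0.0):
        n = max(int(round(latency_s / dt)), 0)
        self._buf: deque[float] = deque([initial] * n, maxlen=max(n, 1))
        self._passthrough = n == 0

    def push(self, value: float) -> float:
        if self._passthrough:
            return value
        out = self._buf[0]
        self._buf.append(value)
        return out
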