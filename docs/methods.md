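# Methods

## Scope and model structure

`ecco2rsim` simulates a wearable ECCO₂R sweep-gas control system and the
closed water (or blood) test circuit used to characterize it. The
simulation advances a fixed-step explicit loop (default `dt = 0.1 s`):

1. liquid leaves the well-mixed reservoir at the pump flow;
2. the conditioning lung loads CO₂ toward its gas-side pCO₂;
3. the membrane lung (AL) removes CO₂ at the current sweep flow;
4. the exhaust-gas CO₂ signal travels through a plug-flow dead volume and
   a fixed side-stream latency to the CO₂ sensor (1 Hz updates);
5. once per second the outer controller (PI or fixed-sweep) emits a sweep
   suggestion, the supervisor arbitrates it, and the inner loop slews
   blower duty toward the commanded flow;
6. the returned liquid updates the reservoir mass balance.

All states and signals are logged at a configurable decimation (default
1 Hz) in a fixed-header CSV with a JSON config sidecar.

## Gas exchange

The AL gas side uses a one-parameter transfer-unit law,
`EGCO₂ = p_L·(1 − exp(−β/Q))`: full equilibration with the liquid inlet
pCO₂ at vanishing sweep, a widening gas–liquid gap as sweep grows, molar
removal `Q·EGCO₂·1000/(R·T)` strictly increasing in sweep. The exhaust can
never exceed the liquid inlet pCO₂ — the device only removes CO₂.

Per pass, removal is capped at the CO₂ the liquid actually carries in
(`Q_liquid · content`), with the effective EGCO₂ back-computed when the cap
binds; without this the gas-side law alone could violate liquid-side mass
conservation at high sweep and low liquid flow.

Carrier chemistry: water follows Henry's law, `c = α·pCO₂` with
`α = 0.03 mmol/(L·mmHg)` at 37 °C; whole blood uses an empirical power-law
total-content dissociation curve `c = k₁·pCO₂^k₂` (defaults `k₁ = 2.2`,
`k₂ = 0.40`, mmol/L with pCO₂ in mmHg), which reproduces the usual
physiological facts that blood carries far more CO₂ than water at equal
tension and that its curve flattens with rising pCO₂. Both are strictly
increasing, hence invertible; reservoir pCO₂ is always re-derived from
content so the two never disagree.

## Calibration of the plant

The device publishes its operating envelope, not its physical constants,
so two constants are calibrated to printed observations and the rest are
standard values:

* **Blower/lung**: a duty-proportional constant-pressure source
  (`70 mmHg` at full duty) into the tall lung's gas-side resistance
  (`10 mmHg/(L/min)`) gives the observed 7 L/min ceiling; the short lung
  has exactly half the resistance, hence 14 L/min. Blower internal
  resistance defaults to zero so that doubling is exact.
* **β (gas-side equilibration), default 0.8 L/min**, chosen jointly with
  the conditioning-lung efficiency (0.5 per pass) so that the full bench
  envelope is reproduced: the 20 mmHg target is achievable at every
  metabolic step within the sweep range, targets of 30 and 40 mmHg are
  unachievable at the lowest metabolic rate (sweep pinned at the floor
  with EGCO₂ below target), and the operating point at the flow floor is
  flat enough (`|dEGCO₂/dQ|`) for the outer loop to be stable there.
  Values of β below ~0.5 make the floor operating point so steep that the
  loop limit-cycles through the 12 s transport delay.

A consequence of the transfer-unit model with no liquid-side film
resistance: at the highest CO₂ challenge the AL strips nearly all CO₂ from
the water in one pass (post-AL pCO₂ approaches zero). Real exchangers have
a liquid boundary layer that prevents complete extraction; none is
modelled here, which mainly affects the post-AL liquid trace, not the
controlled EGCO₂.

## Controller

The outer loop is a velocity-form PI on the sensed EGCO₂ error
(`u ← clamp(u + k_p·Δe + k_i·T·e)`), updated at 1 Hz, clamped to
[0.25, 7.0] L/min. Velocity form makes the clamp itself the anti-windup
mechanism. Defaults `k_p = 0.02 (L/min)/mmHg`, `k_i = 0.008
(L/min)/(mmHg·s)` were calibrated on the reference scenario against three
requirements at once: settling < 1 min at every metabolic step, post-
settling regulation within ±5 mmHg, and no limit cycling at the flow
floor, where the plant gain and the transport delay are both at their
worst. A first-order filter (3 s time constant, configurable, 0 disables)
low-passes the sensed EGCO₂ before the PI law; without it the loop's
post-step ringing re-exits the ±5 mmHg band after the settling criterion
has been met. A derivative term exists only as a configuration stub.

The inner loop converts the flow command to blower duty with a calibrated
feedforward (duty per L/min from the source-pressure/resistance model)
plus a slow integral trim (`0.1 duty/(L/min·s)`) on a 0.5 s-smoothed flow
reading. The integral is gated off while the flow error exceeds
0.5 L/min, so it cannot wind up during the blower's own first-order
transient (τ = 0.3 s); a 0.25 → 4.0 L/min step enters and holds the
±0.1 L/min band in about 1 s. A pure-integral inner loop through the
measurement filter was tried first and rings (≈13° phase margin).

## Sensors, delays and calibration

* Flow sensor: Gaussian noise, SD 0.25 L/min per raw sample at a nominal
  100 Hz; a 10 s average therefore has SD 0.25/√1000 ≈ 0.0079 L/min.
* EGCO₂ sensor: reads a molar fraction, normalized by the sensing-chamber
  pressure; error model is a multiplicative gain (default +3%), a small
  offset (default +0.1 mmHg) and Gaussian noise (SD 0.3 mmHg) at 1 Hz.
  A one-point calibration against a reference analyzer at 20 mmHg
  corrects the gain (the dominant term); a two-point helper corrects gain
  and offset. Under the default error model the post-calibration error
  stays below 1 mmHg over 0–50 mmHg.
* The EGCO₂ signal is delayed by a volume-tracked plug-flow buffer
  (dead volume 0.05 L → 12 s at the 0.25 L/min floor, 1.5 s at 2 L/min)
  plus a fixed 1 s side-stream sampling latency.

## Supervisor

Fault heuristics: frozen suggestion (< 0.01 L/min variation over 30 s),
frozen EGCO₂ (< 0.1 mmHg over 60 s), out-of-range EGCO₂ (outside
1–100 mmHg) or suggestion, and a patient-operated switch. Detection
windows exceed the worst-case transport delay so a slow signal is not
mistaken for a dead one, and windows containing clamp-saturated samples
are exempt from freeze detection (a pinned command is legitimately
constant for minutes at an unachievable target). Any fault latches a
fixed-sweep fallback (default 1.0 L/min) until the faults clear *and* a
manual re-arm — the conservative reading of a safety fallback. A pressure
guard flags and caps sweep when the AL inlet exceeds ambient by more than
80 mmHg (just above the blower's own 70 mmHg capability, so it fires only
on anomalies such as an occluded gas path); the cap is
`limit/gas_resistance` under the linear pressure model. Overpressure caps
but does not force the fallback mode.

## Scenarios and metrics

`reference_scenarios()` encodes the bench protocol: conditioning CO₂
stepped 0.1/0.2/0.4/0.8 L/min at 4 min per level (up and back down, so
both overshoot and undershoot are exercised), water at 1.0 L/min with
targets 10–40 mmHg; fixed-sweep arms at 1.0 and 2.0 L/min; water flows
0.5–2.0 L/min at target 20 with the 0.8 level omitted; and a blood run
(levels 0.1/0.2/0.4, same β — no blood-specific exchange data exists to
refit it). Runs begin with a 5 min warm-up at the first level from a
reservoir initialized at 20 mmHg, so start-up transients do not
contaminate segment statistics.

Metric definitions: settling time runs from the first post-change
divergence of more than 5 mmHg from target until the first re-entry into
the ±5 mmHg band that is then sustained for 3 s; the settling interval
ends at band entry (the sustain is a qualification, not part of the
duration — the alternative is a one-line change). Never-diverging
segments settle in 0; never-re-entering ones are reported explicitly as
not settled rather than as a large number. Overshoot is the largest
absolute excursion in the transition window. Segment statistics drop the
first 120 s after each change; whole-run statistics include everything.
The settling operator is verified against an exhaustive O(n²) scan oracle
on 1000 random traces, and is stable to trace decimation (1 Hz vs 10 Hz)
to within one coarse tick.

## What the synthetic circuit does and does not show

The circuit emulates the bench study: stepped, instantaneous metabolic
changes into a large well-mixed reservoir. Real patients change CO₂
production gradually, blood recirculates in 10–120 s rather than ~19 min,
and EGCO₂ underestimates post-AL blood pCO₂ increasingly as sweep rises
— so passing tests demonstrate the controller's behavior against this
circuit's dynamics, not clinical performance. Sensor error magnitudes,
conditioning-lung efficiency and the blower pressure–flow curve are
plausible stand-ins for unpublished hardware characteristics; all are
exposed in configuration.

## Numerical choices

Explicit Euler at `dt = 0.1 s`; a 100× finer step moves the final
reservoir inventory of a representative run by well under 0.5%. All
randomness flows from one `numpy` generator seeded per scenario, so equal
seeds give bit-identical traces. Temperature is fixed at 310 K and
ambient pressure at 760 mmHg (both configurable); gas volumes are treated
as incompressible at ambient pressure on the sensor path. Simulation
sizes throughout (4 min per metabolic level, 10-minute floor-drive run,
2000 Monte-Carlo windows for the sensor-amortization estimate) match the
bench protocol's own durations.
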