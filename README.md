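# ecco2rsim

A desk-scale simulator of a wearable **extracorporeal CO₂ removal (ECCO₂R)**
system with closed-loop sweep-gas control, together with the in vitro water
circuit used to characterize such a controller on the bench.

## The problem

ECCO₂R supports patients in respiratory failure by clearing CO₂ from blood
through a membrane ("artificial") lung. CO₂ removal is a strong function of
the *sweep gas* flow through the lung's gas side, but a patient's metabolic
CO₂ production changes with activity and disease state — a fixed sweep flow
(the clinical standard of care) over- or under-removes CO₂ as metabolism
changes. Since no long-term blood-contacting CO₂ sensor exists, the exhaust
gas CO₂ partial pressure (**EGCO₂**) at the lung outlet is used as a
surrogate for blood pCO₂ and regulated to a prescribed target (tEGCO₂) by a
negative-feedback loop: EGCO₂ above target → more sweep → more removal, and
vice versa.

This package is for control and biomedical engineers who want to
stress-test that control architecture — gains, fault handling, sensor
noise, transport delays — without a benchtop circuit. It simulates the full
loop and reports the same outcome metrics a bench study would: settling
time after a simulated metabolic step, overshoot, and steady-state spread.

## The model

The gas side of the membrane lung is a single-transfer-unit equilibration
law. With liquid inlet pCO₂ `p_L` (mmHg) and sweep flow `Q` (L/min),

    EGCO₂ = p_L · (1 − exp(−β/Q))

so the exhaust equilibrates with the liquid as `Q → 0` and the gas–liquid
gap widens as `Q` grows; molar removal `Q·EGCO₂/(R·T)` still rises
monotonically with `Q`. The test circuit closes a mass balance around a
well-mixed reservoir (5 US gal of water, Henry's-law CO₂ content
`c = α·pCO₂`; an empirical power-law dissociation curve for whole blood), a
conditioning lung that loads CO₂ from a stepped air/CO₂ mixture to emulate
metabolism, and the membrane lung. Hardware models include the twin-blower
constant-pressure source (7 L/min ceiling into the tall lung, 14 L/min with
the half-resistance short lung), a noisy mass-flow sensor (SD 0.25 L/min
raw, 0.008 L/min amortized over 10 s), a side-stream EGCO₂ sensor with
pressure normalization, one-point calibration at 20 mmHg, and a plug-flow
transport delay (12 s at the 0.25 L/min flow floor).

Control is two-loop: an inner loop drives blower duty to a commanded flow
(feedforward + integral trim), and an outer velocity-form PI converts the
EGCO₂ error into the next sweep command, clamped to [0.25, 7] L/min — the
floor keeps gas moving past the sensor, and clamping doubles as anti-windup.
A supervisor validates the "suggested" sweep, detects frozen or out-of-range
exhaust-module outputs, and latches into a fixed-sweep fallback.

See `docs/methods.md` for assumptions, calibration and limitations.

## Worked example

Run the reference experiment — water at 1.0 L/min, target EGCO₂ 20 mmHg,
conditioning CO₂ stepped 0.1 → 0.2 → 0.4 → 0.8 → 0.4 → 0.2 → 0.1 L/min at
4 min per level:

```sh
$ ecco2rsim run --scenario target_20 --seed 1 --out runs
settling (min): [0.12, 0.1, 0.15, 0.2, 0.15, 0.18]
whole-run EGCO2: mean 19.96 mmHg, SD 1.85 mmHg
trace written to runs/target_20_seed1.csv
```

Each of the six metabolic transitions settles (re-enters and holds the
±5 mmHg band after diverging) in well under a minute, and the whole-run
mean sits on the 20 mmHg target. The same challenge under the standard of
care, `ecco2rsim run --scenario fixed_1.0 --seed 1`, gives mean 27.10 mmHg
with SD 15.92 mmHg — the fixed sweep lets EGCO₂ swing freely with the
simulated metabolism, which is precisely what the feedback loop suppresses.

The output directory also holds a JSON metrics report, a dual-panel
EGCO₂/sweep figure, and a config sidecar sufficient to reproduce the run
bit-for-bit. `ecco2rsim list-scenarios` shows the other scenarios (targets
10–40 mmHg, water flows 0.5–2.0 L/min, fixed-sweep arms, a blood run), and
`ecco2rsim metrics <trace.csv> --target 20 --changes 300,540` scores
externally produced traces with the same definitions.

As a library:

```python
from ecco2rsim import reference_scenarios, run, segment_stats

res = run(reference_scenarios(seed=1)["target_20"])
rep = segment_stats(res.frame(), res.change_times, target=20.0)
print(rep.settling_min, rep.whole_run.sd)
```

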