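"""Lumped-parameter physics of the CO2 test circuit.

The in vitro circuit is a closed liquid loop: a well-mixed reservoir feeds a
pump, the liquid is CO2-loaded by a conditioning lung (an oxygenator run in
reverse, fed an air/CO2 mixture to emulate patient metabolism), CO2 is then
stripped by the artificial membrane lung (AL) whose gas side is swept with
room air, and the liquid returns to the reservoir.

The AL gas side is modelled with a single-transfer-unit equilibration law:
the exhaust-gas CO2 partial pressure (EGCO2) approaches the liquid inlet
pCO2 as the residence time grows,

    EGCO2 = pL_in * (1 - exp(-beta / Q_sweep)),

with ``beta`` (L/min) the one calibrated gas-side parameter.  This captures
the physics that matters for sweep-gas control: full equilibration at low
sweep, a widening gas/liquid gap at high sweep, and CO2 removal that rises
monotonically with sweep flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

#: Ideal-gas constant in circuit units, L*mmHg/(mol*K).
R_MMHG_L = 62.36367


class Fluid(str, Enum):
    """Carrier fluid in the liquid loop."""

    water = "water"
    blood = "blood"


@dataclass(frozen=True)
class CarrierChemistry:
    """CO2 carrying capacity of the liquid phase.

    Water carries CO2 as a physically dissolved gas (Henry's law),
    ``content = alpha_water * pCO2``.  Blood additionally carries CO2 as
    bicarbonate and carbamino compounds; over the physiological range the
    total-content dissociation curve is well approximated by a power law
    ``content = k1 * pCO2 ** k2``.  Both forms are strictly increasing and
    therefore invertible.

    Parameters
    ----------
    alpha_water : CO2 solubility in water at 37 C, mmol/(L*mmHg).
    blood_k1, blood_k2 : power-law dissociation coefficients for whole
        blood (mmol/L when pCO2 is in mmHg).
    """

    alpha_water: float = 0.03
    blood_k1: float = 2.2
    blood_k2: float = 0.40

    def content(self, fluid: Fluid, pco2: float) -> float:
        """CO2 content (mmol/L) of the fluid at partial pressure ``pco2``."""
        if pco2 < 0:
            raise ValueError(f"pco2 must be >= 0, got {pco2}")
        if Fluid(fluid) is Fluid.water:
            return self.alpha_water * pco2
        return self.blood_k1 * pco2 ** self.blood_k2

    def pco2(self, fluid: Fluid, content: float) -> float:
        """Invert the dissociation curve: partial pressure at ``content``."""
        if content < 0:
            raise ValueError(f"content must be >= 0, got {content}")
        if Fluid(fluid) is Fluid.water:
            return content / self.alpha_water
        return (content / self.blood_k1) ** (1.0 / self.blood_k2)


def content_curve(fluid: Fluid, pco2: float,
                  chem: CarrierChemistry | None = None) -> float:
    """CO2 content (mmol/L) of ``fluid`` at ``pco2`` (mmHg)."""
    return (chem or CarrierChemistry()).content(fluid, pco2)


@dataclass
class LiquidState:
    """Carrier-fluid state at a point in the liquid loop.

    ``content`` and ``pco2`` are kept consistent through the dissociation
    curve; construct via :meth:`from_pco2` or :meth:`from_content`.
    """

    flow: float           # L/min
    pco2: float           # mmHg
    content: float        # mmol/L
    fluid: Fluid = Fluid.water

    @classmethod
    def from_pco2(cls, flow: float, pco2: float, fluid: Fluid = Fluid.water,
                  chem: CarrierChemistry | None = None) -> "LiquidState":
        chem = chem or CarrierChemistry()
        return cls(flow=flow, pco2=pco2, content=chem.content(fluid, pco2),
                   fluid=Fluid(fluid))

    @classmethod
    def from_content(cls, flow: float, content: float,
                     fluid: Fluid = Fluid.water,
                     chem: CarrierChemistry | None = None) -> "LiquidState":
        chem = chem or CarrierChemistry()
        return cls(flow=flow, pco2=chem.pco2(fluid, content), content=content,
                   fluid=Fluid(fluid))


@dataclass
class GasStream:
    """Sweep/exhaust gas state: flow (L/min), pCO2 and total pressure (mmHg)."""

    flow: float
    pco2: float
    pressure: float = 760.0

    def __post_init__(self) -> None:
        if self.flow < 0:
            raise ValueError("gas flow must be >= 0")
        if not 0 <= self.pco2 <= self.pressure:
            raise ValueError("require 0 <= pco2 <= total pressure")


@dataclass(frozen=True)
class LungConfig:
    """Gas-side description of one membrane-lung variant.

    The short lung has half the gas-side resistance of the tall lung, which
    doubles the attainable sweep flow for the same blower pressure.

    Parameters
    ----------
    gas_resistance : pressure drop per unit sweep flow, mmHg/(L/min).
    beta : gas-side equilibration parameter of the transfer-unit model, L/min.
    dead_volume : gas-path volume from the AL fibers to the CO2 sensor, L.
        Sets the plug-flow transport delay of the EGCO2 signal.
    """

    variant: str = "tall"
    gas_resistance: float = 10.0
    beta: float = 0.8
    dead_volume: float = 0.05

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.dead_volume <= 0 or self.gas_resistance <= 0:
            raise ValueError("beta, dead_volume, gas_resistance must be > 0")


def tall_lung(**kw) -> LungConfig:
    return LungConfig(variant="tall", **kw)


def short_lung(**kw) -> LungConfig:
    """Short lung variant: half the gas-side resistance of the tall lung."""
    kw.setdefault("gas_resistance", 5.0)
    return LungConfig(variant="short", **kw)


@dataclass
class ReservoirState:
    """Well-mixed liquid reservoir (default 5 US gallons = 18.93 L)."""

    volume: float = 18.93     # L
    content: float = 0.6      # mmol/L
    pco2: float = 20.0        # mmHg, consistent with content

    @classmethod
    def from_pco2(cls, pco2: float, volume: float = 18.93,
                  fluid: Fluid = Fluid.water,
                  chem: CarrierChemistry | None = None) -> "ReservoirState":
        chem = chem or CarrierChemistry()
        return cls(volume=volume, content=chem.content(fluid, pco2), pco2=pco2)


@dataclass(frozen=True)
class ConditioningConfig:
    """Gas feed to the conditioning lung that loads CO2 into the liquid.

    ``efficiency`` is the fraction of the gas-liquid pCO2 gap closed per
    liquid pass; the loader only adds CO2 (no stripping when the gas side
    is leaner than the liquid).
    """

    air_flow: float = 2.0      # L/min
    co2_flow: float = 0.1      # L/min, scenario-controlled
    efficiency: float = 0.5    # dimensionless, 0-1

    def __post_init__(self) -> None:
        if self.air_flow <= 0 or self.co2_flow < 0:
            raise ValueError("air_flow must be > 0 and co2_flow >= 0")
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")


def egco2_of_sweep(pl_in: float, sweep: float, lung: LungConfig) -> float:
    """Exhaust-gas pCO2 (mmHg) for liquid inlet pCO2 ``pl_in`` at ``sweep``.

    Single-transfer-unit model ``pl_in * (1 - exp(-beta/sweep))``; tends to
    the full-equilibration limit ``pl_in`` as sweep -> 0+, decreases
    strictly with sweep, and never exceeds ``pl_in`` (the device removes
    CO2, it cannot add it).
    """
    if pl_in < 0 or sweep < 0:
        raise ValueError("pl_in and sweep must be >= 0")
    if sweep == 0:
        return pl_in
    return pl_in * (1.0 - math.exp(-lung.beta / sweep))


def removal_rate(egco2: float, sweep: float, pressure: float = 760.0,
                 temp: float = 310.0) -> float:
    """Molar CO2 carried out of the AL gas side, mmol/min.

    Ideal gas: the sweep carries a CO2 volumetric flow
    ``sweep * egco2 / pressure`` at total pressure ``pressure``, i.e. a
    partial-pressure flow ``sweep * egco2``; moles follow from pV = nRT
    (the total pressure cancels).
    """
    if egco2 < 0 or sweep < 0:
        raise ValueError("egco2 and sweep must be >= 0")
    if pressure <= 0:
        raise ValueError("pressure must be > 0")
    if temp <= 0:
        raise ValueError("temp must be > 0")
    return sweep * egco2 * 1000.0 / (R_MMHG_L * temp)


def conditioning_inlet_pco2(cfg: ConditioningConfig,
                            pressure: float = 760.0) -> float:
    """Gas-side pCO2 (mmHg) fed to the conditioning lung.

    Mole-fraction mixing of pure CO2 into air; the ~0.04% CO2 already in
    air is neglected.
    """
    total = cfg.air_flow + cfg.co2_flow
    if total <= 0:
        raise ValueError("air_flow + co2_flow must be > 0")
    return pressure * cfg.co2_flow / total


def conditioning_pass(liquid: LiquidState, cfg: ConditioningConfig,
                      pressure: float = 760.0,
                      chem: CarrierChemistry | None = None) -> LiquidState:
    """One liquid pass through the conditioning lung.

    The outlet pCO2 relaxes toward the gas-side pCO2 by ``cfg.efficiency``
    of the gap; the loader only adds CO2 (no change when the gas side is
    not richer than the liquid).
    """
    chem = chem or CarrierChemistry()
    gas_pco2 = conditioning_inlet_pco2(cfg, pressure)
    if gas_pco2 <= liquid.pco2:
        return replace(liquid)
    out_pco2 = liquid.pco2 + cfg.efficiency * (gas_pco2 - liquid.pco2)
    return LiquidState.from_pco2(liquid.flow, out_pco2, liquid.fluid, chem)


def al_exchange(liquid: LiquidState, sweep: float, lung: LungConfig,
                pressure: float = 760.0, temp: float = 310.0,
                chem: CarrierChemistry | None = None
                ) -> tuple[float, float, LiquidState]:
    """CO2 removal across the AL for one liquid pass.

    Returns ``(egco2, removal_mmol_min, liquid_out)``.  The gas-side model
    sets the requested removal; it is capped at the CO2 the liquid actually
    carries in (``flow * content``) so the post-AL content can never go
    negative, and the effective EGCO2 is back-computed when the cap binds.
    """
    chem = chem or CarrierChemistry()
    egco2 = egco2_of_sweep(liquid.pco2, sweep, lung)
    removal = removal_rate(egco2, sweep, pressure, temp)
    available = liquid.flow * liquid.content
    if removal > available:
        removal = available
        egco2 = (removal * R_MMHG_L * temp / (1000.0 * sweep)
                 if sweep > 0 else liquid.pco2)
    if liquid.flow > 0:
        out_content = liquid.content - removal / liquid.flow
    else:
        out_content = liquid.content
    out = LiquidState.from_content(liquid.flow, max(out_content, 0.0),
                                   liquid.fluid, chem)
    return egco2, removal, out


def reservoir_step(res: ReservoirState, return_liquid: LiquidState,
                   dt: float, fluid: Fluid = Fluid.water,
                   chem: CarrierChemistry | None = None) -> ReservoirState:
    """Advance the well-mixed reservoir by ``dt`` seconds.

    Explicit Euler on the compartment balance
    ``d(content)/dt = (flow/volume) * (content_return - content)``;
    ``pco2`` is re-derived by inverting the dissociation curve so the two
    fields never disagree.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    chem = chem or CarrierChemistry()
    new_content = res.content + (return_liquid.flow / res.volume) * (
        return_liquid.content - res.content) * (dt / 60.0)
    new_content = max(new_content, 0.0)
    return ReservoirState(volume=res.volume, content=new_content,
                          pco2=chem.pco2(fluid, new_content))
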