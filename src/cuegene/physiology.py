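"""Culture physiology: growth rate, respiration, metabolic quotient and CUE.

Converts per-sample culture measurements (inoculum and harvest dry mass,
culture duration, CO2 accumulation in a closed sampling loop) into the
carbon fluxes of interest:

* relative growth rate  mu = ln(Bt/B0)/t  (day^-1), assuming exponential
  growth over the culture period;
* respiration rate (mmol C/day) from the ppm rise in a closed loop of
  known volume via the ideal gas law;
* metabolic quotient qCO2 = respiration / biomass carbon (day^-1);
* carbon-use efficiency CUE = mu / (mu + qCO2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "PhysioConstants",
    "PhenotypeRecord",
    "FluxRecord",
    "NEGATIVE_GROWTH",
    "ZERO_BIOMASS",
    "relative_growth_rate",
    "co2_to_respiration",
    "biomass_carbon",
    "metabolic_quotient",
    "carbon_use_efficiency",
    "compute_fluxes",
]

#: QC flag: harvest mass at or below inoculum mass, so mu <= 0.
NEGATIVE_GROWTH = "NEGATIVE_GROWTH"
#: QC flag: zero harvested biomass, metabolic quotient undefined.
ZERO_BIOMASS = "ZERO_BIOMASS"

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class PhysioConstants:
    """Physical constants and measurement-system geometry.

    Defaults describe a 274 cm^3 closed sampling loop read over 2.5 min at
    20 degC and 1 atm, and a mycelial carbon content of 0.43 g C per g dry
    mass.  All values may be overridden, e.g. from a pipeline config.

    Attributes
    ----------
    carbon_fraction : g carbon per g dry mass, in (0, 1].
    molar_mass_C : g/mol.
    gas_constant : J/(mol K).
    temperature : K.
    pressure : Pa.
    loop_volume_cm3 : closed-loop volume, cm^3.
    measurement_duration_min : CO2 accumulation window, minutes.
    """

    carbon_fraction: float = 0.43
    molar_mass_C: float = 12.011
    gas_constant: float = 8.314462
    temperature: float = 293.15
    pressure: float = 101325.0
    loop_volume_cm3: float = 274.0
    measurement_duration_min: float = 2.5

    def __post_init__(self) -> None:
        for name in (
            "carbon_fraction",
            "molar_mass_C",
            "gas_constant",
            "temperature",
            "pressure",
            "loop_volume_cm3",
            "measurement_duration_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.carbon_fraction > 1:
            raise ValueError("carbon_fraction must lie in (0, 1]")

    @property
    def loop_moles(self) -> float:
        """Moles of gas in the sampling loop, n = PV/RT (V in m^3)."""
        volume_m3 = self.loop_volume_cm3 * 1e-6
        return self.pressure * volume_m3 / (self.gas_constant * self.temperature)


@dataclass(frozen=True)
class PhenotypeRecord:
    """Raw per-sample culture measurements.

    B0 and Bt are dry masses in mg, t the culture duration in days, and
    delta_co2 the ppm rise over the loop measurement window.
    """

    sample_id: str
    B0: float
    Bt: float
    t: float
    delta_co2: float

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError(f"{self.sample_id}: B0 must be > 0")
        if self.Bt < 0:
            raise ValueError(f"{self.sample_id}: Bt must be >= 0")
        if self.t <= 0:
            raise ValueError(f"{self.sample_id}: t must be > 0")
        if self.delta_co2 < 0:
            raise ValueError(f"{self.sample_id}: delta_co2 must be >= 0")


@dataclass(frozen=True)
class FluxRecord:
    """Derived fluxes for one sample, with QC flags.

    mu is day^-1, respiration mmol C/day, biomass_c mmol C at harvest,
    qco2 day^-1 and cue dimensionless.  qco2/cue are NaN when undefined
    (flagged).  Samples flagged NEGATIVE_GROWTH are excluded from marker
    fitting by default but still reported.
    """

    sample_id: str
    mu: float
    respiration: float
    biomass_c: float
    qco2: float
    cue: float
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def usable(self) -> bool:
        """True when the record carries no QC flags."""
        return not self.qc_flags


def relative_growth_rate(B0: float, Bt: float, t: float) -> float:
    """Specific growth rate ln(Bt/B0)/t in day^-1 under exponential growth."""
    if B0 <= 0:
        raise ValueError("B0 must be > 0")
    if Bt <= 0:
        raise ValueError("Bt must be > 0")
    if t <= 0:
        raise ValueError("t must be > 0")
    return math.log(Bt / B0) / t


def co2_to_respiration(delta_ppm: float, constants: PhysioConstants | None = None) -> float:
    """Convert a ppm CO2 rise in the closed loop to mmol C/day.

    The loop holds n = PV/RT moles of gas; a rise of delta_ppm over the
    measurement window corresponds to delta_ppm * 1e-6 * n moles of CO2
    (one C each), scaled to a daily rate and expressed in mmol.
    """
    if delta_ppm < 0:
        raise ValueError("delta_ppm must be >= 0")
    c = constants or PhysioConstants()
    mol_co2 = delta_ppm * 1e-6 * c.loop_moles
    per_day = MINUTES_PER_DAY / c.measurement_duration_min
    return mol_co2 * per_day * 1e3


def biomass_carbon(dry_mass_mg: float, constants: PhysioConstants | None = None) -> float:
    """Carbon content of dry mycelium in mmol C (mg dry mass input)."""
    if dry_mass_mg < 0:
        raise ValueError("dry_mass_mg must be >= 0")
    c = constants or PhysioConstants()
    return dry_mass_mg * c.carbon_fraction / c.molar_mass_C


def metabolic_quotient(respiration: float, biomass_c: float) -> float:
    """qCO2 = respiration rate per unit biomass carbon, day^-1."""
    if biomass_c <= 0:
        raise ValueError("biomass_c must be > 0")
    return respiration / biomass_c


def carbon_use_efficiency(mu: float, qco2: float) -> float:
    """CUE = mu / (mu + qCO2); in (0, 1) when both rates are positive."""
    denom = mu + qco2
    if denom == 0:
        raise ValueError("mu + qco2 must be nonzero")
    return mu / denom


def compute_fluxes(
    records: Iterable[PhenotypeRecord],
    constants: PhysioConstants | None = None,
) -> list[FluxRecord]:
    """Derive one FluxRecord per phenotype record, flagging QC failures.

    Per-record problems become flags rather than aborting the batch:
    mu <= 0 -> NEGATIVE_GROWTH, zero harvest mass -> ZERO_BIOMASS (with
    NaN qCO2 and CUE).
    """
    c = constants or PhysioConstants()
    records = list(records)
    if not records:
        raise ValueError("records must be nonempty")
    out: list[FluxRecord] = []
    for rec in records:
        flags: set[str] = set()
        resp = co2_to_respiration(rec.delta_co2, c)
        bc = biomass_carbon(rec.Bt, c)
        if rec.Bt <= 0:
            flags.add(ZERO_BIOMASS)
            mu = float("nan")
            qco2 = float("nan")
            cue = float("nan")
        else:
            mu = relative_growth_rate(rec.B0, rec.Bt, rec.t)
            qco2 = metabolic_quotient(resp, bc)
            if mu <= 0:
                flags.add(NEGATIVE_GROWTH)
            cue = carbon_use_efficiency(mu, qco2) if (mu + qco2) != 0 else float("nan")
        out.append(
            FluxRecord(
                sample_id=rec.sample_id,
                mu=mu,
                respiration=resp,
                biomass_c=bc,
                qco2=qco2,
                cue=cue,
                qc_flags=frozenset(flags),
            )
        )
    return out
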