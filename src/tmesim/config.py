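"""Aggregate parameter set and simulation configuration.

All model constants are collected in :class:`ParameterSet`, one dataclass
block per subsystem, serializable to/from JSON so every run can echo its
full configuration.  The numeric defaults form a self-consistent,
normalized placeholder parameter set (characteristic concentrations = 1);
see docs/methods.md for the reasoning behind each value.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

from .angiogenesis import (
    AdaptationParams,
    ComplianceParams,
    DisruptionParams,
    LumenParams,
    SproutingParams,
)
from .biochem import CRParams, GrowthFactorParams
from .grid import ConfigurationError, LatticeSpec, stability_dt
from .hemodynamics import FluidParams
from .tumor_cells import MotilityParams, PhenotypeParams, SolidStressParams


@dataclass
class ParameterSet:
    """Every model constant, grouped by subsystem."""

    cr: CRParams = field(default_factory=CRParams)
    gf: GrowthFactorParams = field(default_factory=GrowthFactorParams)
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    stress: SolidStressParams = field(default_factory=SolidStressParams)
    motility: MotilityParams = field(default_factory=MotilityParams)
    lumen: LumenParams = field(default_factory=LumenParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    compliance: ComplianceParams = field(default_factory=ComplianceParams)
    disruption: DisruptionParams = field(default_factory=DisruptionParams)
    sprouting: SproutingParams = field(default_factory=SproutingParams)
    fluid: FluidParams = field(default_factory=FluidParams)
    d_primary: float = 30.0   # primary-ring vessel diameter, um

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            **{
                f.name: dataclasses.replace(getattr(self, f.name))
                if dataclasses.is_dataclass(getattr(self, f.name))
                else getattr(self, f.name)
                for f in fields(self)
            }
        )

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        kwargs = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            typ = f.default_factory if f.default_factory is not dataclasses.MISSING else None
            if typ is not None and isinstance(v, dict):
                kwargs[f.name] = typ().__class__(**v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the full parameter set (recorded in every report)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScenarioSpec:
    """Pathophysiology scenario as multipliers on the baseline parameters.

    Blood-chemistry abnormalities scale the perfusion rate constants;
    hypo-/hypertension replaces the inlet pressure; desmoplasia scales the
    interstitial hydraulic conductivity.
    """

    label: str = "normal"
    glucose_perfusion_mult: float = 1.0
    oxygen_perfusion_mult: float = 1.0
    co2_perfusion_mult: float = 1.0
    inlet_pressure: float | None = None   # mmHg; None keeps the baseline
    K_ins_mult: float = 1.0

    def __post_init__(self) -> None:
        for m in (self.glucose_perfusion_mult, self.oxygen_perfusion_mult,
                  self.co2_perfusion_mult, self.K_ins_mult):
            if m <= 0:
                raise ConfigurationError("scenario multipliers must be positive")


#: named presets mirroring the blood-abnormality study conditions
SCENARIO_PRESETS: dict[str, ScenarioSpec] = {
    "normal": ScenarioSpec(label="normal"),
    "hyperglycemia": ScenarioSpec(label="hyperglycemia", glucose_perfusion_mult=2.0),
    "hypoglycemia": ScenarioSpec(label="hypoglycemia", glucose_perfusion_mult=0.5),
    "hyperoxemia": ScenarioSpec(label="hyperoxemia", oxygen_perfusion_mult=2.0),
    "hypoxemia": ScenarioSpec(label="hypoxemia", oxygen_perfusion_mult=0.5),
    # hyper-/hypocarbia alter CO2 *clearance* into blood: hypercarbia halves it
    "hypercarbia": ScenarioSpec(label="hypercarbia", co2_perfusion_mult=0.5),
    "hypocarbia": ScenarioSpec(label="hypocarbia", co2_perfusion_mult=2.0),
    "hypertension": ScenarioSpec(label="hypertension", inlet_pressure=40.0),
    "hypotension": ScenarioSpec(label="hypotension", inlet_pressure=20.0),
    "low_ihc": ScenarioSpec(label="low_ihc", K_ins_mult=0.5),
    "high_ihc": ScenarioSpec(label="high_ihc", K_ins_mult=2.0),
}


def apply_scenario(params: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Return a new parameter set with the scenario multipliers applied.

    Pure function: the input is untouched, and applying the identity
    scenario returns an equal copy.
    """
    out = params.copy()
    out.cr.f_g *= spec.glucose_perfusion_mult
    out.cr.f_o2 *= spec.oxygen_perfusion_mult
    out.cr.f_co2 *= spec.co2_perfusion_mult
    if spec.inlet_pressure is not None:
        out.fluid.p_inlet = spec.inlet_pressure
    out.fluid.K_ins *= spec.K_ins_mult
    return out


@dataclass
class SimulationConfig:
    """Run configuration: geometry, time hierarchy, parameters, scenario."""

    lattice: LatticeSpec
    t_end_days: float
    dt_transport: float = 60.0      # s, soluble-species substep
    dt_cell: float = 600.0          # s, agent macro step
    dt_remodel: float = 3600.0      # s, flow/remodeling step
    seed: int = 0
    parameters: ParameterSet = field(default_factory=ParameterSet)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    snapshot_every: float = 3600.0  # s
    output_dir: str | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        for big, small, label in (
            (self.dt_cell, self.dt_transport, "dt_cell/dt_transport"),
            (self.dt_remodel, self.dt_cell, "dt_remodel/dt_cell"),
        ):
            ratio = big / small
            if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
                raise ConfigurationError(f"{label} must be a positive integer ({ratio})")
        self.validate_stability()

    def validate_stability(self) -> None:
        p = self.parameters
        h = self.lattice.h
        diffusivities = {
            "oxygen": p.cr.D_o2, "glucose": p.cr.D_g, "co2": p.cr.D_co2,
            "vegf": p.gf.D_v, "ang1": p.gf.D_a1, "ang2": p.gf.D_a2, "mmp": p.gf.D_m,
        }
        for name, D in diffusivities.items():
            bound = stability_dt(D, h)
            if self.dt_transport > bound * (1 + 1e-12):
                raise ConfigurationError(
                    f"dt_transport={self.dt_transport:g}s exceeds stability bound "
                    f"{bound:g}s for species {name!r}"
                )
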