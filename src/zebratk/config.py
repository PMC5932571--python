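"""Schema-validated analysis configuration (JSON in, strict keys)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from .core_units import Compound, micromolar_to_mg_per_l
from .tk_multicomp import BodyComposition, MultiCompartmentParams
from .tk_onecomp import ExposureScenario

__all__ = ["AnalysisConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CompoundConfig(_Strict):
    name: str = "mCPP"
    molecular_weight: float = 196.68
    log_p: float = 2.06
    p_ka: float = 8.87

    def build(self) -> Compound:
        return Compound(self.name, self.molecular_weight, self.log_p, self.p_ka)


class ScenarioConfig(_Strict):
    water_conc_um: float = 5.0
    t_uptake_h: float = 8.0
    t_depuration_h: float = 48.0

    def build(self, compound: Compound) -> ExposureScenario:
        return ExposureScenario(
            c_w=micromolar_to_mg_per_l(self.water_conc_um, compound),
            t_uptake=self.t_uptake_h,
            t_depuration=self.t_depuration_h,
        )


class BodyConfig(_Strict):
    larva_weight_ug: float = 360.0
    eye_mass_fraction: float = 0.10

    def build(self) -> BodyComposition:
        return BodyComposition.from_fraction(
            self.larva_weight_ug * 1e-9, self.eye_mass_fraction
        )


class GeneratorConfig(_Strict):
    """True rates used when the pipeline synthesizes its own data."""

    k_in_eyes: float = 325.0
    k_out_eyes: float = 0.05
    k_in_rest: float = 143.2
    k_out_rest: float = 0.8
    n_replicates: int = Field(default=16, ge=1)

    def build(self) -> MultiCompartmentParams:
        return MultiCompartmentParams(
            k_in_eyes=self.k_in_eyes,
            k_out_eyes=self.k_out_eyes,
            k_in_rest=self.k_in_rest,
            k_out_rest=self.k_out_rest,
        )


class NoiseConfig(_Strict):
    kind: Literal["multiplicative-lognormal", "additive-normal"] = (
        "multiplicative-lognormal"
    )
    cv: float = Field(default=0.06, ge=0)
    seed: int = 0


class PassiveConfig(_Strict):
    lipid_fraction: float = 0.05
    body_weight_kg: float = 3.6e-7
    water_temperature_c: float = 28.0
    dissolved_oxygen_mg_per_l: float | None = None
    ph: float | None = None


class AnalysisConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected."""

    compound: CompoundConfig = CompoundConfig()
    scenario: ScenarioConfig = ScenarioConfig()
    body: BodyConfig = BodyConfig()
    generator: GeneratorConfig = GeneratorConfig()
    noise: NoiseConfig = NoiseConfig()
    passive: PassiveConfig = PassiveConfig()
    models: list[Literal["one_compartment", "multi_compartment"]] = Field(
        default_factory=lambda: ["one_compartment", "multi_compartment"]
    )
    timecourse_csv: str | None = None
    reference_pigmentation: str = "WT"


def load_config(path) -> AnalysisConfig:
    with open(Path(path)) as fh:
        raw = json.load(fh)
    return AnalysisConfig.model_validate(raw)
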