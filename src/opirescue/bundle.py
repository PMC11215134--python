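"""Loading and validation of the declarative parameter bundle.

The bundle is a YAML file with one block per drug/route for PK, one block
per drug for receptor binding, the physiological constants, the population
presets, and the nalmefene<-naloxone scaling ratios.  Every block carries
provenance strings; the default bundle shipped with the package mixes
published estimates with clearly labelled synthetic stand-ins (see the file
header and ``docs/methods.md``).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .binding import BindingParameters, scale_nalmefene
from .physiology import PhysiologyParameters, TolerancePreset
from .pk import PopulationPKModel


class SourcedBlock(BaseModel):
    """A dict of values where every key carries a provenance string."""

    model_config = ConfigDict(extra="forbid")

    values: dict[str, Any]
    sources: dict[str, Any]

    @model_validator(mode="after")
    def _complete_sources(self) -> "SourcedBlock":
        missing = set(self.values) - set(self.sources)
        if missing:
            raise ValueError(f"values without a source string: {sorted(missing)}")
        return self


class PKEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    source: str
    model: PopulationPKModel


class ParameterBundle(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int
    name: str
    description: str = ""
    pk: dict[str, PKEntry]
    binding: dict[str, SourcedBlock]
    nalmefene_scaling: SourcedBlock
    physiology: SourcedBlock
    tolerance: dict[str, SourcedBlock]
    population: SourcedBlock

    # -- accessors ---------------------------------------------------------

    def pk_model(self, key: str) -> PopulationPKModel:
        if key not in self.pk:
            raise KeyError(f"no PK model {key!r} in bundle {self.name!r}")
        return self.pk[key].model

    def scaling_ratios(self) -> tuple[float, float]:
        v = self.nalmefene_scaling.values
        return float(v["r_on"]), float(v["r_off"])

    def binding_parameters(self, drug: str) -> BindingParameters:
        """Point-estimate binding set; nalmefene is derived from naloxone."""
        if drug == "nalmefene":
            base = self.binding_parameters("naloxone")
            r_on, r_off = self.scaling_ratios()
            scaled = scale_nalmefene(base, r_on, r_off)
            nalm = self.binding["nalmefene"].values
            return scaled.model_copy(
                update={"fu": float(nalm["fu"]), "mw": float(nalm["mw"])}
            )
        if drug not in self.binding:
            raise KeyError(f"no binding parameters for {drug!r} in bundle {self.name!r}")
        vals = dict(self.binding[drug].values)
        return BindingParameters(drug=drug, **vals)

    def physiology_parameters(self, preset: str = "chronic") -> PhysiologyParameters:
        if preset not in self.tolerance:
            raise KeyError(
                f"unknown population preset {preset!r}; expected one of "
                f"{sorted(self.tolerance)}"
            )
        tol = TolerancePreset(**self.tolerance[preset].values)
        return PhysiologyParameters(**self.physiology.values, tolerance=tol)

    def population_settings(self) -> dict[str, Any]:
        return dict(self.population.values)


DEFAULT_BUNDLE_NAME = "default_synthetic.yaml"


def load_bundle(path: Optional[str | Path] = None) -> ParameterBundle:
    """Load and schema-validate a parameter bundle (default: packaged file)."""
    if path is None:
        ref = resources.files("opirescue.bundles").joinpath(DEFAULT_BUNDLE_NAME)
        raw = yaml.safe_load(ref.read_text())
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"parameter bundle not found: {p}")
        raw = yaml.safe_load(p.read_text())
    return ParameterBundle(**raw)


@lru_cache(maxsize=1)
def default_bundle() -> ParameterBundle:
    return load_bundle(None)


def antagonist_pk_key(antagonist: str, route: str) -> str:
    """Map (drug, route) to the bundle PK entry implementing it."""
    if antagonist == "nalmefene":
        return "nalmefene"
    if antagonist == "naloxone":
        if route == "intranasal":
            return "naloxone_in"
        if route == "intramuscular":
            return "naloxone_im"
    raise ValueError(f"no PK model for antagonist {antagonist!r} via route {route!r}")
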