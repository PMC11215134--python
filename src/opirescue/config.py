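"""Scenario configuration, run manifests, and result serialization.

Configs are YAML or JSON mappings validated against a strict schema
(unknown keys are rejected with a field-level message); defaults follow the
trial design: 40% ventilation trigger, 60 s administration delay, 2000
virtual subjects, 4 h horizon, 400x2500 bootstrap.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .simulation import RescuePolicy, Scenario, TrialResult

DEFAULT_UNIT_DOSES = {
    ("nalmefene", "intranasal"): 3.0,
    ("naloxone", "intranasal"): 4.0,
    ("naloxone", "intramuscular"): 2.0,
}


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    opioid: Literal["fentanyl", "carfentanil", "remifentanil"]
    dose_mg: float = Field(ge=0)
    population: Literal["chronic", "naive"] = "chronic"
    antagonist: Optional[Literal["nalmefene", "naloxone"]] = None
    route: Literal["intranasal", "intramuscular"] = "intranasal"
    n_doses: int = Field(default=1, ge=0)
    dose_per_unit_mg: Optional[float] = Field(default=None, gt=0)
    trigger_fraction: float = Field(default=0.40, gt=0, lt=1)
    delay_s: float = Field(default=60.0, ge=0)
    seed: int = 1
    n_subjects: int = Field(default=2000, ge=1)
    horizon_s: float = Field(default=14400.0, gt=0)
    rtol: float = Field(default=1e-6, gt=0)
    atol: float = Field(default=1e-8, gt=0)
    bootstrap_m: int = Field(default=400, ge=1)
    bootstrap_b: int = Field(default=2500, ge=1)

    def to_scenario(self) -> Scenario:
        unit = self.dose_per_unit_mg
        if unit is None and self.antagonist is not None:
            unit = DEFAULT_UNIT_DOSES[(self.antagonist, self.route)]
        rescue = RescuePolicy(
            antagonist=self.antagonist,
            route=self.route,
            n_simultaneous_doses=self.n_doses if self.antagonist else 0,
            dose_per_unit_mg=unit or 0.0,
            trigger_fraction=self.trigger_fraction,
            delay_s=self.delay_s,
        )
        return Scenario(
            opioid=self.opioid,
            opioid_dose_mg=self.dose_mg,
            population=self.population,
            rescue=rescue,
            horizon_s=self.horizon_s,
            seed=self.seed,
            rtol=self.rtol,
            atol=self.atol,
            bootstrap_m=self.bootstrap_m,
            bootstrap_b=self.bootstrap_b,
        )


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario config file (YAML or JSON)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    raw = yaml.safe_load(p.read_text())
    try:
        return ScenarioConfig(**raw)
    except ValidationError as err:
        lines = [f"invalid scenario config {p}:"]
        for e in err.errors():
            loc = ".".join(str(x) for x in e["loc"]) or "<root>"
            lines.append(f"  {loc}: {e['msg']}")
        raise ValueError("\n".join(lines)) from err


def save_config(cfg: ScenarioConfig, path: str | Path) -> Path:
    p = Path(path)
    p.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    return p


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")

    config_hash: str
    bundle_name: str
    seed: int
    software_version: str
    created_at: str

    @classmethod
    def create(cls, cfg: ScenarioConfig, bundle_name: str) -> "RunManifest":
        from . import __version__

        canonical = json.dumps(cfg.model_dump(), sort_keys=True).encode()
        return cls(
            config_hash=hashlib.sha256(canonical).hexdigest(),
            bundle_name=bundle_name,
            seed=cfg.seed,
            software_version=__version__,
            created_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def write_results(
    trial: TrialResult, manifest: RunManifest, out_dir: str | Path
) -> dict[str, Path]:
    """Write per-subject CSV, summary JSON and manifest JSON.

    The summary JSON contains only computed quantities (no timestamps), so
    re-running the same config and seed reproduces it byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects_csv = out / "subjects.csv"
    trial.to_frame().to_csv(subjects_csv, index=False)
    summary = {
        "scenario": trial.scenario.describe(),
        "n_subjects": len(trial.subjects),
        "incidence_pct": trial.incidence_pct,
        **trial.bootstrap.to_dict(),
        "seed": trial.scenario.seed,
        "config_hash": manifest.config_hash,
    }
    summary_json = out / "summary.json"
    summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest_json = out / "manifest.json"
    manifest_json.write_text(manifest.model_dump_json(indent=2) + "\n")
    return {"subjects": subjects_csv, "summary": summary_json, "manifest": manifest_json}
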