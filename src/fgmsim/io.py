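"""Readers, writers, configuration and run metadata.

All CSV artifacts are UTF-8, comma-separated, "." decimal, with a
mandatory header row; see docs/formats.md for the column contracts.
Every writer's output is readable by the matching reader with exact
value preservation.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .costing import INTERVENTIONS, MarkupSchedule, UnitCostEntry
from .country import CountryProfile
from .demography import IncidenceSurface, PrevalenceSurface, Surface
from .errors import ValidationError
from .norms import MICRODATA_COLUMNS, validate_microdata

# ---------------------------------------------------------------------------
# microdata
# ---------------------------------------------------------------------------

def write_microdata(df: pd.DataFrame, path: str | Path, *, seed: int | None = None) -> None:
    """Write a woman-level extract; the generating seed is recorded alongside."""
    path = Path(path)
    df.to_csv(path, index=False)
    if seed is not None:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps({"seed": seed, "rows": len(df)}) + "\n"
        )


def read_microdata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_microdata(df)
    return df[list(MICRODATA_COLUMNS)]


# ---------------------------------------------------------------------------
# surfaces (long format: age, year, value)
# ---------------------------------------------------------------------------

def write_surface(surface: Surface, path: str | Path, value_name: str = "value") -> None:
    surface.to_frame(value_name).to_csv(path, index=False)


def read_incidence(path: str | Path, value_name: str = "value") -> IncidenceSurface:
    return IncidenceSurface.from_frame(pd.read_csv(path), value_name)


def read_prevalence(path: str | Path, value_name: str = "value") -> PrevalenceSurface:
    return PrevalenceSurface.from_frame(pd.read_csv(path), value_name)


# ---------------------------------------------------------------------------
# country profiles (JSON or YAML by extension)
# ---------------------------------------------------------------------------

def write_profile(profile: CountryProfile, path: str | Path) -> None:
    path = Path(path)
    d = profile.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_profile(path: str | Path) -> CountryProfile:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return CountryProfile.from_dict(d)


# ---------------------------------------------------------------------------
# unit costs (CSV: intervention, reference_cost, reference_gdp_ppp)
# ---------------------------------------------------------------------------

def write_unit_costs(costs: dict[str, UnitCostEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "intervention": e.intervention,
                "reference_cost": e.reference_cost,
                "reference_gdp_ppp": e.reference_gdp_ppp,
            }
            for e in costs.values()
        ]
    ).to_csv(path, index=False)


def read_unit_costs(path: str | Path) -> dict[str, UnitCostEntry]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        name = str(row["intervention"])
        if name not in INTERVENTIONS:
            raise ValidationError(f"unit_costs.intervention: unknown intervention {name!r}")
        out[name] = UnitCostEntry(
            name, float(row["reference_cost"]), float(row["reference_gdp_ppp"])
        )
    return out


def write_ledger(ledger: pd.DataFrame, path: str | Path) -> None:
    """Cost ledger CSV; all monetary columns are USD2020."""
    ledger.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "countries": {"n_countries": 8, "n_communities": 60, "women_per_community": 150},
    "scenario": {
        "name": "high",
        "coverage_target": 1.0,
        "effects": {"direct": 0.710, "indirect": 0.446, "indirect_ratio": 3.0},
        "planning_indirect_ratio": 3.0,
        "persistence": 1.0,
        "spillover": False,
        "covid_delay_years": 0,
    },
    "unit_costs": None,  # path to CSV, or null for package defaults
    "sensitivity_rows": None,  # null = all rows
}

_SCENARIO_KEYS = set(DEFAULT_CONFIG["scenario"]) | {
    "cost_start", "cost_end", "impact_end", "front_load_years",
    "historic_trend_override",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration, applying documented defaults.

    Unknown keys, unknown interventions in a referenced unit-cost file,
    and invalid field values raise :class:`ValidationError` naming the
    offending field path.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValidationError(f"config: unknown key(s) {sorted(unknown)}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in raw.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            bad = set(v) - (_SCENARIO_KEYS if k == "scenario" else set(cfg[k]))
            if bad:
                raise ValidationError(f"config.{k}: unknown key(s) {sorted(bad)}")
            cfg[k].update(v)
        else:
            cfg[k] = v
    if cfg["unit_costs"] is not None:
        read_unit_costs(cfg["unit_costs"])  # resolves the cross-reference
    sc = cfg["scenario"]
    if not 0 <= sc["coverage_target"] <= 1:
        raise ValidationError("config.scenario.coverage_target: must lie in [0, 1]")
    return cfg


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def build_scenario(cfg: dict[str, Any]):
    """Construct a ScenarioDefinition from a validated configuration."""
    from .impact import EffectSizes
    from .scenarios import ScenarioDefinition

    sc = dict(cfg["scenario"])
    eff = sc.pop("effects", {})
    return ScenarioDefinition(effects=EffectSizes(**eff), **sc)


# ---------------------------------------------------------------------------
# run metadata
# ---------------------------------------------------------------------------

def config_hash(cfg: dict[str, Any]) -> str:
    """SHA-256 over the canonical JSON form; identical configs hash equal."""
    canonical = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunMetadata:
    """Provenance emitted with every output set."""

    config_hash: str
    seed: int
    timestamp: str
    version: str
    input_digests: dict[str, str]

    @classmethod
    def create(
        cls, cfg: dict[str, Any], seed: int, inputs: dict[str, str | Path] | None = None
    ) -> "RunMetadata":
        digests = {}
        for label, p in (inputs or {}).items():
            digests[label] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        return cls(
            config_hash=config_hash(cfg),
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(),
            version=__version__,
            input_digests=digests,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
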