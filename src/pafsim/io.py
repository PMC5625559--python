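"""Reading and writing run configurations and exchange CSVs.

All exchange formats are UTF-8 comma-delimited CSV with a mandatory
header row, plus a YAML run configuration.  The exposure CSV has columns
``sex, age_low, age_high, mean_g_day, sd_g_day`` and an optional
``family`` column (default gamma); incidence and population CSVs are
documented in :mod:`pafsim.demography`.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .demography import PopulationTable, StandardPopulation, StratifiedRateTable, segi_standard
from .errors import ConfigError
from .exposure_model import ExposureDistribution
from .risk_model import DEFAULT_STEP_G_DAY, RelativeRiskSpec
from .simulation_engine import Scenario

__all__ = [
    "RunConfig",
    "load_run_config",
    "read_exposures",
    "write_exposures",
]


@dataclass(frozen=True)
class RunConfig:
    """A validated run configuration (one scenario per invocation)."""

    rr_spec: RelativeRiskSpec
    step: float
    scenario: Scenario
    exposure_csv: Path
    incidence_csv: Path
    population_csv: Path
    standard: StandardPopulation
    output_dir: Path
    raw: dict = field(default_factory=dict, compare=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing required key {key!r} in {context}")
    return mapping[key]


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"run config {path} must be a mapping")

    rf = _require(raw, "risk_factor", "run config")
    spec = RelativeRiskSpec(
        risk_factor=_require(rf, "name", "risk_factor"),
        rr_central=float(_require(rf, "rr_central", "risk_factor")),
        rr_lower=float(rf.get("rr_lower", rf["rr_central"])),
        rr_upper=float(rf.get("rr_upper", rf["rr_central"])),
        reference_dose=float(_require(rf, "reference_dose_g_per_day", "risk_factor")),
        sex=rf.get("sex", "both"),
    )
    step = float(rf.get("step_g_per_day", DEFAULT_STEP_G_DAY))

    sc = raw.get("scenario", {})
    transform = sc.get("transform", "zero")
    scenario = Scenario(
        name=sc.get("name", str(transform)),
        exposure_transform=transform,
        year=int(sc.get("year", 2010)),
        latency_years=int(sc.get("latency_years", 0)),
    )

    inputs = _require(raw, "inputs", "run config")
    base = path.parent
    paths = {}
    for key in ("exposure_csv", "incidence_csv", "population_csv"):
        p = Path(_require(inputs, key, "inputs"))
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ConfigError(f"input file does not exist: {p}")
        paths[key] = p

    std_name = raw.get("standard_population", "segi")
    if std_name == "segi":
        std = segi_standard()
    else:
        std_path = Path(std_name)
        if not std_path.is_absolute():
            std_path = base / std_path
        if not std_path.exists():
            raise ConfigError(f"standard population file does not exist: {std_path}")
        std = StandardPopulation.from_csv(std_path, name=std_path.stem)

    out_dir = Path(raw.get("output_dir", "out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir

    return RunConfig(
        rr_spec=spec,
        step=step,
        scenario=scenario,
        exposure_csv=paths["exposure_csv"],
        incidence_csv=paths["incidence_csv"],
        population_csv=paths["population_csv"],
        standard=std,
        output_dir=out_dir,
        raw=raw,
    )


def read_exposures(path: str | Path) -> list[ExposureDistribution]:
    """Read an exposure CSV into per-stratum distributions."""
    df = pd.read_csv(path)
    required = {"sex", "age_low", "age_high", "mean_g_day", "sd_g_day"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"exposure CSV {path} missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples():
        fam = getattr(r, "family", "gamma")
        if not isinstance(fam, str) or (isinstance(fam, float) and math.isnan(fam)):
            fam = "gamma"
        out.append(
            ExposureDistribution(
                sex=r.sex,
                age_low=int(r.age_low),
                age_high=int(r.age_high),
                mean=float(r.mean_g_day),
                sd=float(r.sd_g_day),
                family=fam,
            )
        )
    return out


def write_exposures(exposures, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sex": e.sex,
                "age_low": e.age_low,
                "age_high": e.age_high,
                "mean_g_day": e.mean,
                "sd_g_day": e.sd,
                "family": e.family,
            }
            for e in exposures
        ]
    ).to_csv(path, index=False)


def load_tables(config: RunConfig):
    """Load the three input tables referenced by a run configuration."""
    return (
        read_exposures(config.exposure_csv),
        StratifiedRateTable.from_csv(config.incidence_csv),
        PopulationTable.from_csv(config.population_csv),
    )
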