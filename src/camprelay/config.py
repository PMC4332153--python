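"""Run configuration: YAML/JSON parsing, validation, defaults.

A run config has sections `cell`, `population`, `sim`, `fret` (parameter
overrides; defaults are the study's values), an `experiment` name, an
optional `protocol` (a preset name or an explicit segment list), optional
experiment-specific keys (grids, levels), a master `seed` and an `outdir`.
Unknown keys are rejected; the fully resolved config is echoed into the
output directory by the CLI so every artifact carries its provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import CellParams, FretParams, KdDistribution, PopulationParams, SimConfig
from .stimulus import StimulusProtocol, build_protocol, preset

EXPERIMENTS = ("simulate-cell", "simulate-population", "phase-diagram",
               "density-flow", "entrainment-scan", "scenario", "suite",
               "short-pulse")

_TOP_KEYS = {"cell", "population", "sim", "fret", "experiment", "protocol",
             "grids", "alpha_f_levels", "seed", "outdir"}


class ConfigError(ValueError):
    pass


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(section) - known
    if bad:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(bad)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name} parameters: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one reproducible run."""

    experiment: str = "simulate-cell"
    cell: CellParams = field(default_factory=CellParams)
    population: PopulationParams = field(default_factory=PopulationParams)
    sim: SimConfig = field(default_factory=SimConfig)
    fret: FretParams = field(default_factory=FretParams)
    protocol: StimulusProtocol | None = None
    grids: dict = field(default_factory=dict)
    alpha_f_levels: tuple = ()
    seed: int = 0
    outdir: str = "camprelay-out"

    def resolved(self) -> dict:
        """The defaults-merged config as a plain JSON-serializable dict."""
        out = {
            "experiment": self.experiment,
            "cell": self.cell.asdict(),
            "population": self.population.asdict(),
            "sim": dataclasses.replace(self.sim, seed=self.seed).asdict(),
            "fret": self.fret.asdict(),
            "grids": dict(self.grids),
            "alpha_f_levels": list(self.alpha_f_levels),
            "seed": self.seed,
            "outdir": self.outdir,
        }
        if self.protocol is not None:
            out["protocol"] = self.protocol.asdict()
        return out


def load_config(source) -> RunConfig:
    """Parse a YAML/JSON file path, text or dict into a RunConfig."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        raw = yaml.safe_load(text)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
    bad = set(raw) - _TOP_KEYS
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")

    experiment = raw.get("experiment", "simulate-cell")
    if experiment not in EXPERIMENTS:
        raise ConfigError(
            f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}")

    pop_section = dict(raw.get("population", {}))
    if isinstance(pop_section.get("kd_distribution"), dict):
        pop_section["kd_distribution"] = _build(
            KdDistribution, pop_section["kd_distribution"],
            "population.kd_distribution")

    proto_raw = raw.get("protocol")
    if proto_raw is None:
        protocol = None
    elif isinstance(proto_raw, str):
        protocol = preset(proto_raw)
    else:
        protocol = build_protocol(proto_raw)

    seed = int(raw.get("seed", 0))
    sim = _build(SimConfig, {**raw.get("sim", {}), "seed": seed}, "sim")
    return RunConfig(
        experiment=experiment,
        cell=_build(CellParams, raw.get("cell", {}), "cell"),
        population=_build(PopulationParams, pop_section, "population"),
        sim=sim,
        fret=_build(FretParams, raw.get("fret", {}), "fret"),
        protocol=protocol,
        grids=dict(raw.get("grids", {})),
        alpha_f_levels=tuple(raw.get("alpha_f_levels", ())),
        seed=seed,
        outdir=str(raw.get("outdir", "camprelay-out")),
    )


def echo_config(config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved-config.json").write_text(
        json.dumps(config.resolved(), indent=2, default=float))
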