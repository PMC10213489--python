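"""Configuration files, tabular/JSON writers and run manifests.

Config files are TOML (or JSON) with three sections — ``landscape``,
``demography`` and ``simulation`` — whose keys default to the reference
parameter set (delta=1.3, r00=0.2, r10=0.35, r01=0.9, r11=1, death rate 0.1,
n=1e12, p=0.5, s=0.1, 7 cycles).  Unknown keys are rejected rather than
ignored.  Every run directory receives a ``manifest.json`` with the resolved
parameters, the seed and the software version, sufficient to reproduce the
run bit for bit.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .core import FitnessLandscape, ParameterError
from .simulate import CycleRecord

__all__ = [
    "ConfigError",
    "UnknownKeyError",
    "ParameterBundle",
    "DEFAULT_CONFIG",
    "load_config",
    "dump_config",
    "records_to_frame",
    "write_table",
    "read_table",
    "write_json",
    "build_manifest",
    "write_run_outputs",
]


class ConfigError(ValueError):
    """The configuration file could not be parsed."""


class UnknownKeyError(ConfigError):
    """The configuration file contains a key the model does not define."""


#: Reference parameter set (phase-diagram and density-simulation defaults).
DEFAULT_CONFIG: dict = {
    "landscape": {"r00": 0.2, "r10": 0.35, "r01": 0.9, "r11": 1.0},
    "demography": {"n": 1.0e12, "delta": 1.3},
    "simulation": {"death_rate": 0.1, "p": 0.5, "s": 0.1, "cycles": 7},
}


@dataclass(frozen=True)
class ParameterBundle:
    """Resolved landscape, demography and simulation parameters."""

    landscape: FitnessLandscape
    n: float
    delta: float
    death_rate: float
    p: float
    s: float
    cycles: int

    def to_dict(self) -> dict:
        return {
            "landscape": dataclasses.asdict(self.landscape),
            "demography": {"n": self.n, "delta": self.delta},
            "simulation": {
                "death_rate": self.death_rate,
                "p": self.p,
                "s": self.s,
                "cycles": self.cycles,
            },
        }


def _merge_checked(raw: dict) -> dict:
    merged = {section: dict(values) for section, values in DEFAULT_CONFIG.items()}
    for section, values in raw.items():
        if section not in merged:
            raise UnknownKeyError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"section {section!r} must be a table of key/value pairs")
        for key, value in values.items():
            if key not in merged[section]:
                raise UnknownKeyError(f"unknown key {key!r} in section {section!r}")
            merged[section][key] = value
    return merged


def load_config(path: str | Path | None = None) -> ParameterBundle:
    """Load and validate a config file; ``None`` yields the full default bundle.

    Raises :class:`ConfigError` on parse failure, :class:`UnknownKeyError` on
    unrecognized keys, and :class:`~bottlepath.core.ParameterError` when a
    value violates a model inequality (the message names the constraint).
    """
    raw: dict = {}
    if path is not None:
        path = Path(path)
        try:
            if path.suffix == ".json":
                raw = json.loads(path.read_text())
            else:
                with open(path, "rb") as fh:
                    raw = tomllib.load(fh)
        except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
    merged = _merge_checked(raw)
    landscape = FitnessLandscape(**merged["landscape"])
    dem, sim = merged["demography"], merged["simulation"]
    if not dem["n"] > 1:
        raise ParameterError(f"scaling parameter must satisfy n > 1 (got {dem['n']})")
    if not dem["delta"] > 1:
        raise ParameterError(f"rarity exponent must satisfy delta > 1 (got {dem['delta']})")
    if sim["death_rate"] < 0:
        raise ParameterError(f"death rate must be non-negative (got {sim['death_rate']})")
    if not 0 < sim["p"] <= 1:
        raise ParameterError(f"trigger fraction must satisfy 0 < p <= 1 (got {sim['p']})")
    if sim["s"] < 0:
        raise ParameterError(f"capacity advantage must satisfy s >= 0 (got {sim['s']})")
    if int(sim["cycles"]) < 1:
        raise ParameterError(f"cycles must be >= 1 (got {sim['cycles']})")
    return ParameterBundle(
        landscape=landscape,
        n=float(dem["n"]),
        delta=float(dem["delta"]),
        death_rate=float(sim["death_rate"]),
        p=float(sim["p"]),
        s=float(sim["s"]),
        cycles=int(sim["cycles"]),
    )


def dump_config(bundle: ParameterBundle) -> dict:
    """Resolved parameters as the nested dict a config file would contain."""
    return bundle.to_dict()


def records_to_frame(records: list[CycleRecord]) -> pd.DataFrame:
    """Per-cycle records as a long table (one row per cycle and genotype)."""
    rows = []
    for rec in records:
        for key in ("10", "01", "11_from10", "11_from01", "11"):
            genotype = key[:2]
            origin = key[3:] if "_" in key else ("total" if key == "11" else "")
            rows.append(
                {
                    "cycle": rec.cycle,
                    "genotype": genotype,
                    "origin": origin,
                    "foundings": rec.foundings[key],
                    "end_size": rec.end_size[key],
                    "established": rec.established[key],
                    "post_bottleneck": rec.post_size[key],
                    "survived": rec.survived[key],
                    "duration": rec.duration,
                    "wt_end": rec.wt_end,
                }
            )
    return pd.DataFrame(rows)


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a TSV with a header row, '.' decimals and full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        frame.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"could not write table to {path}: {exc}") from exc
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if hasattr(obj, "item"):  # numpy scalars
        return _sanitize(obj.item())
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        path.write_text(json.dumps(_sanitize(obj), indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"could not write JSON to {path}: {exc}") from exc
    return path


def build_manifest(
    parameters: dict,
    seed: int,
    variant: str,
    outputs: list[str],
) -> dict:
    """Everything needed to reproduce a run bit for bit."""
    return {
        "parameters": _sanitize(parameters),
        "seed": int(seed),
        "variant": variant,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": sorted(outputs),
    }


def write_run_outputs(
    destination: str | Path,
    seed: int,
    variant: str,
    parameters: dict,
    tables: dict[str, pd.DataFrame] | None = None,
    summaries: dict[str, dict] | None = None,
) -> Path:
    """Write tables (TSV), summaries (JSON) and the run manifest to a directory."""
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name, frame in (tables or {}).items():
        written.append(write_table(frame, destination / f"{name}.tsv").name)
    for name, summary in (summaries or {}).items():
        written.append(write_json(summary, destination / f"{name}.json").name)
    manifest = build_manifest(parameters, seed, variant, written)
    write_json(manifest, destination / "manifest.json")
    return destination
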