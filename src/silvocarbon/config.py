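"""Structured run configuration.

A single YAML file declares everything a pipeline run needs — input paths,
engine settings (realization count, seed, CI level, CLT plan), allometry
constants, parameter distributions, and the management-scenario fractions —
so runs are reproducible from one artifact. Anything omitted falls back to
the packaged fixtures and documented defaults.

Example::

    paths:
      area_tables: {"1929": a29.csv, "1954": a54.csv, "2024": a24.csv}
      range_table: ranges.csv
      output_dir: out
    engine: {n: 100000, seed: 42, ci_level: 0.95}
    allometry: {form_factor: 0.5, carbon_fraction: 0.47}
    distributions:
      - {name: SOCt, family: uniform, lower: 35, upper: 70}
    scenario_fractions: [0.10, 0.15, 0.20, 0.25, 0.30]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .lulc import AreaTable, load_epoch_table, read_area_table
from .montecarlo import ParameterDistribution, SamplingPlan, default_distributions
from .scenarios import DEFAULT_FRACTIONS, CarbonDensityRange, load_default_ranges, read_range_table
from .silvoarable import AllometryConfig


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    area_table_paths: dict[str, Path] = field(default_factory=dict)
    range_table_path: Path | None = None
    output_dir: Path = Path("out")
    n: int = 100_000
    seed: int | None = None
    ci_level: float = 0.95
    clt_plan: SamplingPlan | None = None
    allometry: AllometryConfig = field(default_factory=AllometryConfig)
    distributions: dict[str, ParameterDistribution] = field(
        default_factory=default_distributions
    )
    scenario_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    sobol_base_n: int = 4096

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be positive, got {self.n}")
        if not 0 < self.ci_level < 1:
            raise ConfigError(f"ci_level must be in (0,1), got {self.ci_level}")
        for epoch, path in self.area_table_paths.items():
            if not Path(path).exists():
                raise ConfigError(f"area table for {epoch} not found: {path}")
        if self.range_table_path is not None and not Path(self.range_table_path).exists():
            raise ConfigError(f"range table not found: {self.range_table_path}")

    def epoch_tables(self) -> dict[str, AreaTable]:
        """Configured area tables, falling back to the packaged fixtures."""
        out: dict[str, AreaTable] = {}
        for epoch in ("1929", "1954", "2024"):
            if epoch in self.area_table_paths:
                out[epoch] = read_area_table(self.area_table_paths[epoch], epoch)
            else:
                out[epoch] = load_epoch_table(epoch)
        return out

    def ranges(self) -> dict[str, CarbonDensityRange]:
        if self.range_table_path is not None:
            return read_range_table(self.range_table_path)
        return load_default_ranges()


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; None gives the all-defaults config."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    paths = raw.get("paths", {})
    engine = raw.get("engine", {})
    kwargs: dict = {}
    if "area_tables" in paths:
        kwargs["area_table_paths"] = {
            str(k): Path(v) for k, v in paths["area_tables"].items()
        }
    if "range_table" in paths:
        kwargs["range_table_path"] = Path(paths["range_table"])
    if "output_dir" in paths:
        kwargs["output_dir"] = Path(paths["output_dir"])
    for key in ("n", "seed", "ci_level"):
        if key in engine:
            kwargs[key] = engine[key]
    if "sobol_base_n" in engine:
        kwargs["sobol_base_n"] = int(engine["sobol_base_n"])
    if "clt_plan" in engine:
        kwargs["clt_plan"] = SamplingPlan(**engine["clt_plan"])
    if "allometry" in raw:
        kwargs["allometry"] = AllometryConfig(**raw["allometry"])
    if "distributions" in raw:
        dists = dict(default_distributions())
        for spec in raw["distributions"]:
            d = ParameterDistribution(**spec)
            dists[d.name] = d
        kwargs["distributions"] = dists
    if "scenario_fractions" in raw:
        kwargs["scenario_fractions"] = tuple(float(f) for f in raw["scenario_fractions"])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
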