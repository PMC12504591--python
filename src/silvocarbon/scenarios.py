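"""Scenario-based regional carbon-stock simulation.

Each scenario is a per-category hectare allocation of the regional
landscape. The regional mean carbon stock under a scenario is estimated by
Monte Carlo: per realization r, one carbon density c_i^(r) is drawn
uniformly within the category's documented range (perfect spatial
correlation within a category, independence across categories) and the
area-weighted mean

    m^(r) = Σ_i a_i · c_i^(r) / Σ_i a_i        [t C ha^-1]

is recorded; the scenario's mean is the average of the m^(r) and its 95%
confidence interval the empirical 2.5/97.5 percentiles, so the interval
reflects the documented density uncertainty rather than a standard error.

Nine scenarios make up the standard suite: the three historical epochs
(1929, 1954, 2024) and six management scenarios applied to the 2024
landscape — full conversion of non-irrigated arable land to silvoarable
agroforestry (S_AF) and afforestation of 10–30% of arable land into mixed
forest (S_F10…S_F30). Carbon sequestration is the percent difference in
mean stock: management scenarios against the 2024 baseline, historical
epochs against the preceding epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    CoverageError,
    FormatError,
    UndefinedBaselineError,
    ValidationError,
)
from .lulc import (
    AGROFORESTRY,
    ARABLE,
    CANONICAL_CATEGORIES,
    MIXED_FOREST,
    WATER_BODY,
    AreaTable,
)

#: Afforestation fractions of the standard S_F ladder.
DEFAULT_FRACTIONS: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass(frozen=True)
class CarbonDensityRange:
    """Documented min/max carbon density of one LULC category, t C ha^-1."""

    category: str
    lower: float
    upper: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.category not in CANONICAL_CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if not 0 <= self.lower <= self.upper:
            raise ValidationError(
                f"{self.category}: need 0 <= lower <= upper, got "
                f"({self.lower}, {self.upper})"
            )
        if self.category == WATER_BODY and (self.lower, self.upper) != (0.0, 0.0):
            raise ValidationError("Water body carbon density is fixed at zero")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


RangeMap = Mapping[str, CarbonDensityRange]


def read_range_table(path: str | Path) -> dict[str, CarbonDensityRange]:
    """Read a ``category,lower,upper[,source]`` CSV of density ranges."""
    df = pd.read_csv(path)
    missing = {"category", "lower", "upper"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, CarbonDensityRange] = {}
    for row in df.itertuples():
        r = CarbonDensityRange(
            category=str(row.category),
            lower=float(row.lower),
            upper=float(row.upper),
            source=str(getattr(row, "source", "")),
        )
        out[r.category] = r
    return out


def load_default_ranges() -> dict[str, CarbonDensityRange]:
    """The packaged regional density ranges (national inventory values for
    established categories, the silvoarable model's 95% CI for
    agroforestry, zero for water)."""
    ref = resources.files("silvocarbon.data") / "carbon_density_ranges.csv"
    with resources.as_file(ref) as path:
        return read_range_table(path)


@dataclass
class Scenario:
    """A named hectare allocation plus where it came from."""

    name: str
    area_table: AreaTable
    provenance: str = ""


@dataclass
class ScenarioResult:
    """Simulated regional stock for one scenario (a results-table row)."""

    name: str
    mean_cs: float
    ci_lower: float
    ci_upper: float
    seq_percent: float | None
    n: int
    seed: int | None

    def __post_init__(self) -> None:
        # tolerance absorbs last-ulp rounding when the CI is zero-width
        tol = 1e-9 * max(1.0, abs(self.mean_cs))
        if not self.ci_lower - tol <= self.mean_cs <= self.ci_upper + tol:
            raise ValidationError(
                f"{self.name}: mean {self.mean_cs} outside CI "
                f"[{self.ci_lower}, {self.ci_upper}]"
            )


def make_temporal_scenario(table: AreaTable) -> Scenario:
    return Scenario(name=table.epoch, area_table=table,
                    provenance=f"historical allocation {table.epoch}")


def make_management_scenario(
    base: AreaTable, kind: str, fraction: float | None = None
) -> Scenario:
    """Transform a base allocation into a management scenario.

    ``S_AF`` converts all non-irrigated arable land to agroforestry;
    ``S_F`` converts ``fraction`` of it to mixed forest. Every other
    category, and the total area, is untouched (exactly).
    """
    arable = base[ARABLE]
    if kind == "S_AF":
        table = base.replace(
            epoch="S_AF",
            **{ARABLE: 0.0, AGROFORESTRY: base[AGROFORESTRY] + arable},
        )
        return Scenario(
            name="S_AF",
            area_table=table,
            provenance=f"{base.epoch}: all arable land to agroforestry",
        )
    if kind == "S_F":
        if fraction is None or not 0.0 <= fraction <= 1.0:
            raise ConfigError(f"S_F fraction must be in [0, 1], got {fraction}")
        moved = fraction * arable
        name = f"S_F{round(fraction * 100):d}"
        table = base.replace(
            epoch=name,
            **{ARABLE: arable - moved, MIXED_FOREST: base[MIXED_FOREST] + moved},
        )
        return Scenario(
            name=name,
            area_table=table,
            provenance=f"{base.epoch}: {fraction:.0%} of arable land afforested",
        )
    raise ConfigError(f"unknown management scenario kind {kind!r}")


def simulate_scenario(
    scenario: Scenario,
    ranges: RangeMap,
    n: int = 100_000,
    seed: int | None = None,
    ci_level: float = 0.95,
    af_sample: Sequence[float] | None = None,
) -> ScenarioResult:
    """Monte Carlo estimate of a scenario's regional mean carbon stock.

    Every category with positive area needs a density range (zero-width
    allowed). When ``af_sample`` is given, agroforestry densities are
    resampled from that empirical carbon-stock sample instead of its
    uniform range — the alternative coupling to the silvoarable model's
    output distribution.
    """
    table = scenario.area_table
    populated = [c for c in CANONICAL_CATEGORIES if table[c] > 0]
    uncovered = [c for c in populated if c not in ranges]
    if uncovered:
        raise CoverageError(f"no carbon-density range for: {uncovered}")
    if n < 1:
        raise ConfigError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    areas = np.array([table[c] for c in populated])
    total = areas.sum()
    if total <= 0:
        raise ValidationError(f"{scenario.name}: scenario has zero total area")
    densities = np.empty((n, len(populated)))
    for j, c in enumerate(populated):
        if c == AGROFORESTRY and af_sample is not None:
            densities[:, j] = rng.choice(np.asarray(af_sample, dtype=float),
                                         size=n, replace=True)
        else:
            r = ranges[c]
            if r.lower == r.upper:
                densities[:, j] = r.lower
            else:
                densities[:, j] = rng.uniform(r.lower, r.upper, size=n)
    m = densities @ areas / total
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(m, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ScenarioResult(
        name=scenario.name,
        mean_cs=float(m.mean()),
        ci_lower=float(lo),
        ci_upper=float(hi),
        seq_percent=None,
        n=int(n),
        seed=seed,
    )


def expected_mean_cs(scenario: Scenario, ranges: RangeMap) -> float:
    """Closed-form limit of the simulated mean: area-weighted range midpoints."""
    table = scenario.area_table
    populated = [c for c in CANONICAL_CATEGORIES if table[c] > 0]
    uncovered = [c for c in populated if c not in ranges]
    if uncovered:
        raise CoverageError(f"no carbon-density range for: {uncovered}")
    areas = np.array([table[c] for c in populated])
    mids = np.array([ranges[c].midpoint for c in populated])
    return float(areas @ mids / areas.sum())


def sequestration_percent(target: ScenarioResult, reference: ScenarioResult) -> float:
    """Percent difference of mean stocks, target vs reference."""
    if reference.mean_cs <= 0:
        raise UndefinedBaselineError(
            f"reference {reference.name} has non-positive mean stock"
        )
    return 100.0 * (target.mean_cs - reference.mean_cs) / reference.mean_cs


def run_suite(
    tables: Mapping[str, AreaTable],
    ranges: RangeMap,
    n: int = 100_000,
    seed: int | None = None,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    af_sample: Sequence[float] | None = None,
) -> list[ScenarioResult]:
    """The standard nine-scenario suite with sequestration percentages.

    ``tables`` must hold the '1929', '1954' and '2024' epoch allocations.
    Historical results are referenced to the preceding epoch (1929 has no
    reference); management results to the 2024 baseline. Each scenario
    gets an independent child seed derived from ``seed``.
    """
    missing = {"1929", "1954", "2024"} - set(tables)
    if missing:
        raise ConfigError(f"missing epoch table(s): {sorted(missing)}")
    scenarios = [make_temporal_scenario(tables[e]) for e in ("1929", "1954", "2024")]
    base = tables["2024"]
    scenarios.append(make_management_scenario(base, "S_AF"))
    scenarios.extend(
        make_management_scenario(base, "S_F", fraction=f) for f in fractions
    )
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(scenarios))]
    results = [
        simulate_scenario(sc, ranges, n=n, seed=cs, af_sample=af_sample)
        for sc, cs in zip(scenarios, child_seeds)
    ]
    by_name = {r.name: r for r in results}
    reference = {
        "1929": None,
        "1954": by_name["1929"],
        "2024": by_name["1954"],
    }
    out = []
    for r in results:
        ref = reference.get(r.name, by_name["2024"])
        seq = sequestration_percent(r, ref) if ref is not None else None
        out.append(replace(r, seq_percent=seq))
    return out


def results_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Results-table view: scenario, mean, CI bounds, sequestration %."""
    return pd.DataFrame(
        [
            {
                "scenario": r.name,
                "mean": r.mean_cs,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "seq_percent": r.seq_percent,
                "n": r.n,
                "seed": r.seed,
            }
            for r in results
        ]
    )


def plot_suite(results: Sequence[ScenarioResult], path: str | Path) -> None:
    """Line-and-ribbon plot of scenario means with their 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [r.name for r in results]
    means = [r.mean_cs for r in results]
    los = [r.ci_lower for r in results]
    his = [r.ci_upper for r in results]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    x = np.arange(len(names))
    ax.plot(x, means, marker="o", color="forestgreen", label="mean carbon stock")
    ax.fill_between(x, los, his, alpha=0.25, color="forestgreen", label="95% CI")
    ax.set_xticks(x, names, rotation=45, ha="right")
    ax.set_ylabel("carbon stock (t C ha$^{-1}$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
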