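"""Synthetic data generation for end-to-end testing without downloads.

Three generators mirror the three kinds of real input the pipeline
consumes:

* paired categorical grids whose cross-tabulation equals a prescribed
  transition table *exactly* — construction allocates the required number
  of cells per (from, to) flow and then shuffles cell positions, so the
  marginals are exact by counting rather than approximate by rejection;
* literature-style parameter samples: noisy draws around known truth
  values with labelled, well-separated outliers injected at a controlled
  rate, so outlier-filter recall and precision are measurable;
* per-category carbon-density range tables: the packaged regional table,
  optionally perturbed while preserving 0 ≤ lower ≤ upper and the fixed
  zero water-body range.

Every generator takes an explicit seed; none touches global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .lulc import WATER_BODY, CategoricalGrid, TransitionTable
from .scenarios import CarbonDensityRange, load_default_ranges


@dataclass
class SyntheticSpec:
    """Everything a synthetic fixture run needs, in one declarative object."""

    grid_shape: tuple[int, int] = (10, 10)
    flows: dict[tuple[int, int], float] = field(default_factory=dict)
    cell_area: float = 1.0
    nodata: int = 0
    truth: dict[str, float] = field(default_factory=dict)
    noise_scale: float = 0.05
    outlier_rate: float = 0.0
    outlier_mads: float = 5.0
    samples_per_param: int = 50
    range_perturbation: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, rate in (("outlier_rate", self.outlier_rate),):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if self.cell_area <= 0:
            raise ConfigError(f"cell_area must be positive, got {self.cell_area}")
        if self.outlier_mads < 0 or self.noise_scale < 0 or self.range_perturbation < 0:
            raise ConfigError("scales must be non-negative")


def generate_grid_pair(spec: SyntheticSpec) -> tuple[CategoricalGrid, CategoricalGrid]:
    """A pair of aligned grids realising the prescribed transition table.

    Each flow (i, j) → a hectares claims round(a / cell_area) cells that
    hold code i in the first grid and code j in the second; unclaimed
    cells are nodata in both. Cell positions are shuffled with the spec's
    seed, so the spatial pattern is random but the cross-tabulation exact.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.grid_shape[0] * spec.grid_shape[1]
    counts: dict[tuple[int, int], int] = {}
    for (i, j), area in spec.flows.items():
        if area < 0:
            raise ConfigError(f"negative flow {(i, j)}: {area}")
        c = area / spec.cell_area
        if abs(c - round(c)) > 1e-9:
            raise ConfigError(
                f"flow {(i, j)} = {area} is not a multiple of cell_area {spec.cell_area}"
            )
        if i == spec.nodata or j == spec.nodata:
            raise ConfigError(f"flow {(i, j)} uses the nodata code {spec.nodata}")
        counts[(i, j)] = int(round(c))
    total = sum(counts.values())
    if total > n_cells:
        raise ConfigError(
            f"prescribed flows need {total} cells but the grid has {n_cells}"
        )
    a = np.full(n_cells, spec.nodata, dtype=np.int32)
    b = np.full(n_cells, spec.nodata, dtype=np.int32)
    positions = rng.permutation(n_cells)[:total]
    pos = 0
    for (i, j), c in counts.items():
        sel = positions[pos : pos + c]
        a[sel] = i
        b[sel] = j
        pos += c
    shape = spec.grid_shape
    return (
        CategoricalGrid(cells=a.reshape(shape), nodata=spec.nodata, cell_area=spec.cell_area),
        CategoricalGrid(cells=b.reshape(shape), nodata=spec.nodata, cell_area=spec.cell_area),
    )


def random_transition_table(
    rng: np.random.Generator,
    codes: tuple[int, ...] = (1, 2, 3, 4),
    max_cells: int = 80,
    cell_area: float = 1.0,
) -> TransitionTable:
    """A random valid flow table that fits a grid of at least max_cells."""
    k = len(codes)
    n_flows = int(rng.integers(1, k * k + 1))
    pairs = [(int(codes[int(p // k)]), int(codes[int(p % k)]))
             for p in rng.choice(k * k, size=n_flows, replace=False)]
    budget = max_cells
    flows: dict[tuple[int, int], float] = {}
    for pair in pairs:
        if budget == 0:
            break
        c = int(rng.integers(1, budget + 1))
        flows[pair] = c * cell_area
        budget -= c
    return TransitionTable(flows=flows)


@dataclass
class LabelledSample:
    """A synthetic literature sample with ground-truth outlier labels."""

    name: str
    truth: float
    values: np.ndarray
    outlier_indices: list[int]

    @property
    def clean_values(self) -> np.ndarray:
        mask = np.ones(len(self.values), dtype=bool)
        mask[self.outlier_indices] = False
        return self.values[mask]


def generate_literature_samples(spec: SyntheticSpec) -> dict[str, LabelledSample]:
    """Per-parameter noisy samples with labelled injected outliers.

    Inliers are Normal(truth, noise_scale·truth); outliers replace a
    ``outlier_rate`` share of the draws with values displaced from the
    median by at least ``outlier_mads`` raw MADs of the clean sample
    (random sign, random extra distance), so a median-tolerance filter at
    a smaller k_mad can separate them.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, LabelledSample] = {}
    for name, truth in spec.truth.items():
        n = spec.samples_per_param
        sigma = spec.noise_scale * (abs(truth) if truth != 0 else 1.0)
        values = rng.normal(truth, sigma, size=n)
        n_out = int(round(spec.outlier_rate * n))
        idx: list[int] = []
        if n_out > 0:
            idx = sorted(int(i) for i in rng.choice(n, size=n_out, replace=False))
            med = float(np.median(values))
            mad = float(np.median(np.abs(values - med)))
            if mad == 0:
                mad = sigma if sigma > 0 else 1.0
            sign = rng.choice([-1.0, 1.0], size=n_out)
            extra = rng.uniform(0.0, 2.0, size=n_out)
            values[idx] = med + sign * (spec.outlier_mads + extra) * mad
        out[name] = LabelledSample(
            name=name, truth=float(truth), values=values, outlier_indices=idx
        )
    return out


def generate_range_table(spec: SyntheticSpec) -> dict[str, CarbonDensityRange]:
    """The packaged density-range table, optionally perturbed.

    Perturbation scales each bound by an independent relative factor of
    magnitude ``range_perturbation``, clamps at zero, restores ordering,
    and never touches the water-body zero range.
    """
    ranges = load_default_ranges()
    if spec.range_perturbation == 0.0:
        return ranges
    rng = np.random.default_rng(spec.seed)
    out: dict[str, CarbonDensityRange] = {}
    for name, r in ranges.items():
        if name == WATER_BODY:
            out[name] = r
            continue
        lo = max(0.0, r.lower * (1.0 + rng.uniform(-1, 1) * spec.range_perturbation))
        hi = max(0.0, r.upper * (1.0 + rng.uniform(-1, 1) * spec.range_perturbation))
        lo, hi = min(lo, hi), max(lo, hi)
        out[name] = CarbonDensityRange(
            category=name, lower=lo, upper=hi, source=f"{r.source} (perturbed)"
        )
    return out
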