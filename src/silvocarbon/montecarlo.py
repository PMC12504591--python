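"""Monte Carlo uncertainty propagation for the silvoarable carbon model.

The model inputs are not known point values: each of the twelve biophysical
parameters is characterised by a range gathered from literature and
historical cadastral records. This module provides the machinery the
estimation pipeline needs around that fact:

* robust cleaning of literature samples (skewness-gated trimmed-mean /
  median-tolerance outlier filtering);
* simulation sizing from a pilot run via the Central Limit Theorem;
* seeded Monte Carlo propagation of parameter distributions through
  :func:`silvocarbon.silvoarable.silvoarable_cs`;
* summary statistics with an empirical-percentile confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateSampleError, FilterCollapseError
from .silvoarable import AllometryConfig, BiophysicalParams, PARAM_NAMES, silvoarable_cs

FAMILIES = ("uniform", "triangular", "empirical")


@dataclass
class ParameterDistribution:
    """Marginal distribution of one model input.

    Supported families: ``uniform`` on [lower, upper] (lower == upper gives
    a degenerate point mass), ``triangular`` with a mode inside the
    support, and ``empirical`` (resampling with replacement from supplied
    values). Parameters are sampled independently of one another.
    """

    name: str
    family: str = "uniform"
    lower: float = 0.0
    upper: float = 0.0
    mode: float | None = None
    values: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.name not in PARAM_NAMES:
            raise ConfigError(f"unknown parameter name {self.name!r}")
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if self.family == "empirical":
            if not self.values:
                raise ConfigError(f"{self.name}: empirical family needs values")
            self.values = [float(v) for v in self.values]
            self.lower = float(min(self.values))
            self.upper = float(max(self.values))
        if self.lower > self.upper:
            raise ConfigError(f"{self.name}: lower {self.lower} > upper {self.upper}")
        if self.family == "triangular":
            if self.mode is None:
                self.mode = 0.5 * (self.lower + self.upper)
            if not self.lower <= self.mode <= self.upper:
                raise ConfigError(f"{self.name}: mode {self.mode} outside support")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "empirical":
            return rng.choice(np.asarray(self.values, dtype=float), size=n, replace=True)
        if self.lower == self.upper:
            return np.full(n, self.lower)
        if self.family == "triangular":
            return rng.triangular(self.lower, self.mode, self.upper, size=n)
        return rng.uniform(self.lower, self.upper, size=n)

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Quantile transform of [0,1) points (for quasi-random designs)."""
        q = np.asarray(q, dtype=float)
        if self.family == "empirical":
            v = np.sort(np.asarray(self.values, dtype=float))
            return v[np.minimum((q * len(v)).astype(int), len(v) - 1)]
        if self.lower == self.upper:
            return np.full_like(q, self.lower)
        if self.family == "triangular":
            c = (self.mode - self.lower) / (self.upper - self.lower)
            return stats.triang.ppf(q, c, loc=self.lower, scale=self.upper - self.lower)
        return self.lower + q * (self.upper - self.lower)


def uniform(name: str, lower: float, upper: float) -> ParameterDistribution:
    return ParameterDistribution(name=name, family="uniform", lower=lower, upper=upper)


def point(name: str, value: float) -> ParameterDistribution:
    """Degenerate distribution: the parameter is held fixed."""
    return ParameterDistribution(name=name, family="uniform", lower=value, upper=value)


def default_distributions() -> dict[str, ParameterDistribution]:
    """Literature-plausible ranges for the historic mulberry–vine–wheat system.

    These are the package's documented surrogate inputs: mulberry rows at
    50–250 trees ha^-1 with mature trees of 7–11 m and 0.20–0.30 m DBH,
    hardwood density 0.52–0.68 t m^-3, root-to-shoot 0.20–0.30; wheat
    yields centred on the 1929 cadastral mean of 1.45 t ha^-1; vines at
    500–700 ha^-1 with 8–12 kg standing biomass each; and compartment soil
    organic carbon dominated by the tree rows (35–70 t C ha^-1). See
    docs/methods.md for the rationale per range.
    """
    d = [
        uniform("PH", 7.0, 11.0),
        uniform("DBH", 0.20, 0.30),
        uniform("RSt", 0.20, 0.30),
        point("TA", 0.0),
        uniform("TD", 50.0, 250.0),
        uniform("WD", 0.52, 0.68),
        uniform("WY", 1.20, 1.70),
        uniform("VD", 500.0, 700.0),
        uniform("BioV", 0.008, 0.012),
        uniform("SOCt", 35.0, 70.0),
        uniform("SOCw", 9.0, 11.0),
        uniform("SOCv", 4.0, 6.0),
    ]
    return {dist.name: dist for dist in d}


def skewness(sample: Sequence[float]) -> float:
    """Fisher–Pearson moment coefficient g1 = m3 / m2^(3/2)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise DegenerateSampleError(f"need at least 3 values, got {x.size}")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise DegenerateSampleError("zero-variance sample has undefined skewness")
    return float(stats.skew(x, bias=True))


@dataclass
class FilterReport:
    """What the outlier filter did: regime used, bounds, removed values."""

    method: str
    skewness: float
    lower: float
    upper: float
    removed: list[float] = field(default_factory=list)
    removed_indices: list[int] = field(default_factory=list)


def filter_outliers(
    sample: Sequence[float],
    skew_threshold: float = 1.0,
    k_sd: float = 3.0,
    k_mad: float = 3.0,
    trim_fraction: float = 0.1,
    mad_scale: float = 1.0,
    max_removed_fraction: float = 0.4,
    method: str = "auto",
) -> tuple[np.ndarray, FilterReport]:
    """Skewness-gated robust outlier filter.

    Near-symmetric samples (|g1| ≤ ``skew_threshold``) are cleaned with the
    trimmed-mean tolerance: keep values within trimmed_mean ± k_sd·sd,
    where both the centre and the sd are computed on the trimmed core
    (values inside the trim-fraction quantiles) so that the tolerance band
    itself is not inflated by the very outliers it is meant to reject; the
    core sd carries the truncated-normal consistency factor, so on clean
    Gaussian data the band equals the usual ±k_sd·σ.
    Skewed samples use the median tolerance: keep values within
    median ± k_mad·MAD (raw MAD by default; set ``mad_scale`` = 1.4826 for
    the normal-consistent estimate). The filter refuses to discard more
    than ``max_removed_fraction`` of the sample.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise DegenerateSampleError(f"need at least 5 values, got {x.size}")
    g1 = skewness(x)
    if method == "auto":
        method = "trimmed_mean" if abs(g1) <= skew_threshold else "median_mad"
    if method == "trimmed_mean":
        centre = stats.trim_mean(x, trim_fraction)
        qlo, qhi = np.quantile(x, [trim_fraction, 1.0 - trim_fraction])
        core = x[(x >= qlo) & (x <= qhi)]
        if core.size < 2:
            core = x
        # consistency factor: sd of a standard normal truncated to its
        # central (1 - 2·trim) mass, so the core sd estimates the full σ
        a = stats.norm.ppf(1.0 - trim_fraction)
        consistency = float(stats.truncnorm.std(-a, a)) if trim_fraction > 0 else 1.0
        spread = k_sd * float(np.std(core, ddof=1)) / consistency
    elif method == "median_mad":
        med = float(np.median(x))
        mad = mad_scale * float(np.median(np.abs(x - med)))
        centre, spread = med, k_mad * mad
    else:
        raise ConfigError(f"unknown filter method {method!r}")
    lower, upper = centre - spread, centre + spread
    keep = (x >= lower) & (x <= upper)
    if not keep.any():
        raise FilterCollapseError("outlier filter removed every value")
    removed_frac = 1.0 - keep.mean()
    if removed_frac > max_removed_fraction:
        raise FilterCollapseError(
            f"outlier filter would remove {removed_frac:.0%} of the sample "
            f"(limit {max_removed_fraction:.0%})"
        )
    report = FilterReport(
        method=method,
        skewness=g1,
        lower=float(lower),
        upper=float(upper),
        removed=[float(v) for v in x[~keep]],
        removed_indices=[int(i) for i in np.flatnonzero(~keep)],
    )
    return x[keep], report


@dataclass
class SamplingPlan:
    """CLT-based sizing of a Monte Carlo run.

    The realization count needed for the sample mean to sit within
    ``margin_of_error`` of the true mean at the given confidence is
    n = (z · sd / margin)², estimated from a pilot run's sd and clamped to
    [n_min, n_max].
    """

    pilot_n: int = 1000
    margin_of_error: float = 0.5
    confidence: float = 0.95
    n_min: int = 10_000
    n_max: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ConfigError(f"confidence must be in (0,1), got {self.confidence}")
        if self.margin_of_error <= 0:
            raise ConfigError(f"margin_of_error must be positive, got {self.margin_of_error}")
        if self.n_min > self.n_max:
            raise ConfigError(f"n_min {self.n_min} > n_max {self.n_max}")


def clt_sample_size(sd_pilot: float, plan: SamplingPlan) -> int:
    """Realizations needed for the plan's margin of error, clamped."""
    if sd_pilot < 0:
        raise ConfigError(f"sd_pilot must be non-negative, got {sd_pilot}")
    z = stats.norm.ppf(0.5 * (1.0 + plan.confidence))
    n = math.ceil((z * sd_pilot / plan.margin_of_error) ** 2)
    return int(min(max(n, plan.n_min), plan.n_max))


def _as_dist_map(
    dists: Mapping[str, ParameterDistribution] | Iterable[ParameterDistribution],
) -> dict[str, ParameterDistribution]:
    if isinstance(dists, Mapping):
        out = dict(dists)
    else:
        out = {d.name: d for d in dists}
    for name, d in out.items():
        if name != d.name:
            raise ConfigError(f"distribution map key {name!r} != name {d.name!r}")
    return out


def draw_parameters(
    dists: Mapping[str, ParameterDistribution] | Iterable[ParameterDistribution],
    n: int,
    rng: np.random.Generator,
) -> BiophysicalParams:
    """n joint draws of the twelve inputs (missing ones fixed at 0)."""
    dmap = _as_dist_map(dists)
    missing = [p for p in PARAM_NAMES if p not in dmap]
    if missing:
        warnings.warn(f"parameters fixed at 0 (no distribution given): {missing}",
                      stacklevel=2)
    draws = {
        name: dmap[name].sample(n, rng) if name in dmap else np.zeros(n)
        for name in PARAM_NAMES
    }
    return BiophysicalParams(**draws)


def run_monte_carlo(
    dists: Mapping[str, ParameterDistribution] | Iterable[ParameterDistribution],
    cfg: AllometryConfig | None = None,
    n: int = 100_000,
    seed: int | None = None,
) -> np.ndarray:
    """n independent carbon-stock realizations, t C ha^-1.

    Each realization draws all twelve parameters independently from their
    declared distributions and evaluates the silvoarable model once; the
    run is reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    params = draw_parameters(dists, n, rng)
    return np.asarray(silvoarable_cs(params, cfg).total, dtype=float)


@dataclass
class SummaryStats:
    """Distributional summary of a carbon-stock sample (t C ha^-1)."""

    min: float
    mean: float
    median: float
    max: float
    sd: float
    ci_lower: float
    ci_upper: float
    n: int
    ci_level: float

    def to_dict(self) -> dict[str, float]:
        return {
            "Min": self.min,
            "Mean": self.mean,
            "Median": self.median,
            "Max": self.max,
            "Standard Deviation": self.sd,
            f"{self.ci_level:.0%} CI Lower": self.ci_lower,
            f"{self.ci_level:.0%} CI Upper": self.ci_upper,
        }


def summarize(sample: Sequence[float], ci_level: float = 0.95) -> SummaryStats:
    """Min/mean/median/max/sd and an empirical-percentile CI.

    The CI is the (α/2, 1−α/2) quantile pair of the sample itself — a
    distribution interval, wider than a standard error band — with the sd
    using the n−1 denominator.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise DegenerateSampleError(f"need at least 2 values, got {x.size}")
    if not 0 < ci_level < 1:
        raise ConfigError(f"ci_level must be in (0,1), got {ci_level}")
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(x, [alpha / 2.0, 1.0 - alpha / 2.0])
    return SummaryStats(
        min=float(x.min()),
        mean=float(x.mean()),
        median=float(np.median(x)),
        max=float(x.max()),
        sd=float(np.std(x, ddof=1)),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n=int(x.size),
        ci_level=float(ci_level),
    )
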