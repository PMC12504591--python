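"""Variance-based (Sobol) global sensitivity analysis.

Decomposes the variance of the silvoarable carbon stock into contributions
of the twelve biophysical inputs. First-order indices S1_i = V_i / V(Y)
measure the direct effect of input i; total-order indices
ST_i = 1 − V_~i / V(Y) add every interaction involving i; second-order
indices S2_ij isolate pairwise interactions.

Estimation uses the radial (Saltelli) design: two independent base
matrices A and B of shape (N, k) and, per input i, the hybrid matrix AB_i
equal to A with column i taken from B — N·(k+2) model runs for S1/ST, or
N·(2k+2) with the mirrored BA_i matrices when second-order indices are
requested. Base points come from a scrambled Sobol sequence (seeded), and
the estimators are Saltelli-2010 for S1, Jansen for ST:

    S1_i = mean(Y_B · (Y_ABi − Y_A)) / V(Y)
    ST_i = mean((Y_A − Y_ABi)²) / (2 V(Y))

Small negative estimates are statistical noise and are reported as-is; a
clipped view is available for presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import ConfigError, ZeroVarianceError
from .montecarlo import ParameterDistribution, _as_dist_map, default_distributions
from .silvoarable import AllometryConfig, BiophysicalParams, PARAM_NAMES, silvoarable_cs

#: Reporting tolerance on index estimates: values in [-CLIP_EPS, 1+CLIP_EPS]
#: are treated as estimator noise around the [0, 1] theoretical range.
CLIP_EPS = 0.05


class _Uniform:
    """Bare uniform marginal for generic (non-carbon-model) analyses."""

    def __init__(self, lower: float, upper: float):
        if lower > upper:
            raise ConfigError(f"lower {lower} > upper {upper}")
        self.lower, self.upper = float(lower), float(upper)

    def ppf(self, q: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(q, dtype=float) * (self.upper - self.lower)


def _normalise_dists(dists) -> tuple[list[str], list]:
    """Accept a dist map, a dist sequence, or (lower, upper) tuples."""
    if isinstance(dists, Mapping):
        return list(dists.keys()), list(dists.values())
    names, margs = [], []
    for i, d in enumerate(dists):
        if isinstance(d, tuple):
            names.append(f"x{i + 1}")
            margs.append(_Uniform(*d))
        else:
            names.append(getattr(d, "name", f"x{i + 1}"))
            margs.append(d)
    return names, margs


@dataclass
class SaltelliDesign:
    """The evaluation points of a radial Sobol design."""

    names: list[str]
    A: np.ndarray          # (N, k)
    B: np.ndarray          # (N, k)
    AB: np.ndarray         # (k, N, k); AB[i] is A with column i from B
    BA: np.ndarray | None  # (k, N, k) when second-order requested

    @property
    def base_n(self) -> int:
        return self.A.shape[0]

    @property
    def k(self) -> int:
        return self.A.shape[1]

    @property
    def n_evaluations(self) -> int:
        extra = self.k if self.BA is not None else 0
        return self.base_n * (self.k + 2 + extra)

    def evaluate(self, func: Callable[[np.ndarray], np.ndarray]):
        """Run ``func`` (vectorised over rows) on every design point."""
        y_a = np.asarray(func(self.A), dtype=float)
        y_b = np.asarray(func(self.B), dtype=float)
        y_ab = np.stack([np.asarray(func(self.AB[i]), dtype=float) for i in range(self.k)])
        y_ba = None
        if self.BA is not None:
            y_ba = np.stack([np.asarray(func(self.BA[i]), dtype=float) for i in range(self.k)])
        return y_a, y_b, y_ab, y_ba


def saltelli_design(
    dists,
    base_n: int,
    seed: int | None = None,
    with_second_order: bool = False,
) -> SaltelliDesign:
    """Build the A/B/AB_i (and optionally BA_i) matrices.

    ``dists`` may be a name→distribution mapping, a sequence of
    distributions, or a sequence of (lower, upper) tuples for plain
    uniform inputs. Points are a scrambled Sobol sequence transformed
    through each marginal's quantile function; the same seed reproduces
    the same design.
    """
    if base_n < 2:
        raise ConfigError(f"base_n must be at least 2, got {base_n}")
    names, margs = _normalise_dists(dists)
    k = len(names)
    if k < 1:
        raise ConfigError("need at least one input")
    with warnings.catch_warnings():
        # base_n that is not a power of two is allowed, at some loss of
        # balance in the Sobol sequence
        warnings.simplefilter("ignore", UserWarning)
        sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
        u = sampler.random(base_n)
    A = np.column_stack([margs[j].ppf(u[:, j]) for j in range(k)])
    B = np.column_stack([margs[j].ppf(u[:, k + j]) for j in range(k)])
    AB = np.repeat(A[None, :, :], k, axis=0)
    for i in range(k):
        AB[i, :, i] = B[:, i]
    BA = None
    if with_second_order:
        BA = np.repeat(B[None, :, :], k, axis=0)
        for i in range(k):
            BA[i, :, i] = A[:, i]
    return SaltelliDesign(names=names, A=A, B=B, AB=AB, BA=BA)


def _output_variance(y_a: np.ndarray, y_b: np.ndarray) -> float:
    v = float(np.var(np.concatenate([y_a, y_b])))
    if v <= 0:
        raise ZeroVarianceError("model output has zero variance")
    return v


def estimate_first_order(
    y_a: np.ndarray, y_b: np.ndarray, y_ab: np.ndarray
) -> np.ndarray:
    """Saltelli-2010 first-order estimator, one value per input."""
    y_a, y_b, y_ab = (np.asarray(v, dtype=float) for v in (y_a, y_b, y_ab))
    v = _output_variance(y_a, y_b)
    return np.mean(y_b[None, :] * (y_ab - y_a[None, :]), axis=1) / v


def estimate_total_order(
    y_a: np.ndarray, y_b: np.ndarray, y_ab: np.ndarray
) -> np.ndarray:
    """Jansen total-order estimator, one value per input."""
    y_a, y_b, y_ab = (np.asarray(v, dtype=float) for v in (y_a, y_b, y_ab))
    v = _output_variance(y_a, y_b)
    return 0.5 * np.mean((y_a[None, :] - y_ab) ** 2, axis=1) / v


def estimate_second_order(
    y_a: np.ndarray,
    y_b: np.ndarray,
    y_ab: np.ndarray,
    y_ba: np.ndarray,
    s1: np.ndarray,
) -> dict[tuple[int, int], float]:
    """Pairwise interaction indices S2_ij (i < j)."""
    v = _output_variance(y_a, y_b)
    k = y_ab.shape[0]
    out: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            vij = np.mean(y_ba[i] * y_ab[j] - y_a * y_b) / v
            out[(i, j)] = float(vij - s1[i] - s1[j])
    return out


@dataclass
class SensitivityResult:
    """Per-input sensitivity indices for one analysis run."""

    names: list[str]
    S1: np.ndarray
    ST: np.ndarray
    S2: dict[tuple[str, str], float] | None
    base_n: int
    estimator: str
    variance: float

    def clipped(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices clipped to [0, 1] for presentation."""
        return np.clip(self.S1, 0.0, 1.0), np.clip(self.ST, 0.0, 1.0)

    def ranking(self) -> list[str]:
        """Input names ordered by decreasing total-order index."""
        return [self.names[i] for i in np.argsort(self.ST)[::-1]]

    def to_frame(self) -> pd.DataFrame:
        s1c, stc = self.clipped()
        return pd.DataFrame(
            {"variable": self.names, "S1": self.S1, "ST": self.ST,
             "S1_clipped": s1c, "ST_clipped": stc}
        )

    def second_order_frame(self) -> pd.DataFrame:
        if self.S2 is None:
            raise ConfigError("second-order indices were not computed")
        rows = [
            {"variable_i": i, "variable_j": j, "S2": v}
            for (i, j), v in self.S2.items()
        ]
        return pd.DataFrame(rows, columns=["variable_i", "variable_j", "S2"])


def analyse(
    dists,
    func: Callable[[np.ndarray], np.ndarray],
    base_n: int,
    seed: int | None = None,
    with_second_order: bool = False,
) -> SensitivityResult:
    """Design + evaluate + estimate for an arbitrary row-vectorised model."""
    design = saltelli_design(dists, base_n, seed, with_second_order)
    y_a, y_b, y_ab, y_ba = design.evaluate(func)
    s1 = estimate_first_order(y_a, y_b, y_ab)
    st = estimate_total_order(y_a, y_b, y_ab)
    s2 = None
    if y_ba is not None:
        pair = estimate_second_order(y_a, y_b, y_ab, y_ba, s1)
        s2 = {
            (design.names[i], design.names[j]): v for (i, j), v in pair.items()
        }
    return SensitivityResult(
        names=design.names,
        S1=s1,
        ST=st,
        S2=s2,
        base_n=base_n,
        estimator="Saltelli-2010 (S1) / Jansen (ST)",
        variance=_output_variance(y_a, y_b),
    )


def run_sobol(
    dists: Mapping[str, ParameterDistribution] | Sequence[ParameterDistribution] | None = None,
    cfg: AllometryConfig | None = None,
    base_n: int = 4096,
    seed: int | None = None,
    with_second_order: bool = False,
) -> SensitivityResult:
    """End-to-end sensitivity analysis of the silvoarable carbon model.

    All twelve inputs are analysed in their canonical order; inputs without
    a declared distribution are held at 0 (and therefore come out inert).
    Defaults to the package's documented surrogate ranges.
    """
    dmap = _as_dist_map(dists) if dists is not None else default_distributions()
    from .montecarlo import point

    full = {
        name: dmap.get(name, point(name, 0.0)) for name in PARAM_NAMES
    }
    cfg = cfg or AllometryConfig()

    def model(x: np.ndarray) -> np.ndarray:
        params = BiophysicalParams(
            **{name: x[:, j] for j, name in enumerate(PARAM_NAMES)}
        )
        return np.asarray(silvoarable_cs(params, cfg).total, dtype=float)

    return analyse(full, model, base_n=base_n, seed=seed,
                   with_second_order=with_second_order)
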