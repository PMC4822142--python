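"""Shannon entropy of expression distributions and the simulated entropy curve.

Two entropies play complementary roles:

* *Sample entropy* -- the Shannon entropy of the histogram of one sample's
  expression values over the low-information-ratio gene universe,
  ``H = -sum_b p_b log p_b``.  It quantifies disorder / lack of
  co-regulation of a transcriptome snapshot.
* *Mixing entropy* -- the Shannon entropy of the 2K-population weight
  vector of the compartment model.  It is maximal when healthy and
  leukemic cell populations are most heterogeneous.

The model-side ("simulated") entropy curve is built by drawing a random
per-population expression matrix (one row per healthy and CML compartment,
one column per gene), collapsing it with the time-dependent population
weights into a virtual bulk sample, and scoring that sample's entropy at
every day of the disease window.  The curve is high while a single
population dominates, dips to a singular minimum at maximal population
mixing (the averaging narrows the value distribution), and recovers as the
leukemic clone takes over -- the minimum marks the critical transition
used as the T1/T2 boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .popmodel import (
    ModelParams,
    TrajectorySeries,
    cd34_ratio,
    population_fraction_matrix,
    simulate_trajectories,
)

__all__ = [
    "EntropyConfig",
    "SGEM",
    "SimulatedEntropyCurve",
    "EntropyMinimum",
    "DegenerateRangeWarning",
    "sample_entropy",
    "matrix_entropy",
    "generate_sgem",
    "simulated_entropy_curve",
    "mixing_entropy_curve",
    "find_entropy_minimum",
    "simulated_entropy_minimum",
]


class DegenerateRangeWarning(UserWarning):
    """All values identical under per-sample range binning."""


@dataclass(frozen=True)
class EntropyConfig:
    """Histogram estimator settings for sample entropy.

    ``n_bins`` equal-width bins are spread over the binning range; with
    ``binning_range=None`` (default) the per-sample min-max range is used,
    otherwise a fixed global ``(lo, hi)`` tuple.  ``log_base`` is ``"e"``
    (nats) or ``2`` (bits).
    """

    n_bins: int = 64
    log_base: float | str = "e"
    binning_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.log_base not in ("e", 2, 2.0):
            raise ValueError("log_base must be 'e' or 2")

    @property
    def log(self):
        return np.log if self.log_base == "e" else np.log2


def _discrete_entropy(probs: np.ndarray, log) -> float:
    nz = probs[probs > 0]
    return float(-(nz * log(nz)).sum())


def sample_entropy(values, config: EntropyConfig | None = None) -> float:
    """Shannon entropy of one sample's expression value distribution.

    Empty bins contribute zero.  A degenerate sample (all values equal)
    yields ``H = 0`` with a :class:`DegenerateRangeWarning`.
    """
    cfg = config or EntropyConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < cfg.n_bins:
        raise ValueError(
            f"need at least n_bins={cfg.n_bins} finite values, got {x.size}"
        )
    rng = cfg.binning_range or (float(x.min()), float(x.max()))
    if rng[0] == rng[1]:
        warnings.warn(
            "degenerate value range; entropy is 0 by convention",
            DegenerateRangeWarning,
            stacklevel=2,
        )
        return 0.0
    counts, _ = np.histogram(x, bins=cfg.n_bins, range=rng)
    return _discrete_entropy(counts / counts.sum(), cfg.log)


def matrix_entropy(matrix: np.ndarray, config: EntropyConfig | None = None) -> np.ndarray:
    """Row-wise :func:`sample_entropy` of a (samples x genes) array."""
    cfg = config or EntropyConfig()
    return np.array([sample_entropy(row, cfg) for row in np.asarray(matrix, float)])


@dataclass
class SGEM:
    """Randomly simulated gene expression matrix.

    One row per (lineage, compartment) population -- 64 rows for the
    default 32-compartment model -- and one column per gene of the
    low-information-ratio universe.
    """

    values: np.ndarray
    rng_seed: int
    gene_ids: list[str] = field(default_factory=list)
    distribution: str = "uniform"

    @property
    def n_populations(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def generate_sgem(
    gene_list: Sequence[str] | int,
    rng_seed: int,
    n_rows: int = 64,
    distribution: str = "uniform",
) -> SGEM:
    """Draw a random per-population expression matrix.

    ``gene_list`` may be the gene identifiers themselves or just their
    count.  Entries are i.i.d. uniform on [0, 1] by default; a
    ``"lognormal"`` alternative (mu=0, sigma=1) is offered to probe the
    robustness of the entropy-curve shape to the distributional choice.
    """
    if isinstance(gene_list, (int, np.integer)):
        gene_ids = [f"G{i + 1:05d}" for i in range(int(gene_list))]
    else:
        gene_ids = [str(g) for g in gene_list]
    if not gene_ids:
        raise ValueError("gene list must be nonempty")
    rng = np.random.default_rng(rng_seed)
    shape = (n_rows, len(gene_ids))
    if distribution == "uniform":
        values = rng.random(shape)
    elif distribution == "lognormal":
        values = rng.lognormal(mean=0.0, sigma=1.0, size=shape)
    else:
        raise ValueError(f"unknown SGEM distribution {distribution!r}")
    return SGEM(values=values, rng_seed=int(rng_seed), gene_ids=gene_ids,
                distribution=distribution)


@dataclass
class SimulatedEntropyCurve:
    """Model-side entropy, mixing entropy and CD34 ratio per time point."""

    times: np.ndarray
    entropy: np.ndarray
    mixing_entropy: np.ndarray
    cd34_ratio: np.ndarray
    config: EntropyConfig = field(default_factory=EntropyConfig, repr=False)

    def __post_init__(self) -> None:
        n = self.times.size
        if not (self.entropy.size == self.mixing_entropy.size == self.cd34_ratio.size == n):
            raise ValueError("curve components must share one time grid")

    def normalized_cd34(self) -> np.ndarray:
        lo, hi = self.cd34_ratio.min(), self.cd34_ratio.max()
        return (self.cd34_ratio - lo) / (hi - lo)

    def normalized_entropy(self) -> np.ndarray:
        lo, hi = self.entropy.min(), self.entropy.max()
        return (self.entropy - lo) / (hi - lo)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "simulated_entropy": self.entropy,
                "mixing_entropy": self.mixing_entropy,
                "cd34_ratio": self.cd34_ratio,
            }
        )


def mixing_entropy_curve(
    traj: TrajectorySeries, log_base: float | str = "e"
) -> np.ndarray:
    """Entropy of the population weight vector at every grid time."""
    log = np.log if log_base == "e" else np.log2
    weights = population_fraction_matrix(traj)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(weights > 0, weights * log(weights), 0.0)
    return -terms.sum(axis=1)


def simulated_entropy_curve(
    sgem: SGEM,
    traj: TrajectorySeries,
    config: EntropyConfig | None = None,
) -> SimulatedEntropyCurve:
    """Entropy of the population-weighted SGEM mixture over disease time.

    At each day the virtual bulk expression is
    ``m_g(t) = sum_c w_c(t) * SGEM[c, g]`` with ``w`` the population
    fractions; its sample entropy gives ``s_t``.
    """
    cfg = config or EntropyConfig()
    weights = population_fraction_matrix(traj)
    if weights.shape[1] != sgem.n_populations:
        raise ValueError(
            f"SGEM has {sgem.n_populations} populations but the trajectory "
            f"has {weights.shape[1]} (= 2 x n_compartments)"
        )
    mixture = weights @ sgem.values
    entropy = matrix_entropy(mixture, cfg)
    mixing = mixing_entropy_curve(traj, cfg.log_base)
    ratio = cd34_ratio(traj).ratio
    return SimulatedEntropyCurve(
        times=traj.times,
        entropy=entropy,
        mixing_entropy=mixing,
        cd34_ratio=ratio,
        config=cfg,
    )


@dataclass
class EntropyMinimum:
    """Location of the (smoothed) entropy minimum."""

    t_min: float
    value: float
    boundary: bool  # True when the argmin sits on the window edge
    per_seed_t_min: list[float] = field(default_factory=list)


def _smooth(values: np.ndarray, window: int) -> tuple[np.ndarray, int]:
    """Centered moving average; returns (smoothed interior, left offset)."""
    if window <= 1:
        return values, 0
    if window % 2 == 0:
        raise ValueError("smoothing_window must be odd")
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(values, kernel, mode="valid")
    return smoothed, window // 2


def find_entropy_minimum(
    curve: SimulatedEntropyCurve | np.ndarray,
    times: np.ndarray | None = None,
    smoothing_window: int = 11,
) -> EntropyMinimum:
    """Argmin of the (optionally smoothed) entropy curve.

    A minimum on the window boundary is flagged as non-singular rather
    than treated as a transition point; a flat curve raises.
    """
    if isinstance(curve, SimulatedEntropyCurve):
        values, times = curve.entropy, curve.times
    else:
        values = np.asarray(curve, dtype=float)
        if times is None:
            raise ValueError("times required when passing a bare entropy array")
    if values.size < 3:
        raise ValueError("need at least 3 time points")
    if np.ptp(values) == 0:
        raise ValueError("flat entropy curve: no singular minimum")
    smoothed, offset = _smooth(values, smoothing_window)
    idx = int(np.argmin(smoothed)) + offset
    boundary = idx <= offset or idx >= values.size - 1 - offset
    return EntropyMinimum(
        t_min=float(times[idx]), value=float(values[idx]), boundary=boundary
    )


def simulated_entropy_minimum(
    params: ModelParams,
    n_seeds: int = 10,
    base_seed: int = 0,
    config: EntropyConfig | None = None,
    smoothing_window: int = 11,
    trajectory: TrajectorySeries | None = None,
    gene_list: Sequence[str] | int = 6384,
) -> EntropyMinimum:
    """Entropy-minimum time averaged over several SGEM seeds.

    A single random SGEM makes the argmin noisy; averaging the per-seed
    (smoothed) argmins over ``n_seeds`` independent matrices stabilizes
    the boundary estimate.  Seeds are spawned deterministically from
    ``base_seed``.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    cfg = config or EntropyConfig()
    traj = trajectory or simulate_trajectories(params)
    seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31)
    per_seed = []
    boundary_any = False
    value_at = []
    for s in seeds:
        sgem = generate_sgem(gene_list, int(s), n_rows=2 * params.n_compartments)
        curve = simulated_entropy_curve(sgem, traj, cfg)
        m = find_entropy_minimum(curve, smoothing_window=smoothing_window)
        per_seed.append(m.t_min)
        value_at.append(m.value)
        boundary_any = boundary_any or m.boundary
    return EntropyMinimum(
        t_min=float(np.mean(per_seed)),
        value=float(np.mean(value_at)),
        boundary=boundary_any,
        per_seed_t_min=[float(t) for t in per_seed],
    )
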