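"""Synthetic compositional count data with known ground truth.

Each sample row is drawn Multinomial(ybar, p) where p = softmax(z) and
z ~ MVN(mu_group, cov_scale * I_K).  The diagonal covariance 0.05 * I
mimics the sample-to-sample variability seen in intestinal epithelium
cell-count data while assuming no correlation between cell types beyond
the compositional closure itself.

Two mean-vector layouts are supported:

* single-effect ("power" layout): the first cell type has mean count mu0 in
  controls and mu0 + effect in cases; all other types share the remaining
  mass equally.
* two-effect ("comparison" layout): all K types have mean count 1000 in
  controls; cases add (effect_1, effect_2) to the first two types and the
  remaining types share the rest.

The generator also produces heterogeneous response groups, where only a
fraction of the case samples actually follow the case distribution while
all of them keep the case label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datacore import CompositionalDataset

__all__ = [
    "SimulationConfig",
    "GridSpec",
    "build_mean_vector",
    "comparison_grid",
    "generate_dataset",
    "generate_heterogeneous",
    "expand_grid",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one synthetic dataset.

    ``effect`` is a scalar (single-effect layout, added to the first cell
    type) or a pair (two-effect layout, added to the first two cell types).
    ``response_fraction`` < 1 makes only that fraction of case samples
    responders; the rest are drawn from the control distribution.
    """

    n_cell_types: int
    n_control: int
    n_case: int
    total: int
    base_count: float = 1000.0
    effect: float | tuple = 1000.0
    covariance_scale: float = 0.05
    response_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.base_count <= 0:
            raise ValueError("base_count must be positive")
        if not (0 < self.response_fraction <= 1):
            raise ValueError("response_fraction must lie in (0, 1]")
        if self.covariance_scale < 0:
            raise ValueError("covariance_scale must be nonnegative")

    @property
    def effects(self) -> tuple:
        e = self.effect
        return tuple(e) if np.ndim(e) else (float(e),)

    @property
    def truth_mask(self) -> np.ndarray:
        """Boolean mask over cell types: True where a nonzero effect applies."""
        mask = np.zeros(self.n_cell_types, dtype=bool)
        for j, e in enumerate(self.effects):
            mask[j] = e != 0
        return mask


@dataclass(frozen=True)
class GridSpec:
    """Cartesian grid of simulation settings with r replicates per cell."""

    n_cell_types: tuple = (5,)
    group_sizes: tuple = (5,)          # balanced n_control = n_case values
    total: int | None = None           # None -> K * 1000 per the grid's K
    base_counts: tuple = (1000.0,)
    effects: tuple = (1000.0,)
    covariance_scale: float = 0.05
    response_fractions: tuple = (1.0,)
    replicates: int = 20
    master_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def comparison_grid(replicates: int = 20, master_seed: int = 0) -> GridSpec:
    """The two-effect benchmark grid: K in {5,10,15}, n per group in 1..5,
    ybar = 1000 K, six effect pairs, r replicates per combination."""
    return GridSpec(
        n_cell_types=(5, 10, 15),
        group_sizes=(1, 2, 3, 4, 5),
        total=None,
        base_counts=(1000.0,),
        effects=((0, 500), (0, 1000), (0, 2000), (500, 1000), (500, 2000), (1000, 2000)),
        replicates=replicates,
        master_seed=master_seed,
    )


def build_mean_vector(config: SimulationConfig, group: str) -> np.ndarray:
    """Log-mean vector mu of the latent MVN for one group.

    Single effect: controls get log(mu0, (ybar-mu0)/(K-1), ...); cases get
    log(mu0+e, (ybar-(mu0+e))/(K-1), ...).  Two effects: controls get
    log(1000, ..., 1000) scaled by base_count; cases add (e1, e2) to the
    first two types with the rest sharing (K*b - (2b+e1+e2))/(K-2).
    """
    if group not in ("control", "case"):
        raise ValueError("group must be 'control' or 'case'")
    k = config.n_cell_types
    b = config.base_count
    effects = config.effects
    if len(effects) == 1:
        ybar = float(config.total)
        first = b + (effects[0] if group == "case" else 0.0)
        rest = (ybar - first) / (k - 1)
        if first <= 0 or rest <= 0:
            raise ValueError(
                f"nonpositive mean count (first={first}, rest={rest}); "
                "effect too large for the total"
            )
        mu = np.full(k, np.log(rest))
        mu[0] = np.log(first)
        return mu
    if len(effects) == 2:
        if k < 3:
            raise ValueError("two-effect layout needs at least 3 cell types")
        e1, e2 = (effects if group == "case" else (0.0, 0.0))
        rest = (k * b - (2 * b + e1 + e2)) / (k - 2)
        if b + e1 <= 0 or b + e2 <= 0 or rest <= 0:
            raise ValueError("nonpositive mean count in two-effect layout")
        mu = np.full(k, np.log(rest))
        mu[0] = np.log(b + e1)
        mu[1] = np.log(b + e2)
        return mu
    raise ValueError("effect must be a scalar or a pair")


def _sample_rows(n: int, mu: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    k = config.n_cell_types
    out = np.empty((n, k), dtype=float)
    scale = np.sqrt(config.covariance_scale)
    for i in range(n):
        z = mu + scale * rng.standard_normal(k)
        z = z - z.max()
        p = np.exp(z)
        p /= p.sum()
        out[i] = rng.multinomial(int(config.total), p)
    return out


def _assemble(counts: np.ndarray, config: SimulationConfig) -> CompositionalDataset:
    n0, n1 = config.n_control, config.n_case
    sample_ids = [f"control_{i}" for i in range(n0)] + [f"case_{i}" for i in range(n1)]
    cell_types = [f"cell_type_{j}" for j in range(config.n_cell_types)]
    condition = ["control"] * n0 + ["case"] * n1
    metadata = pd.DataFrame({"condition": condition}, index=pd.Index(sample_ids, name="sample_id"))
    covariates = np.array([0.0] * n0 + [1.0] * n1)[:, None]
    return CompositionalDataset(
        counts=counts, sample_ids=sample_ids, cell_types=cell_types,
        metadata=metadata, covariates=covariates, covariate_names=["condition"],
    )


def generate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None):
    """Generate one case-control dataset; returns (dataset, truth mask).

    The truth mask marks the cell types whose latent mean was changed in the
    case group (nonzero effect entries).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu0 = build_mean_vector(config, "control")
    mu1 = build_mean_vector(config, "case")
    counts = np.vstack([
        _sample_rows(config.n_control, mu0, config, rng),
        _sample_rows(config.n_case, mu1, config, rng),
    ])
    return _assemble(counts, config), config.truth_mask


def generate_heterogeneous(config: SimulationConfig,
                           rng: np.random.Generator | None = None):
    """Case group with a partial response; returns (dataset, truth mask).

    round(response_fraction * n_case) case samples follow the case
    distribution; the rest follow the control distribution but keep the case
    covariate label.  With response_fraction = 1 this reduces exactly to
    :func:`generate_dataset`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu0 = build_mean_vector(config, "control")
    mu1 = build_mean_vector(config, "case")
    n_resp = int(round(config.response_fraction * config.n_case))
    counts = np.vstack([
        _sample_rows(config.n_control, mu0, config, rng),
        _sample_rows(n_resp, mu1, config, rng),
        _sample_rows(config.n_case - n_resp, mu0, config, rng),
    ])
    return _assemble(counts, config), config.truth_mask


def expand_grid(grid: GridSpec) -> list[SimulationConfig]:
    """All grid combinations x replicates, with deterministic per-dataset seeds.

    Seeds derive from (master seed, combination index, replicate index) via a
    counter-based SeedSequence, so the assignment does not depend on
    execution order.
    """
    combos = list(itertools.product(
        grid.n_cell_types, grid.group_sizes, grid.base_counts,
        grid.effects, grid.response_fractions,
    ))
    configs = []
    for ci, (k, n, b, eff, rf) in enumerate(combos):
        for r in range(grid.replicates):
            seed = int(
                np.random.SeedSequence([grid.master_seed, ci, r]).generate_state(1)[0]
                % (2 ** 31)
            )
            configs.append(SimulationConfig(
                n_cell_types=k,
                n_control=n,
                n_case=n,
                total=(k * 1000 if grid.total is None else grid.total),
                base_count=b,
                effect=eff,
                covariance_scale=grid.covariance_scale,
                response_fraction=rf,
                seed=seed,
            ))
    return configs
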