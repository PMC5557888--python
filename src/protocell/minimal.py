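"""Minimal hierarchical Moran process for functional symmetry breaking.

Replicators carry two cooperativity values (k1, k2) and live in protocells
that divide binomially once they exceed V members.  Each time step one
replicator reproduces with probability proportional to its fitness

    f = exp(kbar1 + kbar2 - r (k1 + k2)),

where kbar_i are the averages over the replicator's protocell and r is the
relative cost of cooperation (0 < r < 1), and one replicator dies uniformly
at random, keeping the total population size constant.  Protocell means
reward cooperative compartments; the -r(k1+k2) term makes cooperation
individually costly, so the two selection levels conflict.

Two variance modes control how mutational variance in f behaves near k = 0:

* ``rectified`` (default): every k entering f is clamped at 0 from below, so
  df/dk_i = 0 for k_i < 0 and the mutational variance of f collapses as a
  trait pins to the boundary.  This is the regime in which functional
  symmetry breaking (|k1 - k2| asymmetry -> 1) can occur.
* ``invariant``: no clamping and no bounds, so the mutational variance of f
  is independent of where (k1, k2) sits; no symmetry breaking is expected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K

__all__ = [
    "MinimalParams",
    "MinimalPopulation",
    "fitness_minimal",
    "moran_step",
    "run_minimal",
    "asymmetry_index",
]


@dataclass
class MinimalParams:
    """Parameters of the minimal model."""

    V: int = 300
    n_total: int = 3000
    r: float = 0.3
    m: float = 0.1
    delta: float = 0.2
    variance_mode: str = "rectified"   # or "invariant"
    k_upper: float | None = 1.0
    death_within_cell: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError(f"r must lie in (0, 1), got {self.r}")
        if self.variance_mode not in ("rectified", "invariant"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")
        if self.V < 1:
            raise ValueError("V must be >= 1")
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")

    @property
    def rectified(self) -> bool:
        return self.variance_mode == "rectified"

    @property
    def k_upper_value(self) -> float:
        return np.inf if self.k_upper is None else self.k_upper


@dataclass
class MinimalPopulation:
    """Population arrays: per-replicator (k1, k2) and protocell ids."""

    k1: np.ndarray
    k2: np.ndarray
    cell: np.ndarray

    @classmethod
    def initial(cls, params: MinimalParams, k0: float = 1.0,
                k0_pair: tuple[float, float] | None = None) -> "MinimalPopulation":
        n = params.n_total
        if k0_pair is None:
            k0_pair = (k0, k0)
        n_cells = max(1, 2 * n // max(params.V, 1))
        cell = np.arange(n) % n_cells
        return cls(k1=np.full(n, float(k0_pair[0])),
                   k2=np.full(n, float(k0_pair[1])),
                   cell=np.sort(cell).astype(np.int64))

    @property
    def n(self) -> int:
        return self.k1.shape[0]

    @property
    def n_cells(self) -> int:
        return int(np.unique(self.cell).size)

    def cell_means(self, c: int) -> tuple[float, float]:
        sel = self.cell == c
        return float(self.k1[sel].mean()), float(self.k2[sel].mean())


def fitness_minimal(k1: float, k2: float, kbar1: float, kbar2: float,
                    params: MinimalParams) -> float:
    """Fitness exp(kbar1 + kbar2 - r(k1 + k2)); in rectified mode every k
    entering f is clamped at 0 from below (so a negative k behaves exactly
    like 0)."""
    if params.rectified:
        k1, k2 = max(k1, 0.0), max(k2, 0.0)
        kbar1, kbar2 = max(kbar1, 0.0), max(kbar2, 0.0)
    return float(np.exp(kbar1 + kbar2 - params.r * (k1 + k2)))


def _population_fitness(pop: MinimalPopulation, params: MinimalParams) -> np.ndarray:
    cells, inv = np.unique(pop.cell, return_inverse=True)
    cnt = np.bincount(inv).astype(float)
    m1 = np.bincount(inv, weights=pop.k1) / cnt
    m2 = np.bincount(inv, weights=pop.k2) / cnt
    a, b = pop.k1, pop.k2
    if params.rectified:
        m1, m2 = np.maximum(m1, 0.0), np.maximum(m2, 0.0)
        a, b = np.maximum(a, 0.0), np.maximum(b, 0.0)
    return np.exp(m1[inv] + m2[inv] - params.r * (a + b))


def moran_step(pop: MinimalPopulation, params: MinimalParams,
               rng: np.random.Generator) -> MinimalPopulation:
    """One birth-death event in place (reference implementation).

    Birth: global roulette proportional to fitness; the offspring joins the
    parent's protocell, with each of k1, k2 independently mutated with
    probability m by a Uniform(-delta, delta) step.  Death: one replicator
    removed uniformly at random.  A protocell exceeding V members splits
    binomially; empty protocells disappear (ids are not reused here).
    """
    f = _population_fitness(pop, params)
    parent = int(np.searchsorted(np.cumsum(f), rng.random() * f.sum()))
    parent = min(parent, pop.n - 1)
    c1, c2 = float(pop.k1[parent]), float(pop.k2[parent])
    hi = params.k_upper_value if params.rectified else np.inf
    if rng.random() < params.m:
        c1 += float(rng.uniform(-params.delta, params.delta))
        if c1 > hi:
            c1 = 2 * hi - c1
    if rng.random() < params.m:
        c2 += float(rng.uniform(-params.delta, params.delta))
        if c2 > hi:
            c2 = 2 * hi - c2
    pc = int(pop.cell[parent])
    if params.death_within_cell:
        members = np.flatnonzero(pop.cell == pc)
        victim = int(members[rng.integers(members.size)])
    else:
        victim = int(rng.integers(pop.n))
    pop.k1[victim], pop.k2[victim] = c1, c2
    pop.cell[victim] = pc
    members = np.flatnonzero(pop.cell == pc)
    if members.size > params.V:
        new_id = int(pop.cell.max()) + 1
        coins = rng.random(members.size) < 0.5
        pop.cell[members[coins]] = new_id
    return pop


def asymmetry_index(mean_k1: float, mean_k2: float, rectified: bool = True) -> float:
    """|(k1 - k2)/(k1 + k2)| on population means; rectified mode clamps the
    means at 0 first, which maps a fully broken state onto exactly 1."""
    if rectified:
        mean_k1, mean_k2 = max(mean_k1, 0.0), max(mean_k2, 0.0)
        den = mean_k1 + mean_k2
        return abs(mean_k1 - mean_k2) / den if den > 0 else np.nan
    den = mean_k1 + mean_k2
    return abs(mean_k1 - mean_k2) / abs(den) if den != 0 else np.nan


def run_minimal(params: MinimalParams, steps: int,
                rng: np.random.Generator | int, *,
                stride: int = 1_000, k0: float = 1.0,
                k0_pair: tuple[float, float] | None = None) -> pd.DataFrame:
    """Run the Moran chain, recording (step, mean_k1, mean_k2, asymmetry,
    n_cells) every ``stride`` steps.  Means are of the rectified values in
    rectified mode and of the raw values otherwise."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pop = MinimalPopulation.initial(params, k0=k0, k0_pair=k0_pair)
    n_rows = steps // stride + 1 if stride > 0 else 1
    rec = np.full((n_rows, 5), np.nan)
    rows = K._minimal_run(pop.k1, pop.k2, pop.cell,
                          int(pop.cell.max()) + 1, params.V, params.r,
                          params.m, params.delta,
                          params.k_upper_value, params.rectified,
                          params.death_within_cell, int(steps), int(stride),
                          rec, int(rng.integers(2**31 - 1)))
    df = pd.DataFrame(rec[:rows],
                      columns=["step", "mean_k1", "mean_k2", "asymmetry",
                               "n_cells"])
    df["step"] = df["step"].astype("int64")
    df["n_cells"] = df["n_cells"].astype("int64")
    return df
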