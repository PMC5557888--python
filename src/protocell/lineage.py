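"""Single-protocell line-of-descent assays against an infinite background.

One protocell is followed while competing with a very large stationary
population of protocells characterised only by its replicator density
N'_R/(N'_R + N'_S).  In the diffusion step the focal cell's substrate count
is redrawn from a Poisson distribution with mean n_R * N'_S/N'_R (the share
an infinitely large well-mixed pool would allocate to its n_R replicators).
When the cell divides, one daughter is discarded at random and the other is
followed, counting divisions until all replicators are lost.

Two measurements are built on this machinery: the number of divisions along
the line of descent as a function of functional asymmetry, and the
probability of bottleneck-induced growth restoration (a division occurring
after the cell's particle count has dropped below 0.3 V) as a function of
kinetic asymmetry kappa.  In these assays k is not bounded above and the
probability scaling alpha is recomputed each step from the current maximum
effective rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .core import Params, SymmetryMode, compute_alpha

__all__ = [
    "LineageConfig",
    "LineageOutcome",
    "sample_background_substrates",
    "run_lineage",
    "estimate_restoration_probability",
    "calibrate_initial_k",
    "closed_cell_density",
]


@dataclass
class LineageConfig:
    """Parameters of the line-of-descent assay."""

    V: int = 1700
    d: float = 0.0632
    m: float = 0.01
    delta: float = 0.05
    background_density: float = 0.7    # N'_R / (N'_R + N'_S)
    initial_density: float = 0.725     # E0[n_R / (n_R + n_S)]
    initial_k: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    symmetry_mode: SymmetryMode = SymmetryMode.kinetic
    mutation_method: int = 0
    restoration_threshold_fraction: float = 0.3
    max_steps: int = 1_000_000
    strand_ratio_PM: float | None = None  # initial N_P:(N_P+N_M); None = auto

    def __post_init__(self) -> None:
        if not 0 < self.background_density < 1:
            raise ValueError("background_density must lie in (0, 1)")
        if not 0 < self.initial_density <= 1:
            raise ValueError("initial_density must lie in (0, 1]")
        if isinstance(self.symmetry_mode, str):
            self.symmetry_mode = SymmetryMode[self.symmetry_mode]

    @property
    def substrate_ratio(self) -> float:
        """N'_S / N'_R of the background population."""
        return (1.0 - self.background_density) / self.background_density

    def to_params(self) -> Params:
        return Params(V=self.V, N=max(self.V, 2), m=self.m, delta=self.delta,
                      d=self.d, k_upper=None,
                      symmetry_mode=self.symmetry_mode,
                      mutation_method=self.mutation_method)


@dataclass
class LineageOutcome:
    division_count: int
    min_particles_seen: int
    min_replicators_seen: int
    restored: bool
    restoration_count: int
    extinct: bool
    steps: int
    min_replicators_at_restoration: int | None = None


def sample_background_substrates(n_R: int, cfg: LineageConfig,
                                 rng: np.random.Generator) -> int:
    """Substrate count allocated to a cell of n_R replicators by the infinite
    background pool: Poisson with mean n_R * N'_S/N'_R (0 when n_R = 0)."""
    if n_R < 0:
        raise ValueError("n_R must be non-negative")
    if n_R == 0:
        return 0
    return int(rng.poisson(n_R * cfg.substrate_ratio))


class _Cell:
    """Replicator table of the focal cell (substrates kept as a count)."""

    __slots__ = ("strand", "k", "partner", "role", "n_sub")

    def __init__(self, strand, k, partner, role, n_sub):
        self.strand = strand
        self.k = k
        self.partner = partner
        self.role = role
        self.n_sub = int(n_sub)

    @property
    def n_rep(self) -> int:
        return self.strand.shape[0]

    @property
    def particles(self) -> int:
        return self.n_rep + self.n_sub


def _initial_cell(cfg: LineageConfig, rng: np.random.Generator) -> _Cell:
    size = max(2, cfg.V // 2)
    n_rep = int(round(cfg.initial_density * size))
    n_rep = min(max(n_rep, 0), size)
    k = np.asarray(cfg.initial_k, dtype=float)
    if cfg.strand_ratio_PM is not None:
        frac_p = cfg.strand_ratio_PM
    else:
        frac_p = _steady_strand_fraction(k)
    n_p = int(round(frac_p * n_rep))
    strand = np.zeros(n_rep, np.uint8)
    strand[n_p:] = 1
    return _Cell(strand=strand, k=np.tile(k, (n_rep, 1)),
                 partner=np.full(n_rep, -1, np.int64),
                 role=np.zeros(n_rep, np.uint8), n_sub=size - n_rep)


def _steady_strand_fraction(k: np.ndarray) -> float:
    """Deterministic steady-state P fraction implied by the k profile.

    Balancing production (template y is copied at total catalytic rate
    sum_x k_xy) against equal decay gives (N_M/N_P)^2 = c_P/c_M with
    c_y = sum_x max(k_xy, 0)."""
    c_p = max(k[0], 0.0) + max(k[2], 0.0)  # templates of strand P -> makes M
    c_m = max(k[1], 0.0) + max(k[3], 0.0)  # templates of strand M -> makes P
    if c_p <= 0 and c_m <= 0:
        return 0.5
    if c_m <= 0:
        return 0.0  # only P templates copied; P cannot be produced
    if c_p <= 0:
        return 1.0
    ratio_mp = np.sqrt(c_p / c_m)  # N_M / N_P
    return 1.0 / (1.0 + ratio_mp)


def _reaction_on_cell(cell: _Cell, cfg: LineageConfig,
                      rng: np.random.Generator) -> _Cell:
    """One reaction step on the focal cell via the compiled substep."""
    n = cell.particles
    n_rep = cell.n_rep
    is_rep = np.zeros(n, np.uint8)
    is_rep[:n_rep] = 1
    strand = np.zeros(n, np.uint8)
    strand[:n_rep] = cell.strand
    chir = np.zeros(n, np.uint8)
    k = np.zeros((n, 4))
    k[:n_rep] = cell.k
    partner = np.full(n, -1, np.int64)
    partner[:n_rep] = cell.partner
    role = np.zeros(n, np.uint8)
    role[:n_rep] = cell.role
    cells = np.zeros(n, np.int64)

    k_eff = max(float(np.max(k[:n_rep])) if n_rep else 0.0, 0.0)
    alpha = compute_alpha(k_eff, cfg.d)
    x = n / alpha
    n_iter = int(x) + (1 if rng.random() < x - int(x) else 0)
    K._seed(int(rng.integers(2**31 - 1)))
    K._reaction_substep(is_rep, strand, chir, k, partner, role, cells, 1,
                        n_iter, alpha, cfg.d, cfg.m, cfg.delta, np.inf,
                        int(cfg.mutation_method), int(cfg.symmetry_mode),
                        K.VARIANT_TWO_STEP, True)
    keep = np.flatnonzero(is_rep == 1)
    remap = np.full(n, -1, np.int64)
    remap[keep] = np.arange(keep.size)
    new_partner = partner[keep]
    live = new_partner >= 0
    new_partner[live] = remap[new_partner[live]]
    return _Cell(strand=strand[keep].copy(), k=k[keep].copy(),
                 partner=new_partner, role=role[keep].copy(),
                 n_sub=n - keep.size)


def _divide_cell(cell: _Cell, rng: np.random.Generator) -> _Cell:
    """Binomial split with complexes as units; keep one random daughter."""
    n_rep = cell.n_rep
    side = np.zeros(n_rep, np.int8)
    for i in range(n_rep):
        p = cell.partner[i]
        if p >= 0 and p < i:
            side[i] = side[p]
        else:
            side[i] = 1 if rng.random() < 0.5 else 0
    keep_side = int(rng.integers(2))
    keep = np.flatnonzero(side == keep_side)
    remap = np.full(n_rep, -1, np.int64)
    remap[keep] = np.arange(keep.size)
    new_partner = cell.partner[keep]
    live = new_partner >= 0
    new_partner[live] = remap[new_partner[live]]
    n_sub = int(rng.binomial(cell.n_sub, 0.5))
    if keep_side == 0:
        n_sub = cell.n_sub - n_sub
    return _Cell(strand=cell.strand[keep].copy(), k=cell.k[keep].copy(),
                 partner=new_partner, role=cell.role[keep].copy(),
                 n_sub=n_sub)


def run_lineage(cfg: LineageConfig, rng: np.random.Generator | int) -> LineageOutcome:
    """Follow one protocell line of descent until its replicators are gone.

    Counts divisions, tracks the minimum particle and replicator counts, and
    scores bottleneck-induced growth restoration: a division occurring after
    the particle count has dropped below ``restoration_threshold_fraction*V``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cell = _initial_cell(cfg, rng)
    thr = cfg.restoration_threshold_fraction * cfg.V
    divisions = 0
    restorations = 0
    min_particles = cell.particles
    min_reps = cell.n_rep
    dipped = cell.particles < thr
    dip_min_rep = cell.n_rep if dipped else None
    min_rep_at_restore = None
    steps = 0
    extinct = False
    for steps in range(1, cfg.max_steps + 1):
        cell = _reaction_on_cell(cell, cfg, rng)
        if cell.n_rep == 0:
            extinct = True
            min_particles = 0
            min_reps = 0
            break
        cell.n_sub = sample_background_substrates(cell.n_rep, cfg, rng)
        if cell.particles >= cfg.V:
            divisions += 1
            if dipped:
                restorations += 1
                if min_rep_at_restore is None:
                    min_rep_at_restore = dip_min_rep
                dipped = False
                dip_min_rep = None
            cell = _divide_cell(cell, rng)
            if cell.n_rep == 0:
                extinct = True
                min_particles = 0
                min_reps = 0
                break
        min_particles = min(min_particles, cell.particles)
        min_reps = min(min_reps, cell.n_rep)
        if cell.particles < thr:
            if not dipped:
                dipped = True
                dip_min_rep = cell.n_rep
            else:
                dip_min_rep = min(dip_min_rep, cell.n_rep)
    return LineageOutcome(division_count=divisions,
                          min_particles_seen=min_particles,
                          min_replicators_seen=min_reps,
                          restored=restorations > 0,
                          restoration_count=restorations,
                          extinct=extinct, steps=steps,
                          min_replicators_at_restoration=min_rep_at_restore)


def estimate_restoration_probability(cfg: LineageConfig,
                                     rng: np.random.Generator | int,
                                     reps: int = 1000) -> dict:
    """Fraction of lineages with at least one bottleneck-induced growth
    restoration, with its standard error, plus the distribution of minimum
    replicator counts among restored lineages."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    restored = 0
    minima = []
    outcomes = []
    for _ in range(reps):
        out = run_lineage(cfg, rng)
        outcomes.append(out)
        if out.restored:
            restored += 1
            if out.min_replicators_at_restoration is not None:
                minima.append(out.min_replicators_at_restoration)
    p = restored / reps
    se = float(np.sqrt(p * (1 - p) / reps))
    return {"probability": p, "se": se, "reps": reps,
            "min_replicator_distribution": np.asarray(minima, dtype=int),
            "outcomes": outcomes}


# ---------------------------------------------------------------------------
# initial-k calibration
# ---------------------------------------------------------------------------

def closed_cell_density(k: np.ndarray, cfg: LineageConfig, *, seed: int,
                        steps: int = 2000, size: int | None = None) -> float:
    """Mean replicator density of a closed cell (no substrate diffusion, no
    division) carrying the fixed k profile, averaged over the second half of
    a pilot run with mutation off."""
    size = max(10, cfg.V // 2) if size is None else size
    pilot = LineageConfig(V=cfg.V, d=cfg.d, m=0.0, delta=cfg.delta,
                          background_density=cfg.background_density,
                          initial_density=0.5, initial_k=tuple(k),
                          symmetry_mode=cfg.symmetry_mode,
                          strand_ratio_PM=cfg.strand_ratio_PM)
    rng = np.random.default_rng(seed)
    cell = _initial_cell(pilot, rng)
    dens = []
    for s in range(steps):
        cell = _reaction_on_cell(cell, pilot, rng)
        if cell.n_rep == 0:
            return 0.0
        if s >= steps // 2:
            dens.append(cell.n_rep / cell.particles)
    return float(np.mean(dens))


def calibrate_initial_k(target_density: float, cfg: LineageConfig, *,
                        profile: np.ndarray | None = None,
                        s_max: float = 60.0, tol: float = 1e-3,
                        seed: int = 0, pilot_steps: int = 2000,
                        max_iter: int = 40) -> np.ndarray:
    """Find k = s * profile whose closed-cell steady-state replicator density
    matches ``target_density``, by bisection on the scalar multiplier s
    against pilot simulations (common random numbers per evaluation).

    ``profile`` is the shape of the four k values (default the configured
    initial_k); negative profile entries stay negative (non-catalytic strand)
    and are not scaled.
    """
    if not 0 < target_density < 1:
        if target_density == 0:
            return np.zeros(4)
        raise ValueError("target_density must lie in (0, 1)")
    base = np.asarray(cfg.initial_k if profile is None else profile, float)

    def k_of(s):
        k = base.copy()
        pos = k > 0
        k[pos] = k[pos] * s
        return k

    def density(s):
        return closed_cell_density(k_of(s), cfg, seed=seed, steps=pilot_steps)

    d_hi = density(s_max)
    if d_hi + tol < target_density:
        d_lo0 = density(1e-3)
        raise ValueError(
            f"target density {target_density} unattainable for this profile; "
            f"achievable range is about [{d_lo0:.3f}, {d_hi:.3f}]")
    lo, hi = 0.0, s_max
    s = 0.5 * s_max
    for _ in range(max_iter):
        s = 0.5 * (lo + hi)
        d = density(s)
        if abs(d - target_density) <= tol:
            break
        if d < target_density:
            lo = s
        else:
            hi = s
        if hi - lo < 1e-4 * s_max:
            break
    return k_of(s)
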