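"""Particle-level state and the stochastic reaction step.

The model holds two kinds of particles, replicators and substrates, inside
protocells.  Each replicator carries a strand type (plus ``P`` or minus
``M``) and four complex-formation rates ``k_xy`` (catalyst strand ``x``,
template strand ``y``).  Replication is two-step: a catalyst-template complex
forms at rate ``k_xy`` and subsequently converts one substrate into the
complement of the template (copying its ``k`` values, with mutation at
probability ``m`` per replication).  Replicators decay back into substrates
at rate ``d``, so the total particle number is conserved.

Event probabilities within one reaction iteration are ``alpha*beta*k_xy``
(complex formation, either orientation), ``alpha*gamma`` (replication) and
``alpha*d`` (decay), with ``beta = 1/2`` and ``gamma = 1/4`` correcting for
the multiple orders in which the reacting particles can be drawn, and
``alpha`` chosen so the probabilities can never sum above one.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K

__all__ = [
    "Strand",
    "MutationMethod",
    "SymmetryMode",
    "Variant",
    "Params",
    "ReactionScaling",
    "SystemState",
    "Replicator",
    "Protocell",
    "compute_alpha",
    "mutate_k",
    "attempt_complex_formation",
    "attempt_replication",
    "attempt_decay",
    "reaction_step",
    "validate_state",
    "K_COLUMNS",
]

K_COLUMNS = ("kPP", "kPM", "kMP", "kMM")

BETA = K.BETA
GAMMA = K.GAMMA


class Strand(enum.IntEnum):
    P = 0
    M = 1


class MutationMethod(enum.IntEnum):
    """How a mutation event perturbs the four k values."""

    additive = K.METHOD_ADDITIVE              # uniform step, free below zero
    additive_reflect_zero = K.METHOD_ADDITIVE_REFLECT0
    multiplicative = K.METHOD_MULTIPLICATIVE  # log-scale random walk


class SymmetryMode(enum.IntEnum):
    """Which equalities between the k_xy values are enforced."""

    none = K.SYM_NONE
    kinetic = K.SYM_KINETIC        # k_PP = k_PM and k_MP = k_MM
    functional = K.SYM_FUNCTIONAL  # k_PP = k_MP and k_PM = k_MM
    both = K.SYM_BOTH


class Variant(enum.IntEnum):
    two_step = K.VARIANT_TWO_STEP
    one_step = K.VARIANT_ONE_STEP
    cross_chiral = K.VARIANT_CROSS_CHIRAL


def compute_alpha(k_max: float, d: float) -> float:
    """Probability scaling constant for the reaction algorithm.

    Chosen at the equality of the bound
    ``alpha * (beta*k + beta*k' + gamma + d) <= 1`` with ``k = k' = k_max``,
    i.e. ``alpha = 1 / (k_max + 1/4 + d)``.
    """
    if k_max < 0 or d < 0:
        raise ValueError("k_max and d must be non-negative")
    return 1.0 / (k_max + GAMMA + d)


@dataclass(frozen=True)
class ReactionScaling:
    """The (alpha, beta, gamma) probability scaling of one reaction iteration."""

    alpha: float
    beta: float = BETA
    gamma: float = GAMMA

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @classmethod
    def for_run(cls, params: "Params") -> "ReactionScaling":
        k_max = params.k_upper if params.k_upper is not None else 1.0
        return cls(alpha=compute_alpha(k_max, params.d))


@dataclass
class Params:
    """Model parameters (defaults: m=0.01, delta=0.05, d=0.02, N=50V, k<=1)."""

    V: int = 100
    N: int | None = None  # defaults to 50*V
    m: float = 0.01
    delta: float = 0.05
    d: float = 0.02
    k_upper: float | None = 1.0  # None disables the upper bound
    mutation_method: MutationMethod = MutationMethod.additive
    symmetry_mode: SymmetryMode = SymmetryMode.none
    variant: Variant = Variant.two_step
    mutate_all: bool = True   # mutate all four k per event (vs one random one)
    complexes_split_as_unit: bool = True

    def __post_init__(self) -> None:
        if self.N is None:
            self.N = 50 * self.V
        if isinstance(self.mutation_method, str):
            self.mutation_method = MutationMethod[self.mutation_method]
        if isinstance(self.symmetry_mode, str):
            self.symmetry_mode = SymmetryMode[self.symmetry_mode]
        if isinstance(self.variant, str):
            self.variant = Variant[self.variant]
        if not 0 <= self.m <= 1:
            raise ValueError(f"m must lie in [0, 1], got {self.m}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if not 0 < self.d < 1:
            raise ValueError(f"d must lie in (0, 1), got {self.d}")
        if self.V < 2:
            raise ValueError(f"V must be >= 2, got {self.V}")
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")

    @property
    def k_upper_value(self) -> float:
        return math.inf if self.k_upper is None else self.k_upper


class SystemState:
    """Flat-array container for the whole particle population.

    Particle slots are stable: replication and decay flip ``is_rep`` in place
    (substrates are anonymous, so slot identity carries no history).  Total
    slot count therefore equals the conserved particle number N.
    """

    def __init__(self, n: int, n_cells: int = 1):
        self.is_rep = np.zeros(n, np.uint8)
        self.strand = np.zeros(n, np.uint8)
        self.chir = np.zeros(n, np.uint8)
        self.k = np.zeros((n, 4), np.float64)
        self.partner = np.full(n, -1, np.int64)
        self.role = np.zeros(n, np.uint8)
        self.cell = np.zeros(n, np.int64)
        self.n_cells = n_cells
        self.time_step = 0
        self.extinct = False

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return self.is_rep.shape[0]

    @property
    def n_replicators(self) -> int:
        return int(self.is_rep.sum())

    @property
    def n_substrates(self) -> int:
        return self.n_particles - self.n_replicators

    def strand_counts(self) -> tuple[int, int]:
        rep = self.is_rep == 1
        n_p = int(np.sum(rep & (self.strand == 0)))
        return n_p, int(rep.sum()) - n_p

    def cell_sizes(self) -> np.ndarray:
        return np.bincount(self.cell, minlength=self.n_cells)

    def replicator_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_rep == 1)

    def replicator(self, i: int) -> "Replicator":
        return Replicator(self, i)

    def protocell(self, c: int) -> "Protocell":
        return Protocell(self, c)

    def protocells(self):
        return (Protocell(self, c) for c in range(self.n_cells))

    def effective_kmax(self) -> float:
        idx = self.replicator_indices()
        if idx.size == 0:
            return 0.0
        return max(float(self.k[idx].max()), 0.0)

    def copy(self) -> "SystemState":
        s = SystemState(self.n_particles, self.n_cells)
        for name in ("is_rep", "strand", "chir", "k", "partner", "role", "cell"):
            getattr(s, name)[...] = getattr(self, name)
        s.time_step = self.time_step
        s.extinct = self.extinct
        return s


@dataclass
class Replicator:
    """Read/write view of one replicator slot."""

    system: SystemState
    index: int

    @property
    def strand(self) -> Strand:
        return Strand(int(self.system.strand[self.index]))

    @property
    def k(self) -> np.ndarray:
        return self.system.k[self.index]

    @property
    def effective_k(self) -> np.ndarray:
        return np.maximum(self.k, 0.0)

    @property
    def partner(self) -> int:
        return int(self.system.partner[self.index])

    @property
    def complex_state(self) -> str:
        r = self.system.role[self.index]
        return ("free", "catalyst", "template")[r]

    @property
    def cell(self) -> int:
        return int(self.system.cell[self.index])

    def k_against(self, template_strand: Strand) -> float:
        """Effective complex-formation rate of this replicator as a catalyst
        of a template of the given strand."""
        v = self.system.k[self.index, 2 * int(self.strand) + int(template_strand)]
        return max(float(v), 0.0)


@dataclass
class Protocell:
    """View of one protocell (compartment)."""

    system: SystemState
    index: int

    @property
    def member_indices(self) -> np.ndarray:
        return np.flatnonzero(self.system.cell == self.index)

    @property
    def particle_count(self) -> int:
        return int(np.sum(self.system.cell == self.index))

    @property
    def n_substrate(self) -> int:
        sel = self.system.cell == self.index
        return int(np.sum(sel & (self.system.is_rep == 0)))

    @property
    def replicators(self) -> list[Replicator]:
        sel = (self.system.cell == self.index) & (self.system.is_rep == 1)
        return [Replicator(self.system, int(i)) for i in np.flatnonzero(sel)]


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

_TIED_GROUPS = {
    SymmetryMode.none: [(0,), (1,), (2,), (3,)],
    SymmetryMode.kinetic: [(0, 1), (2, 3)],
    SymmetryMode.functional: [(0, 2), (1, 3)],
    SymmetryMode.both: [(0, 1, 2, 3)],
}


def _reflect(v: float, lo: float, hi: float) -> float:
    for _ in range(64):
        if v > hi:
            v = 2 * hi - v
        elif v < lo:
            v = 2 * lo - v
        else:
            break
    return v


def mutate_k(k: np.ndarray, params: Params, rng: np.random.Generator) -> np.ndarray:
    """Return a mutated copy of the four k values (one mutation event).

    Under a symmetry constraint, each tied group receives a single step equal
    to the mean of one independent draw per tied entry, which leaves the
    variance of the mutational change in sum(k_xy) at 4*delta^2/3 exactly as
    in the unconstrained model.
    """
    k = np.asarray(k, dtype=float).copy()
    if k.shape != (4,):
        raise ValueError("k must have shape (4,)")
    method = params.mutation_method
    sym = params.symmetry_mode
    delta = params.delta
    hi = params.k_upper_value
    groups = _TIED_GROUPS[sym]

    if method == MutationMethod.multiplicative:
        for g in groups:
            if sym == SymmetryMode.none and params.mutate_all is False:
                continue  # handled below
            draws = rng.uniform(1 - delta, 1 + delta, size=len(g))
            f = float(np.exp(np.mean(np.log(draws))))
            for c in g:
                k[c] *= f
        if sym == SymmetryMode.none and not params.mutate_all:
            c = int(rng.integers(4))
            k[c] *= float(rng.uniform(1 - delta, 1 + delta))
        if hi < math.inf:
            over = k > hi
            k[over] = hi * hi / k[over]  # reflect in log space
        return k

    lo = 0.0 if method == MutationMethod.additive_reflect_zero else -math.inf
    if sym == SymmetryMode.none and not params.mutate_all:
        c = int(rng.integers(4))
        k[c] = _reflect(k[c] + float(rng.uniform(-delta, delta)), lo, hi)
        return k
    for g in groups:
        e = float(np.mean(rng.uniform(-delta, delta, size=len(g))))
        v = _reflect(k[g[0]] + e, lo, hi)
        for c in g:
            k[c] = v
    return k


# ---------------------------------------------------------------------------
# single-event operations (reference semantics; also the unit-test surface)
# ---------------------------------------------------------------------------

def attempt_complex_formation(system: SystemState, i: int, j: int,
                              scaling: ReactionScaling,
                              rng: np.random.Generator) -> bool:
    """One complex-formation attempt between free replicators ``i`` and ``j``
    drawn in that order (``i`` plays the X role).

    With probability ``alpha*beta*max(k_xy^X, 0)`` X becomes the catalyst and
    Y the template; failing that, with probability ``alpha*beta*max(k_yx^Y,
    0)`` the orientation is reversed.  At most one complex forms.
    """
    if system.is_rep[i] != 1 or system.is_rep[j] != 1:
        raise ValueError("both particles must be replicators")
    if system.partner[i] >= 0 or system.partner[j] >= 0:
        raise ValueError("both replicators must be uncomplexed")
    if system.cell[i] != system.cell[j] or i == j:
        raise ValueError("particles must be distinct members of one protocell")
    ab = scaling.alpha * scaling.beta
    kx = max(float(system.k[i, 2 * system.strand[i] + system.strand[j]]), 0.0)
    ky = max(float(system.k[j, 2 * system.strand[j] + system.strand[i]]), 0.0)
    u = rng.random()
    if u < ab * kx:
        cat, tem = i, j
    elif u < ab * (kx + ky):
        cat, tem = j, i
    else:
        return False
    system.partner[cat] = tem
    system.partner[tem] = cat
    system.role[cat] = 1
    system.role[tem] = 2
    return True


def attempt_replication(system: SystemState, member: int, substrate: int,
                        params: Params, scaling: ReactionScaling,
                        rng: np.random.Generator) -> int | None:
    """One replication attempt by the complex containing ``member`` on
    ``substrate``; returns the index of the new replicator or None.

    With probability ``alpha*gamma`` the substrate becomes the complement of
    the template (k values copied, mutated with probability ``m``) and the
    complex dissociates.
    """
    if system.partner[member] < 0:
        raise ValueError("member must belong to a formed complex")
    if system.is_rep[substrate] != 0:
        raise ValueError("substrate slot must hold a substrate")
    if system.cell[member] != system.cell[substrate]:
        raise ValueError("substrate must reside in the complex's protocell")
    if rng.random() >= scaling.alpha * scaling.gamma:
        return None
    tem = member if system.role[member] == 2 else int(system.partner[member])
    system.is_rep[substrate] = 1
    system.strand[substrate] = 1 - system.strand[tem]
    system.chir[substrate] = system.chir[tem]
    kk = system.k[tem].copy()
    if rng.random() < params.m:
        kk = mutate_k(kk, params, rng)
    system.k[substrate] = kk
    p = int(system.partner[tem])
    system.partner[[tem, p]] = -1
    system.role[[tem, p]] = 0
    return substrate


def attempt_decay(system: SystemState, i: int, params: Params,
                  scaling: ReactionScaling, rng: np.random.Generator) -> bool:
    """One decay attempt on replicator ``i`` (probability ``alpha*d``).

    A complexed replicator first dissociates its complex; the partner
    survives as a free replicator.  Decay converts the replicator back into a
    substrate, leaving total particle number unchanged.
    """
    if system.is_rep[i] != 1:
        raise ValueError("only replicators decay")
    if rng.random() >= scaling.alpha * params.d:
        return False
    p = int(system.partner[i])
    if p >= 0:
        system.partner[[i, p]] = -1
        system.role[[i, p]] = 0
    system.is_rep[i] = 0
    return True


# ---------------------------------------------------------------------------
# the reaction step
# ---------------------------------------------------------------------------

def _n_iterations(n: int, alpha: float, rng: np.random.Generator) -> int:
    x = n / alpha
    n_iter = int(x)
    if rng.random() < x - n_iter:
        n_iter += 1
    return n_iter


def reaction_step(system: SystemState, params: Params,
                  scaling: ReactionScaling | None,
                  rng: np.random.Generator, *,
                  engine: str = "numba",
                  log: list | None = None) -> SystemState:
    """Perform one reaction step (N/alpha iterations) in place.

    ``engine='python'`` runs a readable reference loop built from the
    single-event operations and supports event logging: ``log`` receives
    tuples ``(iteration, event, info)`` with event in {"complex",
    "replication", "decay"} (info is the catalyst index for complexes, the
    template index for replications, the decaying index for decays).
    """
    if scaling is None:
        k_max = (params.k_upper if params.k_upper is not None
                 else max(system.effective_kmax(), 1e-12))
        scaling = ReactionScaling(alpha=compute_alpha(k_max, params.d))
    n = system.n_particles
    n_iter = _n_iterations(n, scaling.alpha, rng)
    if engine == "numba":
        K._seed(int(rng.integers(2**31 - 1)))
        K._reaction_substep(system.is_rep, system.strand, system.chir,
                            system.k, system.partner, system.role,
                            system.cell, system.n_cells, n_iter,
                            scaling.alpha, params.d, params.m, params.delta,
                            params.k_upper_value, int(params.mutation_method),
                            int(params.symmetry_mode), int(params.variant),
                            params.mutate_all)
        return system
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")
    _reaction_step_python(system, params, scaling, rng, n_iter, log)
    return system


def _reaction_step_python(system, params, scaling, rng, n_iter, log):
    is_rep = system.is_rep
    partner = system.partner
    cell = system.cell
    strand = system.strand
    chir = system.chir
    role = system.role
    k = system.k
    n = system.n_particles
    ab = scaling.alpha * scaling.beta
    ag = scaling.alpha * scaling.gamma
    ad = scaling.alpha * params.d
    one_step = params.variant == Variant.one_step
    cross = params.variant == Variant.cross_chiral
    members_of = [np.flatnonzero(cell == c) for c in range(system.n_cells)]

    for it in range(n_iter):
        x = int(rng.integers(n))
        mem = members_of[cell[x]]
        n_excl = 2 if partner[x] >= 0 else 1
        y = -1
        if mem.size > n_excl:
            while True:
                j = int(mem[rng.integers(mem.size)])
                if j != x and j != partner[x]:
                    y = j
                    break
        u = rng.random()
        acc = 0.0
        if y >= 0 and not one_step:
            if (is_rep[x] == 1 and is_rep[y] == 1
                    and partner[x] < 0 and partner[y] < 0
                    and (not cross or chir[x] != chir[y])):
                kx = max(float(k[x, 2 * strand[x] + strand[y]]), 0.0)
                acc += ab * kx
                if u < acc:
                    partner[x], partner[y] = y, x
                    role[x], role[y] = 1, 2
                    if log is not None:
                        log.append((it, "complex", x))
                    continue
                ky = max(float(k[y, 2 * strand[y] + strand[x]]), 0.0)
                acc += ab * ky
                if u < acc:
                    partner[x], partner[y] = y, x
                    role[y], role[x] = 1, 2
                    if log is not None:
                        log.append((it, "complex", y))
                    continue
            elif ((is_rep[x] == 1 and partner[x] >= 0 and is_rep[y] == 0)
                  or (is_rep[x] == 0 and is_rep[y] == 1 and partner[y] >= 0)):
                member, sub = (x, y) if is_rep[x] == 1 else (y, x)
                acc += ag
                if u < acc:
                    tem = member if role[member] == 2 else int(partner[member])
                    is_rep[sub] = 1
                    strand[sub] = 1 - strand[tem]
                    chir[sub] = chir[tem]
                    kk = k[tem].copy()
                    if rng.random() < params.m:
                        kk = mutate_k(kk, params, rng)
                    k[sub] = kk
                    p = int(partner[tem])
                    partner[[tem, p]] = -1
                    role[[tem, p]] = 0
                    if log is not None:
                        log.append((it, "replication", tem))
                    continue
        elif y >= 0 and one_step:
            if is_rep[x] == 1 and is_rep[y] == 1:
                fired = -1
                kx = max(float(k[x, 2 * strand[x] + strand[y]]), 0.0)
                acc += ab * kx
                if u < acc:
                    fired = y
                else:
                    ky = max(float(k[y, 2 * strand[y] + strand[x]]), 0.0)
                    acc += ab * ky
                    if u < acc:
                        fired = x
                if fired >= 0:
                    subs = mem[is_rep[mem] == 0]
                    if subs.size > 0:
                        s = int(subs[rng.integers(subs.size)])
                        is_rep[s] = 1
                        strand[s] = 1 - strand[fired]
                        chir[s] = chir[fired]
                        kk = k[fired].copy()
                        if rng.random() < params.m:
                            kk = mutate_k(kk, params, rng)
                        k[s] = kk
                        if log is not None:
                            log.append((it, "replication", fired))
                    continue
        if is_rep[x] == 1:
            acc += ad
            if u < acc:
                p = int(partner[x])
                if p >= 0:
                    partner[[x, p]] = -1
                    role[[x, p]] = 0
                is_rep[x] = 0
                if log is not None:
                    log.append((it, "decay", x))


# ---------------------------------------------------------------------------
# invariant walk
# ---------------------------------------------------------------------------

def validate_state(system: SystemState) -> None:
    """Walk the state invariants; raises AssertionError on violation."""
    n = system.n_particles
    assert system.cell.min() >= 0 and system.cell.max() < system.n_cells
    sizes = system.cell_sizes()
    assert sizes.sum() == n
    for i in range(n):
        p = int(system.partner[i])
        if system.is_rep[i] == 0:
            assert p == -1 and system.role[i] == 0, f"substrate {i} in complex"
            continue
        if p == -1:
            assert system.role[i] == 0, f"free replicator {i} with a role"
        else:
            assert system.is_rep[p] == 1, f"{i} partnered with a substrate"
            assert int(system.partner[p]) == i, f"partner of {i} inconsistent"
            assert system.cell[i] == system.cell[p], f"complex {i}-{p} split"
            assert {int(system.role[i]), int(system.role[p])} == {1, 2}, \
                f"complex {i}-{p} roles invalid"
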