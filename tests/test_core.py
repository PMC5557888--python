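"""Unit tests for the particle-level reaction operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protocell import (MutationMethod, Params, ReactionScaling, Strand,
                       SymmetryMode, SystemState, compute_alpha,
                       make_fixture, mutate_k, reaction_step, validate_state)
from protocell.core import (attempt_complex_formation, attempt_decay,
                            attempt_replication)


class _StubRng:
    """Deterministic stand-in for a Generator: fixed uniform step, fixed
    low/high random() draws."""

    def __init__(self, eps=0.05, u=0.0):
        self.eps = eps
        self.u = u

    def uniform(self, lo, hi, size=None):
        if size is None:
            return self.eps
        return np.full(size, self.eps)

    def random(self):
        return self.u

    def integers(self, n):
        return 0


# ---------------------------------------------------------------------------
# probability scaling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k_max, d, expected", [
    (1.0, 0.02, 1 / 1.27),
    (0.0, 0.0, 4.0),
    (2.0, 0.1, 1 / 2.35),
])
def test_compute_alpha_examples(k_max, d, expected):
    assert compute_alpha(k_max, d) == pytest.approx(expected, rel=1e-12)


def test_compute_alpha_rejects_negative_inputs():
    with pytest.raises(ValueError):
        compute_alpha(-0.1, 0.02)
    with pytest.raises(ValueError):
        compute_alpha(1.0, -0.5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(k_max=st.floats(0, 10), d=st.floats(0, 1),
       f1=st.floats(0, 1), f2=st.floats(0, 1))
def test_event_probabilities_never_exceed_unity(k_max, d, f1, f2):
    """alpha(beta k + beta k' + gamma + d) <= 1 for all admissible rates."""
    alpha = compute_alpha(k_max, d)
    k, kp = f1 * k_max, f2 * k_max
    assert alpha * (0.5 * k + 0.5 * kp + 0.25 + d) <= 1 + 1e-12


def test_scaling_constants():
    s = ReactionScaling(alpha=0.5)
    assert (s.beta, s.gamma) == (0.5, 0.25)
    with pytest.raises(ValueError):
        ReactionScaling(alpha=0.0)


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", list(MutationMethod))
@pytest.mark.parametrize("sym", list(SymmetryMode))
def test_mutate_k_preserves_declared_ties_bitwise(method, sym, rng):
    params = Params(V=10, N=100, mutation_method=method, symmetry_mode=sym)
    k = np.array([0.6, 0.6, 0.4, 0.4])
    if sym in (SymmetryMode.functional, SymmetryMode.both):
        k = np.array([0.5, 0.5, 0.5, 0.5])
    for _ in range(200):
        k = mutate_k(k, params, rng)
        if sym in (SymmetryMode.kinetic, SymmetryMode.both):
            assert k[0] == k[1] and k[2] == k[3]
        if sym in (SymmetryMode.functional, SymmetryMode.both):
            assert k[0] == k[2] and k[1] == k[3]


def test_mutate_k_reflects_at_upper_bound():
    params = Params(V=10, N=100)
    out = mutate_k(np.array([0.98, 0.5, 0.5, 0.5]), params, _StubRng(eps=0.05))
    assert out[0] == pytest.approx(0.97)  # 1.03 reflected about 1
    assert out[1] == pytest.approx(0.55)


def test_mutate_k_free_below_zero_keeps_negative_value():
    params = Params(V=10, N=100)
    out = mutate_k(np.array([0.02, 0.5, 0.5, 0.5]), params, _StubRng(eps=-0.05))
    assert out[0] == pytest.approx(-0.03)


def test_mutate_k_reflecting_boundary_at_zero():
    params = Params(V=10, N=100,
                    mutation_method=MutationMethod.additive_reflect_zero)
    out = mutate_k(np.array([0.02, 0.5, 0.5, 0.5]), params, _StubRng(eps=-0.05))
    assert out[0] == pytest.approx(0.03)


def test_mutate_k_multiplicative_stays_positive_and_bounded(rng):
    params = Params(V=10, N=100,
                    mutation_method=MutationMethod.multiplicative, delta=0.3)
    k = np.array([0.9, 0.99, 0.1, 0.5])
    for _ in range(500):
        k = mutate_k(k, params, rng)
        assert np.all(k > 0) and np.all(k <= 1.0)


def test_mutate_k_unbounded_when_upper_disabled(rng):
    params = Params(V=10, N=100, k_upper=None, delta=0.5)
    k = np.array([1.0, 1.0, 1.0, 1.0])
    seen_above = False
    for _ in range(300):
        k = mutate_k(k, params, rng)
        seen_above = seen_above or np.any(k > 1.0)
    assert seen_above


def test_mutate_one_random_entry_switch(rng):
    params = Params(V=10, N=100, mutate_all=False)
    changed = 0
    for _ in range(100):
        k0 = np.array([0.5, 0.5, 0.5, 0.5])
        k1 = mutate_k(k0, params, rng)
        changed += int(np.sum(k1 != k0))
    assert changed == 100  # exactly one entry per event


# ---------------------------------------------------------------------------
# single-event operations
# ---------------------------------------------------------------------------

def _two_free_replicators(k_x, k_y, strands=(Strand.P, Strand.M)):
    state = SystemState(4, 1)
    state.is_rep[:2] = 1
    state.strand[0], state.strand[1] = int(strands[0]), int(strands[1])
    state.k[0] = k_x
    state.k[1] = k_y
    return state


def test_complex_formation_probability_matches_alpha_beta(rng):
    # X is P with k_PM = 1 against an M template: success prob alpha*beta
    scaling = ReactionScaling(alpha=compute_alpha(1.0, 0.02))
    n_trials, formed = 20_000, 0
    for _ in range(n_trials):
        state = _two_free_replicators([0, 1.0, 0, 0], [0, 0, 0, 0])
        if attempt_complex_formation(state, 0, 1, scaling, rng):
            formed += 1
            assert state.role[0] == 1 and state.role[1] == 2
    p = scaling.alpha * scaling.beta
    se = math.sqrt(p * (1 - p) / n_trials)
    assert abs(formed / n_trials - p) < 4 * se


def test_complex_formation_orientation_ratio(rng):
    # orientation frequencies proportional to k_xy^X : k_yx^Y
    scaling = ReactionScaling(alpha=compute_alpha(1.0, 0.02))
    kx, ky = 0.9, 0.3
    as_cat = {0: 0, 1: 0}
    for _ in range(30_000):
        state = _two_free_replicators([0, kx, 0, 0], [0, 0, ky, 0])
        if attempt_complex_formation(state, 0, 1, scaling, rng):
            as_cat[int(np.flatnonzero(state.role == 1)[0])] += 1
    ratio = as_cat[0] / as_cat[1]
    assert ratio == pytest.approx(kx / ky, rel=0.15)


def test_complex_formation_never_with_negative_rates(rng):
    scaling = ReactionScaling(alpha=0.7)
    for _ in range(500):
        state = _two_free_replicators([-1, -0.5, -2, -0.1], [-1, -1, -1, -1])
        assert not attempt_complex_formation(state, 0, 1, scaling, rng)


def test_complex_formation_contract_violation():
    scaling = ReactionScaling(alpha=0.7)
    state = _two_free_replicators([1, 1, 1, 1], [1, 1, 1, 1])
    state.partner[0], state.partner[1] = 1, 0
    state.role[0], state.role[1] = 1, 2
    with pytest.raises(ValueError):
        attempt_complex_formation(state, 0, 1, scaling, np.random.default_rng(0))


@pytest.mark.parametrize("template_strand, product_strand",
                         [(Strand.P, Strand.M), (Strand.M, Strand.P)])
def test_replication_product_is_complement_of_template(template_strand,
                                                       product_strand):
    params = Params(V=10, N=100, m=0.0)
    scaling = ReactionScaling(alpha=0.7)
    state = _two_free_replicators([0.1, 0.2, 0.3, 0.4], [1, 1, 1, 1],
                                  strands=(Strand.P, template_strand))
    state.partner[:2] = [1, 0]
    state.role[0], state.role[1] = 1, 2  # slot 1 is the template
    state.k[1] = [0.11, 0.22, 0.33, 0.44]
    new = attempt_replication(state, 0, 2, params, scaling, _StubRng(u=0.0))
    assert new == 2
    assert state.strand[2] == int(product_strand)
    # with m = 0 the k values are copied bit-exactly from the template
    assert np.array_equal(state.k[2], [0.11, 0.22, 0.33, 0.44])
    # the complex dissociated and the particle count is unchanged
    assert state.partner[0] == -1 and state.partner[1] == -1
    assert state.n_particles == 4 and state.n_replicators == 3
    validate_state(state)


def test_decay_dissociates_complex_and_conserves_particles():
    params = Params(V=10, N=100, d=0.5)
    scaling = ReactionScaling(alpha=0.7)
    state = _two_free_replicators([1, 1, 1, 1], [1, 1, 1, 1])
    state.partner[:2] = [1, 0]
    state.role[0], state.role[1] = 1, 2
    assert attempt_decay(state, 0, params, scaling, _StubRng(u=0.0))
    assert state.is_rep[0] == 0
    # the partner survives as a free replicator
    assert state.is_rep[1] == 1 and state.partner[1] == -1 and state.role[1] == 0
    assert state.n_particles == 4
    validate_state(state)


def test_decay_never_when_rate_zero(rng):
    from types import SimpleNamespace
    params = SimpleNamespace(d=0.0)
    scaling = ReactionScaling(alpha=0.7)
    state = _two_free_replicators([1, 1, 1, 1], [1, 1, 1, 1])
    assert not any(attempt_decay(state, 0, params, scaling, rng)
                   for _ in range(2000))


# ---------------------------------------------------------------------------
# the reaction step
# ---------------------------------------------------------------------------

def test_substrate_only_system_is_inert(rng):
    params = Params(V=10, N=30)
    state = SystemState(30, 2)
    state.cell[15:] = 1
    before_cells = state.cell.copy()
    for engine in ("python", "numba"):
        reaction_step(state, params, None, rng, engine=engine)
        assert state.n_replicators == 0
        assert np.array_equal(state.cell, before_cells)


def test_per_step_decay_frequency_matches_d(rng):
    """Across ~1e5 replicator-steps, replicators decay at ~d per step."""
    params = Params(V=4000, N=1000, d=0.02)
    scaling = ReactionScaling.for_run(params)
    decays = 0
    exposure = 0
    for _ in range(20):
        state = SystemState(1000, 1)
        state.is_rep[:500] = 1
        state.strand[:500] = np.arange(500) % 2
        state.k[:500] = -1.0  # no complexes, no replication: decay only
        for _ in range(10):
            n0 = state.n_replicators
            exposure += n0
            reaction_step(state, params, scaling, rng, engine="numba")
            decays += n0 - state.n_replicators
    expected = params.d * exposure
    assert abs(decays - expected) < 3 * math.sqrt(expected)


def test_complex_formation_frequency_matches_rate_law(rng):
    """An uncomplexed replicator forms a catalyst-side complex at ~k N_y/N^v
    per reaction step."""
    k_foc = 0.2
    params = Params(V=100, N=20, d=0.01, m=0.0)
    scaling = ReactionScaling.for_run(params)
    n, n_m = 20, 9
    hits = 0
    trials = 4000
    for _ in range(trials):
        state = SystemState(n, 1)
        state.is_rep[:1 + n_m] = 1
        state.strand[0] = 0
        state.k[0] = [-1, k_foc, -1, -1]   # P catalyst of M templates only
        state.strand[1:1 + n_m] = 1
        state.k[1:1 + n_m] = -1.0          # inert partners
        log = []
        reaction_step(state, params, scaling, rng, engine="python", log=log)
        if any(ev == "complex" for _, ev, _ in log):
            hits += 1
    # exact one-step probability of >= 1 formation
    p1 = (2 * n_m / (n * (n - 1))) * scaling.alpha * scaling.beta * k_foc
    n_iter = n / scaling.alpha
    expected = 1 - (1 - p1) ** n_iter
    rate_law = k_foc * n_m / n  # the quoted approximation, per step
    assert expected == pytest.approx(rate_law, rel=0.1)
    se = math.sqrt(expected * (1 - expected) / trials)
    assert abs(hits / trials - expected) < 4 * se + 0.005


def test_python_and_numba_engines_agree_statistically():
    """The compiled reaction kernel and the reference python loop produce the
    same replicator-count dynamics on a fixture."""
    means = {}
    for engine in ("python", "numba"):
        rng = np.random.default_rng(99)
        finals = []
        for _ in range(60):
            state, params = make_fixture("one_cell_three_reps")
            scaling = ReactionScaling.for_run(params)
            for _ in range(30):
                reaction_step(state, params, scaling, rng, engine=engine)
            validate_state(state)
            finals.append(state.n_replicators)
        means[engine] = (np.mean(finals), np.std(finals) / math.sqrt(len(finals)))
    diff = abs(means["python"][0] - means["numba"][0])
    se = math.hypot(means["python"][1], means["numba"][1])
    assert diff < 4 * se + 1e-9


def test_validate_state_catches_inconsistencies():
    state, _ = make_fixture("one_cell_three_reps")
    state.partner[0] = 1  # one-sided partner link
    state.role[0] = 1
    with pytest.raises(AssertionError):
        validate_state(state)
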