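"""Tests for system construction, diffusion, division and the main loop."""

import math

import numpy as np
import pytest
from scipy import stats

from protocell import (Params, ReactionScaling, SymmetryMode, SystemState,
                       Variant, diffusion_step, division_step,
                       initialize_system, reaction_step, run_simulation,
                       validate_state)
from protocell.dynamics import (read_snapshot_json, read_trajectory_tsv,
                                write_snapshot_json, write_trajectory_tsv)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def test_initialize_system_counts_and_defaults(rng):
    params = Params(V=100)  # N defaults to 50V
    state = initialize_system(params, rng)
    assert state.n_particles == 5000
    assert state.n_cells == 100          # ceil(2N/V)
    assert np.all(np.diff(np.sort(state.cell_sizes())) <= 1)  # ~V/2 each
    n_p, n_m = state.strand_counts()
    assert abs(n_p - n_m) <= state.n_cells  # equal P/M up to per-cell rounding
    idx = state.replicator_indices()
    assert np.all(state.k[idx] == 1.0)   # every k_xy initialised to 1
    assert state.n_replicators == 2500
    validate_state(state)


def test_initialize_system_rejects_small_N(rng):
    with pytest.raises(ValueError):
        initialize_system(Params(V=100, N=50), rng)


def test_initialize_custom_k_must_respect_ties(rng):
    params = Params(V=20, N=200, symmetry_mode=SymmetryMode.kinetic)
    with pytest.raises(ValueError):
        initialize_system(params, rng, init_k=[1.0, 0.5, 1.0, 1.0])
    state = initialize_system(params, rng, init_k=[0.8, 0.8, 0.3, 0.3])
    assert np.all(state.k[state.replicator_indices(), 0] == 0.8)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def test_diffusion_conserves_substrates_and_respects_weights(rng):
    params = Params(V=20, N=200)
    state = initialize_system(params, rng)
    # strip cell 0 of replicators: it must receive no substrates
    c0 = state.cell == 0
    state.is_rep[c0] = 0
    n_sub = state.n_substrates
    diffusion_step(state, rng)
    assert state.n_substrates == n_sub
    assert state.n_particles == 200
    sub_in_0 = np.sum((state.cell == 0) & (state.is_rep == 0))
    assert sub_in_0 == 0
    assert not state.extinct


def test_diffusion_single_cell_receives_everything(rng):
    state = SystemState(30, 1)
    state.is_rep[:3] = 1
    diffusion_step(state, rng)
    assert np.all(state.cell == 0)


def test_diffusion_flags_extinction(rng):
    state = SystemState(30, 2)
    state.cell[15:] = 1
    diffusion_step(state, rng)
    assert state.extinct


# ---------------------------------------------------------------------------
# division
# ---------------------------------------------------------------------------

def _one_full_cell(n, n_rep, V):
    state = SystemState(n, 1)
    state.is_rep[:n_rep] = 1
    state.strand[:n_rep] = np.arange(n_rep) % 2
    state.k[:n_rep] = 1.0
    return state, Params(V=V, N=max(n, V))


def test_division_threshold_semantics(rng):
    state, params = _one_full_cell(19, 10, 20)   # V-1 particles: untouched
    division_step(state, rng, params)
    assert state.n_cells == 1
    state, params = _one_full_cell(20, 10, 20)   # exactly V: divides
    division_step(state, rng, params)
    assert state.n_cells == 2
    assert state.cell_sizes().sum() == 20


def test_division_daughter_counts_are_binomial(rng):
    """Sizes of one daughter across many divisions fit Binomial(n, 1/2)."""
    n = 40
    counts = []
    for _ in range(800):
        state, params = _one_full_cell(n, 20, n)
        division_step(state, rng, params)
        counts.append(int(np.sum(state.cell == 1)))
    counts = np.asarray(counts)
    edges = [0, 16, 18, 20, 22, 24, n + 1]
    obs, _ = np.histogram(counts, bins=edges)
    cdf = stats.binom(n, 0.5).cdf
    probs = np.diff([cdf(e - 1) for e in edges])
    chi2 = ((obs - 800 * probs) ** 2 / (800 * probs)).sum()
    assert chi2 < stats.chi2(len(edges) - 2).ppf(0.999)


def test_division_keeps_complexes_together(rng):
    for _ in range(50):
        state, params = _one_full_cell(30, 20, 30)
        # pair replicators 0-1, 2-3, ... as complexes
        for a in range(0, 20, 2):
            state.partner[a], state.partner[a + 1] = a + 1, a
            state.role[a], state.role[a + 1] = 1, 2
        division_step(state, rng, params)
        validate_state(state)
        for a in range(0, 20, 2):
            assert state.cell[a] == state.cell[a + 1]


def test_division_dissociation_flag(rng):
    params = Params(V=30, N=30, complexes_split_as_unit=False)
    split_apart = 0
    for _ in range(100):
        state, _ = _one_full_cell(30, 20, 30)
        for a in range(0, 20, 2):
            state.partner[a], state.partner[a + 1] = a + 1, a
            state.role[a], state.role[a + 1] = 1, 2
        division_step(state, rng, params)
        validate_state(state)
        assert np.all(state.partner == -1)  # complexes dissociated
        split_apart += sum(state.cell[a] != state.cell[a + 1]
                           for a in range(0, 20, 2))
    assert split_apart > 0


def test_empty_cells_are_removed(rng):
    state = SystemState(10, 3)
    state.cell[:] = 2          # cells 0 and 1 empty
    state.is_rep[:2] = 1
    params = Params(V=100, N=100)
    division_step(state, rng, params)
    assert state.n_cells == 1
    validate_state(state)


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def test_run_simulation_conserves_N_and_is_deterministic():
    params = Params(V=20, N=400)
    res1 = run_simulation(params, 123, steps=300, stride=20,
                          check_invariants=True)
    res2 = run_simulation(params, 123, steps=300, stride=20)
    t1, t2 = res1.trajectory, res2.trajectory
    assert (t1["N_P"] + t1["N_M"] + t1["n_substrate"] == 400).all()
    assert t1.equals(t2)
    res3 = run_simulation(params, 124, steps=300, stride=20)
    assert not t1.equals(res3.trajectory)


def test_run_simulation_extinction_without_catalysis():
    params = Params(V=20, N=200, d=0.2)
    res = run_simulation(params, 3, steps=2000, stride=10, init_k=[0.0] * 4)
    assert res.extinct
    assert res.steps_run < 2000
    last = res.trajectory.iloc[-1]
    assert last["N_P"] + last["N_M"] == 0


def test_cross_chiral_structure():
    """Opposite chirality in every complex; replication preserves the
    template's chirality and complements its strand."""
    rng = np.random.default_rng(7)
    params = Params(V=40, N=400, variant=Variant.cross_chiral)
    state = initialize_system(params, rng)
    scaling = ReactionScaling.for_run(params)
    chir0 = {}
    for _ in range(40):
        reaction_step(state, params, scaling, rng, engine="python")
        validate_state(state)
        comp = np.flatnonzero(state.partner >= 0)
        for i in comp:
            assert state.chir[i] != state.chir[state.partner[i]]
    assert state.n_replicators > 0


def test_one_step_variant_has_no_complexes_and_replicates():
    rng = np.random.default_rng(11)
    params = Params(V=40, N=400, variant=Variant.one_step)
    state = initialize_system(params, rng)
    res = run_simulation(params, 13, steps=200, stride=10, state=state)
    assert np.all(res.state.partner == -1)
    t = res.trajectory
    assert (t["N_P"] + t["N_M"] + t["n_substrate"] == 400).all()
    assert (t["N_P"] + t["N_M"]).iloc[-1] > 0


def _class_competition(variant, n_reps, n_steps, seed):
    """Closed one-cell competition between high-k and low-k replicator
    classes (m = 0); returns mean final high-k fraction over replicates."""
    rng = np.random.default_rng(seed)
    params = Params(V=1000, N=30, m=0.0, variant=variant)
    scaling = ReactionScaling.for_run(params)
    fracs = []
    for _ in range(n_reps):
        state = SystemState(30, 1)
        state.is_rep[:16] = 1
        state.strand[:16] = np.arange(16) % 2
        state.k[:8] = 1.0     # cooperative class
        state.k[8:16] = 0.2   # selfish class
        for _ in range(n_steps):
            reaction_step(state, params, scaling, rng, engine="python")
        idx = state.replicator_indices()
        if idx.size:
            fracs.append(float(np.mean(state.k[idx, 0] > 0.5)))
    return np.asarray(fracs)


def test_one_step_replication_is_neutral_within_cells():
    """With instantaneous replication, serving as a catalyst carries no
    fitness cost: the within-cell selection gradient on k is zero.  With
    two-step replication the low-k class is favoured."""
    one = _class_competition(Variant.one_step, 80, 120, seed=21)
    two = _class_competition(Variant.two_step, 80, 120, seed=22)
    se_one = one.std(ddof=1) / math.sqrt(one.size)
    assert abs(one.mean() - 0.5) < 4 * se_one
    se = math.hypot(se_one, two.std(ddof=1) / math.sqrt(two.size))
    assert two.mean() < one.mean() - 3 * se


def test_trajectory_tsv_roundtrip(tmp_path):
    params = Params(V=20, N=200)
    res = run_simulation(params, 5, steps=100, stride=20)
    path = tmp_path / "traj.tsv"
    write_trajectory_tsv(res, path, config_hash="abc123")
    text = path.read_text()
    assert text.startswith("#") and "abc123" in text and "seed=5" in text
    back = read_trajectory_tsv(path)
    assert back.shape == res.trajectory.shape
    assert np.allclose(back["eff_kPP"], res.trajectory["eff_kPP"])


def test_snapshot_json_roundtrip(tmp_path):
    params = Params(V=20, N=200)
    res = run_simulation(params, 5, steps=50, stride=50)
    path = tmp_path / "state.json"
    write_snapshot_json(res.state, path, config_hash="abc", seed=5)
    back = read_snapshot_json(path)
    validate_state(back)
    for name in ("is_rep", "strand", "chir", "k", "partner", "role", "cell"):
        assert np.array_equal(getattr(back, name), getattr(res.state, name))
    assert back.time_step == res.state.time_step
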