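"""Deterministic micro-systems for tests and examples."""

from __future__ import annotations

from .core import Params, SystemState, validate_state

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("one_cell_three_reps", "two_cells_asym",
                 "gillespie_compartment", "broken_state")


def make_fixture(name: str, seed: int = 0) -> tuple[SystemState, Params]:
    """Build a named deterministic micro-system.

    * ``one_cell_three_reps``   one compartment, 3 replicators + 7 substrates
    * ``two_cells_asym``        two compartments with unequal k profiles
    * ``gillespie_compartment`` one well-mixed compartment (3 replicators,
      12 substrates) with distinct k values, for oracle comparisons
    * ``broken_state``          a functionally broken population
      (k_Py > 0, k_My = 0, minus strand in the minority)
    """
    if name == "one_cell_three_reps":
        state = SystemState(10, 1)
        _fill(state, [(0, 0, [1.0, 1.0, 1.0, 1.0]),
                      (1, 1, [0.8, 0.6, 0.9, 0.7]),
                      (2, 0, [0.5, 0.5, 0.5, 0.5])])
        params = Params(V=20, N=10)
    elif name == "two_cells_asym":
        state = SystemState(24, 2)
        state.cell[12:] = 1
        _fill(state, [(0, 0, [1.0, 1.0, 1.0, 1.0]),
                      (1, 1, [1.0, 1.0, 1.0, 1.0]),
                      (2, 0, [1.0, 1.0, 1.0, 1.0]),
                      (12, 0, [0.2, 0.2, 0.2, 0.2]),
                      (13, 1, [0.2, 0.2, 0.2, 0.2]),
                      (14, 0, [0.2, 0.2, 0.2, 0.2])])
        params = Params(V=20, N=24)
    elif name == "gillespie_compartment":
        state = SystemState(15, 1)
        _fill(state, [(0, 0, [1.0, 0.7, 0.4, 0.2]),
                      (1, 1, [0.3, 0.9, 0.6, 0.5]),
                      (2, 0, [0.5, 0.5, 0.5, 0.5])])
        params = Params(V=100, N=15, m=0.0)
    elif name == "broken_state":
        state = SystemState(40, 2)
        state.cell[20:] = 1
        entries = []
        for c0 in (0, 20):
            for i in range(10):
                strand = 0 if i < 7 else 1  # minority minus strand
                entries.append((c0 + i, strand, [0.6, 1.0, 0.0, 0.0]))
        _fill(state, entries)
        params = Params(V=40, N=40)
    else:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"known: {', '.join(FIXTURE_NAMES)}")
    validate_state(state)
    return state, params


def _fill(state: SystemState, entries) -> None:
    for idx, strand, k in entries:
        state.is_rep[idx] = 1
        state.strand[idx] = strand
        state.k[idx] = k
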