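"""System construction, diffusion and cell-division sub-steps, and the main
time loop.

One time step is reaction -> diffusion -> division.  Substrates diffuse
freely (each step the global substrate pool is redistributed among protocells
multinomially, with weights equal to replicator counts); replicators never
leave their protocell except by cell division.  Every protocell reaching V
particles splits into two, each particle going to a daughter with
probability 1/2 (complexes as a unit), so the number of protocells
fluctuates around 2N/V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .core import Params, SystemState, Variant, validate_state

__all__ = [
    "initialize_system",
    "diffusion_step",
    "division_step",
    "run_simulation",
    "SimulationResult",
    "TRAJECTORY_COLUMNS",
    "write_trajectory_tsv",
]

TRAJECTORY_COLUMNS = (
    "step", "n_cells", "N_P", "N_M", "n_substrate",
    "mean_kPP", "mean_kPM", "mean_kMP", "mean_kMM",
    "sd_kPP", "sd_kPM", "sd_kMP", "sd_kMM",
    "eff_kPP", "eff_kPM", "eff_kMP", "eff_kMM",
)


def initialize_system(params: Params, rng: np.random.Generator, *,
                      init_k=None, replicator_fraction: float = 0.5) -> SystemState:
    """Build the initial population: ceil(2N/V) protocells of ~V/2 particles
    (total exactly N), half replicators with equal P/M counts, and all k
    values equal to 1 unless ``init_k`` (a length-4 sequence) overrides them.
    """
    if params.N < params.V:
        raise ValueError("N must be at least V")
    n = params.N
    n_cells = -(-2 * n // params.V)  # ceil
    state = SystemState(n, n_cells)
    # cell sizes: as equal as possible, remainder round-robin
    base = n // n_cells
    rem = n % n_cells
    sizes = np.full(n_cells, base, np.int64)
    sizes[:rem] += 1
    state.cell[:] = np.repeat(np.arange(n_cells), sizes)

    if init_k is None:
        init_k = np.ones(4)
    init_k = np.asarray(init_k, dtype=float)
    if init_k.shape != (4,):
        raise ValueError("init_k must have four entries (kPP, kPM, kMP, kMM)")
    _check_ties(init_k, params)

    # within each cell: round(fraction*size) replicators, alternating strands
    offset = 0
    for c in range(n_cells):
        sz = int(sizes[c])
        n_rep = int(round(replicator_fraction * sz))
        idx = np.arange(offset, offset + n_rep)
        state.is_rep[idx] = 1
        state.strand[idx] = np.arange(n_rep) % 2
        if params.variant == Variant.cross_chiral:
            state.chir[idx] = (np.arange(n_rep) // 2) % 2
        state.k[idx] = init_k
        offset += sz
    state.time_step = 0
    return state


def _check_ties(k: np.ndarray, params: Params) -> None:
    from .core import SymmetryMode
    sym = params.symmetry_mode
    if sym in (SymmetryMode.kinetic, SymmetryMode.both):
        if k[0] != k[1] or k[2] != k[3]:
            raise ValueError("kinetic symmetry requires kPP=kPM and kMP=kMM")
    if sym in (SymmetryMode.functional, SymmetryMode.both):
        if k[0] != k[2] or k[1] != k[3]:
            raise ValueError("functional symmetry requires kPP=kMP and kPM=kMM")


def diffusion_step(system: SystemState, rng: np.random.Generator) -> SystemState:
    """Redistribute the global substrate pool multinomially (weights =
    per-cell replicator counts).  Cells without replicators receive nothing.
    Flags the run extinct when no replicator exists anywhere."""
    K._seed(int(rng.integers(2**31 - 1)))
    alive = K._diffusion_substep(system.is_rep, system.cell, system.n_cells)
    if not alive:
        system.extinct = True
    return system


def division_step(system: SystemState, rng: np.random.Generator,
                  params: Params | None = None) -> SystemState:
    """Divide every protocell with >= V particles into two daughters and
    remove empty protocells."""
    V = params.V if params is not None else _infer_V(system)
    as_unit = params.complexes_split_as_unit if params is not None else True
    K._seed(int(rng.integers(2**31 - 1)))
    system.n_cells = int(K._division_substep(
        system.is_rep, system.partner, system.role, system.cell,
        system.n_cells, V, as_unit))
    return system


def _infer_V(system: SystemState) -> int:
    raise ValueError("division_step requires params (to know V)")


@dataclass
class SimulationResult:
    """Trajectory summaries plus the final state of a run."""

    trajectory: pd.DataFrame
    state: SystemState
    params: Params
    steps_run: int
    extinct: bool
    seed: int | None = None

    @property
    def survived(self) -> bool:
        return not self.extinct


def run_simulation(params: Params, rng: np.random.Generator | int, *,
                   steps: int = 10_000, stride: int = 1_000,
                   init_k=None, replicator_fraction: float = 0.5,
                   state: SystemState | None = None,
                   check_invariants: bool = False) -> SimulationResult:
    """Run the full model for ``steps`` time steps.

    Records one summary row every ``stride`` steps (population strand counts,
    substrate count, protocell count, and the mean/sd of each k_xy over all
    replicators, plus the mean of the rectified rates max(k, 0)).
    Terminates early, flagged extinct, when the last replicator decays.
    """
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(rng)
    if state is None:
        state = initialize_system(params, rng, init_k=init_k,
                                  replicator_fraction=replicator_fraction)
    if check_invariants:
        validate_state(state)
    n_rows = steps // stride + 2 if stride > 0 else 1
    rec = np.full((n_rows, K.N_RECORD_COLS), np.nan)
    kernel_seed = int(rng.integers(2**31 - 1))
    n_cells, steps_done, extinct, rows = K._run_steps(
        state.is_rep, state.strand, state.chir, state.k, state.partner,
        state.role, state.cell, state.n_cells, params.V, params.d, params.m,
        params.delta, params.k_upper_value, int(params.mutation_method),
        int(params.symmetry_mode), int(params.variant), params.mutate_all,
        params.complexes_split_as_unit, steps, stride, rec,
        state.time_step, kernel_seed)
    state.n_cells = int(n_cells)
    state.time_step += int(steps_done)
    state.extinct = bool(extinct)
    if check_invariants:
        validate_state(state)
    traj = pd.DataFrame(rec[:rows], columns=list(TRAJECTORY_COLUMNS))
    for col in ("step", "n_cells", "N_P", "N_M", "n_substrate"):
        traj[col] = traj[col].astype("int64")
    return SimulationResult(trajectory=traj, state=state, params=params,
                            steps_run=int(steps_done), extinct=bool(extinct),
                            seed=seed)


def write_trajectory_tsv(result: SimulationResult, path, *,
                         config_hash: str = "", seed=None) -> None:
    """Write the trajectory as TSV with a provenance header line."""
    seed = result.seed if seed is None else seed
    with open(path, "w") as fh:
        fh.write(f"# protocell trajectory\tconfig_hash={config_hash}\t"
                 f"seed={seed}\textinct={result.extinct}\n")
        result.trajectory.to_csv(fh, sep="\t", index=False)


def read_trajectory_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_snapshot_json(state: SystemState, path, *, config_hash: str = "",
                        seed=None) -> None:
    """Serialise the full particle state as JSON (with provenance fields)."""
    import json
    payload = {
        "config_hash": config_hash,
        "seed": seed,
        "time_step": state.time_step,
        "n_cells": state.n_cells,
        "extinct": state.extinct,
        "is_rep": state.is_rep.tolist(),
        "strand": state.strand.tolist(),
        "chir": state.chir.tolist(),
        "k": state.k.tolist(),
        "partner": state.partner.tolist(),
        "role": state.role.tolist(),
        "cell": state.cell.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_snapshot_json(path) -> SystemState:
    import json
    with open(path) as fh:
        payload = json.load(fh)
    state = SystemState(len(payload["is_rep"]), payload["n_cells"])
    state.is_rep[:] = payload["is_rep"]
    state.strand[:] = payload["strand"]
    state.chir[:] = payload["chir"]
    state.k[:] = payload["k"]
    state.partner[:] = payload["partner"]
    state.role[:] = payload["role"]
    state.cell[:] = payload["cell"]
    state.time_step = payload["time_step"]
    state.extinct = payload["extinct"]
    return state
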