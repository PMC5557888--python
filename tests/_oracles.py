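"""Independent reference implementations used as test oracles.

These are deliberately written from the model definition alone (continuous-
time stochastic simulation, direct enumeration) and share no code with the
package's reaction kernels.
"""

from dataclasses import dataclass

import numpy as np

BETA = 0.5
GAMMA = 0.25


@dataclass
class SSAState:
    """One well-mixed compartment for the continuous-time oracle."""

    k: np.ndarray          # (n_rep, 4) rates of the replicators
    strand: np.ndarray     # (n_rep,)
    partner: np.ndarray    # complex partner index or -1
    role: np.ndarray       # 0 free, 1 catalyst, 2 template
    n_sub: int

    @property
    def n_rep(self) -> int:
        return self.strand.shape[0]

    @property
    def n(self) -> int:
        return self.n_rep + self.n_sub


def gillespie_compartment(state: SSAState, t_max: float,
                          d: float, rng: np.random.Generator):
    """Exact stochastic simulation of the single-compartment reaction network
    in continuous time (unit time = one reaction step of the discrete
    algorithm).

    Channel rates per unit time, derived from the discrete algorithm's
    per-iteration probabilities times n/alpha iterations per step:

    * complex formation (i catalyst, j template), i and j free:
      2*beta*max(k_i[x_i, x_j], 0)/(n-1)
    * replication by an existing complex with n_S substrates present:
      2*gamma*n_S*(1/(n-2) + 1/(n-1))   (the complexed member's partner is
      excluded from its Y draw, hence n-2 on one side); the product is the
      complement of the template member
    * decay of any replicator: d

    Returns a list of (time, event_type) with event_type in {"complex",
    "replication", "decay"}.
    """
    events = []
    t = 0.0
    while True:
        n = state.n
        channels = []   # (rate, kind, payload)
        free = np.flatnonzero(state.partner == -1)
        for i in free:
            for j in free:
                if i == j:
                    continue
                rate = 2 * BETA * max(
                    state.k[i, 2 * state.strand[i] + state.strand[j]], 0.0
                ) / (n - 1)
                if rate > 0:
                    channels.append((rate, "complex", (int(i), int(j))))
        if state.n_sub > 0 and n > 2:
            seen = set()
            for i in range(state.n_rep):
                p = int(state.partner[i])
                if p >= 0 and i not in seen:
                    seen.update((i, p))
                    rate = 2 * GAMMA * state.n_sub * (1.0 / (n - 2)
                                                      + 1.0 / (n - 1))
                    channels.append((rate, "replication", (i, p)))
        for i in range(state.n_rep):
            channels.append((d, "decay", (i,)))
        if not channels:
            break
        rates = np.array([c[0] for c in channels])
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        kind, payload = channels[
            int(rng.choice(len(channels), p=rates / total))][1:]
        events.append((t, kind))
        if kind == "complex":
            i, j = payload
            state.partner[i] = j
            state.partner[j] = i
            state.role[i] = 1
            state.role[j] = 2
        elif kind == "replication":
            i, p = payload
            tem = i if state.role[i] == 2 else p
            state.k = np.vstack([state.k, state.k[tem][None, :]])
            state.strand = np.append(state.strand, 1 - state.strand[tem])
            state.partner = np.append(state.partner, -1)
            state.role = np.append(state.role, 0)
            state.partner[i] = -1
            state.partner[p] = -1
            state.role[i] = 0
            state.role[p] = 0
            state.n_sub -= 1
        else:
            (i,) = payload
            p = int(state.partner[i])
            if p >= 0:
                state.partner[p] = -1
                state.role[p] = 0
            keep = np.ones(state.n_rep, bool)
            keep[i] = False
            remap = np.cumsum(keep) - 1
            new_partner = state.partner[keep].copy()
            for a in range(new_partner.size):
                if new_partner[a] >= 0:
                    new_partner[a] = remap[new_partner[a]]
            state.k = state.k[keep]
            state.strand = state.strand[keep]
            state.partner = new_partner
            state.role = state.role[keep].copy()
            state.n_sub += 1
    return events


def mc_mutation_sum_variance(delta: float, groups, n_draws: int,
                             rng: np.random.Generator) -> float:
    """Monte-Carlo variance of the change in sum(k) when each tied group of
    columns receives the mean of one uniform(-delta, delta) draw per member
    (direct enumeration oracle, no package code)."""
    tot = np.zeros(n_draws)
    for g in groups:
        eps = rng.uniform(-delta, delta, size=(n_draws, len(g))).mean(axis=1)
        tot += eps * len(g)
    return float(tot.var())
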