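"""Compiled inner loops for the particle-based simulator.

All kernels operate in place on flat numpy arrays and use numba's own
``np.random`` state, which is seeded once per driver call (``_seed``).
Array conventions (shared with :mod:`protocell.core`):

* ``is_rep``  uint8, 1 for replicators, 0 for substrates
* ``strand``  uint8, 0 = plus (P), 1 = minus (M)
* ``chir``    uint8, 0 = L, 1 = D (meaningful only in the cross-chiral variant)
* ``k``       float64 (n, 4), columns ordered (k_PP, k_PM, k_MP, k_MM);
              the rate of catalyst strand ``x`` binding template strand ``y``
              sits in column ``2*x + y``
* ``partner`` int64, index of the complex partner, -1 if free
* ``role``    uint8, 0 free, 1 catalyst, 2 template
* ``cell``    int64, compact protocell ids in [0, n_cells)

Stored k values may be negative; the effective complex-formation rate is
``max(k, 0)``.
"""

import numpy as np
from numba import njit

# mutation methods
METHOD_ADDITIVE = 0          # additive, free below zero (default)
METHOD_ADDITIVE_REFLECT0 = 1  # additive, reflecting boundary at 0
METHOD_MULTIPLICATIVE = 2     # multiplicative (log-scale random walk)

# symmetry constraints on the four k_xy values
SYM_NONE = 0
SYM_KINETIC = 1      # k_PP = k_PM, k_MP = k_MM
SYM_FUNCTIONAL = 2   # k_PP = k_MP, k_PM = k_MM
SYM_BOTH = 3         # all four tied

# model variants
VARIANT_TWO_STEP = 0
VARIANT_ONE_STEP = 1
VARIANT_CROSS_CHIRAL = 2

BETA = 0.5
GAMMA = 0.25

N_RECORD_COLS = 17  # step, n_cells, N_P, N_M, n_sub, mean_k x4, sd_k x4, eff_mean_k x4


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _reflect_add(v, lo, hi):
    # fold v back into [lo, hi]; bounds may be +-inf
    for _ in range(64):
        if v > hi:
            v = 2.0 * hi - v
        elif v < lo:
            v = 2.0 * lo - v
        else:
            break
    return v


@njit(cache=True)
def _mutate_row(k, i, method, sym, delta, k_upper, mutate_all):
    """Mutate the four k values of particle ``i`` in place.

    Tied groups under a symmetry constraint share a step equal to the mean of
    as many independent draws as there are tied entries, which keeps the
    variance of the mutational change in sum(k_xy) identical to the
    unconstrained model.
    """
    hi = k_upper
    if method == METHOD_MULTIPLICATIVE:
        if sym == SYM_NONE:
            if mutate_all:
                for c in range(4):
                    k[i, c] *= 1.0 - delta + 2.0 * delta * np.random.random()
            else:
                c = np.random.randint(4)
                k[i, c] *= 1.0 - delta + 2.0 * delta * np.random.random()
        elif sym == SYM_BOTH:
            g = 0.0
            for _ in range(4):
                g += np.log(1.0 - delta + 2.0 * delta * np.random.random())
            f = np.exp(g / 4.0)
            for c in range(4):
                k[i, c] *= f
        else:
            # two tied pairs; kinetic ties (PP,PM),(MP,MM); functional (PP,MP),(PM,MM)
            for pair in range(2):
                g = np.log(1.0 - delta + 2.0 * delta * np.random.random())
                g += np.log(1.0 - delta + 2.0 * delta * np.random.random())
                f = np.exp(g / 2.0)
                if sym == SYM_KINETIC:
                    k[i, 2 * pair] *= f
                    k[i, 2 * pair + 1] *= f
                else:
                    k[i, pair] *= f
                    k[i, pair + 2] *= f
        # reflect in log space at the upper bound
        if hi < np.inf:
            for c in range(4):
                if k[i, c] > hi:
                    k[i, c] = hi * hi / k[i, c]
        return

    lo = 0.0 if method == METHOD_ADDITIVE_REFLECT0 else -np.inf
    if sym == SYM_NONE:
        if mutate_all:
            for c in range(4):
                e = -delta + 2.0 * delta * np.random.random()
                k[i, c] = _reflect_add(k[i, c] + e, lo, hi)
        else:
            c = np.random.randint(4)
            e = -delta + 2.0 * delta * np.random.random()
            k[i, c] = _reflect_add(k[i, c] + e, lo, hi)
    elif sym == SYM_BOTH:
        e = 0.0
        for _ in range(4):
            e += -delta + 2.0 * delta * np.random.random()
        e *= 0.25
        v = _reflect_add(k[i, 0] + e, lo, hi)
        for c in range(4):
            k[i, c] = v
    else:
        for pair in range(2):
            e = (-delta + 2.0 * delta * np.random.random()) * 0.5
            e += (-delta + 2.0 * delta * np.random.random()) * 0.5
            if sym == SYM_KINETIC:
                v = _reflect_add(k[i, 2 * pair] + e, lo, hi)
                k[i, 2 * pair] = v
                k[i, 2 * pair + 1] = v
            else:
                v = _reflect_add(k[i, pair] + e, lo, hi)
                k[i, pair] = v
                k[i, pair + 2] = v


@njit(cache=True)
def _do_replicate(is_rep, strand, chir, k, partner, role, member, sub,
                  m, delta, k_upper, method, sym, mutate_all):
    """Convert substrate ``sub`` into the complement of the template of
    ``member``'s complex, then dissociate the complex."""
    t = member if role[member] == 2 else partner[member]
    is_rep[sub] = 1
    strand[sub] = 1 - strand[t]
    chir[sub] = chir[t]
    for c in range(4):
        k[sub, c] = k[t, c]
    if np.random.random() < m:
        _mutate_row(k, sub, method, sym, delta, k_upper, mutate_all)
    p = partner[t]
    partner[t] = -1
    role[t] = 0
    partner[p] = -1
    role[p] = 0


@njit(cache=True)
def _reaction_substep(is_rep, strand, chir, k, partner, role, cell, n_cells,
                      n_iter, alpha, d, m, delta, k_upper, method, sym,
                      variant, mutate_all):
    """Iterate the particle-pair reaction algorithm ``n_iter`` times.

    Per iteration one particle X is drawn uniformly from all particles, a
    second particle Y uniformly from X's protocell (excluding X and X's
    complex partner), and at most one of complex formation / replication /
    decay fires, with probabilities alpha*beta*k, alpha*gamma and alpha*d
    stacked on a single uniform draw.
    """
    n = is_rep.shape[0]
    # CSR view of cell membership; membership is constant within the substep
    # (reactions flip particle types in place, they never move particles).
    size = np.zeros(n_cells, np.int64)
    for i in range(n):
        size[cell[i]] += 1
    start = np.zeros(n_cells + 1, np.int64)
    for c in range(n_cells):
        start[c + 1] = start[c] + size[c]
    pos = start[:n_cells].copy()
    order = np.empty(n, np.int64)
    for i in range(n):
        c = cell[i]
        order[pos[c]] = i
        pos[c] += 1
    nsub = np.zeros(n_cells, np.int64)
    for i in range(n):
        if is_rep[i] == 0:
            nsub[cell[i]] += 1

    ab = alpha * BETA
    ag = alpha * GAMMA
    ad = alpha * d

    for _ in range(n_iter):
        x = np.random.randint(n)
        c = cell[x]
        sz = size[c]
        n_excl = 2 if partner[x] >= 0 else 1
        y = -1
        if sz > n_excl:
            while True:
                j = order[start[c] + np.random.randint(sz)]
                if j != x and j != partner[x]:
                    y = j
                    break
        u = np.random.random()
        acc = 0.0
        if y >= 0:
            if variant != VARIANT_ONE_STEP:
                if (is_rep[x] == 1 and is_rep[y] == 1
                        and partner[x] < 0 and partner[y] < 0
                        and (variant != VARIANT_CROSS_CHIRAL or chir[x] != chir[y])):
                    kx = k[x, 2 * strand[x] + strand[y]]
                    if kx < 0.0:
                        kx = 0.0
                    acc += ab * kx
                    if u < acc:
                        partner[x] = y
                        partner[y] = x
                        role[x] = 1
                        role[y] = 2
                        continue
                    ky = k[y, 2 * strand[y] + strand[x]]
                    if ky < 0.0:
                        ky = 0.0
                    acc += ab * ky
                    if u < acc:
                        partner[x] = y
                        partner[y] = x
                        role[y] = 1
                        role[x] = 2
                        continue
                elif is_rep[x] == 1 and partner[x] >= 0 and is_rep[y] == 0:
                    acc += ag
                    if u < acc:
                        _do_replicate(is_rep, strand, chir, k, partner, role,
                                      x, y, m, delta, k_upper, method, sym,
                                      mutate_all)
                        nsub[c] -= 1
                        continue
                elif is_rep[x] == 0 and is_rep[y] == 1 and partner[y] >= 0:
                    acc += ag
                    if u < acc:
                        _do_replicate(is_rep, strand, chir, k, partner, role,
                                      y, x, m, delta, k_upper, method, sym,
                                      mutate_all)
                        nsub[c] -= 1
                        continue
            else:
                # one-step replication: a successful catalyst-template
                # encounter immediately converts one substrate (if any) into
                # the complement of the template; no complex persists.
                if is_rep[x] == 1 and is_rep[y] == 1:
                    kx = k[x, 2 * strand[x] + strand[y]]
                    if kx < 0.0:
                        kx = 0.0
                    acc += ab * kx
                    if u < acc:
                        if nsub[c] > 0:
                            _one_step_copy(is_rep, strand, chir, k, order,
                                           start, size, c, y, m, delta,
                                           k_upper, method, sym, mutate_all)
                            nsub[c] -= 1
                        continue
                    ky = k[y, 2 * strand[y] + strand[x]]
                    if ky < 0.0:
                        ky = 0.0
                    acc += ab * ky
                    if u < acc:
                        if nsub[c] > 0:
                            _one_step_copy(is_rep, strand, chir, k, order,
                                           start, size, c, x, m, delta,
                                           k_upper, method, sym, mutate_all)
                            nsub[c] -= 1
                        continue
        if is_rep[x] == 1:
            acc += ad
            if u < acc:
                p = partner[x]
                if p >= 0:
                    partner[p] = -1
                    role[p] = 0
                    partner[x] = -1
                    role[x] = 0
                is_rep[x] = 0
                nsub[c] += 1


@njit(cache=True)
def _one_step_copy(is_rep, strand, chir, k, order, start, size, c, templ,
                   m, delta, k_upper, method, sym, mutate_all):
    # convert a uniformly chosen substrate of cell c into the complement of
    # ``templ``; the caller guarantees the cell holds at least one substrate
    while True:
        s = order[start[c] + np.random.randint(size[c])]
        if is_rep[s] == 0:
            break
    is_rep[s] = 1
    strand[s] = 1 - strand[templ]
    chir[s] = chir[templ]
    for q in range(4):
        k[s, q] = k[templ, q]
    if np.random.random() < m:
        _mutate_row(k, s, method, sym, delta, k_upper, mutate_all)


@njit(cache=True)
def _diffusion_substep(is_rep, cell, n_cells):
    """Redistribute all substrates among protocells with probabilities
    proportional to each cell's replicator count (multinomial).

    Returns False when no replicator exists anywhere (extinction); substrates
    are then left in place.
    """
    n = is_rep.shape[0]
    w = np.zeros(n_cells, np.float64)
    alive = 0
    for i in range(n):
        if is_rep[i] == 1:
            w[cell[i]] += 1.0
            alive += 1
    if alive == 0:
        return False
    cw = np.cumsum(w)
    tot = cw[n_cells - 1]
    for i in range(n):
        if is_rep[i] == 0:
            u = np.random.random() * tot
            lo = 0
            hi = n_cells - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if cw[mid] <= u:
                    lo = mid + 1
                else:
                    hi = mid
            cell[i] = lo
    return True


@njit(cache=True)
def _division_substep(is_rep, partner, role, cell, n_cells, V, as_unit):
    """Split every protocell holding >= V particles into two daughters
    (each particle to a daughter with probability 1/2; complexes move as a
    unit unless ``as_unit`` is False, in which case they dissociate first),
    then drop empty cells and compact ids.  Returns the new cell count."""
    n = cell.shape[0]
    size = np.zeros(n_cells, np.int64)
    for i in range(n):
        size[cell[i]] += 1
    nc = n_cells
    for c in range(n_cells):
        if size[c] >= V:
            if not as_unit:
                for i in range(n):
                    if cell[i] == c and partner[i] >= 0:
                        p = partner[i]
                        partner[i] = -1
                        role[i] = 0
                        partner[p] = -1
                        role[p] = 0
            for i in range(n):
                if cell[i] == c:
                    p = partner[i]
                    if p >= 0 and p < i:
                        cell[i] = cell[p]  # complexes segregate as one unit
                    elif np.random.random() < 0.5:
                        cell[i] = nc
            nc += 1
    # compact: drop empty ids
    size2 = np.zeros(nc, np.int64)
    for i in range(n):
        size2[cell[i]] += 1
    remap = np.empty(nc, np.int64)
    m = 0
    for c in range(nc):
        if size2[c] > 0:
            remap[c] = m
            m += 1
        else:
            remap[c] = -1
    for i in range(n):
        cell[i] = remap[cell[i]]
    return m


@njit(cache=True)
def _record_row(rec, row, step, n_cells, is_rep, strand, k):
    n = is_rep.shape[0]
    n_p = 0
    n_m = 0
    s1 = np.zeros(4)
    s2 = np.zeros(4)
    se = np.zeros(4)
    for i in range(n):
        if is_rep[i] == 1:
            if strand[i] == 0:
                n_p += 1
            else:
                n_m += 1
            for c in range(4):
                v = k[i, c]
                s1[c] += v
                s2[c] += v * v
                if v > 0.0:
                    se[c] += v
    nr = n_p + n_m
    rec[row, 0] = step
    rec[row, 1] = n_cells
    rec[row, 2] = n_p
    rec[row, 3] = n_m
    rec[row, 4] = n - nr
    for c in range(4):
        if nr > 0:
            mu = s1[c] / nr
            var = s2[c] / nr - mu * mu
            if var < 0.0:
                var = 0.0
            rec[row, 5 + c] = mu
            rec[row, 9 + c] = np.sqrt(var)
            rec[row, 13 + c] = se[c] / nr
        else:
            rec[row, 5 + c] = np.nan
            rec[row, 9 + c] = np.nan
            rec[row, 13 + c] = np.nan


@njit(cache=True)
def _effective_kmax(is_rep, k):
    km = 0.0
    for i in range(is_rep.shape[0]):
        if is_rep[i] == 1:
            for c in range(4):
                if k[i, c] > km:
                    km = k[i, c]
    return km


@njit(cache=True)
def _run_steps(is_rep, strand, chir, k, partner, role, cell, n_cells,
               V, d, m, delta, k_upper, method, sym, variant, mutate_all,
               as_unit, n_steps, stride, rec, start_step, seed):
    """Main time loop: reaction -> diffusion -> division, recording summary
    rows every ``stride`` steps.  Returns (n_cells, steps_done, extinct,
    n_rows_recorded)."""
    np.random.seed(seed)
    n = is_rep.shape[0]
    extinct = False
    row = 0
    steps_done = 0
    for s in range(n_steps):
        if k_upper < np.inf:
            alpha = 1.0 / (k_upper + GAMMA + d)
        else:
            km = _effective_kmax(is_rep, k)
            alpha = 1.0 / (km + GAMMA + d)
        x = n / alpha
        n_iter = int(x)
        if np.random.random() < x - n_iter:
            n_iter += 1
        _reaction_substep(is_rep, strand, chir, k, partner, role, cell,
                          n_cells, n_iter, alpha, d, m, delta, k_upper,
                          method, sym, variant, mutate_all)
        alive = _diffusion_substep(is_rep, cell, n_cells)
        if not alive:
            extinct = True
            steps_done = s + 1
            if row < rec.shape[0]:
                _record_row(rec, row, start_step + s + 1, n_cells, is_rep,
                            strand, k)
                row += 1
            break
        n_cells = _division_substep(is_rep, partner, role, cell, n_cells, V,
                                    as_unit)
        steps_done = s + 1
        if stride > 0 and (s + 1) % stride == 0 and row < rec.shape[0]:
            _record_row(rec, row, start_step + s + 1, n_cells, is_rep, strand, k)
            row += 1
    return n_cells, steps_done, extinct, row


# ---------------------------------------------------------------------------
# minimal hierarchical Moran process
# ---------------------------------------------------------------------------

@njit(cache=True)
def _minimal_run(k1, k2, cell, n_cells0, V, r, m, delta, k_upper, rectified,
                 death_within_cell, n_steps, stride, rec, seed):
    """Birth-death chain on a fixed-size replicator population partitioned
    into protocells.  One fitness-proportional birth and one random death per
    step; cells exceeding V replicators split binomially.

    ``rec`` rows: (step, mean_k1, mean_k2, asymmetry, n_cells).
    Returns the number of rows recorded.
    """
    np.random.seed(seed)
    n = k1.shape[0]
    cap = 2 * n + 4
    sum1 = np.zeros(cap)
    sum2 = np.zeros(cap)
    cnt = np.zeros(cap, np.int64)
    for i in range(n):
        c = cell[i]
        sum1[c] += k1[i]
        sum2[c] += k2[i]
        cnt[c] += 1
    free = np.empty(cap, np.int64)
    n_free = 0
    for c in range(cap - 1, n_cells0 - 1, -1):
        free[n_free] = c
        n_free += 1
    n_active = n_cells0
    f = np.empty(n)
    row = 0
    for s in range(n_steps):
        tot = 0.0
        for i in range(n):
            c = cell[i]
            m1 = sum1[c] / cnt[c]
            m2 = sum2[c] / cnt[c]
            a = k1[i]
            b = k2[i]
            if rectified:
                if m1 < 0.0:
                    m1 = 0.0
                if m2 < 0.0:
                    m2 = 0.0
                if a < 0.0:
                    a = 0.0
                if b < 0.0:
                    b = 0.0
            fi = np.exp(m1 + m2 - r * (a + b))
            f[i] = fi
            tot += fi
        u = np.random.random() * tot
        acc = 0.0
        parent = n - 1
        for i in range(n):
            acc += f[i]
            if u < acc:
                parent = i
                break
        pc = cell[parent]
        c1 = k1[parent]
        c2 = k2[parent]
        if np.random.random() < m:
            c1 += -delta + 2.0 * delta * np.random.random()
            if rectified and c1 > k_upper:
                c1 = 2.0 * k_upper - c1
        if np.random.random() < m:
            c2 += -delta + 2.0 * delta * np.random.random()
            if rectified and c2 > k_upper:
                c2 = 2.0 * k_upper - c2
        # death: uniform (global) or within the parent's cell
        if death_within_cell:
            # pick uniformly among members of pc
            target = np.random.randint(cnt[pc])
            victim = -1
            seen = 0
            for i in range(n):
                if cell[i] == pc:
                    if seen == target:
                        victim = i
                        break
                    seen += 1
        else:
            victim = np.random.randint(n)
        vc = cell[victim]
        sum1[vc] -= k1[victim]
        sum2[vc] -= k2[victim]
        cnt[vc] -= 1
        k1[victim] = c1
        k2[victim] = c2
        cell[victim] = pc
        sum1[pc] += c1
        sum2[pc] += c2
        cnt[pc] += 1
        if cnt[vc] == 0:
            free[n_free] = vc
            n_free += 1
            n_active -= 1
        # division
        if cnt[pc] > V:
            dc = free[n_free - 1]
            n_free -= 1
            for i in range(n):
                if cell[i] == pc and np.random.random() < 0.5:
                    cell[i] = dc
                    sum1[pc] -= k1[i]
                    sum2[pc] -= k2[i]
                    cnt[pc] -= 1
                    sum1[dc] += k1[i]
                    sum2[dc] += k2[i]
                    cnt[dc] += 1
            if cnt[dc] == 0:
                free[n_free] = dc
                n_free += 1
            elif cnt[pc] == 0:
                free[n_free] = pc
                n_free += 1
                n_active += 0
            else:
                n_active += 1
        if stride > 0 and (s + 1) % stride == 0 and row < rec.shape[0]:
            mu1 = 0.0
            mu2 = 0.0
            for i in range(n):
                a = k1[i]
                b = k2[i]
                if rectified:
                    if a < 0.0:
                        a = 0.0
                    if b < 0.0:
                        b = 0.0
                mu1 += a
                mu2 += b
            mu1 /= n
            mu2 /= n
            den = mu1 + mu2
            if rectified:
                asym = np.abs(mu1 - mu2) / den if den > 0.0 else np.nan
            else:
                asym = np.abs(mu1 - mu2) / np.abs(den) if den != 0.0 else np.nan
            rec[row, 0] = s + 1
            rec[row, 1] = mu1
            rec[row, 2] = mu2
            rec[row, 3] = asym
            rec[row, 4] = n_active
            row += 1
    return row
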