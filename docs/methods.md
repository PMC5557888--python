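# Methods

This note records the model as implemented, the numerical choices made where
the design was genuinely open, and what the bundled tests do and do not
establish.

## The particle model

The system holds a fixed number `N` of particles — replicators and
substrates — partitioned into protocells.  A replicator carries a strand
label (`P` or `M`), four complex-formation rates `k_xy` with
`x, y ∈ {P, M}` (stored as `(k_PP, k_PM, k_MP, k_MM)`), and a complex state
(free, catalyst, or template, with a partner reference).  Substrates are
anonymous.  One time step is three sub-steps, in order: **reaction**,
**diffusion**, **division**.

### Reaction

The reaction sub-step iterates a pair-sampling algorithm `N/α` times.  Each
iteration draws a particle `X` uniformly from all `N` particles, then a
second particle `Y` uniformly from `X`'s protocell, excluding `X` itself and
`X`'s complex partner (a cell's volume is taken proportional to its particle
count, so the per-pair encounter rate is inversely proportional to cell
size).  If no eligible `Y` exists, only `X`'s decay is attempted.  A single
uniform draw then selects at most one event:

* **complex formation** (both `X`, `Y` free replicators): `X` catalyses `Y`
  with probability `αβ·max(k_xy^X, 0)`, else `Y` catalyses `X` with
  probability `αβ·max(k_yx^Y, 0)`;
* **replication** (one of the pair is a complexed replicator, the other a
  substrate): with probability `αγ` the substrate becomes the *complement*
  of the template (k values copied, then mutated with probability `m`), and
  the complex dissociates;
* **decay** (`X` a replicator): with probability `αd`, `X` reverts to a
  substrate, dissociating its complex first.  `Y` never decays.

`β = 1/2` cancels the two orders in which a pair can be drawn; `γ = 1/4`
cancels both the two orders and the doubled chance of hitting a two-particle
complex; `α = 1/(k_max + 1/4 + d)` makes the stacked probabilities sum to at
most one at the largest admissible rate.  With these choices the realised
per-step event rates are `k_xy · N_y/N^v` (complex formation), `1` per
complex-substrate pair class (replication), and `d` (decay), and on a single
well-mixed compartment the algorithm is statistically equivalent to an exact
continuous-time stochastic simulation of the same network — the test suite
verifies this against an independently written Gillespie oracle, including
the `1/(n−2)` vs `1/(n−1)` finite-size corrections from the partner
exclusion in the `Y` draw.

`N/α` is generally not an integer: the loop runs `⌊N/α⌋` iterations plus one
more with probability equal to the fractional part, which keeps the expected
iteration count exact without biasing relative rates.  When `k` is bounded
(`k_upper = 1` by default) `α` is a constant; when unbounded (the lineage
assays) `α` is recomputed every time step from the current maximum effective
rate in the system.

### Mutation

A replication event mutates the offspring's k values with probability `m`;
a mutation event perturbs **all four** values, each with an independent
step (the derivation of the fitness-variance argument below requires the
traits' mutations to be uncorrelated; a switch to mutate a single random
entry instead is exposed).  Three step kernels are implemented:

1. **additive** (default): `k += ε`, `ε ~ U(−δ, δ)`, reflecting boundary at
   `k_upper`, *no lower bound* — negative values are stored and simply act
   as rate 0.  This removes any boundary effect at `k = 0`.
2. **additive with reflection at 0**: as above plus a reflecting boundary
   at 0.
3. **multiplicative**: `k *= u`, `u ~ U(1−δ, 1+δ)` (a log-scale random
   walk); reflection at `k_upper` is performed in log space
   (`k → k_upper²/k`) to preserve the walk's character.

When a symmetry constraint ties k entries together (kinetic:
`k_PP = k_PM`, `k_MP = k_MM`; functional: `k_PP = k_MP`, `k_PM = k_MM`;
both: all four), each tied group is perturbed by the *mean* of as many
independent draws as the group has members (log-mean for the multiplicative
kernel).  This correction keeps the variance of the mutational change in
`Σk_xy` at exactly `4δ²/3` in every mode, so constrained and unconstrained
models see the same mutational input and remain comparable.  Ties are
preserved bit-exactly; reflection of a tied group reflects the shared value.

### Diffusion and division

Each step, the entire substrate pool is redistributed among protocells
multinomially with weights equal to replicator counts (substrates diffuse
infinitely fast; replicators not at all).  Cells without replicators receive
nothing.  If no replicator exists anywhere the run is flagged extinct.

Every protocell with `≥ V` particles then splits: each particle joins a
daughter with probability 1/2.  A catalyst–template complex is one physical
object and segregates as a unit (a flag switches to dissociation at
division for sensitivity analysis).  Empty cells are removed.  Under these
rules the number of protocells is conventionally estimated as `2N/V` (mean
cell size `V/2`).  The simulated stationary count is actually ≈ `2.7 N/V`:
the cell-size distribution of the driftless growth–splitting–death process
is flat below `V/2` and falls off as `(V−s)/s` above it, putting the mean
size near `0.36V`.  `scripts/acceptance.py` computes this count at `V=100`,
`N=50V`; an independent from-scratch reimplementation of the model gives
the same value, so we report the computed number rather than the rule of
thumb.

### Variants

* **one-step replication**: a successful catalyst–template encounter
  (probability `αβk`) immediately converts one uniformly chosen substrate of
  the same cell into the complement of the template; no complex ever exists.
  If the cell holds no substrate the event is consumed without effect.
  Because catalysing costs no templating opportunity here, within-cell
  selection on `k` is neutral (verified by a class-competition test) and no
  symmetry breaking is expected.
* **cross-chiral**: four replicator classes `L_P, L_M, D_P, D_M`; complexes
  form only between opposite chiralities, with rates read from the
  catalyst's `k_xy` by strand indices; replication preserves the template's
  chirality and complements its strand; both chiralities share the
  substrate pool.

## The minimal hierarchical Moran model

Replicators carry two cooperativity values `(k₁, k₂)` and live in cells that
split binomially when exceeding `V` members.  Per step: one
fitness-proportional birth (offspring in the parent's cell; each trait
mutated with probability `m` by `U(−δ, δ)`) and one uniformly random death
(global by default; within-cell death is available as a flag).  Fitness is

    f = exp(k̄₁ + k̄₂ − r(k₁ + k₂)),   0 < r < 1,

with `k̄ᵢ` the cell means.  The cell-mean terms reward cooperative
compartments; the `−r(k₁+k₂)` term prices cooperation individually, so the
levels conflict.  Two variance modes:

* **rectified**: every `k` entering `f` is clamped at 0 from below, so
  `∂f/∂kᵢ = 0` for `kᵢ < 0` and the mutational variance of `f` collapses
  when a trait pins to the boundary; `k_upper = 1` reflects, mirroring the
  main model.
* **invariant**: no clamping and no bounds, so the mutational variance of
  `f` does not depend on where the traits sit.

Parameter choice: the main-text description fixes only `0 < r < 1`; we use
`r = 0.3`.  Mutation and size parameters (`m = 0.1`, `δ = 0.2`,
`n_total = 3000`, `V = 300`, i.e. ≈ 20 cells) were chosen once, by scanning
the model's own regimes, so that all three phases are reachable within a
few million birth–death events on one CPU: at `V ≈ 100` cellular selection
maximises both traits, at `V ≈ 300` the rectified mode breaks symmetry (one
trait pinned at ≤ 0, the other maintained, asymmetry → 1), and at
`V ≈ 600` molecular selection minimises both.  In invariant mode at the
same `V = 300` both traits drift downward together and the asymmetry index
stays small — the contrast that the acceptance test asserts.  The
asymmetry index `|(k₁−k₂)/(k₁+k₂)|` is computed on clamped population means
in rectified mode (a fully broken state maps to exactly 1) and on raw means
in invariant mode.

## Lineage assays

A single protocell is followed against an infinite, stationary background
population characterised by its replicator density `N'_R/(N'_R+N'_S)`.  The
reaction step is unchanged; the diffusion step replaces the cell's substrate
count by a Poisson draw with mean `n_R·N'_S/N'_R`; at division one daughter
is kept at random.  The assay records divisions along the line of descent,
the minimum particle and replicator counts, and bottleneck-induced growth
restoration — at least one division after the particle count has dropped
below `0.3V`.  `k` is unbounded above here and `α` is recomputed per step.

Initial k profiles are calibrated so that different asymmetry profiles start
at equal cell fitness: a closed-cell pilot simulation (no substrate
exchange, no mutation) is bisected on a scalar multiplier until the
steady-state replicator density matches the target.  Two properties of the
closed cell matter in practice: the density–k curve is a plateau
(≈ `1 − 4d`-ish) with a steep drop to extinction at small k, and pair
formation gives small populations an Allee effect, so targets must lie on
the stable monotone slope just below the plateau; the calibration raises a
diagnostic error listing the achievable range otherwise.  Test
configurations scale the assay down (`V = 120–400`, `m = 0.1–0.2`,
`δ = 0.3–0.5`) so that a lineage completes its life cycle in thousands of
steps rather than the much longer horizons of the full-scale setting
(`V = 1700–2500`, `m = 0.01`).

## Analysis conventions

* Population mean `k_xy` values used in the asymmetry metrics are means of
  the *rectified* per-replicator rates `max(k, 0)`; trajectories also record
  raw means and standard deviations.  A metric whose denominator is not
  positive is flagged undefined.
* `N_e = 2(1/N_P + 1/N_M)⁻¹ = (1+θ)(1−θ)(N_P+N_M)/2`; zero if either
  strand is absent.
* Phase classification: *extinct* if replicators reached zero; *broken* if
  the time-averaged `|a_f|` exceeds 0.5 **and** the minor strand's raw
  catalytic aggregate is statistically indistinguishable from ≤ 0 (within
  two standard errors); *symmetric* otherwise.  The 0.5 threshold is an
  operationalisation (the original classification was by inspection) and is
  exposed as a parameter.  With trajectories from several initial
  conditions, label disagreement sets a metastability flag.
* The `(m, V)` phase-scan boundary slope is the log–log regression of the
  smallest symmetry-breaking `m` on `V`; the expected scaling
  `mV ∝ 1/V` corresponds to slope −2 (asserted at ±0.5 on synthetic
  boundaries; full-scale scans are cluster-scale and out of desk scope).

## Reproducibility and engines

Every run is driven by a single integer seed: numpy `Generator` streams for
Python-level sampling and derived 31-bit seeds for the numba kernels' own
RNG.  Identical (config, seed) pairs produce byte-identical TSV outputs.
The reaction step has two interchangeable engines — a readable pure-Python
reference loop (which also supports event logging) and the compiled numba
kernel used by the main time loop — and the suite checks their statistical
agreement on fixtures.  Trajectory writers emit TSV with a header naming the
config hash and seed; full-state snapshots serialise to JSON.

## Problem sizes used by the bundled checks

Conservation and algebra checks run on 400-particle systems for 10⁴ steps
and 10⁵ Monte-Carlo mutation draws; the Gillespie comparison uses a
15-particle compartment over 150 time steps × 40 replicates; the
directionality demonstration uses `V = 50, N = 2500` for 2×10⁵ steps
(rising) and `V = 2000, N = 10⁵` for 3×10³ steps (falling); the minimal
model runs 3×10⁶ birth–death events; the protocell-count measurement uses
`V = 100, N = 5000` over 1.2×10⁴ steps, averaged over three seeds.

## What the tests do and do not show

The synthetic systems exercise the model's own dynamics; they are not data.
Desk-scale runs demonstrate the *direction* of each regime and the
existence of the minimal model's symmetry breaking, not the full-scale
phase boundaries (`V ≈ 650–8000` at `m = 0.01`, `N = 50V`, ≥10⁷ steps),
which are cluster-scale by several orders of magnitude.  Known limitations:
no spatial structure within or between protocells; no explicit sequences or
folding phenotypes (the minimal model's fitness function is pluggable for
such extensions); no parasite-emergence variant; the phase classifier
assumes equilibrated trajectories.
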