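"""Summary statistics, asymmetry metrics, effective population size, the
mutational-variance estimator, and phase classification / scans.

Asymmetry metrics (population means of the rectified rates max(k, 0)):

* kinetic      kappa = (k_PM - k_PP) / (k_PM + k_PP)
* copy-number  theta = (N_P - N_M) / (N_P + N_M)
* functional   a_f   = (k_P - k_M) / (k_P + k_M), with k_P and k_M the
  catalytic aggregates of each strand (row means of k_Py and k_My; exactly
  the tied values when kinetic symmetry is imposed).

The variance effective population size of an alternating-strand population
is the harmonic mean N_e = 2 (1/N_P + 1/N_M)^-1 = (1+theta)(1-theta)(N_P+N_M)/2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AsymmetryMetrics",
    "MutationalVarianceEstimate",
    "asymmetry_metrics",
    "effective_population_size",
    "mutational_variance",
    "minimal_model_gradient",
    "equilibrium_summary",
    "classify_phase",
    "phase_scan",
    "boundary_slope",
]


@dataclass(frozen=True)
class AsymmetryMetrics:
    kinetic: float       # kappa
    copy_number: float   # theta
    functional: float    # a_f
    kinetic_defined: bool = True
    copy_number_defined: bool = True
    functional_defined: bool = True


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den <= 0:
        return np.nan, False
    return num / den, True


def asymmetry_metrics(system_or_k, strand=None, is_rep=None) -> AsymmetryMetrics:
    """Asymmetry metrics of a replicator population.

    Accepts either a :class:`~protocell.core.SystemState` or a pair of
    arrays ``(k (n,4), strand (n,))`` restricted to replicators.  Mean k
    values are of the rectified rates max(k, 0); a metric whose denominator
    is not positive is flagged undefined (NaN).
    """
    if strand is None:
        sys = system_or_k
        idx = sys.replicator_indices()
        if idx.size == 0:
            raise ValueError("no replicators in the population")
        k = sys.k[idx]
        strand = sys.strand[idx]
    else:
        k = np.asarray(system_or_k, float)
        strand = np.asarray(strand)
        if is_rep is not None:
            k = k[is_rep == 1]
            strand = strand[is_rep == 1]
        if k.shape[0] == 0:
            raise ValueError("no replicators in the population")
    ke = np.maximum(k, 0.0).mean(axis=0)  # (kPP, kPM, kMP, kMM)
    n_p = int(np.sum(strand == 0))
    n_m = int(np.sum(strand == 1))
    kappa, kap_ok = _ratio(ke[1] - ke[0], ke[1] + ke[0])
    theta, th_ok = _ratio(n_p - n_m, n_p + n_m)
    k_p = 0.5 * (ke[0] + ke[1])
    k_m = 0.5 * (ke[2] + ke[3])
    a_f, af_ok = _ratio(k_p - k_m, k_p + k_m)
    return AsymmetryMetrics(kinetic=kappa, copy_number=theta, functional=a_f,
                            kinetic_defined=kap_ok, copy_number_defined=th_ok,
                            functional_defined=af_ok)


def effective_population_size(n_p: int, n_m: int) -> float:
    """Variance effective population size 2(1/N_P + 1/N_M)^-1 of an
    alternating-strand population; 0 when either strand is absent."""
    if n_p < 0 or n_m < 0:
        raise ValueError("strand counts must be non-negative")
    if n_p == 0 and n_m == 0:
        raise ValueError("at least one strand must be present")
    if n_p == 0 or n_m == 0:
        return 0.0
    return 2.0 / (1.0 / n_p + 1.0 / n_m)


@dataclass(frozen=True)
class MutationalVarianceEstimate:
    sigma2_f: float
    term_P: float
    term_M: float


def mutational_variance(k_p: np.ndarray, k_m: np.ndarray,
                        gradient) -> MutationalVarianceEstimate:
    """Mutational variance of replicator fitness within one protocell,

        sigma_f^2 ~ (df/dk_P)^2 sigma_kP^2 + (df/dk_M)^2 sigma_kM^2,

    with the derivatives (supplied by ``gradient(mean_kP, mean_kM) ->
    (df/dk_P, df/dk_M)``) evaluated at the per-cell average values and a term
    set to zero when the corresponding mean is negative (a trait pinned
    below the boundary contributes no fitness variation).
    """
    k_p = np.asarray(k_p, float)
    k_m = np.asarray(k_m, float)
    if k_p.size < 2 or k_m.size < 2:
        raise ValueError("need at least two replicators per cell")
    m_p, m_m = float(k_p.mean()), float(k_m.mean())
    g_p, g_m = gradient(m_p, m_m)
    term_p = 0.0 if m_p < 0 else float(g_p) ** 2 * float(k_p.var())
    term_m = 0.0 if m_m < 0 else float(g_m) ** 2 * float(k_m.var())
    return MutationalVarianceEstimate(sigma2_f=term_p + term_m,
                                      term_P=term_p, term_M=term_m)


def minimal_model_gradient(r: float, rectified: bool = True):
    """Analytic within-cell fitness gradient of the minimal Moran model,
    df/dk_i = -r f evaluated at the cell means (zero below the boundary in
    rectified mode)."""
    def gradient(m1: float, m2: float):
        a = max(m1, 0.0) if rectified else m1
        b = max(m2, 0.0) if rectified else m2
        f = np.exp(a + b - r * (a + b))
        g1 = 0.0 if (rectified and m1 < 0) else -r * f
        g2 = 0.0 if (rectified and m2 < 0) else -r * f
        return g1, g2
    return gradient


# ---------------------------------------------------------------------------
# trajectory summaries and phase classification
# ---------------------------------------------------------------------------

_SWAP = {"mean_kPP": "mean_kMM", "mean_kMM": "mean_kPP",
         "mean_kPM": "mean_kMP", "mean_kMP": "mean_kPM",
         "sd_kPP": "sd_kMM", "sd_kMM": "sd_kPP",
         "sd_kPM": "sd_kMP", "sd_kMP": "sd_kPM",
         "eff_kPP": "eff_kMM", "eff_kMM": "eff_kPP",
         "eff_kPM": "eff_kMP", "eff_kMP": "eff_kPM",
         "N_P": "N_M", "N_M": "N_P"}


def relabel_strands(traj: pd.DataFrame) -> pd.DataFrame:
    """Swap the P and M labels of a trajectory (k_PP<->k_MM, k_PM<->k_MP,
    N_P<->N_M); an involution used to report the non-catalytic strand as M."""
    return traj.rename(columns=_SWAP)[traj.columns]


def _catalytic_aggregates(traj: pd.DataFrame, prefix: str = "eff_"):
    k_p = 0.5 * (traj[f"{prefix}kPP"] + traj[f"{prefix}kPM"])
    k_m = 0.5 * (traj[f"{prefix}kMP"] + traj[f"{prefix}kMM"])
    return k_p, k_m


def equilibrium_summary(traj: pd.DataFrame, burn_in: int) -> pd.DataFrame:
    """Time-average (and sd) of the population-mean k_xy after ``burn_in``
    steps, with strands relabelled so that the less catalytic strand is
    reported as M."""
    post = traj[traj["step"] > burn_in]
    if len(post) == 0:
        raise ValueError("trajectory not longer than burn_in")
    alive = post[(post["N_P"] + post["N_M"]) > 0]
    if len(alive) == 0:
        return pd.DataFrame({"quantity": ["extinct"], "mean": [np.nan],
                             "sd": [np.nan]})
    k_p, k_m = _catalytic_aggregates(alive)
    if k_m.mean() > k_p.mean():
        alive = relabel_strands(alive)
    rows = []
    for col in ("mean_kPP", "mean_kPM", "mean_kMP", "mean_kMM",
                "eff_kPP", "eff_kPM", "eff_kMP", "eff_kMM",
                "N_P", "N_M", "n_cells"):
        rows.append((col, float(alive[col].mean()), float(alive[col].std(ddof=0))))
    return pd.DataFrame(rows, columns=["quantity", "mean", "sd"])


def classify_phase(trajectories, burn_in: int = 0, *,
                   af_threshold: float = 0.5) -> dict:
    """Classify equilibrated run(s) as symmetric / broken / extinct.

    A run is extinct when its replicators reach zero; broken when the
    time-averaged |a_f| (functional asymmetry of the catalytic aggregates)
    exceeds ``af_threshold`` and the minor strand's raw catalytic aggregate
    is statistically indistinguishable from <= 0; symmetric otherwise.  With
    several trajectories (different initial conditions) the metastable flag
    marks label disagreement.
    """
    if isinstance(trajectories, pd.DataFrame):
        trajectories = [trajectories]
    labels = []
    for traj in trajectories:
        labels.append(_classify_one(traj, burn_in, af_threshold))
    label = labels[0]
    metastable = len(set(labels)) > 1
    if metastable:
        non_ext = [l for l in labels if l != "extinct"]
        label = non_ext[0] if non_ext else "extinct"
    return {"label": label, "labels": labels, "metastable": metastable}


def _classify_one(traj: pd.DataFrame, burn_in: int, af_threshold: float) -> str:
    last = traj.iloc[-1]
    if last["N_P"] + last["N_M"] == 0:
        return "extinct"
    post = traj[traj["step"] > burn_in]
    if len(post) == 0:
        post = traj.tail(1)
    k_p, k_m = _catalytic_aggregates(post)
    den = k_p + k_m
    a_f = np.where(den > 0, (k_p - k_m) / den, np.nan)
    mean_af = float(np.nanmean(np.abs(a_f)))
    if not np.isfinite(mean_af) or mean_af <= af_threshold:
        return "symmetric"
    # raw catalytic aggregate of the minor strand
    raw_p, raw_m = _catalytic_aggregates(post, prefix="mean_")
    minor = raw_m if raw_p.mean() >= raw_m.mean() else raw_p
    mu = float(minor.mean())
    se = float(minor.std(ddof=0)) / max(np.sqrt(len(minor)), 1.0)
    if mu <= max(2 * se, 1e-9):
        return "broken"
    return "symmetric"


def phase_scan(m_values, V_values, *, replicates: int = 1,
               steps: int = 10_000, stride: int = 500, burn_in: int | None = None,
               seed: int = 0, af_threshold: float = 0.5,
               params_kwargs: dict | None = None) -> pd.DataFrame:
    """Run the full model over an (m, V) grid and classify each replicate.

    Returns a tidy table with one row per (m, V, replicate, label).
    """
    from .core import Params
    from .dynamics import run_simulation
    params_kwargs = dict(params_kwargs or {})
    burn_in = steps // 2 if burn_in is None else burn_in
    rows = []
    root = np.random.default_rng(seed)
    for m, V, rep in itertools.product(m_values, V_values, range(replicates)):
        params = Params(V=int(V), m=float(m), **params_kwargs)
        res = run_simulation(params, root, steps=steps, stride=stride)
        if res.extinct:
            label = "extinct"
        else:
            label = classify_phase(res.trajectory, burn_in,
                                   af_threshold=af_threshold)["label"]
        rows.append({"m": m, "V": V, "replicate": rep, "label": label,
                     "extinct": res.extinct})
    return pd.DataFrame(rows)


def boundary_slope(table: pd.DataFrame) -> float:
    """Slope of log m* against log V at the symmetric/broken boundary, where
    m* is the smallest mutation rate at which symmetry breaking is the
    majority outcome for a given V.  The expected scaling m V ~ 1/V gives a
    slope of about -2."""
    pts = []
    for V, grp in table.groupby("V"):
        broken_ms = []
        for m, g2 in grp.groupby("m"):
            frac = float((g2["label"] == "broken").mean())
            if frac > 0.5:
                broken_ms.append(m)
        if broken_ms:
            pts.append((np.log(float(V)), np.log(min(broken_ms))))
    if len(pts) < 2:
        raise ValueError("need a broken boundary at >= 2 values of V")
    x, y = np.array(pts).T
    return float(np.polyfit(x, y, 1)[0])
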