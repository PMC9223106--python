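"""Two-population divergence demography and ABC inference.

Four canonical scenarios of species-pair divergence are simulated under
the structured coalescent: strict isolation (SI), ancient migration
(AM), isolation with migration (IM), and secondary contact (SC).  Each
allows an instantaneous size change at the split (post-split bottleneck
to Nf1/Nf2 from the ancestral Na) and a later, per-population size
change at Tdem1/Tdem2 (to the current N1/N2), plus optional
genome-wide heterogeneity in effective size (per-locus Ne multiplier
drawn from a rescaled Beta: linked-selection proxy) and in effective
migration rate (a fraction of barrier loci with me = 0: semipermeable
barrier proxy).

Inference is likelihood-free: a reference table of simulations drawn
from the prior is compared to the observed summary-statistic vector
(locus-averaged diversity/divergence statistics plus a coarse-binned
folded joint site frequency spectrum) by standardized Euclidean
distance; model choice is by acceptance proportions, parameter
posteriors by the accepted particles with optional local-linear
regression adjustment.

Time is in generations backward from sampling; sizes are diploid
effective sizes; migration is parameterised as M = 4*N*m per direction
(backward lineage-movement rate m = M/(4N) per generation); theta =
4*N*mu per site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import Epoch, drop_infinite_sites, simulate_genealogy

__all__ = [
    "DemographicModel",
    "PriorConfig",
    "SummaryStatVector",
    "ABCResult",
    "simulate",
    "summary_stats",
    "jsfs",
    "build_reference_table",
    "abc_model_choice",
    "abc_estimate",
    "goodness_of_fit",
]

SCENARIOS = ("SI", "AM", "IM", "SC")


@dataclass
class DemographicModel:
    """Parameters of one two-population divergence scenario."""

    scenario: str
    Na: float
    Nf1: float
    Nf2: float
    N1: float
    N2: float
    Tsplit: float
    Tdem1: float
    Tdem2: float
    Tsc: float = 0.0           # SC: secondary-contact start; AM: migration-stop time
    M12: float = 0.0           # 4*N1*m12 (backward rate of pop1 lineages into pop2)
    M21: float = 0.0
    mu: float = 1e-8
    hetero_N: bool = False
    beta_a: float = 2.0        # Beta shape hyperparameters for the Ne multiplier
    beta_b: float = 2.0
    hetero_m: bool = False
    barrier_fraction: float = 0.0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("Na", "Nf1", "Nf2", "N1", "N2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Tsplit <= 0:
            raise ValueError("Tsplit must be > 0")
        if not (0 <= self.Tdem1 < self.Tsplit and 0 <= self.Tdem2 < self.Tsplit):
            raise ValueError("Tdem1/Tdem2 must lie in [0, Tsplit)")
        if self.scenario in ("SC", "AM") and not 0 < self.Tsc < self.Tsplit:
            raise ValueError("Tsc/Tam must lie in (0, Tsplit)")
        if self.M12 < 0 or self.M21 < 0:
            raise ValueError("migration rates must be >= 0")
        if self.scenario == "SI" and (self.M12 > 0 or self.M21 > 0):
            raise ValueError("SI requires M12 = M21 = 0")
        if not 0 <= self.barrier_fraction <= 1:
            raise ValueError("barrier_fraction must be in [0, 1]")

    def migration_window(self) -> tuple[float, float]:
        """Backward-time interval [a, b) during which migration is active."""
        if self.scenario == "SI":
            return (0.0, 0.0)
        if self.scenario == "IM":
            return (0.0, self.Tsplit)
        if self.scenario == "SC":
            return (0.0, self.Tsc)
        return (self.Tsc, self.Tsplit)  # AM: Tsc doubles as Tam


@dataclass
class PriorConfig:
    """Uniform / log-uniform prior bounds and simulation settings.

    ``bounds`` maps parameter names to (low, high); parameters in
    ``log_params`` are drawn log-uniformly.  The defaults span sizes
    1e3..2e5, split times 1e4..1e6 generations, migration 0..10 and a
    documented mutation-rate range of 5e-10..3e-8 (mu is fixed at 1e-8
    by default and only drawn when listed in ``bounds``).
    """

    bounds: dict = field(default_factory=lambda: {
        "Na": (1e3, 2e5),
        "Nf1": (1e3, 2e5),
        "Nf2": (1e3, 2e5),
        "N1": (1e3, 2e5),
        "N2": (1e3, 2e5),
        "Tsplit": (1e4, 1e6),
        "Tdem_frac1": (0.0, 1.0),   # Tdem1 = frac * Tsplit
        "Tdem_frac2": (0.0, 1.0),
        "Tsc_frac": (0.01, 0.3),    # Tsc (or Tam) = frac * Tsplit
        "M12": (0.0, 10.0),
        "M21": (0.0, 10.0),
    })
    log_params: tuple = ("Na", "Nf1", "Nf2", "N1", "N2", "Tsplit")
    mu: float = 1e-8
    mu_bounds: tuple = (5e-10, 3e-8)   # documented plausible range (not drawn)
    n_sims: int = 1000
    acceptance_fraction: float = 0.05
    n_loci: int = 50
    locus_len: int = 1000
    samples: tuple = (10, 10)
    hetero_N: bool = False
    hetero_m: bool = False

    def __post_init__(self):
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior bound for {k} has lower >= upper")

    def draw(self, scenario: str, rng) -> DemographicModel:
        v = {}
        for k, (lo, hi) in self.bounds.items():
            if k in self.log_params:
                v[k] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                v[k] = float(rng.uniform(lo, hi))
        mig = scenario != "SI"
        kwargs = dict(
            scenario=scenario,
            Na=v["Na"], Nf1=v["Nf1"], Nf2=v["Nf2"], N1=v["N1"], N2=v["N2"],
            Tsplit=v["Tsplit"],
            Tdem1=v["Tdem_frac1"] * v["Tsplit"] * 0.999,
            Tdem2=v["Tdem_frac2"] * v["Tsplit"] * 0.999,
            Tsc=v["Tsc_frac"] * v["Tsplit"] if scenario in ("SC", "AM") else 0.0,
            M12=v["M12"] if mig else 0.0,
            M21=v["M21"] if mig else 0.0,
            mu=self.mu,
            hetero_N=self.hetero_N,
            hetero_m=self.hetero_m,
            barrier_fraction=float(rng.uniform(0, 0.5)) if self.hetero_m else 0.0,
        )
        if self.hetero_N:
            kwargs["beta_a"] = float(rng.uniform(0.5, 5.0))
            kwargs["beta_b"] = float(rng.uniform(0.5, 5.0))
        return DemographicModel(**kwargs)


@dataclass
class SummaryStatVector:
    values: np.ndarray
    names: list[str]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


@dataclass
class ABCResult:
    model_probs: dict
    accepted: pd.DataFrame      # scenario + parameters of accepted particles
    distances: np.ndarray
    n_accept: int


def _epochs_for(model: DemographicModel, ne_mult: float = 1.0,
                me_mult: float = 1.0, ploidy_scale: float = 1.0):
    """Build the engine epoch list for a two-population model.

    Gene-copy counts are 2N * ne_mult * ploidy_scale; backward
    migration uses m12 = M12/(4*N1), m21 = M21/(4*N2), scaled by
    ``me_mult`` (0 for barrier loci).
    """
    m12 = me_mult * model.M12 / (4.0 * model.N1)
    m21 = me_mult * model.M21 / (4.0 * model.N2)
    win = model.migration_window()

    breaks = sorted({0.0, model.Tdem1, model.Tdem2, win[0], win[1], model.Tsplit})
    breaks = [b for b in breaks if 0.0 <= b < model.Tsplit]
    scale = 2.0 * ne_mult * ploidy_scale
    epochs = []
    for b in breaks:
        # size holding from time b onward: current size until Tdem, then Nf
        n1 = model.N1 if b < model.Tdem1 else model.Nf1
        n2 = model.N2 if b < model.Tdem2 else model.Nf2
        active = win[0] <= b < win[1]
        mig = [[0.0, m12 if active else 0.0], [m21 if active else 0.0, 0.0]]
        epochs.append(Epoch(start=b, copies=[scale * n1, scale * n2], mig=mig))
    epochs.append(
        Epoch(
            start=model.Tsplit,
            copies=[scale * model.Na, scale * model.Na],
            mig=None,
            merge=[(1, 0)],
        )
    )
    return epochs


def simulate(model: DemographicModel, n_loci: int, locus_len: int,
             samples: tuple[int, int], rng, ploidy_scale: float = 1.0):
    """Simulate a multi-locus dataset under a two-population model.

    Returns a dict with per-locus derived-allele counts:
    ``counts`` is a list of (S_locus, 2) int arrays (columns = derived
    copies in pop 1 and pop 2), plus ``samples`` (haploid sample sizes)
    and ``locus_len``/``n_loci``.  Per-locus Ne multipliers and barrier
    indicators are returned under ``truth`` for testability.
    """
    nA, nB = samples
    if nA < 2 or nB < 2:
        raise ValueError("need >= 2 sampled lineages per population")
    counts = []
    ne_mults = np.ones(n_loci)
    barriers = np.zeros(n_loci, dtype=bool)
    if model.hetero_N:
        # Beta rescaled to (0, 2]: mean ne multiplier stays near 1
        ne_mults = 2.0 * rng.beta(model.beta_a, model.beta_b, size=n_loci)
        ne_mults = np.clip(ne_mults, 1e-3, 2.0)
    if model.hetero_m:
        barriers = rng.uniform(size=n_loci) < model.barrier_fraction
    for j in range(n_loci):
        epochs = _epochs_for(
            model,
            ne_mult=float(ne_mults[j]),
            me_mult=0.0 if barriers[j] else 1.0,
            ploidy_scale=ploidy_scale,
        )
        gen = simulate_genealogy([nA, nB], epochs, rng)
        masks = drop_infinite_sites(gen, model.mu, locus_len, rng)
        popA = (1 << nA) - 1
        arr = np.empty((len(masks), 2), dtype=np.int64)
        for s, m in enumerate(masks):
            arr[s, 0] = bin(m & popA).count("1")
            arr[s, 1] = bin(m >> nA).count("1")
        counts.append(arr)
    return {
        "counts": counts,
        "samples": (nA, nB),
        "locus_len": locus_len,
        "n_loci": n_loci,
        "truth": {"model": model, "ne_mults": ne_mults, "barriers": barriers},
    }


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


_LOCUS_STATS = [
    "piA", "piB", "thetaA", "thetaB", "dxy", "netdiv", "fst", "sxA", "sxB",
    "sf", "ss",
]


def _locus_stats(arr: np.ndarray, nA: int, nB: int, L: int) -> list[float]:
    if len(arr) == 0:
        return [0.0] * len(_LOCUS_STATS)
    cA, cB = arr[:, 0].astype(float), arr[:, 1].astype(float)
    pA, pB = cA / nA, cB / nB
    piA = float(np.sum(2 * pA * (1 - pA) * nA / (nA - 1)) / L)
    piB = float(np.sum(2 * pB * (1 - pB) * nB / (nB - 1)) / L)
    segA = (cA > 0) & (cA < nA)
    segB = (cB > 0) & (cB < nB)
    thetaA = float(segA.sum() / _harmonic(nA) / L)
    thetaB = float(segB.sum() / _harmonic(nB) / L)
    mism = pA * (1 - pB) + pB * (1 - pA)
    d_xy = float(np.sum(mism) / L)
    netdiv = d_xy - (piA + piB) / 2.0
    fst = 0.0 if d_xy == 0 else float(1.0 - ((piA + piB) / 2.0) / d_xy)
    fixedA = (cA == 0) | (cA == nA)
    fixedB = (cB == 0) | (cB == nB)
    sxA = float((segA & fixedB).sum())
    sxB = float((segB & fixedA).sum())
    sf = float((fixedA & fixedB & (pA != pB)).sum())
    ss = float((segA & segB).sum())
    return [piA, piB, thetaA, thetaB, d_xy, netdiv, fst, sxA, sxB, sf, ss]


def jsfs(dataset, folded: bool = True, bins: int | None = None) -> np.ndarray:
    """Joint site frequency spectrum of a simulated/observed dataset.

    Returns an (nA+1, nB+1) count matrix (or a ``bins x bins``
    relative-frequency binned matrix when ``bins`` is given).  Folded
    by default: each site contributes its pooled minor allele.  The
    total equals the number of segregating sites.
    """
    nA, nB = dataset["samples"]
    full = np.zeros((nA + 1, nB + 1))
    for arr in dataset["counts"]:
        for cA, cB in arr:
            if folded and (cA + cB) * 2 > nA + nB:
                cA, cB = nA - cA, nB - cB
            full[cA, cB] += 1
    if bins is None:
        return full
    out = np.zeros((bins, bins))
    for i in range(nA + 1):
        for j in range(nB + 1):
            if full[i, j] == 0:
                continue
            bi = min(int(i / nA * bins), bins - 1)
            bj = min(int(j / nB * bins), bins - 1)
            out[bi, bj] += full[i, j]
    return out


def summary_stats(dataset, jsfs_bins: int = 5) -> SummaryStatVector:
    """Across-locus mean/sd of the locus statistics plus the binned jSFS.

    The jSFS block is normalised to proportions of segregating sites so
    datasets of different sizes are comparable.  A fully monomorphic
    dataset returns an all-zero vector with a warning.
    """
    nA, nB = dataset["samples"]
    L = dataset["locus_len"]
    if len(dataset["counts"]) < 2:
        raise ValueError("need >= 2 loci")
    per_locus = np.array(
        [_locus_stats(arr, nA, nB, L) for arr in dataset["counts"]]
    )
    total_seg = sum(len(a) for a in dataset["counts"])
    if total_seg == 0:
        warnings.warn("monomorphic dataset: zero summary-statistic vector")
    spec = jsfs(dataset, folded=True, bins=jsfs_bins)
    spec = spec / total_seg if total_seg else spec
    names = (
        [f"mean_{s}" for s in _LOCUS_STATS]
        + [f"sd_{s}" for s in _LOCUS_STATS]
        + [f"jsfs_{i}_{j}" for i in range(jsfs_bins) for j in range(jsfs_bins)]
    )
    values = np.concatenate(
        [per_locus.mean(axis=0), per_locus.std(axis=0), spec.ravel()]
    )
    return SummaryStatVector(values=values, names=names)


_MODEL_PARAMS = ["Na", "Nf1", "Nf2", "N1", "N2", "Tsplit", "Tdem1", "Tdem2",
                 "Tsc", "M12", "M21"]


def build_reference_table(scenario: str, prior: PriorConfig, rng,
                          n_sims: int | None = None):
    """Simulate ``n_sims`` prior draws; returns (params DataFrame, stats matrix).

    The table is reusable: one table per scenario supports many ABC
    runs against different observed vectors.
    """
    n_sims = n_sims or prior.n_sims
    rows, stats = [], []
    for _ in range(n_sims):
        model = prior.draw(scenario, rng)
        ds = simulate(model, prior.n_loci, prior.locus_len, prior.samples, rng)
        stats.append(summary_stats(ds).values)
        rows.append({"scenario": scenario, **{k: getattr(model, k) for k in _MODEL_PARAMS}})
    return pd.DataFrame(rows), np.array(stats)


def _standardize(ref_stats: np.ndarray, observed: np.ndarray):
    mean = ref_stats.mean(axis=0)
    sd = ref_stats.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} degenerate summary statistics dropped"
        )
    z_ref = (ref_stats[:, keep] - mean[keep]) / sd[keep]
    z_obs = (observed[keep] - mean[keep]) / sd[keep]
    return z_ref, z_obs, keep


def abc_model_choice(observed: SummaryStatVector, tables: dict,
                     acceptance_fraction: float = 0.05) -> ABCResult:
    """Rejection-ABC model choice over pre-built reference tables.

    ``tables`` maps scenario name -> (params DataFrame, stats matrix)
    from :func:`build_reference_table`.  All simulations are pooled,
    statistics standardized by the pooled mean/sd, the closest
    ``acceptance fraction`` retained, and the posterior model
    probability is each scenario's share of the accepted particles.
    """
    scen_order = list(tables)
    labelled = []
    for s in scen_order:
        p = tables[s][0].copy()
        p["model"] = s  # grid key, distinct from the scenario column
        labelled.append(p)
    all_params = pd.concat(labelled, ignore_index=True)
    all_stats = np.vstack([tables[s][1] for s in scen_order])
    if not np.isfinite(observed.values).all():
        raise ValueError("observed summary vector contains non-finite entries")
    z_ref, z_obs, _ = _standardize(all_stats, observed.values)
    d = np.sqrt(((z_ref - z_obs) ** 2).sum(axis=1))
    n_accept = max(1, int(round(acceptance_fraction * len(d))))
    idx = np.argsort(d)[:n_accept]
    accepted = all_params.iloc[idx].copy()
    accepted["distance"] = d[idx]
    probs = {
        s: float((accepted["model"] == s).mean()) for s in scen_order
    }
    return ABCResult(
        model_probs=probs, accepted=accepted, distances=d, n_accept=n_accept
    )


def abc_estimate(observed: SummaryStatVector, params: pd.DataFrame,
                 stats: np.ndarray, acceptance_fraction: float = 0.05,
                 adjust: bool = True, min_accept: int = 50) -> pd.DataFrame:
    """Parameter posterior from a single-scenario reference table.

    Rejection step as in :func:`abc_model_choice`; with ``adjust``, a
    local-linear regression of each accepted parameter on the
    standardized statistics shifts particles toward the observed vector
    (Beaumont-style adjustment), clipped to the accepted range.
    Returns a DataFrame with median and 2.5/97.5% quantiles per
    parameter.  Raises when fewer than ``min_accept`` particles are
    accepted.
    """
    z_ref, z_obs, _ = _standardize(stats, observed.values)
    d = np.sqrt(((z_ref - z_obs) ** 2).sum(axis=1))
    n_accept = int(round(acceptance_fraction * len(d)))
    if n_accept < min_accept:
        raise ValueError(
            f"only {n_accept} particles would be accepted (< {min_accept}); "
            "increase the number of simulations or the acceptance fraction"
        )
    idx = np.argsort(d)[:n_accept]
    out = {}
    for name in _MODEL_PARAMS:
        vals = params[name].to_numpy()[idx].astype(float)
        adj = vals
        if adjust and np.std(vals) > 0:
            from sklearn.linear_model import LinearRegression

            reg = LinearRegression().fit(z_ref[idx], vals)
            adj = vals - reg.predict(z_ref[idx]) + reg.predict(z_obs[None, :])[0]
            adj = np.clip(adj, vals.min(), vals.max())
        out[name] = {
            "median": float(np.median(adj)),
            "q025": float(np.quantile(adj, 0.025)),
            "q975": float(np.quantile(adj, 0.975)),
        }
    return pd.DataFrame(out).T


def goodness_of_fit(observed: SummaryStatVector, predictive_stats: np.ndarray):
    """Distance of the observed vector to a posterior-predictive cloud.

    Returns ``(distance, percentile)``: the standardized Euclidean
    distance from the predictive mean, and the fraction of predictive
    simulations at least as close to their own mean (so a percentile
    near 1 flags a poor fit).
    """
    if len(predictive_stats) < 2:
        raise ValueError("need >= 2 posterior predictive simulations")
    z_ref, z_obs, _ = _standardize(predictive_stats, observed.values)
    center = z_ref.mean(axis=0)
    d_obs = float(np.sqrt(((z_obs - center) ** 2).sum()))
    d_ref = np.sqrt(((z_ref - center) ** 2).sum(axis=1))
    percentile = float((d_ref <= d_obs).mean())
    return d_obs, percentile
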