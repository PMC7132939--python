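"""Size-distribution fitting, compartment concentration and hypothesis tests.

Organelle volumes are modelled as log-normal: ln V ~ Normal(μ, σ²) with μ, σ
on the natural-log scale of μm³. Fitting is by maximum likelihood on the
logs (divisor n for σ, the MLE). Compartment enrichment is summarised by the
concentration ratio — percentage of objects in a compartment divided by the
compartment's volume fraction of the neuropil; values above 1 mean the
compartment holds more objects than its share of space predicts.

Group comparisons follow the nonparametric toolbox standard in quantitative
neuroanatomy: Mann–Whitney for two groups, Kruskal–Wallis with Dunn's
post-hoc (Holm-adjusted) for several, and χ² for contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------- log-normal

@dataclass
class LognormalFit:
    mu: float
    sigma: float
    n: int
    log_likelihood: float
    ks_statistic: float
    ks_pvalue: float

    @property
    def mean(self) -> float:
        """Mean of the fitted distribution, exp(μ + σ²/2)."""
        return float(np.exp(self.mu + self.sigma**2 / 2.0))

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))


def fit_lognormal(volumes) -> LognormalFit:
    """Maximum-likelihood log-normal fit.

    μ̂ = mean(ln v); σ̂ = sqrt(mean((ln v − μ̂)²)) — the MLE with divisor n.
    The goodness summary is a Kolmogorov–Smirnov statistic of the logs
    against Normal(μ̂, σ̂) (computed post hoc with estimated parameters, so
    its p-value is conservative only as a screening diagnostic).
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 3:
        raise ValueError("log-normal fit needs at least 3 observations")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    logs = np.log(v)
    mu = float(np.mean(logs))
    sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))
    n = v.size
    if sigma > 0:
        ll = float(
            -n / 2 * np.log(2 * np.pi) - n * np.log(sigma)
            - np.sum((logs - mu) ** 2) / (2 * sigma**2) - np.sum(logs)
        )
        ks = sps.kstest(logs, "norm", args=(mu, sigma))
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ll = float("inf")
        ks_stat, ks_p = 0.0, 1.0
    return LognormalFit(mu=mu, sigma=sigma, n=n, log_likelihood=ll,
                        ks_statistic=ks_stat, ks_pvalue=ks_p)


def fit_lognormal_moments(volumes) -> LognormalFit:
    """Moment-matching alternative: solve exp(μ+σ²/2)=m̄, variance likewise."""
    v = np.asarray(volumes, dtype=float)
    if v.size < 3:
        raise ValueError("log-normal fit needs at least 3 observations")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    m = float(np.mean(v))
    s2 = float(np.var(v))
    sigma2 = float(np.log1p(s2 / m**2))
    mu = float(np.log(m) - sigma2 / 2.0)
    sigma = float(np.sqrt(sigma2))
    logs = np.log(v)
    ks = sps.kstest(logs, "norm", args=(mu, max(sigma, 1e-300)))
    n = v.size
    ll = float(np.sum(sps.norm.logpdf(logs, mu, max(sigma, 1e-300))) - np.sum(logs))
    return LognormalFit(mu=mu, sigma=sigma, n=n, log_likelihood=ll,
                        ks_statistic=float(ks.statistic), ks_pvalue=float(ks.pvalue))


# ------------------------------------------------------- concentration ratio

@dataclass(frozen=True)
class ConcentrationRatio:
    compartment: str
    pct_objects: float       # % of objects in the compartment
    volume_fraction: float   # % of reference volume the compartment occupies
    ratio: float             # > 1 means enrichment


def concentration_ratio(
    pct_objects: float, volume_fraction: float, compartment: str = ""
) -> ConcentrationRatio:
    if volume_fraction <= 0:
        raise ValueError("volume fraction must be positive")
    return ConcentrationRatio(
        compartment=compartment,
        pct_objects=float(pct_objects),
        volume_fraction=float(volume_fraction),
        ratio=float(pct_objects) / float(volume_fraction),
    )


# ----------------------------------------------------------------- χ² tests

@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    pvalue: float


def compartment_chi_square(observed_counts, volume_fractions) -> ContingencyResult:
    """Goodness-of-fit χ²: do object counts match compartment volume shares?

    Expected counts are total × volume fraction; df = c − 1. Fractions that
    do not sum to 1 are renormalized (with a warning).
    """
    obs = np.asarray(observed_counts, dtype=float)
    vf = np.asarray(volume_fractions, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("total count must be positive")
    if abs(vf.sum() - 1.0) > 1e-9:
        import warnings

        warnings.warn("volume fractions renormalized to sum to 1", stacklevel=2)
        vf = vf / vf.sum()
    exp = obs.sum() * vf
    if np.any(exp == 0):
        raise ValueError("an expected cell is zero")
    chi2, p = sps.chisquare(obs, f_exp=exp)
    return ContingencyResult(obs, exp, float(chi2), len(obs) - 1, float(p))


def contingency_chi_square(table) -> ContingencyResult:
    """r×c independence χ² (e.g. layer × compartment tables)."""
    obs = np.asarray(table, dtype=float)
    chi2, p, df, exp = sps.chi2_contingency(obs, correction=False)
    return ContingencyResult(obs, exp, float(chi2), int(df), float(p))


# ---------------------------------------------------------- group comparison

@dataclass
class GroupComparison:
    design: str                       # "two_group" or "k_group"
    statistic: float                  # U or H
    pvalue: float
    posthoc: pd.DataFrame | None      # Dunn pairs for k_group


def _dunn_posthoc(samples: dict, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests after Kruskal–Wallis.

    Pooled ranks with mid-rank ties; the tie correction term
    Σ(t³−t) / (12(N−1)) shrinks the variance. Adjustment is Holm's
    step-down Bonferroni by default ("bonferroni" and "none" available).
    """
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    sizes, mean_ranks, i = {}, {}, 0
    for g in names:
        k = len(samples[g])
        sizes[g] = k
        mean_ranks[g] = ranks[i: i + k].mean()
        i += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_unadjusted": p})
    df = pd.DataFrame(rows)
    m = len(df)
    if adjust == "none" or m == 0:
        df["p_adjusted"] = df.get("p_unadjusted", [])
    elif adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p_unadjusted"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p_unadjusted"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_unadjusted"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adjusted"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def group_compare(
    samples: dict,
    design: str = "k_group",
    adjust: str = "holm",
) -> GroupComparison:
    """Mann–Whitney (two_group) or Kruskal–Wallis + Dunn (k_group)."""
    if any(len(np.asarray(v)) == 0 for v in samples.values()):
        raise ValueError("every group must be nonempty")
    if design == "two_group":
        if len(samples) != 2:
            raise ValueError("two_group design needs exactly 2 groups")
        a, b = (np.asarray(v, dtype=float) for v in samples.values())
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison("two_group", float(res.statistic), float(res.pvalue), None)
    if design == "k_group":
        if len(samples) < 2:
            raise ValueError("k_group design needs at least 2 groups")
        arrays = [np.asarray(v, dtype=float) for v in samples.values()]
        h, p = sps.kruskal(*arrays)
        posthoc = _dunn_posthoc(samples, adjust=adjust)
        return GroupComparison("k_group", float(h), float(p), posthoc)
    raise ValueError(f"unknown design {design!r}")


# ------------------------------------------------------------ table reports

def compartment_percentages(catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-layer (+ pooled) percentage of objects per compartment: mean ± sem
    over stacks within a layer; the pooled row averages the layer means."""
    from .synthetic import COMPARTMENTS

    per_stack = (
        catalog.groupby(["layer", "stack_id", "compartment"], sort=True)
        .size()
        .unstack("compartment", fill_value=0)
        .reindex(columns=list(COMPARTMENTS), fill_value=0)
    )
    pct = per_stack.div(per_stack.sum(axis=1), axis=0) * 100.0
    rows = []
    layer_means = {}
    for layer, grp in pct.groupby(level="layer", sort=True):
        mean = grp.mean(axis=0)
        sem = grp.sem(axis=0)
        layer_means[layer] = mean
        row = {"layer": layer}
        for c in COMPARTMENTS:
            row[f"{c}_pct"] = mean[c]
            row[f"{c}_sem"] = sem[c]
        rows.append(row)
    pooled = pd.DataFrame(layer_means).T
    row = {"layer": "I-VI"}
    for c in COMPARTMENTS:
        row[f"{c}_pct"] = pooled[c].mean()
        row[f"{c}_sem"] = pooled[c].sem()
    rows.append(row)
    return pd.DataFrame(rows)


def axon_percentage(excitatory_pct: float, inhibitory_pct: float) -> float:
    """Total axonic share: excitatory + inhibitory axon percentages."""
    return float(excitatory_pct) + float(inhibitory_pct)


def remainder_percentage(*other_pcts: float) -> float:
    """Percentage left after the listed compartments (closure to 100%)."""
    return 100.0 - float(np.sum(other_pcts))


def size_summary(catalog: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sem object volume (μm³) per layer and compartment, objects
    pooled within each cell; includes 'all' compartment and pooled layer."""
    from .synthetic import COMPARTMENTS

    rows = []
    layers = sorted(catalog["layer"].unique())
    for layer in layers + ["I-VI"]:
        sub = catalog if layer == "I-VI" else catalog[catalog["layer"] == layer]
        row = {"layer": layer}
        groups = {"all": sub} | {
            c: sub[sub["compartment"] == c] for c in COMPARTMENTS
        }
        for name, g in groups.items():
            v = g["volume_um3"]
            row[f"{name}_mean"] = v.mean() if len(v) else np.nan
            row[f"{name}_sem"] = v.sem() if len(v) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
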