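"""Fluctuation-assay rate estimation by the method of the median.

The Lea-Coulson median relation calibrates the expected number of
mutation events per culture, m, against the median observed mutant count
r: ``r/m - ln(m) = 1.24``.  The point estimate solves this relation for
the median count across cultures; the rate is m divided by the median
number of viable cells.  Each culture also yields its own rate estimate
(the relation applied to its count), and the 95% CI is the nonparametric
rank interval on those per-culture estimates using binomial(n, 1/2) order
statistics, which reproduces the asymmetric intervals customary for
median-based fluctuation analysis.

Type-partitioned rates multiply a rate and its CI by the fraction of GCRs
of a class; observed uses the genotype's own fractions, expected the
wild-type fractions.  Observed and expected are compared by a two-sided
Mann-Whitney test (exact for small groups), starred at p<0.05 and
p<0.0005.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, GcrScopeError

LEA_COULSON_CONSTANT = 1.24


@dataclass
class FluctuationExperiment:
    counts: np.ndarray  # per-culture mutant counts r_i
    viable_cells: np.ndarray  # per-culture N_i
    plating_fraction: float = 1.0
    genotype: str = "wild-type"
    assay: str = "uGCR"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.viable_cells = np.asarray(self.viable_cells, dtype=float)
        if self.viable_cells.size == 1:
            self.viable_cells = np.full(self.counts.size, float(self.viable_cells.flat[0]))
        if self.counts.size < 2:
            raise ConfigurationError("need at least 2 cultures")
        if np.any(self.counts < 0) or np.any(self.viable_cells <= 0):
            raise ConfigurationError("counts must be >= 0 and viable cells > 0")
        if not (0 < self.plating_fraction <= 1):
            raise ConfigurationError("plating_fraction must be in (0, 1]")

    @property
    def n_cultures(self) -> int:
        return int(self.counts.size)


@dataclass
class RateEstimate:
    rate: float
    ci_low: float
    ci_high: float
    n_measurements: int
    upper_bound_only: bool = False
    per_culture_rates: Optional[np.ndarray] = None
    genotype: str = ""

    def __post_init__(self):
        if not self.upper_bound_only and not (
            self.ci_low <= self.rate <= self.ci_high
        ):
            raise GcrScopeError("CI must bracket the rate")


@dataclass
class TypePartitionedRate:
    event_class: str
    observed: RateEstimate
    expected: RateEstimate


@dataclass
class ComparisonResult:
    U: float
    p_value: float

    @property
    def stars(self) -> str:
        if self.p_value < 0.0005:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def solve_lc_m(median_count: float) -> float:
    """Solve r/m - ln(m) = 1.24 for m given the median count r."""
    r = float(median_count)
    if r <= 0:
        raise GcrScopeError("median count must be positive to solve for m")
    f = lambda m: r / m - np.log(m) - LEA_COULSON_CONSTANT
    lo = 1e-12
    hi = max(r, 1.0)
    while f(hi) > 0:
        hi *= 2
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def _rank_ci_indices(n: int, conf: float = 0.95) -> tuple:
    """Order-statistic indices bracketing the median at ~95% confidence."""
    alpha = (1 - conf) / 2
    lo = int(stats.binom.ppf(alpha, n, 0.5))
    hi = int(stats.binom.ppf(1 - alpha, n, 0.5))
    return max(lo, 0), min(hi, n - 1)


def lc_median_rate(exp: FluctuationExperiment) -> RateEstimate:
    """Method-of-the-median rate with a rank-based 95% CI.

    When the median count is zero only an upper bound can be stated
    (flagged via ``upper_bound_only``): the rate that would put the median
    at a single observed mutant.
    """
    counts = exp.counts / exp.plating_fraction
    n_med = float(np.median(exp.viable_cells))
    r_med = float(np.median(counts))
    if r_med <= 0:
        ub = solve_lc_m(1.0) / n_med
        return RateEstimate(
            ub, 0.0, ub, exp.n_cultures, upper_bound_only=True, genotype=exp.genotype
        )
    m = solve_lc_m(r_med)
    rate = m / n_med
    per = np.array(
        [
            solve_lc_m(r) / n if r > 0 else 0.0
            for r, n in zip(counts, exp.viable_cells)
        ]
    )
    per_sorted = np.sort(per)
    lo_i, hi_i = _rank_ci_indices(exp.n_cultures)
    ci_low = min(per_sorted[lo_i], rate)
    ci_high = max(per_sorted[hi_i], rate)
    return RateEstimate(
        rate,
        float(ci_low),
        float(ci_high),
        exp.n_cultures,
        per_culture_rates=per,
        genotype=exp.genotype,
    )


def partition_rate(est: RateEstimate, fraction: float, event_class: str = "") -> RateEstimate:
    """Scale a rate and its CI by a GCR-class fraction."""
    if not (0 <= fraction <= 1):
        raise ConfigurationError("fraction must be in [0, 1]")
    per = est.per_culture_rates * fraction if est.per_culture_rates is not None else None
    return RateEstimate(
        est.rate * fraction,
        est.ci_low * fraction,
        est.ci_high * fraction,
        est.n_measurements,
        upper_bound_only=est.upper_bound_only,
        per_culture_rates=per,
        genotype=est.genotype,
    )


def type_partitioned_rates(
    est: RateEstimate,
    fractions: dict,
    wildtype_fractions: dict,
) -> list:
    """Fig-4B-style observed/expected rates per GCR class."""
    out = []
    for cls in fractions:
        obs = partition_rate(est, fractions[cls], cls)
        exp_ = partition_rate(est, wildtype_fractions.get(cls, 0.0), cls)
        out.append(TypePartitionedRate(cls, obs, exp_))
    return out


def compare_observed_expected(
    obs: Sequence[float], exp: Sequence[float], exact_max_n: int = 20
) -> ComparisonResult:
    """Two-sided Mann-Whitney U; exact for groups up to ``exact_max_n``."""
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if obs.size < 2 or exp.size < 2:
        raise ConfigurationError("each sample needs n >= 2")
    pooled = np.concatenate([obs, exp])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(U=obs.size * exp.size / 2, p_value=1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (obs.size <= exact_max_n and exp.size <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(obs, exp, alternative="two-sided", method=method)
    return ComparisonResult(U=float(res.statistic), p_value=float(min(res.pvalue, 1.0)))


def mann_whitney_enumeration(obs: Sequence[float], exp: Sequence[float]) -> float:
    """Exact two-sided p by full enumeration of group assignments (oracle)."""
    from itertools import combinations

    obs = list(map(float, obs))
    exp = list(map(float, exp))
    pooled = obs + exp
    n1 = len(obs)

    def u_stat(sample1, sample2):
        u = 0.0
        for x in sample1:
            for y in sample2:
                u += (x > y) + 0.5 * (x == y)
        return u

    u_obs = u_stat(obs, exp)
    mu = n1 * len(exp) / 2
    dev_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        s1 = [pooled[i] for i in comb]
        s2 = [pooled[i] for i in idx if i not in comb]
        total += 1
        if abs(u_stat(s1, s2) - mu) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def fold_change(est: RateEstimate, reference_rate: float) -> RateEstimate:
    """Rate (and CI) expressed as a multiple of a reference rate."""
    if reference_rate <= 0:
        raise ConfigurationError("reference rate must be > 0")
    return RateEstimate(
        est.rate / reference_rate,
        est.ci_low / reference_rate,
        est.ci_high / reference_rate,
        est.n_measurements,
        upper_bound_only=est.upper_bound_only,
        genotype=est.genotype,
    )


# ----------------------------------------------------------------------
# delimited-text interface


def read_experiments(path: str) -> list:
    """Read fluctuation experiments from TSV.

    Expected columns: culture_id, mutant_count, viable_cells,
    plating_fraction, genotype, assay.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"mutant_count", "viable_cells", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"missing columns: {sorted(missing)}")
    out = []
    for (genotype, assay), grp in df.groupby(
        ["genotype", df.get("assay", pd.Series(["uGCR"] * len(df))).fillna("uGCR")]
    ):
        pf = float(grp["plating_fraction"].iloc[0]) if "plating_fraction" in grp else 1.0
        out.append(
            FluctuationExperiment(
                grp["mutant_count"].to_numpy(),
                grp["viable_cells"].to_numpy(),
                plating_fraction=pf,
                genotype=str(genotype),
                assay=str(assay),
            )
        )
    return out


def rates_table(estimates: list, reference: Optional[RateEstimate] = None) -> pd.DataFrame:
    rows = []
    for est in estimates:
        row = {
            "genotype": est.genotype,
            "rate": est.rate,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "n": est.n_measurements,
            "upper_bound_only": est.upper_bound_only,
        }
        if reference is not None:
            row["fold_change"] = est.rate / reference.rate
        rows.append(row)
    return pd.DataFrame(rows)
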