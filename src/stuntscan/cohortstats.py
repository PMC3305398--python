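"""Population-genetic and prospective-cohort statistics.

Hardy-Weinberg expectations, segregation-ratio tests, exact genotype x
outcome contingency tests (probability-ordering Fisher convention),
two-locus linkage disequilibrium, expected-affected-offspring calculators
and per-genotype growth regressions with an interaction (slope-difference)
test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .pedio import CohortTable

__all__ = [
    "GenotypeCounts",
    "TwoLocusHaplotypeCounts",
    "TestResult",
    "hwe_genotype_freqs",
    "prob_no_homozygotes",
    "segregation_test",
    "genotype_outcome_exact_test",
    "two_locus_ld",
    "expected_affected_offspring",
    "carrier_freq_comparison",
    "growth_group_regression",
    "GrowthRegressionResult",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Biallelic genotype counts; q is the alternate-allele frequency."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("total count must be positive")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def q(self) -> float:
        return (self.n_het + 2 * self.n_hom_alt) / (2 * self.total)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_hom_ref, self.n_het, self.n_hom_alt)


@dataclass(frozen=True)
class TwoLocusHaplotypeCounts:
    """Counts of the four two-locus haplotypes."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    @property
    def total(self) -> int:
        t = self.n_AB + self.n_Ab + self.n_aB + self.n_ab
        if t == 0:
            raise ValueError("total haplotype count must be positive")
        return t


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_genotype_freqs(q: float) -> tuple[float, float, float]:
    """Expected (hom-ref, het, hom-alt) frequencies at allele frequency q."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


def prob_no_homozygotes(q: float, n: int) -> tuple[float, float]:
    """Probability that none of *n* individuals is an alt homozygote under
    Hardy-Weinberg, and the expected homozygote count n*q^2."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float((1.0 - q * q) ** n), float(n * q * q)


# ---------------------------------------------------------------------------
# segregation tests
# ---------------------------------------------------------------------------

def segregation_test(counts: GenotypeCounts | tuple[int, ...],
                     expected_ratio=(1, 2, 1),
                     method: str = "pearson") -> TestResult:
    """Test observed genotype counts against an expected segregation ratio.

    Methods: ``pearson`` chi-square, ``g_test`` (log-likelihood ratio), or
    ``exact_multinomial`` (probability-ordering enumeration, N <= 200).
    """
    obs = np.asarray(counts.as_tuple() if isinstance(counts, GenotypeCounts)
                     else counts, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if ratio.shape != obs.shape:
        raise ValueError("expected ratio arity must match counts")
    if np.any(ratio < 0) or ratio.sum() <= 0:
        raise ValueError("expected ratio must be positive")
    n = obs.sum()
    exp = ratio / ratio.sum() * n
    if method in ("pearson", "g_test"):
        if np.any((exp == 0) & (obs > 0)):
            raise ValueError("zero expected class with non-zero observed")
        keep = exp > 0
        lambda_ = 1.0 if method == "pearson" else 0.0
        stat, p = stats.power_divergence(
            obs[keep], exp[keep],
            lambda_="pearson" if method == "pearson" else "log-likelihood")
        return TestResult(float(stat), float(keep.sum() - 1), float(p),
                          method)
    if method == "exact_multinomial":
        # exact p by full enumeration, ordering outcomes by the Pearson
        # discrepancy statistic (tables at least as discrepant as observed)
        if n > 200:
            raise ValueError("exact multinomial limited to N <= 200")
        probs = ratio / ratio.sum()
        dist = stats.multinomial(int(n), probs)
        chi2_obs = float(np.sum((obs - exp) ** 2 / exp))
        total = 0.0
        k = len(obs)
        for combo in _compositions(int(n), k):
            arr = np.array(combo, dtype=float)
            chi2 = float(np.sum((arr - exp) ** 2 / exp))
            if chi2 >= chi2_obs - 1e-9:
                total += dist.pmf(arr)
        return TestResult(chi2_obs, None, float(min(total, 1.0)), method)
    raise ValueError(f"unknown method {method!r}")


def _compositions(n: int, k: int):
    """All k-tuples of non-negative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


# ---------------------------------------------------------------------------
# exact genotype x outcome test
# ---------------------------------------------------------------------------

def genotype_outcome_exact_test(table) -> float:
    """Two-sided exact test for an R x 2 contingency table.

    Probability-ordering (Fisher) convention: sum, over all tables with the
    observed margins, of the multivariate hypergeometric probabilities not
    exceeding that of the observed table.  Matches the hypergeometric
    closed form for 2 x 2 tables.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError("need an R x 2 table with R >= 2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("all margins must be positive")
    n = int(t.sum())
    k = int(col_sums[1])  # events
    # log P(a) = sum_i log C(row_i, a_i) - log C(n, k)
    lognck = _log_comb(n, k)

    def log_prob(events_per_row) -> float:
        return sum(_log_comb(int(r), int(a))
                   for r, a in zip(row_sums, events_per_row)) - lognck

    obs_lp = log_prob(t[:, 1])
    total = 0.0
    for combo in _bounded_compositions(k, row_sums):
        lp = log_prob(combo)
        if lp <= obs_lp + 1e-9:
            total += math.exp(lp)
    return float(min(total, 1.0))


def _bounded_compositions(n: int, bounds):
    bounds = list(bounds)
    if len(bounds) == 1:
        if 0 <= n <= bounds[0]:
            yield (n,)
        return
    hi = min(n, bounds[0])
    lo = max(0, n - int(sum(bounds[1:])))
    for first in range(lo, hi + 1):
        for rest in _bounded_compositions(n - first, bounds[1:]):
            yield (first,) + rest


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return (math.lgamma(n + 1) - math.lgamma(k + 1)
            - math.lgamma(n - k + 1))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def two_locus_ld(h: TwoLocusHaplotypeCounts) -> tuple[float, float, float]:
    """D, D' and r^2 from two-locus haplotype counts."""
    n = h.total
    p_ab = h.n_AB / n
    p_a = (h.n_AB + h.n_Ab) / n  # freq of allele A at locus 1
    p_b = (h.n_AB + h.n_aB) / n  # freq of allele B at locus 2
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("LD undefined: a locus is monomorphic")
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else d / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(d), float(d_prime), float(r2)


# ---------------------------------------------------------------------------
# expected affected offspring / carrier comparisons
# ---------------------------------------------------------------------------

def expected_affected_offspring(q: float,
                                sire_genotype: str = "carrier") -> float:
    """Probability that an offspring of the given sire, mated to a random
    dam under Hardy-Weinberg random mating, is an affected homozygote.

    Carrier sire: 0.5 * q (sire transmits with probability 1/2, random dam
    allele is mutant with probability q); homozygous sire: q.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if sire_genotype == "carrier":
        return 0.5 * q
    if sire_genotype == "hom":
        return float(q)
    raise ValueError("sire_genotype must be 'carrier' or 'hom'")


def carrier_freq_comparison(k1: int, n1: int, k2: int, n2: int,
                            ) -> tuple[float, float, float]:
    """Two carrier frequencies and the 2 x 2 Fisher exact p-value."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    _, p = stats.fisher_exact(
        [[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    return k1 / n1, k2 / n2, float(p)


# ---------------------------------------------------------------------------
# growth regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthRegressionResult:
    response: str
    window: tuple[float, float]
    groups: tuple[str, ...]
    slopes: dict
    intercepts: dict
    interaction_p: float
    n_obs: int


def growth_group_regression(cohort: CohortTable, grouping,
                            response: str = "weight_kg",
                            window: tuple[float, float] = (0.0, 365.0),
                            ) -> GrowthRegressionResult:
    """Per-group OLS of a growth measure on age, with a slope-difference
    test via the age x group interaction.

    ``grouping`` maps genotype (AA/AG/GG) to a group label; genotypes
    mapped to None are dropped.  For two groups the interaction p-value is
    the t-test on the single interaction coefficient; for more groups it is
    the joint F-test of all interaction terms.
    """
    if response not in cohort.measures.columns:
        raise ValueError(f"response {response!r} not measured")
    merged = cohort.measures.merge(
        cohort.calves[["calf", "genotype"]], on="calf")
    if callable(grouping):
        merged["group"] = merged["genotype"].map(grouping)
    else:
        merged["group"] = merged["genotype"].map(dict(grouping))
    merged = merged.dropna(subset=["group", response])
    lo, hi = window
    merged = merged[(merged["age_days"] >= lo) & (merged["age_days"] <= hi)]
    groups = tuple(sorted(merged["group"].unique()))
    if len(groups) < 1:
        raise ValueError("no observations in window")
    counts = merged.groupby("group").size()
    if (counts < 2).any():
        raise ValueError("need at least 2 measures per group in window")
    slopes, intercepts = {}, {}
    for g in groups:
        sub = merged[merged["group"] == g]
        if sub["age_days"].nunique() < 2:
            raise ValueError(f"singular design: group {g} has one age")
        fit = np.polyfit(sub["age_days"], sub[response], 1)
        slopes[g], intercepts[g] = float(fit[0]), float(fit[1])
    if len(groups) == 1:
        interaction_p = 1.0
    else:
        merged = merged.rename(columns={response: "y", "age_days": "age"})
        # repeated measures share each calf's individual level: use
        # calf-clustered robust covariance for the slope-difference test
        model = smf.ols("y ~ age * C(group)", data=merged).fit(
            cov_type="cluster", cov_kwds={"groups": merged["calf"]})
        inter_terms = [t for t in model.params.index
                       if t.startswith("age:")]
        if len(inter_terms) == 1:
            interaction_p = float(model.pvalues[inter_terms[0]])
        else:
            ftest = model.f_test(
                [f"{t} = 0" for t in inter_terms])
            interaction_p = float(ftest.pvalue)
    return GrowthRegressionResult(
        response=response, window=window, groups=groups,
        slopes=slopes, intercepts=intercepts,
        interaction_p=interaction_p, n_obs=len(merged),
    )
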