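"""Gene dropping through a pedigree with transmission-ratio distortion.

A single biallelic locus is dropped from a designated founder carrier down
a known genealogy.  Each heterozygous parent transmits the mutant allele
with probability ``tau`` (0.5 under Mendelian segregation); homozygous
mutant parents always transmit it and wild-type parents never do.  Founders
other than the designated carrier receive the mutant allele independently
per haplotype with probability ``q0``, modelling mutant copies entering the
genealogy from outside the focal lineage.

The Monte-Carlo driver (:func:`gene_drop`) yields the null distribution of
the number of carriers in a target set of descendants; an exact
enumeration (:func:`enumerate_exact`) provides the same distribution by
variable elimination for small pedigrees and serves as the oracle for the
simulator.  :func:`scan_transmission` profiles how compatible each value of
``tau`` is with an observed carrier count — the field's standard test for
a selective sweep by distorted transmission.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .pedio import Pedigree

__all__ = [
    "DropSpec",
    "CarrierCountDistribution",
    "TransmissionScan",
    "gene_drop",
    "tail_probability",
    "scan_transmission",
    "enumerate_exact",
    "exact_mean_carriers",
    "PedigreeTooLargeError",
]

MAX_EXACT_BITS = 22  # meioses + stochastic founder haplotypes


class PedigreeTooLargeError(ValueError):
    """Exact enumeration refused: too many random transmissions."""


@dataclass
class DropSpec:
    """Specification of one gene-dropping experiment."""

    pedigree: Pedigree
    founder: str
    tau: float = 0.5
    q0: float = 0.0
    target: tuple[str, ...] = ()
    n_sims: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must be in [0, 1]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.founder not in self.pedigree.individuals:
            raise ValueError(f"founder {self.founder!r} not in pedigree")
        if not self.pedigree.is_founder(self.founder):
            raise ValueError(f"{self.founder!r} is not a founder")
        self.target = tuple(self.target)
        missing = [t for t in self.target
                   if t not in self.pedigree.individuals]
        if missing:
            raise ValueError(f"target ids not in pedigree: {missing}")
        if not self.target:
            raise ValueError("target set is empty")


@dataclass
class CarrierCountDistribution:
    """Distribution of the carrier count over a target set.

    ``counts[k]`` is either the number of simulations (Monte-Carlo mode;
    sums to ``n_sims``) or the exact probability (``n_sims is None``; sums
    to 1) of observing exactly ``k`` carriers.
    """

    counts: np.ndarray
    tau: float
    q0: float
    n_sims: int | None = None
    seed: int | None = None

    @property
    def exact(self) -> bool:
        return self.n_sims is None

    @property
    def probabilities(self) -> np.ndarray:
        if self.exact:
            return self.counts
        return self.counts / self.n_sims

    @property
    def mean(self) -> float:
        k = np.arange(len(self.counts))
        return float(np.sum(k * self.probabilities))


def _simulate_dosages(pedigree: Pedigree, founder: str, tau: float,
                      q0: float, n_sims: int,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorised drop: per-individual mutant dosage, shape (n_sims,)."""
    dosage: dict[str, np.ndarray] = {}
    for ind in pedigree.topological_order():
        s, d = pedigree.parents(ind)
        if s is None and d is None:
            if ind == founder:
                dosage[ind] = np.ones(n_sims, dtype=np.int8)
            elif q0 > 0:
                dosage[ind] = (
                    (rng.random(n_sims) < q0).astype(np.int8)
                    + (rng.random(n_sims) < q0).astype(np.int8)
                )
            else:
                dosage[ind] = np.zeros(n_sims, dtype=np.int8)
        else:
            alleles = np.zeros(n_sims, dtype=np.int8)
            for parent in (s, d):
                if parent is None:
                    # unknown parent treated as an outside founder haplo pair
                    pd_ = (
                        (rng.random(n_sims) < q0).astype(np.int8)
                        + (rng.random(n_sims) < q0).astype(np.int8)
                    ) if q0 > 0 else np.zeros(n_sims, dtype=np.int8)
                else:
                    pd_ = dosage[parent]
                u = rng.random(n_sims)
                transmit = (pd_ == 2) | ((pd_ == 1) & (u < tau))
                alleles += transmit.astype(np.int8)
            dosage[ind] = alleles
    return dosage


def gene_drop(spec: DropSpec) -> CarrierCountDistribution:
    """Monte-Carlo gene dropping; returns the carrier-count histogram."""
    rng = np.random.default_rng(spec.seed)
    dosage = _simulate_dosages(spec.pedigree, spec.founder, spec.tau,
                               spec.q0, spec.n_sims, rng)
    carriers = np.zeros(spec.n_sims, dtype=np.int64)
    for t in spec.target:
        carriers += dosage[t] >= 1
    counts = np.bincount(carriers, minlength=len(spec.target) + 1)
    return CarrierCountDistribution(
        counts=counts.astype(np.int64), tau=spec.tau, q0=spec.q0,
        n_sims=spec.n_sims, seed=spec.seed,
    )


def tail_probability(dist: CarrierCountDistribution,
                     k_obs: int) -> tuple[float, float | None]:
    """P(carrier count >= k_obs) with a binomial standard error for
    Monte-Carlo distributions (None in exact mode)."""
    if k_obs < 0:
        raise ValueError("k_obs must be >= 0")
    if k_obs >= len(dist.counts):
        p = 0.0
    else:
        p = float(dist.probabilities[k_obs:].sum())
    if dist.exact:
        return p, None
    se = float(np.sqrt(p * (1.0 - p) / dist.n_sims))
    return p, se


# ---------------------------------------------------------------------------
# tau compatibility scan
# ---------------------------------------------------------------------------

@dataclass
class TransmissionScan:
    """Result of profiling tau against an observed carrier count."""

    tau_grid: np.ndarray
    exact_hits: np.ndarray   # simulations yielding exactly k_obs, per tau
    k_obs: int
    n_sims: int
    q0: float
    seed: int

    @property
    def tau_star(self) -> float:
        """Grid value maximizing the exact-hit count (ties -> smallest)."""
        return float(self.tau_grid[int(np.argmax(self.exact_hits))])


def scan_transmission(pedigree: Pedigree, founder: str, q0: float,
                      k_obs: int, tau_grid, target,
                      n_sims: int = 10_000, seed: int = 0,
                      ) -> TransmissionScan:
    """Count, per grid value of tau, the simulations that yield exactly
    ``k_obs`` carriers in the target set.

    Grid point *i* uses ``seed + i`` so the profile is reproducible and
    refinable point by point.
    """
    tau_grid = np.asarray(list(tau_grid), dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau grid is empty")
    if np.any((tau_grid < 0) | (tau_grid > 1)):
        raise ValueError("tau grid values must lie in [0, 1]")
    hits = np.zeros(tau_grid.size, dtype=np.int64)
    for i, tau in enumerate(tau_grid):
        dist = gene_drop(DropSpec(
            pedigree=pedigree, founder=founder, tau=float(tau), q0=q0,
            target=tuple(target), n_sims=n_sims, seed=seed + i,
        ))
        if 0 <= k_obs < len(dist.counts):
            hits[i] = int(dist.counts[k_obs])
    return TransmissionScan(tau_grid=tau_grid, exact_hits=hits, k_obs=k_obs,
                            n_sims=n_sims, q0=q0, seed=seed)


# ---------------------------------------------------------------------------
# exact enumeration (oracle)
# ---------------------------------------------------------------------------

def _founder_dist(q0: float) -> list[tuple[int, float]]:
    out = [(0, (1 - q0) ** 2), (1, 2 * q0 * (1 - q0)), (2, q0 ** 2)]
    return [(d, p) for d, p in out if p > 0]


def _transmit_prob(dosage: int, tau: float) -> float:
    return (0.0, tau, 1.0)[dosage]


def enumerate_exact(pedigree: Pedigree, founder: str, q0: float, tau: float,
                    target) -> CarrierCountDistribution:
    """Exact carrier-count distribution by variable elimination.

    Processes individuals in topological order, tracking the joint dosage
    distribution of the "frontier" (individuals whose offspring remain
    unprocessed) and marginalising everyone else into a running carrier
    count over the target set.  Refuses pedigrees whose number of random
    binary transmissions (2 per non-founder meiosis pair plus 2 per
    stochastic founder) exceeds 22.
    """
    target = tuple(target)
    missing = [t for t in target if t not in pedigree.individuals]
    if missing:
        raise ValueError(f"target ids not in pedigree: {missing}")
    n_stochastic_founders = sum(
        1 for f in pedigree.founders if f != founder) if q0 > 0 else 0
    n_bits = pedigree.n_meioses() + 2 * n_stochastic_founders
    if n_bits > MAX_EXACT_BITS:
        raise PedigreeTooLargeError(
            f"{n_bits} random transmissions exceed the exact-enumeration "
            f"bound of {MAX_EXACT_BITS}"
        )
    order = pedigree.topological_order()
    position = {ind: i for i, ind in enumerate(order)}
    # last step at which each individual is needed as a parent
    last_use = dict.fromkeys(order, -1)
    for ind in order:
        for parent in pedigree.parents(ind):
            if parent is not None:
                last_use[parent] = max(last_use[parent], position[ind])

    target_set = set(target)
    # states: (frontier tuple of (id, dosage) sorted, carriers) -> prob
    states: dict[tuple[tuple[tuple[str, int], ...], int], float] = {
        ((), 0): 1.0}
    for step, ind in enumerate(order):
        s, d = pedigree.parents(ind)
        new_states: dict[tuple[tuple[tuple[str, int], ...], int], float] = {}
        for (frontier, carriers), prob in states.items():
            fdict = dict(frontier)
            if s is None and d is None:
                if ind == founder:
                    branches = [(1, 1.0)]
                else:
                    branches = _founder_dist(q0)
            else:
                def allele_dist(parent: str | None) -> list[tuple[int, float]]:
                    if parent is None:
                        pt = q0 * q0 + 2 * q0 * (1 - q0) * tau  # unknown side
                    else:
                        pt = _transmit_prob(fdict[parent], tau)
                    return [(1, pt), (0, 1.0 - pt)]

                branches_map: dict[int, float] = {}
                for (a1, p1), (a2, p2) in itertools.product(
                        allele_dist(s), allele_dist(d)):
                    if p1 * p2 > 0:
                        branches_map[a1 + a2] = (
                            branches_map.get(a1 + a2, 0.0) + p1 * p2)
                branches = list(branches_map.items())
            for dosage, p in branches:
                if p <= 0:
                    continue
                nd = dict(fdict)
                nd[ind] = dosage
                ncarriers = carriers
                # retire individuals no longer needed as parents
                for who in list(nd):
                    if last_use[who] <= step:
                        dval = nd.pop(who)
                        if who in target_set and dval >= 1:
                            ncarriers += 1
                key = (tuple(sorted(nd.items())), ncarriers)
                new_states[key] = new_states.get(key, 0.0) + prob * p
        states = new_states
    probs = np.zeros(len(target) + 1)
    for (frontier, carriers), prob in states.items():
        extra = sum(1 for who, dval in frontier
                    if who in target_set and dval >= 1)
        probs[carriers + extra] += prob
    return CarrierCountDistribution(counts=probs, tau=tau, q0=q0,
                                    n_sims=None, seed=None)


def exact_mean_carriers(pedigree: Pedigree, founder: str, q0: float,
                        tau: float, target) -> float:
    """Sum of per-individual carrier probabilities by marginal recursion.

    Valid as an independent cross-check of the enumeration mean only for
    pedigrees without inbreeding loops, where the two parental
    transmissions to an individual are independent.
    """
    pd2: dict[str, tuple[float, float, float]] = {}
    for ind in pedigree.topological_order():
        s, d = pedigree.parents(ind)
        if s is None and d is None:
            if ind == founder:
                pd2[ind] = (0.0, 1.0, 0.0)
            else:
                pd2[ind] = ((1 - q0) ** 2, 2 * q0 * (1 - q0), q0 ** 2)
        else:
            def pt(parent: str | None) -> float:
                if parent is None:
                    return q0 * q0 + 2 * q0 * (1 - q0) * tau
                p0, p1, p2 = pd2[parent]
                return p1 * tau + p2
            ps, pda = pt(s), pt(d)
            pd2[ind] = (
                (1 - ps) * (1 - pda),
                ps * (1 - pda) + (1 - ps) * pda,
                ps * pda,
            )
    return float(sum(1.0 - pd2[t][0] for t in target))
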