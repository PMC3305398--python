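"""Synthetic study generator.

Emulates the data setting of a recessive growth-stunting locus segregating
in an intensively bred cattle population: a multi-generation pedigree
descending from a single founder carrier (with artificial-insemination
sires concentrating matings), biallelic SNP genotypes in which every copy
of the mutant allele rides a shared ancestral haplotype, a prospective
birth cohort with excess juvenile mortality (~1/3 of mutant homozygotes)
and post-6-month growth stunting, and qPCR Cq tables generated from a known
(f_skip, f_cryptic, d_nmrd) splicing truth.

All randomness flows from explicit integer seeds via
``numpy.random.default_rng``; repeated calls with the same configuration
are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .pedio import (
    MISSING,
    CohortTable,
    GenotypeMatrix,
    Pedigree,
    QpcrTable,
)

__all__ = [
    "SimConfig",
    "OutcomeModel",
    "QpcrDesign",
    "ExtinctionError",
    "simulate_pedigree",
    "drop_haplotypes",
    "simulate_cohort",
    "simulate_qpcr",
    "isoform_levels",
]


class ExtinctionError(RuntimeError):
    """The simulated population died out before the requested generation."""


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    ``tau_true`` is the probability that a heterozygous parent transmits the
    mutant allele (0.5 = Mendelian); ``q0`` is the per-haplotype mutant
    frequency among founders other than the designated mutation founder.
    Marker density is markers per Mb on a single simulated chromosome;
    recombination follows a Haldane (no-interference) map at
    ``recomb_rate_cm_per_mb``.
    """

    n_generations: int = 5
    n_founders: int = 12
    mean_offspring: float = 2.0        # rate of the zero-truncated Poisson
    ai_sire_fraction: float = 0.25     # fraction of males acting as AI sires
    ai_mating_share: float = 0.75      # share of matings going to AI sires
    chrom: str = "3"
    chrom_length_bp: int = 20_000_000
    marker_density: float = 50.0       # markers / Mb
    carrier_hap_length_bp: int = 4_000_000
    recomb_rate_cm_per_mb: float = 1.0
    freq_range: tuple[float, float] = (0.05, 0.5)
    tau_true: float = 0.5
    q0: float = 0.0
    mutation_founder: str = "G0_000"  # first male founder of simulate_pedigree
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_true <= 1.0:
            raise ValueError("tau_true must be in [0, 1]")
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must be in [0, 1]")
        for name in ("n_generations", "n_founders", "chrom_length_bp",
                     "carrier_hap_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_offspring <= 0 or self.marker_density <= 0:
            raise ValueError("rates and densities must be positive")
        if self.recomb_rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")
        lo, hi = self.freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("freq_range must satisfy 0 < lo <= hi < 1")

    @property
    def mutation_pos(self) -> int:
        """bp coordinate of the causative variant (chromosome midpoint)."""
        return self.chrom_length_bp // 2


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def _zt_poisson(rng: np.random.Generator, lam: float) -> int:
    """Zero-truncated Poisson draw by rejection."""
    while True:
        k = int(rng.poisson(lam))
        if k > 0:
            return k


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Simulate a discrete-generation pedigree with AI-sire mating skew.

    Founders form generation 0 (alternating male/female; the first male,
    ``G0_000``, is the designated mutation founder).  Each later generation
    mates every female of the previous generation to a male of the previous
    generation, with a configurable fraction of "AI sires" receiving a
    configurable share of all matings; sibship sizes are zero-truncated
    Poisson.
    """
    rng = np.random.default_rng(config.seed)
    ids: list[str] = []
    sire: dict[str, str | None] = {}
    dam: dict[str, str | None] = {}
    sex: dict[str, str] = {}
    generation: dict[str, int] = {}

    def add(ind: str, s: str | None, d: str | None, sx: str, g: int) -> None:
        ids.append(ind)
        sire[ind] = s
        dam[ind] = d
        sex[ind] = sx
        generation[ind] = g

    for i in range(config.n_founders):
        add(f"G0_{i:03d}", None, None,
            "male" if i % 2 == 0 else "female", 0)

    prev = [i for i in ids]
    counter = 0
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex[i] == "male"]
        females = [i for i in prev if sex[i] == "female"]
        if not males or not females:
            raise ExtinctionError(
                f"generation {g}: no breeding pair available; increase "
                "mean_offspring or founder count"
            )
        n_ai = max(1, int(round(config.ai_sire_fraction * len(males))))
        ai_sires = males[:n_ai]
        other_sires = males[n_ai:] or ai_sires
        offspring: list[str] = []
        for female in females:
            if rng.random() < config.ai_mating_share:
                s = ai_sires[int(rng.integers(len(ai_sires)))]
            else:
                s = other_sires[int(rng.integers(len(other_sires)))]
            for _ in range(_zt_poisson(rng, config.mean_offspring)):
                child = f"G{g}_{counter:03d}"
                counter += 1
                add(child, s, female,
                    "male" if rng.random() < 0.5 else "female", g)
                offspring.append(child)
        if not offspring:
            raise ExtinctionError(
                f"generation {g}: no offspring drawn; increase "
                "mean_offspring"
            )
        prev = offspring
    return Pedigree(ids, sire, dam, sex, generation=generation)


# ---------------------------------------------------------------------------
# Haplotype dropping
# ---------------------------------------------------------------------------

def _marker_map(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(round(config.marker_density * config.chrom_length_bp / 1e6))
    if n < 1:
        raise ValueError("marker map is empty; increase marker_density")
    pos = np.sort(rng.choice(
        np.arange(1, config.chrom_length_bp + 1), size=n, replace=False))
    return pos.astype(np.int64)


def _meiosis(rng: np.random.Generator, hap_a: np.ndarray, hap_b: np.ndarray,
             mut_a: bool, mut_b: bool, pos: np.ndarray,
             mutation_pos: int, morgans: float,
             tau: float) -> tuple[np.ndarray, bool]:
    """One gamete under a Haldane crossover process.

    When the parent is heterozygous for the mutant allele the haplotype
    present at the mutation site is the mutant one with probability
    ``tau`` (transmission-ratio distortion); crossovers then determine the
    rest of the gamete.
    """
    n_x = int(rng.poisson(morgans)) if morgans > 0 else 0
    if n_x:
        breaks = np.sort(rng.uniform(0, pos[-1] + 1, size=n_x))
    else:
        breaks = np.empty(0)
    # segment index per marker and at the mutation site (segments alternate
    # between the two parental haplotypes)
    seg_at_mut = int(np.searchsorted(breaks, mutation_pos))
    seg = np.searchsorted(breaks, pos)
    if mut_a != mut_b:
        carry_mut = rng.random() < tau
        phase_at_mut = 0 if (carry_mut == mut_a) else 1
    else:
        phase_at_mut = int(rng.integers(2))
        carry_mut = mut_a  # hom parent: both haplotypes agree
    # phase of segment k is phase_at_mut flipped once per crossover away
    first_phase = (phase_at_mut + seg_at_mut) % 2
    use_b = (seg + first_phase) % 2 == 1
    gamete = np.where(use_b, hap_b, hap_a)
    mut = mut_b if (seg_at_mut + first_phase) % 2 == 1 else mut_a
    return gamete, bool(mut)


def drop_haplotypes(
    pedigree: Pedigree, config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop founder haplotypes through *pedigree* and genotype everyone.

    The mutation founder is heterozygous for a tagged ancestral haplotype
    spanning ``carrier_hap_length_bp`` around the mutation site; every other
    founder haplotype is an independent draw from the background allele
    frequency spectrum and carries the mutant allele (on a copy of the same
    ancestral haplotype, identical by descent from an older sweep ancestor)
    with probability ``q0``.  Transmission from heterozygous parents is
    distorted to ``tau_true``.

    Returns the genotype matrix and a truth table with columns
    ``id, dosage, genotype`` (dosage = number of mutant alleles).
    """
    if config.mutation_founder not in pedigree.individuals:
        raise ValueError(
            f"mutation founder {config.mutation_founder!r} not in pedigree")
    if not pedigree.is_founder(config.mutation_founder):
        raise ValueError(
            f"mutation founder {config.mutation_founder!r} has parents")
    rng = np.random.default_rng(config.seed + 1)
    pos = _marker_map(config, rng)
    n_markers = len(pos)
    freqs = rng.uniform(*config.freq_range, size=n_markers)
    mut_pos = config.mutation_pos
    half = config.carrier_hap_length_bp // 2
    in_region = (pos >= mut_pos - half) & (pos <= mut_pos + half)
    if not in_region.any():
        raise ValueError("carrier haplotype region contains no markers")
    ancestral = (rng.random(n_markers) < freqs).astype(np.int8)

    def background_hap() -> np.ndarray:
        return (rng.random(n_markers) < freqs).astype(np.int8)

    def mutant_hap() -> np.ndarray:
        h = background_hap()
        h[in_region] = ancestral[in_region]
        return h

    morgans = (config.chrom_length_bp / 1e6
               * config.recomb_rate_cm_per_mb / 100.0)
    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    muts: dict[str, tuple[bool, bool]] = {}
    order = (pedigree.topological_order()
             if pedigree.generation is None
             else sorted(pedigree.individuals,
                         key=lambda i: (pedigree.generation[i], i)))
    for ind in order:
        s, d = pedigree.parents(ind)
        pair_h: list[np.ndarray] = []
        pair_m: list[bool] = []
        for parent in (s, d):
            if parent is None:
                if ind == config.mutation_founder:
                    # the mutation founder is exactly heterozygous: tagged
                    # ancestral haplotype plus one background haplotype
                    if not pair_m:
                        pair_h.append(mutant_hap())
                        pair_m.append(True)
                    else:
                        pair_h.append(background_hap())
                        pair_m.append(False)
                elif rng.random() < config.q0:
                    pair_h.append(mutant_hap())
                    pair_m.append(True)
                else:
                    pair_h.append(background_hap())
                    pair_m.append(False)
            else:
                ha, hb = haps[parent]
                ma, mb = muts[parent]
                g, m = _meiosis(rng, ha, hb, ma, mb, pos, mut_pos,
                                morgans, config.tau_true)
                pair_h.append(g)
                pair_m.append(m)
        haps[ind] = (pair_h[0], pair_h[1])
        muts[ind] = (pair_m[0], pair_m[1])

    samples = list(pedigree.individuals)
    geno = np.vstack([
        (haps[i][0] + haps[i][1]).astype(np.int8) for i in samples
    ])
    marker_ids = [f"snp{k:05d}" for k in range(n_markers)]
    gm = GenotypeMatrix(samples, marker_ids,
                        np.array([config.chrom] * n_markers, dtype=object),
                        pos, geno)
    dosage = [int(muts[i][0]) + int(muts[i][1]) for i in samples]
    truth = pd.DataFrame({
        "id": samples,
        "dosage": dosage,
        "genotype": [("AA", "AG", "GG")[d] for d in dosage],
    })
    return gm, truth


# ---------------------------------------------------------------------------
# Prospective cohort
# ---------------------------------------------------------------------------

@dataclass
class OutcomeModel:
    """Outcome-generating model for the prospective cohort.

    Mutant homozygotes die (with severe inflammation) before
    ``mortality_by_age`` days with probability ``mortality_prob``; survivors
    diverge from the common linear growth law after ``onset_age_days``,
    ramping over ``ramp_days`` to a proportional stature deficit of
    ``deficit`` relative to contemporaries.  Heterozygotes and wild types
    share one growth law.
    """

    mortality_prob: float = 1.0 / 3.0
    mortality_by_age: float = 210.0
    birth_weight_mean: float = 45.0   # kg
    birth_weight_sd: float = 5.0
    weight_gain_per_day: float = 1.1  # kg / day
    birth_height_mean: float = 75.0   # cm
    birth_height_sd: float = 3.0
    height_gain_per_day: float = 0.13  # cm / day
    onset_age_days: float = 180.0
    ramp_days: float = 90.0
    deficit: float = 0.15
    noise_sd_weight: float = 3.0
    noise_sd_height: float = 1.5
    measure_every_days: float = 30.0
    followup_days: float = 365.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mortality_prob <= 1.0:
            raise ValueError("mortality_prob must be in [0, 1]")
        if self.onset_age_days < 0:
            raise ValueError("onset_age_days must be >= 0")
        if not 0.0 <= self.deficit < 1.0:
            raise ValueError("deficit must be in [0, 1)")


def simulate_cohort(dosages: Sequence[int], model: OutcomeModel,
                    seed: int) -> CohortTable:
    """Simulate a followed birth cohort from true mutant-allele dosages."""
    dosages = list(dosages)
    if any(d not in (0, 1, 2) for d in dosages):
        raise ValueError("dosages must be in {0, 1, 2}")
    rng = np.random.default_rng(seed)
    ages = np.arange(0.0, model.followup_days + 0.5,
                     model.measure_every_days)
    calves, measures = [], []
    for k, d in enumerate(dosages):
        calf = f"calf{k:03d}"
        genotype = ("AA", "AG", "GG")[d]
        dies = d == 2 and rng.random() < model.mortality_prob
        if dies:
            event_age = float(rng.uniform(30.0, model.mortality_by_age))
            status = "dead"
        else:
            event_age = float(model.followup_days)
            status = "alive"
        calves.append({
            "calf": calf, "genotype": genotype, "birth_date": "2020-01-01",
            "status": status, "event_age_days": event_age,
        })
        bw = rng.normal(model.birth_weight_mean, model.birth_weight_sd)
        bh = rng.normal(model.birth_height_mean, model.birth_height_sd)
        for age in ages:
            if age > event_age:
                break
            w = bw + model.weight_gain_per_day * age
            h = bh + model.height_gain_per_day * age
            if d == 2 and age > model.onset_age_days:
                ramp = min(1.0, (age - model.onset_age_days)
                           / model.ramp_days)
                w *= 1.0 - model.deficit * ramp
                h *= 1.0 - model.deficit * ramp
            measures.append({
                "calf": calf, "age_days": float(age),
                "weight_kg": float(w + rng.normal(0, model.noise_sd_weight)),
                "height_cm": float(h + rng.normal(0, model.noise_sd_height)),
            })
    return CohortTable(pd.DataFrame(calves), pd.DataFrame(measures))


def mendelian_carrier_cross_dosages(n: int, seed: int) -> list[int]:
    """Dosages for *n* offspring of carrier x carrier matings (1:2:1)."""
    rng = np.random.default_rng(seed)
    return list(rng.integers(0, 2, size=n) + rng.integers(0, 2, size=n))


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def isoform_levels(f_skip: float, f_cryptic: float,
                   d_nmrd: float) -> tuple[float, float]:
    """Relative transcript levels (mutant / wild type) under the two-isoform
    decay model: exon-2-containing transcripts are only the surviving
    cryptic-site products, exon-3-containing transcripts add the skip
    product (which escapes decay)."""
    if abs(f_skip + f_cryptic - 1.0) > 1e-9:
        raise ValueError("f_skip + f_cryptic must equal 1")
    if not 0.0 <= d_nmrd <= 1.0:
        raise ValueError("d_nmrd must be in [0, 1]")
    surviving = f_cryptic * (1.0 - d_nmrd)
    rel_exon2 = surviving
    rel_exon3 = f_skip + surviving
    return rel_exon2, rel_exon3


@dataclass
class QpcrDesign:
    """Assay layout: two isoform-discriminating target assays, reference
    genes, a two-fold standard-curve dilution series and triplicate wells."""

    exon2_assay: str = "RNF11_ex2"
    exon3_assay: str = "RNF11_ex3"
    reference_genes: tuple[str, ...] = ("ACTB", "YWHAZ")
    wt_sample: str = "WT"
    mut_sample: str = "MUT"
    replicates: int = 3
    efficiency: float = 2.0
    base_cq: float = 22.0
    n_standard_points: int = 5
    standard_fold: float = 2.0

    def all_assays(self) -> tuple[str, ...]:
        return (self.exon2_assay, self.exon3_assay) + self.reference_genes


def simulate_qpcr(f_skip: float, f_cryptic: float, d_nmrd: float,
                  design: QpcrDesign | None = None,
                  noise_sd: float = 0.0, seed: int = 0) -> QpcrTable:
    """Generate a Cq table from a splicing truth.

    Cq follows ``base_cq - log_E(level x dilution) + N(0, noise_sd)``.
    A zero transcript level yields an undetermined reaction, recorded as a
    NaN Cq.  The output contains wild-type and mutant samples for every
    assay plus a wild-type standard-curve dilution series for the two
    target assays.
    """
    design = design or QpcrDesign()
    if design.efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    rel_exon2, rel_exon3 = isoform_levels(f_skip, f_cryptic, d_nmrd)
    rng = np.random.default_rng(seed)
    log_e = math.log(design.efficiency)
    rows = []

    def cq_of(level: float, dilution: float) -> float:
        if level <= 0:
            return float("nan")
        cq = design.base_cq - math.log(level * dilution) / log_e
        if noise_sd > 0:
            cq += rng.normal(0, noise_sd)
        return max(cq, 0.0)

    levels = {
        design.wt_sample: {a: 1.0 for a in design.all_assays()},
        design.mut_sample: {a: 1.0 for a in design.all_assays()},
    }
    levels[design.mut_sample][design.exon2_assay] = rel_exon2
    levels[design.mut_sample][design.exon3_assay] = rel_exon3

    for sample in (design.wt_sample, design.mut_sample):
        for assay in design.all_assays():
            for rep in range(1, design.replicates + 1):
                rows.append({
                    "sample": sample, "target": assay, "replicate": rep,
                    "cq": cq_of(levels[sample][assay], 1.0),
                    "dilution": 1.0,
                })
    # wild-type standard curve for the two target assays
    for assay in (design.exon2_assay, design.exon3_assay):
        for k in range(design.n_standard_points):
            dilution = design.standard_fold ** (-k)
            for rep in range(1, design.replicates + 1):
                rows.append({
                    "sample": f"STD{k}", "target": assay, "replicate": rep,
                    "cq": cq_of(1.0, dilution), "dilution": dilution,
                })
    return QpcrTable(pd.DataFrame(rows))
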