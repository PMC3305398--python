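# Methods

This note documents the models, defaults and numerical choices behind
stuntscan, and what the synthetic-data generator does and does not
emulate.

## Study setting

The package targets the analysis pattern of a recessive defect in an
intensively bred livestock population: a loss-of-function variant spread
by a popular founder sire, common carriers, affected animals homozygous
identical by descent (IBD) around the variant, partial juvenile lethality
in homozygotes, and a suspicion of heterozygote advantage driving a
selective sweep.

## Pedigree and genotype formats (pedio)

Pedigrees are LINKAGE-style (`id sire dam [sex]`, "0" = unknown) or CSV;
unknown parents become absent links, and parents referenced but never
listed are auto-created as founders with a logged warning — field
genealogies, especially AI-sire records, are routinely incomplete, and
silently dropping such links would truncate descent paths. Validation
rejects cycles (naming an individual on the cycle), duplicate ids, and
sire/dam role or sex conflicts.

Genotypes are 0/1/2/missing against a per-marker reference allele.  In
the PLINK text dialect the reference is the first-seen allele and a "0"
allele makes the call missing; consequently a marker whose first
non-missing call is alternate-homozygous reads back with flipped polarity
(round trip is identity up to this polarity, and exact for the
self-contained CSV dialect, whose header cells carry `marker:chrom:pos`).
All positions are 1-based bp; intervals throughout the package are closed
`[start, end]`, with an explicit, tested conversion to 0-based half-open
BED only at export.

## Synthetic data (simdata)

`simulate_pedigree` builds discrete generations. Founders alternate
male/female; each female of a generation is mated to one male, with a
configurable fraction of "AI sires" (default 15% of males) receiving a
configurable share of matings (default 90%) to mimic
artificial-insemination concentration. Sibship sizes are zero-truncated
Poisson (default rate 2.0–2.5 in the shipped configurations). A
population with no breeding pair raises an extinction error rather than
returning a truncated study.

`drop_haplotypes` drops founder haplotypes down the pedigree over a
single simulated chromosome (default 20 Mb, 50 markers/Mb, background
allele frequencies uniform on [0.05, 0.5]). Recombination is a Haldane
(no-interference) Poisson process at 1 cM/Mb. The designated mutation
founder is heterozygous for a tagged ancestral haplotype spanning
`carrier_hap_length_bp` (default 4 Mb) around the variant at the
chromosome midpoint; any other founder haplotype is mutant with
probability q₀ and then carries a copy of the same ancestral haplotype,
reflecting IBD from an older sweep ancestor — this is what makes affected
homozygotes autozygous around the variant whichever path the allele took.
Transmission-ratio distortion is applied at the variant position: a
heterozygous parent passes the mutant-bearing haplotype with probability
τ, and crossovers then determine the rest of the gamete, so the marginal
transmission rate is exactly τ.

The default chromosome is deliberately short (20 Mb vs ~120 Mb for a real
bovine autosome), which makes long-range IBD more common than in real
data; with only ~0.2 crossovers per meiosis, homozygous cases are
sometimes IBD over the whole simulated chromosome. Tests therefore treat
"the shared interval covers the true variant" as the target property
rather than any particular interval length.

`simulate_cohort` models the prospective design: offspring of
carrier × carrier matings (1:2:1 dosages), homozygotes dying before 210
days with probability 1/3, and growth following a linear law (birth
weight 45 ± 5 kg, 1.1 kg/day; height 75 ± 3 cm, 0.13 cm/day) from which
surviving homozygotes diverge after 180 days, ramping over 90 days to a
15% proportional deficit relative to contemporaries. Measures are
month-spaced with Gaussian noise (3 kg / 1.5 cm). The deficit form is a
design choice — any smooth divergence is defensible; the ramped
multiplicative deficit is the minimal one matching "proportionate
stunting appearing at 5–6 months, ~15% below contemporaries".

`simulate_qpcr` generates Cq values as
`Cq = base − log_E(level × dilution) + N(0, sd)` for wild-type and mutant
samples over the two isoform assays and reference genes, plus a wild-type
five-point two-fold standard-curve series per target assay. A zero
transcript level yields an undetermined reaction (NaN Cq). The truth
(f_skip, f_cryptic, d) enters through the two-isoform model below.

Every generator call consumes a single explicitly seeded stream
(`numpy.random.default_rng`), and repeated calls are bit-identical.

## Autozygosity (autozyg)

ROH calling is a greedy left-to-right scan: from the leftmost unconsumed
homozygous marker, extend while the heterozygous (default ≤ 1) and
missing (default ≤ 2) budgets hold and no inter-marker gap exceeds 1 Mb;
trim to the innermost homozygous markers; emit when ≥ 20 markers; resume
after the emitted run (runs never overlap). The thresholds are
configurable — published ROH criteria vary and the emulated study stated
none — and the scan is validated against an exhaustive O(n²) window
oracle.

The shared interval is computed on bp intervals, not marker indices, so
per-case missingness cannot shift boundaries: for every
constant-coverage stretch of the case-segment sweep, the candidate
interval is the intersection of the covering ROH (one per case, they are
non-overlapping within a case), guaranteeing the reported support equals
the number of cases whose ROH contains the whole interval. Ties are
broken by support, then bp length, then leftmost start. Boundaries are
innermost shared homozygous positions; the alternative
(outermost-flanking-heterozygous) convention would widen intervals by one
inter-marker distance per side. Hidden-haplotype-state inference is out
of scope; state assignments are accepted as input and summarised as
case/control frequency contrasts.

## Gene dropping (genedrop)

Distortion applies only to heterozygous parents; homozygous mutant
parents always transmit, wild-type parents never (q₀ enters only through
founder haplotypes, independently per haplotype). Carrier status is
dosage ≥ 1. Monte-Carlo dropping is vectorised over simulations; the τ
scan uses seed + i at grid point i so profiles are reproducible and
refinable, and ties in the exact-hit profile resolve to the smallest τ.

Exact enumeration uses variable elimination in topological order: the
state is the joint dosage of individuals still needed as parents plus the
carrier count among retired target members. It refuses pedigrees with
more than 22 random binary transmissions (2 per non-founder plus 2 per
stochastic founder). The mean of the exact distribution is cross-checked
against an independent per-individual marginal recursion; that recursion
assumes the two parental transmissions are independent, so the check uses
a pedigree without inbreeding loops.

τ estimation is deliberately simulation-compatibility profiling (the
count of simulations reproducing the observed carrier count exactly), not
a likelihood method — matching how such sweep checks are run in practice.

## Splice fractions (splicefrac)

Efficiency: least-squares Cq on log10(input), E = 10^(−1/slope), capped
at 2.1 with a warning (above-2 fits indicate inhibition or pipetting
error, not super-doubling chemistry); ≥ 3 distinct dilutions required.
Reference stability is the geNorm M measure (mean over other genes of the
sd across samples of pairwise log2 ratios, sd with ddof = 1). NRQ uses
replicate-mean Cq (arithmetic mean, sd reported via the table helper),
RQ = E^(ΔCq to calibrator), normalised by the geometric mean of all
passed reference genes; the calibrator has NRQ = 1 by construction.

The two-isoform inversion is closed-form: s = r₂, f_skip = r₃ − r₂,
d = 1 − s/(1 − f_skip). Inputs with r₂ > r₃ violate the model (exon-2
transcripts are a subset of exon-3 transcripts) and raise; noisy d
estimates outside [0, 1] are clamped with a warning rather than rejected,
since replicate noise routinely crosses the boundary when f_cryptic is
small. Uncertainty comes from a seeded nonparametric bootstrap over
replicate wells (default 2,000 resamples); it reflects well-to-well noise
only and is conditional on the realized standard curve.

A note on the published worked example: the printed spleen fold
reductions (1.1× and 11×) solve to d ≈ 0.50, not the published 55%, and
the printed lymph-node folds (2×, 37×) to 47%/53%/95% rather than
44%/56%/95%. The discrepancy is a rounding artefact of the printed folds
— the unrounded study measurements are unavailable — so the package
implements the stated model and documents the gap instead of fitting
hidden inputs.

## Cohort statistics (cohortstats)

The exact R×2 genotype-by-outcome test uses the two-sided
probability-ordering (Fisher) convention — the sum over margin-fixed
tables of multivariate hypergeometric probabilities not exceeding the
observed table's — computed by bounded enumeration of per-row event
counts in log space; it reduces to the hypergeometric closed form for
2×2. The exact multinomial segregation test orders outcomes by the
Pearson discrepancy statistic (tables at least as discrepant as observed
count toward p), which keeps it aligned with the asymptotic χ² test it
replaces at small N; it is limited to N ≤ 200. The default segregation
test is Pearson χ²; a G-test is provided since published p-values of this
kind are often G-based and the emulated study's choice is unstated.

Growth regressions fit ordinary least squares per group and test slope
differences through the age × group interaction with calf-clustered
robust covariance — repeated measures share each calf's individual level
(its birth size), and ignoring that clustering makes the interaction test
strongly anticonservative (the test suite checks the null p-value is
uniform across simulated no-effect cohorts). Survival is summarised as
counts plus the exact test; formal time-to-event analysis is out of
scope.

No multiple-testing correction is applied inside the module; callers own
that decision.

## Problem sizes and tolerances

Simulation-based checks use study-scale but compact problems chosen as
the package's own defaults: 200-seed sweeps of ~300-individual pedigrees
with 1,000 markers for interval coverage; 100,000 simulations against the
exact oracle (χ² goodness of fit); τ recovery on a 61-point grid at
10,000 simulations per point. Closed-form identities are asserted to
1e-9–1e-12; Monte-Carlo quantities to 2–4 standard errors of the check
itself. The shared-interval coverage criterion (≥ 95% of seeds) is
evaluated over seeds that produce at least two affected homozygotes,
because intersecting fewer than two cases is undefined (and the operation
rejects it); roughly 85–90% of seeds are applicable under the default
configuration.

## Known limitations

- The pedigree generator uses discrete generations and a single
  population; overlapping generations, migration and selective culling
  are not modelled.
- Linkage structure exists only on the one simulated chromosome; there is
  no genome-wide LD, no genotyping error, and marker ascertainment is
  uniform rather than array-like.
- Exact gene-drop enumeration is limited to ~11 non-founders; larger
  pedigrees rely on the (tested) Monte-Carlo path.
- The two-isoform model assumes complete decay asymmetry (skip product
  immune, cryptic product susceptible) and exactly two aberrant isoforms.
- Gene dropping treats the target set as unconditioned descendants;
  conditioning on ascertainment (e.g. targets being born/selected) is not
  modelled and would shift tail probabilities for strongly selected sets.
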