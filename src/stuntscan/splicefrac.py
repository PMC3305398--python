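"""qPCR relative quantification and the two-isoform decay model.

The quantification chain is the field-standard one: amplification
efficiency from a standard-curve regression of Cq on log10(input),
reference-gene stability by the geNorm M measure, and normalized relative
quantities (NRQ) against the geometric mean of the reference genes with a
calibrator sample fixed at 1.

The splice model: a splice-acceptor mutation forces every pre-mRNA down one
of two aberrant paths — exon skipping (fraction ``f_skip``) or a cryptic
splice site that retains most of the exon (fraction ``f_cryptic = 1 -
f_skip``).  Only the cryptic product is subject to nonsense-mediated decay
(fraction ``d_nmrd`` degraded), so the observed mutant/wild-type ratios are

    rel_exon2 = f_cryptic * (1 - d_nmrd)            (exon-2 assay)
    rel_exon3 = f_skip + f_cryptic * (1 - d_nmrd)   (exon-3 assay)

which inverts in closed form to ``f_skip = rel_exon3 - rel_exon2`` and
``d_nmrd = 1 - rel_exon2 / (1 - f_skip)``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedio import QpcrTable

logger = logging.getLogger("stuntscan.splicefrac")

__all__ = [
    "EfficiencyFit",
    "RelativeExpression",
    "SpliceEstimate",
    "amplification_efficiency",
    "reference_stability",
    "normalized_relative_quantity",
    "estimate_splice_fractions",
    "bootstrap_splice_estimate",
    "ModelViolationError",
]

MAX_EFFICIENCY = 2.1  # fits above this are capped with a warning


class ModelViolationError(ValueError):
    """Observed quantities are inconsistent with the two-isoform model."""


# ---------------------------------------------------------------------------
# amplification efficiency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficiencyFit:
    assay: str
    slope: float        # Cq per log10(input)
    efficiency: float   # fold amplification per cycle
    r_squared: float
    n_points: int


def amplification_efficiency(series, assay: str = "assay") -> EfficiencyFit:
    """Fit E from (dilution, Cq) standard-curve pairs.

    Least-squares regression of Cq on log10(input); E = 10^(-1/slope).
    A perfect two-fold series has slope -3.3219 and E = 2.  Requires at
    least three distinct dilutions.
    """
    pairs = [(float(d), float(c)) for d, c in series]
    dilutions = sorted({d for d, _ in pairs})
    if len(dilutions) < 3:
        raise ValueError("need at least 3 distinct dilutions for a "
                         "standard curve")
    if any(d <= 0 for d in dilutions):
        raise ValueError("dilutions must be positive")
    x = np.log10([d for d, _ in pairs])
    y = np.array([c for _, c in pairs])
    if np.allclose(y, y[0]):
        raise ValueError("degenerate fit: Cq constant across dilutions")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError("standard-curve slope must be negative "
                         f"(got {res.slope:.3g})")
    eff = 10.0 ** (-1.0 / res.slope)
    if eff > MAX_EFFICIENCY:
        logger.warning("assay %s: efficiency %.3f capped at %.2f",
                       assay, eff, MAX_EFFICIENCY)
        eff = MAX_EFFICIENCY
    return EfficiencyFit(assay=assay, slope=float(res.slope),
                         efficiency=float(eff),
                         r_squared=float(res.rvalue ** 2),
                         n_points=len(pairs))


def efficiencies_from_table(table: QpcrTable,
                            assays=None) -> dict[str, EfficiencyFit]:
    """Standard-curve fits per assay from the dilution-series rows of a Cq
    table (rows with more than one distinct dilution per assay)."""
    out: dict[str, EfficiencyFit] = {}
    df = table.data.dropna(subset=["cq"])
    for assay, sub in df.groupby("target"):
        std = sub[sub["sample"].str.startswith("STD")]
        if assays is not None and assay not in assays:
            continue
        if std["dilution"].nunique() >= 3:
            out[str(assay)] = amplification_efficiency(
                zip(std["dilution"], std["cq"]), assay=str(assay))
    return out


# ---------------------------------------------------------------------------
# geNorm reference stability
# ---------------------------------------------------------------------------

def reference_stability(quantities: pd.DataFrame) -> pd.Series:
    """geNorm stability measure M per candidate reference gene.

    ``quantities``: genes x samples matrix of relative quantities
    (strictly positive).  M_g is the mean, over the other genes h, of the
    standard deviation across samples of log2(q_g / q_h); lower M = more
    stable.  Returned sorted ascending (most stable first).
    """
    q = quantities.astype(float)
    if q.shape[0] < 2 or q.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if (q <= 0).any().any():
        raise ValueError("relative quantities must be positive")
    logq = np.log2(q)
    genes = list(q.index)
    m = {}
    for g in genes:
        sds = [
            float(np.std(logq.loc[g] - logq.loc[h], ddof=1))
            for h in genes if h != g
        ]
        m[g] = float(np.mean(sds))
    return pd.Series(m, name="geNorm_M").sort_values(kind="stable")


# ---------------------------------------------------------------------------
# normalized relative quantities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelativeExpression:
    sample: str
    target: str
    nrq: float

    def __post_init__(self) -> None:
        if not self.nrq > 0:
            raise ValueError("NRQ must be positive")

    @property
    def fold_reduction(self) -> float:
        return 1.0 / self.nrq


def _mean_cq(table: QpcrTable) -> pd.DataFrame:
    df = table.data
    undiluted = df[df["dilution"] == 1.0].dropna(subset=["cq"])
    return (undiluted.groupby(["sample", "target"])["cq"]
            .mean().reset_index())


def normalized_relative_quantity(
    table: QpcrTable,
    efficiencies: dict[str, EfficiencyFit] | dict[str, float],
    refs,
    calibrator: str,
    targets=None,
) -> list[RelativeExpression]:
    """Efficiency-corrected NRQ per sample x target assay.

    RQ_g = E_g^(Cq_calibrator - Cq_sample) from replicate-mean Cq;
    NRQ = RQ_target / geometric-mean over reference genes of RQ_ref.
    The calibrator sample has NRQ = 1 by construction.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("need at least one reference gene")
    eff = {
        g: (e.efficiency if isinstance(e, EfficiencyFit) else float(e))
        for g, e in efficiencies.items()
    }
    mean_cq = _mean_cq(table)
    pivot = mean_cq.pivot(index="sample", columns="target", values="cq")
    if calibrator not in pivot.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    samples = [s for s in pivot.index if not str(s).startswith("STD")]
    assays = ([t for t in pivot.columns if t not in refs]
              if targets is None else list(targets))
    missing = [
        (s, g) for s in samples for g in assays + refs
        if g not in pivot.columns or pd.isna(pivot.loc[s, g])
    ]
    if missing:
        raise ValueError(f"missing assay measurements for {missing}")
    for g in assays + refs:
        if g not in eff:
            raise ValueError(f"no efficiency for assay {g!r}")

    def rq(sample: str, gene: str) -> float:
        dcq = pivot.loc[calibrator, gene] - pivot.loc[sample, gene]
        return eff[gene] ** dcq

    out = []
    for s in samples:
        ref_geo = math.exp(np.mean([math.log(rq(s, g)) for g in refs]))
        for t in assays:
            out.append(RelativeExpression(sample=str(s), target=str(t),
                                          nrq=rq(s, t) / ref_geo))
    return out


# ---------------------------------------------------------------------------
# splice-fraction estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpliceEstimate:
    """Point estimate of the two-isoform decay model.

    ``surviving`` is the undegraded cryptic fraction
    f_cryptic * (1 - d_nmrd) = rel_exon2.
    """

    f_skip: float
    f_cryptic: float
    d_nmrd: float
    surviving: float
    clamped: bool = False


def estimate_splice_fractions(rel_exon2: float, rel_exon3: float,
                              tolerance: float = 1e-9) -> SpliceEstimate:
    """Invert the two-isoform model from mutant/wild-type NRQ ratios.

    ``rel_exon2`` and ``rel_exon3`` are mutant levels relative to wild type
    (= 1) for the exon-2- and exon-3-spanning assays.  Requires
    0 < rel_exon2 <= rel_exon3 <= 1 (up to *tolerance*): under the model,
    exon-2-containing transcripts are a subset of exon-3-containing ones.
    ``d_nmrd`` is clamped to [0, 1] with a warning when noise pushes it
    outside.
    """
    if not rel_exon2 > 0:
        raise ModelViolationError("rel_exon2 must be positive")
    if rel_exon2 > rel_exon3 + tolerance:
        raise ModelViolationError(
            "exon-2-containing level exceeds exon-3-containing level "
            f"({rel_exon2:.4g} > {rel_exon3:.4g}); inconsistent with the "
            "two-isoform model"
        )
    if rel_exon3 > 1.0 + max(tolerance, 0.5):
        raise ModelViolationError(
            f"rel_exon3 = {rel_exon3:.4g} far exceeds the wild-type level"
        )
    surviving = float(rel_exon2)
    f_skip = float(min(max(rel_exon3 - rel_exon2, 0.0), 1.0))
    f_cryptic = 1.0 - f_skip
    clamped = False
    if f_cryptic <= 0:
        raise ModelViolationError("f_cryptic collapsed to 0; d undefined")
    d = 1.0 - surviving / f_cryptic
    if d < 0.0 or d > 1.0:
        logger.warning("d_nmrd %.4f clamped into [0, 1]", d)
        d = min(max(d, 0.0), 1.0)
        clamped = True
    return SpliceEstimate(f_skip=f_skip, f_cryptic=f_cryptic, d_nmrd=d,
                          surviving=surviving, clamped=clamped)


def estimate_from_table(table: QpcrTable, refs, calibrator: str,
                        exon2_assay: str, exon3_assay: str,
                        efficiencies=None) -> SpliceEstimate:
    """Full chain: efficiencies -> NRQ -> splice fractions for the single
    non-calibrator sample of a Cq table."""
    if efficiencies is None:
        efficiencies = efficiencies_from_table(table)
        for g in list(refs) + [exon2_assay, exon3_assay]:
            efficiencies.setdefault(g, EfficiencyFit(g, -3.3219, 2.0, 1.0, 0))
    nrqs = normalized_relative_quantity(
        table, efficiencies, refs, calibrator,
        targets=[exon2_assay, exon3_assay])
    by_key = {(r.sample, r.target): r.nrq for r in nrqs}
    samples = sorted({r.sample for r in nrqs} - {calibrator})
    if len(samples) != 1:
        raise ValueError(f"expected one test sample, found {samples}")
    s = samples[0]
    return estimate_splice_fractions(by_key[(s, exon2_assay)],
                                     by_key[(s, exon3_assay)])


def bootstrap_splice_estimate(table: QpcrTable, refs, calibrator: str,
                              exon2_assay: str, exon3_assay: str,
                              n_boot: int = 2000, seed: int = 0,
                              ) -> pd.DataFrame:
    """Nonparametric bootstrap over replicate wells.

    Resamples replicates within each sample x target x dilution cell,
    re-runs the whole estimation chain, and returns percentile intervals
    for f_skip and d_nmrd.
    """
    rng = np.random.default_rng(seed)
    df = table.data
    groups = [sub for _, sub in
              df.groupby(["sample", "target", "dilution"], sort=True)]
    f_skips, d_nmrds = [], []
    for _ in range(n_boot):
        parts = [
            sub.iloc[rng.integers(0, len(sub), size=len(sub))]
            for sub in groups
        ]
        boot = QpcrTable(pd.concat(parts, ignore_index=True))
        try:
            est = estimate_from_table(boot, refs, calibrator,
                                      exon2_assay, exon3_assay)
        except (ModelViolationError, ValueError):
            continue
        f_skips.append(est.f_skip)
        d_nmrds.append(est.d_nmrd)
    if not f_skips:
        raise RuntimeError("all bootstrap resamples violated the model")
    q = [2.5, 50.0, 97.5]
    return pd.DataFrame(
        {
            "f_skip": np.percentile(f_skips, q),
            "d_nmrd": np.percentile(d_nmrds, q),
        },
        index=pd.Index(["2.5%", "50%", "97.5%"], name="percentile"),
    )
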