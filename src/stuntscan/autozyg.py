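"""Runs of homozygosity and shared-autozygosity mapping.

Recessive mutations that are identical by descent expose themselves as long
runs of homozygous SNP calls (ROH) in affected animals; intersecting the
runs of several affected homozygotes localises the shared autozygous
interval that must contain the causative variant.  Coordinates are 1-based
bp and all intervals are closed ``[start, end]``; a helper converts to the
0-based half-open BED convention for export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedio import MISSING, GenotypeMatrix

__all__ = [
    "RohParams",
    "RohSegment",
    "SharedInterval",
    "detect_roh",
    "detect_roh_matrix",
    "shared_autozygous_interval",
    "state_frequency_contrast",
    "interval_length",
    "to_bed",
]


@dataclass(frozen=True)
class RohParams:
    """ROH calling thresholds.

    A run may contain at most ``max_het`` heterozygous and ``max_missing``
    missing calls, no inter-marker gap above ``max_gap_bp``, and must span
    at least ``min_markers`` markers.  Run boundaries are trimmed to the
    innermost homozygous markers.
    """

    min_markers: int = 20
    max_het: int = 1
    max_missing: int = 2
    max_gap_bp: int = 1_000_000


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chrom: str
    start: int  # bp, closed
    end: int    # bp, closed
    n_markers: int
    n_het: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start exceeds end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SharedInterval:
    chrom: str
    start: int
    end: int
    support: int  # number of cases whose ROH covers the interval

    @property
    def length(self) -> int:
        return self.end - self.start

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def interval_length(start: int, end: int) -> int:
    """Length of a closed bp interval as reported in the field
    (end - start)."""
    if end < start:
        raise ValueError("end must be >= start")
    return end - start


def to_bed(interval: SharedInterval) -> tuple[str, int, int, int]:
    """Convert a closed 1-based interval to BED (0-based, half-open)."""
    return interval.chrom, interval.start - 1, interval.end, interval.support


# ---------------------------------------------------------------------------
# ROH detection
# ---------------------------------------------------------------------------

def _is_hom(g: int) -> bool:
    return g == 0 or g == 2


def detect_roh(genotypes: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
               params: RohParams = RohParams(),
               sample: str = "sample") -> list[RohSegment]:
    """Detect runs of homozygosity in one sample.

    Greedy left-to-right scan: from the leftmost unconsumed homozygous
    marker the run is extended as far as the het/missing budgets and the
    gap ceiling allow, trimmed back to its last homozygous marker, and
    emitted when it spans ``min_markers`` markers; scanning resumes after
    the emitted run, so runs never overlap.
    """
    genotypes = np.asarray(genotypes)
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    if not (len(genotypes) == len(chrom) == len(pos)):
        raise ValueError("genotypes, chrom and pos must align")
    segments: list[RohSegment] = []
    for c in dict.fromkeys(chrom):
        mask = chrom == c
        g = genotypes[mask]
        p = pos[mask]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"markers on chromosome {c} are not sorted")
        segments.extend(_detect_roh_chrom(g, p, params, sample, str(c)))
    return segments


def _detect_roh_chrom(g: np.ndarray, p: np.ndarray, params: RohParams,
                      sample: str, chrom: str) -> list[RohSegment]:
    n = len(g)
    out: list[RohSegment] = []
    i = 0
    while i < n:
        if not _is_hom(int(g[i])):
            i += 1
            continue
        het = miss = 0
        j = i
        last_hom = i
        k = i + 1
        while k < n:
            if p[k] - p[k - 1] > params.max_gap_bp:
                break
            gk = int(g[k])
            nhet = het + (gk == 1)
            nmiss = miss + (gk == MISSING)
            if nhet > params.max_het or nmiss > params.max_missing:
                break
            het, miss = nhet, nmiss
            if _is_hom(gk):
                last_hom = k
            k += 1
        j = last_hom
        n_markers = j - i + 1
        if n_markers >= params.min_markers:
            het_inside = int(np.sum(g[i:j + 1] == 1))
            out.append(RohSegment(sample=sample, chrom=chrom,
                                  start=int(p[i]), end=int(p[j]),
                                  n_markers=n_markers, n_het=het_inside))
            i = j + 1
        else:
            i += 1
    return out


def detect_roh_matrix(gm: GenotypeMatrix,
                      params: RohParams = RohParams(),
                      samples=None) -> dict[str, list[RohSegment]]:
    """ROH per sample of a genotype matrix."""
    samples = list(samples) if samples is not None else list(gm.samples)
    return {
        s: detect_roh(gm.row(s), gm.chrom, gm.pos, params, sample=s)
        for s in samples
    }


# ---------------------------------------------------------------------------
# shared interval
# ---------------------------------------------------------------------------

def shared_autozygous_interval(gm: GenotypeMatrix, case_ids,
                               params: RohParams = RohParams(),
                               ) -> SharedInterval:
    """Maximal interval covered by one ROH in every case.

    If no interval is covered by all cases, the interval with the highest
    case support is returned (support reported in the result).  Ties are
    broken by bp length, then by leftmost start.
    """
    case_ids = list(case_ids)
    if not case_ids:
        raise ValueError("empty case set")
    if len(case_ids) < 2:
        raise ValueError("need at least 2 cases to intersect")
    roh = detect_roh_matrix(gm, params, samples=case_ids)
    best: SharedInterval | None = None
    for c in dict.fromkeys(gm.chrom):
        cand = _best_interval_on_chrom(str(c), roh, case_ids)
        if cand is None:
            continue
        if best is None or (cand.support, cand.length, -cand.start) > (
                best.support, best.length, -best.start):
            best = cand
    if best is None:
        raise ValueError("no ROH detected in any case")
    return best


def _best_interval_on_chrom(chrom: str, roh, case_ids) -> SharedInterval | None:
    # per-case segment lists on this chromosome (non-overlapping per case)
    per_case: list[list[tuple[int, int]]] = []
    for s in case_ids:
        per_case.append(sorted(
            (seg.start, seg.end) for seg in roh[s] if seg.chrom == chrom))
    breakpoints: set[int] = set()
    for ivals in per_case:
        for start, end in ivals:
            breakpoints.add(start)
            breakpoints.add(end + 1)  # closed -> half-open for the sweep
    if not breakpoints:
        return None
    coords = sorted(breakpoints)
    best: tuple[int, int, int, int] | None = None  # support, len, -start, end
    for lo, hi in zip(coords[:-1], coords[1:]):
        x = lo  # any point of [lo, hi-1]; cover is constant on the stretch
        covering: list[tuple[int, int]] = []
        for ivals in per_case:
            for start, end in ivals:
                if start <= x <= end:
                    covering.append((start, end))
                    break
        if not covering:
            continue
        # support of the *full* interval requires every covering ROH to
        # contain it; the maximal such interval is their intersection
        istart = max(s for s, _ in covering)
        iend = min(e for _, e in covering)
        cand = (len(covering), iend - istart, -istart, iend)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    support, _, neg_start, end = best
    return SharedInterval(chrom=chrom, start=-neg_start, end=end,
                          support=support)


# ---------------------------------------------------------------------------
# haplotype-state frequency contrast
# ---------------------------------------------------------------------------

def state_frequency_contrast(states, labels) -> pd.DataFrame:
    """Case vs control frequencies of categorical haplotype states.

    ``states`` and ``labels`` are aligned per-haplotype sequences (two
    haplotypes per individual); labels are 'case' or 'control'.  Returns a
    table with per-state frequencies in each group (each column sums to 1)
    sorted by decreasing case - control difference.
    """
    states = pd.Series(list(states), name="state")
    labels = pd.Series(list(labels), name="label")
    if len(states) != len(labels):
        raise ValueError("states and labels must align")
    if labels.isna().any():
        raise ValueError("missing group label")
    bad = set(labels.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"labels must be 'case'/'control', got {bad}")
    tab = pd.crosstab(states, labels)
    for col in ("case", "control"):
        if col not in tab.columns:
            raise ValueError(f"no haplotypes labelled {col!r}")
    freq = tab / tab.sum(axis=0)
    out = pd.DataFrame({
        "state": freq.index,
        "case_freq": freq["case"].to_numpy(),
        "control_freq": freq["control"].to_numpy(),
    })
    out["difference"] = out["case_freq"] - out["control_freq"]
    return (out.sort_values("difference", ascending=False, kind="stable")
            .reset_index(drop=True))
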