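"""Readers, writers and validated containers for the pipeline's text formats.

Four kinds of input are handled: pedigrees (LINKAGE-style whitespace files or
CSV), biallelic SNP genotype matrices (PLINK .ped/.map text dialect or a
single-file CSV dialect), qPCR Cq tables and prospective-cohort tables.
All formats are plain UTF-8 text; genomic positions are 1-based bp and
intervals elsewhere in the package are closed ``[start, end]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("stuntscan.pedio")

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "QpcrTable",
    "CohortTable",
    "PedigreeError",
    "FormatError",
    "read_pedigree",
    "write_pedigree",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_qpcr_table",
    "write_qpcr_table",
    "read_cohort_table",
    "write_cohort_table",
]

MISSING = -1  # genotype code for a missing call

_SEX_IN = {
    "1": "male", "m": "male", "male": "male",
    "2": "female", "f": "female", "female": "female",
    "0": "unknown", "": "unknown", "unknown": "unknown", "u": "unknown",
}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Invalid pedigree structure (cycle, duplicate id, sex conflict)."""


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """A validated genealogy.

    ``sire``/``dam`` map each individual to a parent id or ``None`` when the
    parent is unknown.  Individuals with both parents unknown are founders.
    An optional per-individual ``generation`` index is carried when the
    pedigree was simulated.
    """

    individuals: list[str]
    sire: dict[str, str | None]
    dam: dict[str, str | None]
    sex: dict[str, str]
    generation: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        seen = set()
        for ind in self.individuals:
            if ind in seen:
                raise PedigreeError(f"duplicate individual id {ind!r}")
            seen.add(ind)
        for ind in self.individuals:
            for parent in (self.sire[ind], self.dam[ind]):
                if parent is not None and parent not in seen:
                    raise PedigreeError(
                        f"parent {parent!r} of {ind!r} is not an individual"
                    )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeError(
                f"pedigree contains a cycle through {cycle[0][0]!r}"
            )
        sires = {s for s in self.sire.values() if s is not None}
        dams = {d for d in self.dam.values() if d is not None}
        for ind in sires & dams:
            raise PedigreeError(f"{ind!r} appears both as sire and as dam")
        for ind in sires:
            if self.sex.get(ind, "unknown") == "female":
                raise PedigreeError(f"sire {ind!r} is recorded as female")
        for ind in dams:
            if self.sex.get(ind, "unknown") == "male":
                raise PedigreeError(f"dam {ind!r} is recorded as male")

    def graph(self) -> nx.DiGraph:
        """Parent -> child directed graph."""
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals:
            for parent in (self.sire[ind], self.dam[ind]):
                if parent is not None:
                    g.add_edge(parent, ind)
        return g

    # -- convenience -------------------------------------------------------

    @property
    def founders(self) -> list[str]:
        return [i for i in self.individuals
                if self.sire[i] is None and self.dam[i] is None]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i in self.individuals
                if self.sire[i] is not None or self.dam[i] is not None]

    def is_founder(self, ind: str) -> bool:
        return self.sire[ind] is None and self.dam[ind] is None

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        return self.sire[ind], self.dam[ind]

    def n_meioses(self) -> int:
        """Number of parent->offspring transmissions (2 per non-founder)."""
        return 2 * len(self.nonfounders)

    def topological_order(self) -> list[str]:
        """Individuals ordered so that parents precede offspring."""
        order = list(nx.lexicographical_topological_sort(self.graph()))
        return order

    def descendants(self, ind: str) -> set[str]:
        return set(nx.descendants(self.graph(), ind))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.individuals,
                "sire": [self.sire[i] or "" for i in self.individuals],
                "dam": [self.dam[i] or "" for i in self.individuals],
                "sex": [self.sex[i] for i in self.individuals],
            }
        )


def _build_pedigree(rows: list[tuple[str, str | None, str | None, str]],
                    generation: dict[str, int] | None = None) -> Pedigree:
    """Assemble a Pedigree from (id, sire, dam, sex) rows, auto-creating
    referenced-but-unlisted parents as founders."""
    ids = [r[0] for r in rows]
    known = set(ids)
    sire = {r[0]: r[1] for r in rows}
    dam = {r[0]: r[2] for r in rows}
    sex = {r[0]: r[3] for r in rows}
    for ind, s, d, _ in rows:
        for parent, role in ((s, "male"), (d, "female")):
            if parent is not None and parent not in known:
                logger.warning(
                    "parent %r of %r not listed; auto-created as founder",
                    parent, ind,
                )
                known.add(parent)
                ids.append(parent)
                sire[parent] = None
                dam[parent] = None
                sex[parent] = role
    return Pedigree(ids, sire, dam, sex, generation=generation)


def read_pedigree(path: str | Path, dialect: str = "linkage") -> Pedigree:
    """Read a pedigree file.

    ``linkage``: whitespace-delimited ``id sire dam [sex]``, "0" = unknown
    parent.  ``csv``: comma-separated with header ``id,sire,dam[,sex]``,
    empty cell = unknown parent.  Parents named but never listed as a row are
    appended as founders (with a logged warning).
    """
    path = Path(path)
    rows: list[tuple[str, str | None, str | None, str]] = []
    if dialect == "linkage":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            ind, s, d = parts[:3]
            sx = parts[3] if len(parts) > 3 else "0"
            rows.append((
                ind,
                None if s == "0" else s,
                None if d == "0" else d,
                _parse_sex(sx, f"{path}:{lineno}"),
            ))
    elif dialect == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        needed = {"id", "sire", "dam"}
        if not needed <= set(df.columns):
            raise FormatError(f"{path}: csv pedigree needs columns {needed}")
        for _, r in df.iterrows():
            rows.append((
                r["id"],
                r["sire"] or None,
                r["dam"] or None,
                _parse_sex(r.get("sex", ""), path),
            ))
    else:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    if not rows:
        raise FormatError(f"{path}: empty pedigree")
    return _build_pedigree(rows)


def _parse_sex(code: str, where: object) -> str:
    try:
        return _SEX_IN[str(code).strip().lower()]
    except KeyError:
        raise FormatError(f"{where}: unrecognised sex code {code!r}") from None


def write_pedigree(ped: Pedigree, path: str | Path,
                   dialect: str = "linkage") -> None:
    path = Path(path)
    if dialect == "linkage":
        lines = []
        for ind in ped.individuals:
            lines.append(" ".join([
                ind,
                ped.sire[ind] or "0",
                ped.dam[ind] or "0",
                _SEX_OUT[ped.sex[ind]],
            ]))
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "csv":
        ped.to_dataframe().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x biallelic markers with a physical map.

    Genotypes are coded 0 (homozygous reference), 1 (heterozygous),
    2 (homozygous alternate) and -1 (missing).  Within each chromosome the
    markers are sorted by 1-based bp position, strictly increasing.
    """

    samples: list[str]
    marker_ids: list[str]
    chrom: np.ndarray  # dtype=object / str, per marker
    pos: np.ndarray    # int64, 1-based bp
    geno: np.ndarray   # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.samples), len(self.marker_ids)):
            raise FormatError("genotype array shape does not match labels")
        bad = ~np.isin(self.geno, [0, 1, 2, MISSING])
        if bad.any():
            raise FormatError("genotype codes must be in {0,1,2,missing}")
        self._sort_markers()

    def _sort_markers(self) -> None:
        # stable sort by position within chromosome, chromosome blocks kept
        # in first-appearance order
        chrom_order = {c: k for k, c in enumerate(dict.fromkeys(self.chrom))}
        keys = np.array([chrom_order[c] for c in self.chrom])
        order = np.lexsort((self.pos, keys))
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.marker_ids = [self.marker_ids[i] for i in order]
        self.geno = self.geno[:, order]
        for c in chrom_order:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(
                    f"duplicate or non-increasing positions on chromosome {c}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_rate(self) -> float:
        return float(np.mean(self.geno == MISSING))

    def row(self, sample: str) -> np.ndarray:
        return self.geno[self.samples.index(sample)]

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(
            list(keep), list(self.marker_ids), self.chrom.copy(),
            self.pos.copy(), self.geno[idx].copy(),
        )

    def map_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker_ids, "chrom": self.chrom, "pos": self.pos}
        )


def read_genotype_matrix(path: str | Path,
                         dialect: str = "csv_matrix") -> GenotypeMatrix:
    """Read a genotype matrix.

    ``csv_matrix``: one CSV; first column ``sample``, remaining header cells
    ``marker:chrom:pos``, values 0/1/2/NA.  ``plink_ped_map``: *path* is the
    .ped file (or prefix); the .map file sits alongside.  PLINK alleles may
    be letters or 1/2; the first-seen allele per marker is taken as the
    reference, and a "0" allele makes the genotype missing.
    """
    path = Path(path)
    if dialect == "csv_matrix":
        return _read_csv_matrix(path)
    if dialect == "plink_ped_map":
        return _read_plink(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_csv_matrix(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "sample":
        raise FormatError(f"{path}: first column must be 'sample'")
    marker_ids, chroms, poss = [], [], []
    for col in df.columns[1:]:
        try:
            mid, c, p = col.rsplit(":", 2)
            poss.append(int(p))
        except ValueError:
            raise FormatError(
                f"{path}: marker header {col!r} is not 'marker:chrom:pos'"
            ) from None
        marker_ids.append(mid)
        chroms.append(c)
    codes = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING}
    geno = np.empty((len(df), len(marker_ids)), dtype=np.int8)
    for j, col in enumerate(df.columns[1:]):
        for i, v in enumerate(df[col]):
            try:
                geno[i, j] = codes[v.strip()]
            except KeyError:
                raise FormatError(
                    f"{path}: bad genotype code {v!r} in column {col}"
                ) from None
    return GenotypeMatrix(list(df["sample"]), marker_ids,
                          np.array(chroms, dtype=object),
                          np.array(poss), geno)


def _read_plink(path: Path) -> GenotypeMatrix:
    if path.suffix == ".ped":
        ped_path, map_path = path, path.with_suffix(".map")
    else:
        ped_path = path.with_suffix(".ped")
        map_path = path.with_suffix(".map")
    marker_ids, chroms, poss = [], [], []
    for lineno, line in enumerate(map_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{map_path}:{lineno}: expected 4 columns")
        chroms.append(parts[0])
        marker_ids.append(parts[1])
        try:
            poss.append(int(parts[3]))
        except ValueError:
            raise FormatError(
                f"{map_path}:{lineno}: non-numeric position {parts[3]!r}"
            ) from None
    n_markers = len(marker_ids)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    ref_allele: list[str | None] = [None] * n_markers
    for lineno, line in enumerate(ped_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_markers:
            raise FormatError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields "
                f"for {n_markers} markers, got {len(parts)}"
            )
        samples.append(parts[1])
        row = np.empty(n_markers, dtype=np.int8)
        for m in range(n_markers):
            a1, a2 = parts[6 + 2 * m], parts[7 + 2 * m]
            if a1 == "0" or a2 == "0":
                row[m] = MISSING
                continue
            for a in (a1, a2):
                if ref_allele[m] is None:
                    ref_allele[m] = a
            row[m] = (a1 != ref_allele[m]) + (a2 != ref_allele[m])
        rows.append(row)
    if not rows:
        raise FormatError(f"{ped_path}: no samples")
    return GenotypeMatrix(samples, marker_ids,
                          np.array(chroms, dtype=object),
                          np.array(poss), np.vstack(rows))


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path,
                          dialect: str = "csv_matrix") -> None:
    path = Path(path)
    if dialect == "csv_matrix":
        header = ["sample"] + [
            f"{m}:{c}:{p}"
            for m, c, p in zip(gm.marker_ids, gm.chrom, gm.pos)
        ]
        out = {"NA": "NA"}
        lines = [",".join(header)]
        code = {0: "0", 1: "1", 2: "2", MISSING: "NA"}
        for i, s in enumerate(gm.samples):
            lines.append(",".join([s] + [code[int(g)] for g in gm.geno[i]]))
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "plink_ped_map":
        if path.suffix == ".ped":
            ped_path, map_path = path, path.with_suffix(".map")
        else:
            ped_path = path.with_suffix(".ped")
            map_path = path.with_suffix(".map")
        map_lines = [
            f"{c}\t{m}\t0\t{p}"
            for m, c, p in zip(gm.marker_ids, gm.chrom, gm.pos)
        ]
        map_path.write_text("\n".join(map_lines) + "\n")
        # reference allele written as A, alternate as B
        pairs = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"),
                 MISSING: ("0", "0")}
        ped_lines = []
        for i, s in enumerate(gm.samples):
            fields = ["FAM", s, "0", "0", "0", "-9"]
            for g in gm.geno[i]:
                fields.extend(pairs[int(g)])
            ped_lines.append(" ".join(fields))
        ped_path.write_text("\n".join(ped_lines) + "\n")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# qPCR table
# ---------------------------------------------------------------------------

@dataclass
class QpcrTable:
    """Long-format quantification-cycle table.

    Columns: sample, target, replicate, cq, dilution.  A NaN cq marks an
    undetermined reaction (no amplification within the run).  Dilution is
    the relative template input (1.0 when undiluted).
    """

    data: pd.DataFrame

    REQUIRED = ("sample", "target", "replicate", "cq")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"qPCR table missing column {col!r}")
        if "dilution" not in df.columns:
            df["dilution"] = 1.0
        df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
        df["dilution"] = pd.to_numeric(df["dilution"])
        bad = df.index[df["cq"] < 0].tolist()
        if bad:
            raise FormatError(f"negative Cq in rows {bad}")
        bad = df.index[~(df["dilution"] > 0)].tolist()
        if bad:
            raise FormatError(f"non-positive dilution in rows {bad}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def mean_cq(self) -> pd.DataFrame:
        """Replicate-mean Cq (and sd, n) per sample x target x dilution."""
        g = self.data.groupby(["sample", "target", "dilution"])["cq"]
        out = g.agg(cq_mean="mean", cq_sd="std", n="size").reset_index()
        return out


def read_qpcr_table(path: str | Path) -> QpcrTable:
    df = pd.read_csv(path)
    return QpcrTable(df)


def write_qpcr_table(table: QpcrTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

VALID_GENOTYPES = ("AA", "AG", "GG")
VALID_STATUS = ("alive", "dead", "culled")


@dataclass
class CohortTable:
    """Prospective-cohort data: one calf-level table and one longitudinal
    measurement table.

    ``calves``: calf, genotype (AA/AG/GG), birth_date, status
    (alive/dead/culled), event_age_days (age at death/culling, or last
    follow-up age for alive animals).
    ``measures``: calf, age_days, weight_kg, height_cm — sorted by age
    within calf.
    """

    calves: pd.DataFrame
    measures: pd.DataFrame

    def __post_init__(self) -> None:
        calves = self.calves.copy()
        for col in ("calf", "genotype", "status", "event_age_days"):
            if col not in calves.columns:
                raise FormatError(f"cohort table missing column {col!r}")
        bad = calves.index[~calves["genotype"].isin(VALID_GENOTYPES)].tolist()
        if bad:
            raise FormatError(f"invalid or missing genotype in rows {bad}")
        bad = calves.index[~calves["status"].isin(VALID_STATUS)].tolist()
        if bad:
            raise FormatError(f"invalid status in rows {bad}")
        calves["event_age_days"] = pd.to_numeric(calves["event_age_days"])
        bad = calves.index[calves["event_age_days"] < 0].tolist()
        if bad:
            raise FormatError(f"negative event age in rows {bad}")
        if calves["calf"].duplicated().any():
            raise FormatError("duplicate calf ids in cohort table")
        measures = self.measures.copy()
        for col in ("calf", "age_days"):
            if col not in measures.columns:
                raise FormatError(f"measures table missing column {col!r}")
        measures["age_days"] = pd.to_numeric(measures["age_days"])
        bad = measures.index[measures["age_days"] < 0].tolist()
        if bad:
            raise FormatError(f"negative measurement age in rows {bad}")
        unknown = set(measures["calf"]) - set(calves["calf"])
        if unknown:
            raise FormatError(f"measures reference unknown calves {unknown}")
        measures = measures.sort_values(["calf", "age_days"],
                                        kind="stable").reset_index(drop=True)
        self.calves = calves.reset_index(drop=True)
        self.measures = measures

    @property
    def n_calves(self) -> int:
        return len(self.calves)

    def genotype_counts(self) -> dict[str, int]:
        counts = self.calves["genotype"].value_counts()
        return {g: int(counts.get(g, 0)) for g in VALID_GENOTYPES}

    def event_counts(self) -> dict[str, int]:
        """Dead-or-culled events per genotype class."""
        dead = self.calves[self.calves["status"].isin(("dead", "culled"))]
        counts = dead["genotype"].value_counts()
        return {g: int(counts.get(g, 0)) for g in VALID_GENOTYPES}


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read a tidy cohort CSV.

    The file is long-format: calf-level columns (genotype, birth_date,
    status, event_age_days) are repeated on every measurement row; rows with
    empty age_days carry calf-level data only.
    """
    df = pd.read_csv(path)
    calf_cols = ["calf", "genotype", "status", "event_age_days"]
    if "birth_date" in df.columns:
        calf_cols.insert(2, "birth_date")
    calves = df[calf_cols].drop_duplicates("calf")
    has_measure = df["age_days"].notna() if "age_days" in df.columns else (
        pd.Series(False, index=df.index))
    mcols = [c for c in ("calf", "age_days", "weight_kg", "height_cm")
             if c in df.columns]
    measures = df.loc[has_measure, mcols]
    return CohortTable(calves, measures)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    merged = table.measures.merge(table.calves, on="calf", how="right")
    front = [c for c in ("calf", "genotype", "birth_date", "status",
                         "event_age_days") if c in merged.columns]
    rest = [c for c in merged.columns if c not in front]
    merged[front + rest].to_csv(path, index=False)
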