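"""Format round trips and validation for pedigree/genotype/qPCR/cohort I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stuntscan import pedio, simdata
from stuntscan.pedio import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    PedigreeError,
    QpcrTable,
)


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

class TestPedigreeIO:
    def test_trio_linkage(self, tmp_path):
        f = tmp_path / "trio.ped"
        f.write_text("A 0 0 1\nB 0 0 2\nC A B 1\n")
        ped = pedio.read_pedigree(f)
        assert len(ped.individuals) == 3
        assert sorted(ped.founders) == ["A", "B"]
        assert ped.parents("C") == ("A", "B")

    def test_self_ancestry_is_a_cycle(self, tmp_path):
        f = tmp_path / "bad.ped"
        f.write_text("X X 0 1\n")
        with pytest.raises(PedigreeError, match="cycle"):
            pedio.read_pedigree(f)

    def test_two_step_cycle(self, tmp_path):
        f = tmp_path / "bad.ped"
        f.write_text("X Y 0 1\nY X 0 1\n")
        with pytest.raises(PedigreeError):
            pedio.read_pedigree(f)

    def test_duplicate_id_rejected(self, tmp_path):
        f = tmp_path / "dup.ped"
        f.write_text("A 0 0 1\nA 0 0 1\n")
        with pytest.raises(PedigreeError, match="duplicate"):
            pedio.read_pedigree(f)

    def test_unlisted_parent_becomes_founder(self, tmp_path):
        """Founder count agrees with an independent minimal re-parse."""
        text = "C S D 1\nD 0 0 2\n"
        f = tmp_path / "p.ped"
        f.write_text(text)
        ped = pedio.read_pedigree(f)
        assert "S" in ped.individuals
        assert ped.is_founder("S")
        assert ped.sex["S"] == "male"

        # brute-force reference parse: founders = ids that never appear as a
        # child with a named parent, including parent-only mentions
        mentioned, child_with_parents = set(), set()
        for line in text.splitlines():
            ind, s, d, *_ = line.split()
            mentioned.add(ind)
            for p in (s, d):
                if p != "0":
                    mentioned.add(p)
            if s != "0" or d != "0":
                child_with_parents.add(ind)
        assert len(ped.founders) == len(mentioned - child_with_parents)

    def test_sire_dam_role_conflict(self, tmp_path):
        f = tmp_path / "p.ped"
        f.write_text("A 0 0 1\nB A 0 1\nC 0 A 2\n")
        with pytest.raises(PedigreeError, match="sire and as dam"):
            pedio.read_pedigree(f)

    @pytest.mark.parametrize("dialect", ["linkage", "csv"])
    def test_round_trip(self, tmp_path, dialect, fixture_f1):
        path = tmp_path / f"rt.{dialect}"
        pedio.write_pedigree(fixture_f1, path, dialect=dialect)
        back = pedio.read_pedigree(path, dialect=dialect)
        assert back.individuals == fixture_f1.individuals
        assert back.sire == fixture_f1.sire
        assert back.dam == fixture_f1.dam
        assert back.sex == fixture_f1.sex

    @pytest.mark.parametrize("seed", range(5))
    def test_accepts_simulated_rejects_cycled(self, seed):
        cfg = simdata.SimConfig(seed=seed, n_founders=8, n_generations=3)
        ped = simdata.simulate_pedigree(cfg)
        ped.validate()  # simulated pedigrees always validate
        # rerouting a founder to descend from a terminal individual
        # creates a cycle and must be rejected
        founder = next(f for f in ped.founders if ped.descendants(f))
        leaf = sorted(ped.descendants(founder))[-1]
        sire, dam = dict(ped.sire), dict(ped.dam)
        if ped.sex[leaf] == "male":
            sire[founder] = leaf
        else:
            dam[founder] = leaf
        with pytest.raises(PedigreeError, match="cycle"):
            pedio.Pedigree(list(ped.individuals), sire, dam, dict(ped.sex))


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def random_matrix(rng, n_samples=5, n_markers=20) -> GenotypeMatrix:
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_markers,
                             replace=False))
    geno = rng.integers(0, 3, size=(n_samples, n_markers)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.05] = MISSING
    return GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)],
        [f"m{j}" for j in range(n_markers)],
        np.array(["3"] * n_markers, dtype=object), pos, geno,
    )


class TestGenotypeIO:
    def test_csv_matrix_toy(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text(
            "sample,m1:1:100,m2:1:200,m3:1:300\n"
            "s1,0,1,2\n"
            "s2,2,0,1\n"
        )
        gm = pedio.read_genotype_matrix(f)
        assert (gm.n_samples, gm.n_markers) == (2, 3)
        assert gm.missing_rate == 0.0
        assert list(gm.row("s2")) == [2, 0, 1]

    def test_plink_zero_allele_is_missing(self, tmp_path):
        (tmp_path / "g.map").write_text("1\tm1\t0\t100\n1\tm2\t0\t200\n")
        (tmp_path / "g.ped").write_text(
            "F s1 0 0 1 -9 A A 0 0\n"
            "F s2 0 0 1 -9 A G G G\n"
        )
        gm = pedio.read_genotype_matrix(tmp_path / "g.ped",
                                        dialect="plink_ped_map")
        assert gm.row("s1")[1] == MISSING
        # first-seen allele per marker is the reference: A at marker 1,
        # G at marker 2 (s1 is missing there), so "G G" is hom-reference
        assert list(gm.row("s2")) == [1, 0]

    def test_plink_inconsistent_marker_count(self, tmp_path):
        (tmp_path / "g.map").write_text("1\tm1\t0\t100\n1\tm2\t0\t200\n")
        (tmp_path / "g.ped").write_text("F s1 0 0 1 -9 A A\n")
        with pytest.raises(FormatError, match="expected 10 fields"):
            pedio.read_genotype_matrix(tmp_path / "g.ped",
                                       dialect="plink_ped_map")

    def test_non_numeric_position(self, tmp_path):
        (tmp_path / "g.map").write_text("1\tm1\t0\tabc\n")
        with pytest.raises(FormatError, match="non-numeric position"):
            pedio.read_genotype_matrix(tmp_path / "g.ped",
                                       dialect="plink_ped_map")

    def test_round_trip_random_matrix_csv(self, tmp_path):
        rng = np.random.default_rng(1)
        gm = random_matrix(rng)
        path = tmp_path / "rt.csv"
        pedio.write_genotype_matrix(gm, path, dialect="csv_matrix")
        back = pedio.read_genotype_matrix(path, dialect="csv_matrix")
        assert back.samples == gm.samples
        np.testing.assert_array_equal(back.pos, gm.pos)
        np.testing.assert_array_equal(back.geno, gm.geno)

    def test_round_trip_random_matrix_plink(self, tmp_path):
        """PLINK round trip is identity up to reference-allele polarity:
        under the first-seen-allele convention a marker whose first
        non-missing call is alternate-homozygous reads back flipped."""
        rng = np.random.default_rng(1)
        gm = random_matrix(rng)
        path = tmp_path / "rt.ped"
        pedio.write_genotype_matrix(gm, path, dialect="plink_ped_map")
        back = pedio.read_genotype_matrix(path, dialect="plink_ped_map")
        assert back.samples == gm.samples
        np.testing.assert_array_equal(back.pos, gm.pos)
        for j in range(gm.n_markers):
            col = gm.geno[:, j]
            non_missing = col[col != MISSING]
            expected = col.copy()
            if len(non_missing) and non_missing[0] == 2:
                flip = expected != MISSING
                expected[flip] = 2 - expected[flip]
            np.testing.assert_array_equal(back.geno[:, j], expected)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(FormatError, match="non-increasing"):
            GenotypeMatrix(
                ["s"], ["a", "b"], np.array(["1", "1"], dtype=object),
                np.array([100, 100]), np.zeros((1, 2), dtype=np.int8),
            )


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

class TestQpcr:
    def test_triplicate_layout(self, tmp_path):
        rows = [
            {"sample": s, "target": t, "replicate": r, "cq": 25.0}
            for s in ("a", "b") for t in ("g1", "g2") for r in (1, 2, 3)
        ]
        f = tmp_path / "cq.csv"
        pd.DataFrame(rows).to_csv(f, index=False)
        table = pedio.read_qpcr_table(f)
        assert len(table) == 12
        assert (table.mean_cq()["n"] == 3).all()

    def test_negative_cq_rejected(self):
        df = pd.DataFrame([{"sample": "a", "target": "g", "replicate": 1,
                            "cq": -1.0}])
        with pytest.raises(FormatError, match="negative Cq"):
            QpcrTable(df)

    def test_round_trip(self, tmp_path):
        table = simdata.simulate_qpcr(0.8, 0.2, 0.5, noise_sd=0.1, seed=4)
        path = tmp_path / "cq.csv"
        pedio.write_qpcr_table(table, path)
        back = pedio.read_qpcr_table(path)
        pd.testing.assert_frame_equal(back.data, table.data)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

class TestCohort:
    def test_simulated_cohort_round_trip(self, tmp_path):
        dosages = simdata.mendelian_carrier_cross_dosages(105, seed=7)
        cohort = simdata.simulate_cohort(dosages, simdata.OutcomeModel(),
                                         seed=7)
        path = tmp_path / "cohort.csv"
        pedio.write_cohort_table(cohort, path)
        back = pedio.read_cohort_table(path)
        assert back.n_calves == 105
        assert sum(back.genotype_counts().values()) == 105
        assert back.genotype_counts() == cohort.genotype_counts()
        pd.testing.assert_frame_equal(
            back.measures.reset_index(drop=True),
            cohort.measures.reset_index(drop=True), check_like=True)

    def test_negative_event_age_rejected(self):
        calves = pd.DataFrame([{"calf": "c1", "genotype": "AA",
                                "status": "alive",
                                "event_age_days": -3.0}])
        with pytest.raises(FormatError, match="negative event age"):
            pedio.CohortTable(calves, pd.DataFrame(
                {"calf": [], "age_days": []}))

    def test_missing_genotype_rejected(self):
        calves = pd.DataFrame([{"calf": "c1", "genotype": "??",
                                "status": "alive",
                                "event_age_days": 0.0}])
        with pytest.raises(FormatError, match="genotype"):
            pedio.CohortTable(calves, pd.DataFrame(
                {"calf": [], "age_days": []}))

    def test_measures_sorted_by_age(self):
        calves = pd.DataFrame([{"calf": "c1", "genotype": "AA",
                                "status": "alive",
                                "event_age_days": 365.0}])
        measures = pd.DataFrame({
            "calf": ["c1", "c1"], "age_days": [60.0, 30.0],
            "weight_kg": [90.0, 75.0],
        })
        table = pedio.CohortTable(calves, measures)
        assert list(table.measures["age_days"]) == [30.0, 60.0]
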