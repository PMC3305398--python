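"""Shared fixtures: the F1 oracle pedigree and study-scale sim configs."""

from __future__ import annotations

import numpy as np
import pytest

from stuntscan import simdata
from stuntscan.pedio import Pedigree


@pytest.fixture
def fixture_f1() -> Pedigree:
    """12-individual, 4-generation pedigree without inbreeding loops.

    Sized so that exact gene-drop enumeration sits exactly at the
    22-random-transmission bound when q0 > 0 (6 non-founder meiosis pairs
    + 5 stochastic founders).  The loop-free structure keeps the marginal
    transmission recursion an exact oracle for the mean carrier count.
    """
    return Pedigree(
        individuals=["M0", "W0", "M1", "W1", "W2", "M2",
                     "A", "B", "C", "D", "E", "F"],
        sire={"M0": None, "W0": None, "M1": None, "W1": None, "W2": None,
              "M2": None, "A": "M0", "B": "M0", "C": "A", "D": "M1",
              "E": "M2", "F": "C"},
        dam={"M0": None, "W0": None, "M1": None, "W1": None, "W2": None,
             "M2": None, "A": "W0", "B": "W0", "C": "W1", "D": "B",
             "E": "D", "F": "W2"},
        sex={"M0": "male", "W0": "female", "M1": "male", "W1": "female",
             "W2": "female", "M2": "male", "A": "male", "B": "female",
             "C": "male", "D": "female", "E": "male", "F": "female"},
    )


F1_TARGET = ("C", "D", "E", "F")


def study_config(seed: int, **overrides) -> simdata.SimConfig:
    """Study-scale generator settings: a six-generation genealogy with
    AI-sire mating concentration and a 30% outside-lineage mutant
    haplotype frequency, which makes affected homozygotes appear at a
    rate comparable to the mapped field population."""
    base = dict(
        q0=0.3, n_founders=10, n_generations=6, mean_offspring=2.5,
        ai_sire_fraction=0.15, ai_mating_share=0.9, seed=seed,
    )
    base.update(overrides)
    return simdata.SimConfig(**base)


@pytest.fixture(scope="session")
def case_study():
    """One realisation with >= 14 affected homozygotes (seed 9)."""
    cfg = study_config(9, n_founders=8)
    ped = simdata.simulate_pedigree(cfg)
    gm, truth = simdata.drop_haplotypes(ped, cfg)
    cases = truth.loc[truth["dosage"] == 2, "id"].tolist()
    assert len(cases) >= 14
    return cfg, ped, gm, truth, cases


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
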