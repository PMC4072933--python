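import numpy as np
import pandas as pd
import pytest

import methfam as mf


@pytest.fixture(scope="session")
def ped117():
    """Study-design-scale cohort: 117 twin families, ~614 individuals."""
    return mf.generate_pedigree(117, seed=11)


@pytest.fixture(scope="session")
def kin117(ped117):
    return mf.additive_relationship(ped117)


@pytest.fixture(scope="session")
def sheet117(ped117):
    return mf.generate_sample_sheet(ped117, seed=12)


@pytest.fixture(scope="session")
def null_screen(ped117, kin117, sheet117):
    """AE screen of 4,000 probes simulated with Va = Vf = 0, Ve = 1.

    Shared by the boundary-fraction and LRT-calibration checks.
    """
    probes = mf.uniform_probes(4000, va=0.0, vf=0.0, ve=1.0)
    sim = mf.simulate_methylation(ped117, sheet117, probes, seed=13)
    resid = mf.logit_values(sim.beta)
    return mf.heritability_screen(resid, kin117, model="AE")


@pytest.fixture
def toy_family():
    """One hand-built family: two parents, an MZ pair and one sibling."""
    return pd.DataFrame(
        {
            "individual_id": ["dad", "mum", "tw1", "tw2", "sib"],
            "family_id": ["fam1"] * 5,
            "father_id": [None, None, "dad", "dad", "dad"],
            "mother_id": [None, None, "mum", "mum", "mum"],
            "sex": ["male", "female", "female", "female", "male"],
            "age": [45.0, 43.0, 14.0, 14.0, 17.0],
            "zygosity": ["none", "none", "MZ_twin", "MZ_twin", "none"],
            "twin_pair_id": [None, None, "tw", "tw", None],
        }
    )


@pytest.fixture
def three_gen_ped():
    """Three-generation pedigree: grandparents, two sibling parents married
    into the family, children including first cousins."""
    rows = [
        # id, fam, father, mother, sex, age, zyg, pair
        ("gpa", "fam1", None, None, "male", 75.0, "none", None),
        ("gma", "fam1", None, None, "female", 73.0, "none", None),
        ("dad1", "fam1", "gpa", "gma", "male", 48.0, "none", None),
        ("dad2", "fam1", "gpa", "gma", "male", 45.0, "none", None),
        ("mum1", "fam1", None, None, "female", 47.0, "none", None),
        ("mum2", "fam1", None, None, "female", 44.0, "none", None),
        ("kid1", "fam1", "dad1", "mum1", "female", 15.0, "none", None),
        ("kid2", "fam1", "dad1", "mum1", "male", 13.0, "none", None),
        ("kid3", "fam1", "dad2", "mum2", "female", 12.0, "none", None),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "family_id", "father_id", "mother_id", "sex",
            "age", "zygosity", "twin_pair_id",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
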