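"""Twin-family pedigrees and relationship matrices.

A pedigree is a :class:`pandas.DataFrame` with one row per individual and
columns ``individual_id``, ``family_id``, ``father_id``, ``mother_id``
(``None`` for founders), ``sex`` (``"male"``/``"female"``), ``age`` (years),
``zygosity`` (``"MZ_twin"``/``"DZ_twin"``/``"none"``) and ``twin_pair_id``
(shared label for the two members of a twin pair, ``None`` otherwise).

The study design emulated by :func:`generate_pedigree` is a cohort of
nuclear families each consisting of two parents, one adolescent twin pair
(MZ or DZ) and a variable number of additional full siblings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PED_COLUMNS = [
    "individual_id",
    "family_id",
    "father_id",
    "mother_id",
    "sex",
    "age",
    "zygosity",
    "twin_pair_id",
]

#: Default family composition. Zygosity follows the study's MZ:DZ pair ratio
#: (67:111); the sibling-count distribution has mean 1.25 extra siblings so the
#: expected cohort size at 117 families is ~614 individuals.
DEFAULT_FAMILY_SPEC = {
    "n_extra_sibs": {0: 0.25, 1: 0.35, 2: 0.30, 3: 0.10},
    "twin_zygosity": {"MZ": 67.0 / 178.0, "DZ": 111.0 / 178.0},
}

# Adolescent-cohort age ranges (years).
PARENT_AGE_RANGE = (35.0, 55.0)
OFFSPRING_AGE_RANGE = (10.0, 20.0)


def _check_distribution(dist: dict, name: str) -> None:
    probs = np.asarray(list(dist.values()), dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"family_spec[{name!r}] probabilities must be non-negative and sum "
            f"to 1 (got sum {probs.sum():.6g})"
        )


def generate_pedigree(
    n_families: int,
    family_spec: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a twin-family cohort pedigree.

    Each family has two founders (one male, one female) and at least two
    children including exactly one twin pair; MZ co-twins share sex and age,
    DZ co-twins share age. Deterministic given ``seed``.

    Parameters
    ----------
    n_families:
        Number of nuclear families (>= 1).
    family_spec:
        Mapping with keys ``"n_extra_sibs"`` (distribution over additional
        sibling counts) and ``"twin_zygosity"`` (distribution over
        ``{"MZ", "DZ"}``). Defaults to :data:`DEFAULT_FAMILY_SPEC`.
    seed:
        Seed for the random generator.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    spec = dict(DEFAULT_FAMILY_SPEC)
    if family_spec is not None:
        spec.update(family_spec)
    _check_distribution(spec["n_extra_sibs"], "n_extra_sibs")
    _check_distribution(spec["twin_zygosity"], "twin_zygosity")

    rng = np.random.default_rng(seed)
    sib_counts = np.asarray(list(spec["n_extra_sibs"].keys()))
    sib_probs = np.asarray(list(spec["n_extra_sibs"].values()), dtype=float)
    zyg_labels = list(spec["twin_zygosity"].keys())
    zyg_probs = np.asarray(list(spec["twin_zygosity"].values()), dtype=float)

    rows = []
    for f in range(n_families):
        fam = f"F{f + 1:04d}"
        father = f"{fam}-01"
        mother = f"{fam}-02"
        rows.append((father, fam, None, None, "male",
                     rng.uniform(*PARENT_AGE_RANGE), "none", None))
        rows.append((mother, fam, None, None, "female",
                     rng.uniform(*PARENT_AGE_RANGE), "none", None))

        zygosity = zyg_labels[rng.choice(len(zyg_labels), p=zyg_probs)]
        twin_age = rng.uniform(*OFFSPRING_AGE_RANGE)
        pair_id = f"{fam}-TW"
        if zygosity == "MZ":
            sexes = [rng.choice(["male", "female"])] * 2
        else:
            sexes = list(rng.choice(["male", "female"], size=2))
        for t in range(2):
            rows.append((f"{fam}-{3 + t:02d}", fam, father, mother, sexes[t],
                         twin_age, f"{zygosity}_twin", pair_id))

        n_sibs = int(sib_counts[rng.choice(len(sib_counts), p=sib_probs)])
        for s in range(n_sibs):
            rows.append((f"{fam}-{5 + s:02d}", fam, father, mother,
                         rng.choice(["male", "female"]),
                         rng.uniform(*OFFSPRING_AGE_RANGE), "none", None))

    ped = pd.DataFrame(rows, columns=PED_COLUMNS)
    validate_pedigree(ped)
    return ped


def founders(ped: pd.DataFrame) -> pd.Series:
    """Boolean mask of founders (both parents missing)."""
    return ped["father_id"].isna() & ped["mother_id"].isna()


def topological_order(ped: pd.DataFrame) -> list[int]:
    """Row indices ordered so every parent precedes its children.

    Raises ``ValueError`` for cyclic pedigrees (an individual being its own
    ancestor).
    """
    ids = ped["individual_id"].tolist()
    pos = {iid: i for i, iid in enumerate(ids)}
    placed: set[str] = set()
    order: list[int] = []
    remaining = list(range(len(ped)))
    father = ped["father_id"].tolist()
    mother = ped["mother_id"].tolist()
    while remaining:
        progress = []
        for i in remaining:
            f, m = father[i], mother[i]
            ok_f = pd.isna(f) or f in placed
            ok_m = pd.isna(m) or m in placed
            if ok_f and ok_m:
                progress.append(i)
        if not progress:
            raise ValueError("pedigree contains a cycle (individual is its own ancestor)")
        for i in progress:
            order.append(i)
            placed.add(ids[i])
            remaining.remove(i)
    del pos
    return order


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Check pedigree invariants; raise ``ValueError`` on violation."""
    missing = [c for c in PED_COLUMNS if c not in ped.columns]
    if missing:
        raise ValueError(f"pedigree missing columns: {missing}")
    if ped["individual_id"].duplicated().any():
        raise ValueError("duplicate individual_id in pedigree")
    fam_of = dict(zip(ped["individual_id"], ped["family_id"]))
    for col in ("father_id", "mother_id"):
        for iid, parent, fam in zip(ped["individual_id"], ped[col], ped["family_id"]):
            if pd.isna(parent):
                continue
            if parent not in fam_of:
                raise ValueError(f"{col} {parent!r} of {iid!r} not in pedigree")
            if fam_of[parent] != fam:
                raise ValueError(f"{col} {parent!r} of {iid!r} is in a different family")
    topological_order(ped)  # raises on cycles

    # Twin-pair consistency.
    twins = ped[ped["twin_pair_id"].notna()]
    for pair_id, grp in twins.groupby("twin_pair_id"):
        if len(grp) != 2:
            raise ValueError(f"twin pair {pair_id!r} does not have exactly 2 members")
        a, b = grp.iloc[0], grp.iloc[1]
        if (a["father_id"], a["mother_id"]) != (b["father_id"], b["mother_id"]):
            raise ValueError(f"twin pair {pair_id!r} members have different parents")
        if a["age"] != b["age"]:
            raise ValueError(f"twin pair {pair_id!r} members differ in age")
        if a["zygosity"] == "MZ_twin" and a["sex"] != b["sex"]:
            raise ValueError(f"MZ pair {pair_id!r} members differ in sex")


def mz_pairs(ped: pd.DataFrame) -> list[tuple[str, str]]:
    """(id_a, id_b) tuples for each MZ twin pair."""
    out = []
    mz = ped[ped["zygosity"] == "MZ_twin"]
    for _, grp in mz.groupby("twin_pair_id"):
        ids = sorted(grp["individual_id"])
        if len(ids) == 2:
            out.append((ids[0], ids[1]))
    return out


@dataclass
class KinshipMatrix:
    """Additive relationship matrix ``A`` (= 2x kinship; MZ entries 1) and
    nuclear-household indicator ``H``, both indexed by individual id."""

    A: pd.DataFrame
    H: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.A.index)


def additive_relationship(ped: pd.DataFrame, household: str = "family") -> KinshipMatrix:
    """Compute the additive relationship and household matrices of a pedigree.

    ``A`` is built with the tabular method (founders assumed unrelated and
    non-inbred), after which MZ co-twin entries are overwritten with 1.
    ``H`` marks shared nuclear households: with ``household="family"`` the
    whole nuclear family (parents included) shares a household; with
    ``household="offspring"`` only the children do.
    """
    if household not in ("family", "offspring"):
        raise ValueError("household must be 'family' or 'offspring'")
    validate_pedigree(ped)
    ids = ped["individual_id"].tolist()
    idx = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    father = ped["father_id"].tolist()
    mother = ped["mother_id"].tolist()

    placed = np.zeros(n, dtype=bool)
    for i in topological_order(ped):
        f, m = father[i], mother[i]
        fi = idx[f] if not pd.isna(f) else None
        mi = idx[m] if not pd.isna(m) else None
        row = np.zeros(n)
        if fi is not None:
            row += 0.5 * A[fi]
        if mi is not None:
            row += 0.5 * A[mi]
        row[~placed] = 0.0
        A[i, :] = row
        A[:, i] = row
        if fi is not None and mi is not None:
            A[i, i] = 1.0 + 0.5 * A[fi, mi]
        else:
            A[i, i] = 1.0
        placed[i] = True

    for a, b in mz_pairs(ped):
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0

    fam = ped["family_id"].to_numpy()
    H = (fam[:, None] == fam[None, :]).astype(float)
    if household == "offspring":
        is_founder = founders(ped).to_numpy()
        H[is_founder, :] = 0.0
        H[:, is_founder] = 0.0
        np.fill_diagonal(H, 1.0)

    A_df = pd.DataFrame(A, index=ids, columns=ids)
    H_df = pd.DataFrame(H, index=ids, columns=ids)
    return KinshipMatrix(A=A_df, H=H_df)
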