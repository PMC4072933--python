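"""Generative model for family methylation data with known variance components.

Each probe has a latent trait on the logit (log-odds) scale,

    l = b0 + covariate effects + mqtl_beta * dosage + a + f + e,

where ``a`` is the additive-genetic value (covariance Va * A over the
pedigree, A the additive relationship matrix with MZ entries 1), ``f`` is a
nuclear-family common-environment value shared by all family members
(variance Vf), and ``e`` is independent residual noise (variance Ve).
Observed methylation is ``beta = expit(l)``; Type II probes are additionally
compressed linearly toward 0.5 emulating the reduced dynamic range of that
assay chemistry. The generative heritability of a probe is
``h2 = Va / (Va + Vf + Ve)`` on the latent scale.

The additive values are produced by gene-dropping rather than a joint
multivariate-normal draw: founders get N(0, Va), each child receives the
parental midvalue plus an independent Mendelian-segregation deviate
N(0, Va/2), and MZ co-twins share the whole additive value. For non-inbred
pedigrees with unrelated founders this reproduces cov(a) = Va * A exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotypes import GenotypeMatrix
from .pedigree import founders, mz_pairs, topological_order, validate_pedigree

CELL_TYPES = ["monocytes", "B_cells", "NK", "CD4_T", "CD8_T", "granulocytes"]

#: Typical mean blood leukocyte composition used for Dirichlet sampling.
CELL_MEANS = {
    "monocytes": 0.08,
    "B_cells": 0.07,
    "NK": 0.07,
    "CD4_T": 0.15,
    "CD8_T": 0.08,
    "granulocytes": 0.55,
}

DENSITY_CLASSES = ["HC", "ICshore", "IC", "LC"]


@dataclass
class ProbeModel:
    """Ground-truth generative parameters for one methylation probe."""

    probe_id: str
    intercept: float = 0.0
    va: float = 0.0
    vf: float = 0.0
    ve: float = 1.0
    mqtl_snp: str | None = None
    mqtl_beta: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    probe_type: str = "I"
    type2_compression: float = 0.2
    cell_signature: dict | None = None
    chromosome: str = "1"
    position: int | None = None
    n_cpg: int = 2
    n_snp: int = 0
    density_class: str = "IC"
    multimap_flag: bool = False

    def __post_init__(self) -> None:
        if min(self.va, self.vf, self.ve) < 0:
            raise ValueError(f"probe {self.probe_id}: variances must be >= 0")
        if self.va + self.vf + self.ve <= 0:
            raise ValueError(f"probe {self.probe_id}: total variance must be > 0")
        if not (0.0 <= self.type2_compression < 1.0):
            raise ValueError(f"probe {self.probe_id}: type2_compression must be in [0,1)")
        if self.probe_type not in ("I", "II"):
            raise ValueError(f"probe {self.probe_id}: probe_type must be 'I' or 'II'")

    @property
    def h2(self) -> float:
        return self.va / (self.va + self.vf + self.ve)

    @property
    def c2(self) -> float:
        return self.vf / (self.va + self.vf + self.ve)


ANNOTATION_COLUMNS = [
    "chromosome",
    "position",
    "probe_type",
    "n_cpg",
    "n_snp",
    "density_class",
    "multimap_flag",
]


@dataclass
class BetaMatrix:
    """Methylation beta values (probes x samples, in [0,1], NaN = missing)
    with per-probe annotation (chromosome, position, probe_type, n_cpg,
    n_snp, density_class, multimap_flag)."""

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if not self.values.index.equals(self.annotation.index):
            raise ValueError("values and annotation must share the same probe index")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def uniform_probes(
    n_probes: int,
    va: float | np.ndarray = 0.0,
    vf: float | np.ndarray = 0.0,
    ve: float | np.ndarray = 1.0,
    prefix: str = "simcg",
    **kwargs,
) -> list[ProbeModel]:
    """Convenience constructor for a batch of probes sharing (or broadcasting)
    variance components; extra keyword arguments pass through to
    :class:`ProbeModel`."""
    va = np.broadcast_to(np.asarray(va, dtype=float), (n_probes,))
    vf = np.broadcast_to(np.asarray(vf, dtype=float), (n_probes,))
    ve = np.broadcast_to(np.asarray(ve, dtype=float), (n_probes,))
    return [
        ProbeModel(
            probe_id=f"{prefix}{k + 1:06d}",
            va=float(va[k]),
            vf=float(vf[k]),
            ve=float(ve[k]),
            **kwargs,
        )
        for k in range(n_probes)
    ]


def generate_sample_sheet(
    ped: pd.DataFrame,
    seed: int = 0,
    samples_per_chip: int = 12,
    with_cell_props: bool = False,
    cell_concentration: float = 200.0,
    cell_family_concentration: float | None = None,
) -> pd.DataFrame:
    """Randomised chip/position assignment (and optional cell composition).

    Samples are shuffled across chips of ``samples_per_chip`` positions so
    batch is not confounded with family, mirroring a randomised array layout.
    Cell proportions, when requested, are Dirichlet draws around typical
    blood leukocyte composition; with ``cell_family_concentration`` set, each
    family first draws a shared Dirichlet mean (blood cell composition is
    itself familial), making cell-signature probes a genuine familial
    confounder of heritability.
    """
    rng = np.random.default_rng(seed)
    ids = ped["individual_id"].tolist()
    order = rng.permutation(len(ids))
    chip = np.empty(len(ids), dtype=object)
    pos = np.empty(len(ids), dtype=object)
    for rank, i in enumerate(order):
        chip[i] = f"chip{rank // samples_per_chip + 1:03d}"
        pos[i] = f"R{rank % samples_per_chip + 1:02d}"
    sheet = pd.DataFrame({"individual_id": ids, "chip": chip, "chip_position": pos})
    if with_cell_props:
        base = np.array([CELL_MEANS[c] for c in CELL_TYPES])
        if cell_family_concentration is None:
            props = rng.dirichlet(cell_concentration * base, size=len(ids))
        else:
            fam_codes, _ = pd.factorize(ped["family_id"])
            fam_means = rng.dirichlet(
                cell_family_concentration * base, size=fam_codes.max() + 1
            )
            props = np.vstack(
                [
                    rng.dirichlet(cell_concentration * fam_means[f])
                    for f in fam_codes
                ]
            )
        for j, c in enumerate(CELL_TYPES):
            sheet[c] = props[:, j]
    return sheet


def _additive_values(
    ped: pd.DataFrame, va: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gene-dropped additive values, shape (n_probes, n_individuals)."""
    ids = ped["individual_id"].tolist()
    idx = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    n_probes = len(va)
    sd = np.sqrt(va)
    a = np.zeros((n_probes, n))
    father = ped["father_id"].tolist()
    mother = ped["mother_id"].tolist()
    twin_of = {}
    for p, q in mz_pairs(ped):
        twin_of[idx[q]] = idx[p]
    for i in topological_order(ped):
        if i in twin_of:
            a[:, i] = a[:, twin_of[i]]
        elif pd.isna(father[i]) and pd.isna(mother[i]):
            a[:, i] = sd * rng.standard_normal(n_probes)
        else:
            mid = 0.5 * (a[:, idx[father[i]]] + a[:, idx[mother[i]]])
            a[:, i] = mid + np.sqrt(va / 2.0) * rng.standard_normal(n_probes)
    return a


@dataclass
class SimulationResult:
    beta: BetaMatrix
    detection_p: pd.DataFrame
    truth: pd.DataFrame


def simulate_methylation(
    ped: pd.DataFrame,
    sheet: pd.DataFrame,
    probes: list[ProbeModel],
    geno: GenotypeMatrix | None = None,
    missing_rate: float = 0.0,
    detect_fail_rate: float = 0.0,
    spouse_var: float = 0.0,
    seed: int = 0,
) -> SimulationResult:
    """Simulate a beta-value matrix, detection p-values and a truth table.

    Parameters
    ----------
    ped, sheet:
        Pedigree and sample sheet; ``sheet`` must cover every individual.
    probes:
        Generative models; any ``mqtl_snp`` must exist in ``geno`` and any
        ``cell_signature`` cell types must be columns of ``sheet``.
    missing_rate, detect_fail_rate:
        Per-entry probabilities of a missing call and of a detection-p
        failure. Passing entries get detection p ~ U(0, 1e-4); failing
        entries ~ U(1e-3, 1).
    spouse_var:
        Optional latent variance shared only by the two founders of each
        family (spouse-correlation knob); default 0.
    """
    validate_pedigree(ped)
    sheet = sheet.set_index("individual_id") if "individual_id" in sheet.columns else sheet
    ids = ped["individual_id"].tolist()
    if not set(ids) <= set(sheet.index):
        raise ValueError("sample sheet does not cover all pedigree individuals")
    sheet = sheet.loc[ids]
    n = len(ids)
    n_probes = len(probes)
    rng = np.random.default_rng(seed)

    va = np.array([p.va for p in probes])
    vf = np.array([p.vf for p in probes])
    ve = np.array([p.ve for p in probes])

    # Sample-level covariate vectors for effect application.
    sex_f = (ped["sex"] == "female").to_numpy(float)
    age = ped["age"].to_numpy(float)
    age_z = (age - age.mean()) / (age.std() if age.std() > 0 else 1.0)
    chip_codes, chip_levels = pd.factorize(sheet["chip"])
    pos_codes, pos_levels = pd.factorize(sheet["chip_position"])

    fam_codes, _ = pd.factorize(ped["family_id"])
    is_founder = founders(ped).to_numpy()

    latent = np.empty((n_probes, n))
    latent[:] = np.array([p.intercept for p in probes])[:, None]

    # Fixed covariate effects: numeric coefficients for sex/age terms,
    # per-level N(0, coef^2) offsets for categorical batch variables.
    numeric = {
        "sex": sex_f,
        "age": age_z,
        "age2": age_z**2,
        "sex_age": sex_f * age_z,
        "sex_age2": sex_f * age_z**2,
    }
    for k, probe in enumerate(probes):
        for name, coef in probe.covariate_effects.items():
            if name in numeric:
                latent[k] += coef * numeric[name]
            elif name == "chip":
                offsets = rng.normal(0.0, abs(coef), size=len(chip_levels))
                latent[k] += offsets[chip_codes]
            elif name == "chip_position":
                offsets = rng.normal(0.0, abs(coef), size=len(pos_levels))
                latent[k] += offsets[pos_codes]
            else:
                raise ValueError(
                    f"probe {probe.probe_id}: unknown covariate {name!r}"
                )
        if probe.mqtl_snp is not None:
            if geno is None or probe.mqtl_snp not in geno.dosage.index:
                raise ValueError(
                    f"probe {probe.probe_id}: mqtl_snp {probe.mqtl_snp!r} not in genotypes"
                )
            dose = geno.dosage.loc[probe.mqtl_snp, ids].to_numpy(float)
            dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
            latent[k] += probe.mqtl_beta * dose
        if probe.cell_signature:
            for cell, offset in probe.cell_signature.items():
                if cell not in sheet.columns:
                    raise ValueError(
                        f"probe {probe.probe_id}: cell type {cell!r} not in sample sheet"
                    )
                latent[k] += offset * sheet[cell].to_numpy(float)

    # Random components.
    latent += _additive_values(ped, va, rng)
    fam_effects = np.sqrt(vf)[:, None] * rng.standard_normal((n_probes, fam_codes.max() + 1))
    latent += fam_effects[:, fam_codes]
    if spouse_var > 0:
        sp = np.sqrt(spouse_var) * rng.standard_normal((n_probes, fam_codes.max() + 1))
        latent += np.where(is_founder[None, :], sp[:, fam_codes], 0.0)
    latent += np.sqrt(ve)[:, None] * rng.standard_normal((n_probes, n))

    beta = expit(latent)
    shrink = np.array(
        [p.type2_compression if p.probe_type == "II" else 0.0 for p in probes]
    )
    beta = 0.5 + (1.0 - shrink[:, None]) * (beta - 0.5)

    # Detection p-values and random missingness.
    detect = rng.uniform(0.0, 1e-4, size=beta.shape)
    if detect_fail_rate > 0:
        fails = rng.random(beta.shape) < detect_fail_rate
        detect[fails] = rng.uniform(1e-3, 1.0, size=int(fails.sum()))
    if missing_rate > 0:
        beta[rng.random(beta.shape) < missing_rate] = np.nan

    probe_ids = [p.probe_id for p in probes]
    values = pd.DataFrame(beta, index=probe_ids, columns=ids)
    detect_df = pd.DataFrame(detect, index=probe_ids, columns=ids)
    annotation = pd.DataFrame(
        {
            "chromosome": [p.chromosome for p in probes],
            "position": [
                p.position if p.position is not None else 1_000_000 + 1000 * k
                for k, p in enumerate(probes)
            ],
            "probe_type": [p.probe_type for p in probes],
            "n_cpg": [p.n_cpg for p in probes],
            "n_snp": [p.n_snp for p in probes],
            "density_class": [p.density_class for p in probes],
            "multimap_flag": [p.multimap_flag for p in probes],
        },
        index=probe_ids,
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "va": va,
            "vf": vf,
            "ve": ve,
            "h2": va / (va + vf + ve),
            "c2": vf / (va + vf + ve),
            "mqtl_snp": [p.mqtl_snp for p in probes],
            "mqtl_beta": [p.mqtl_beta for p in probes],
        }
    ).set_index("probe_id")
    return SimulationResult(
        beta=BetaMatrix(values=values, annotation=annotation),
        detection_p=detect_df,
        truth=truth,
    )
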