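"""Plain-text readers and writers for the pipeline's tables.

Pedigrees are PED-like tab-delimited text (0 = missing parent); genotypes a
dosage TSV with SNP map columns; beta / detection-p / residual matrices are
TSV with probe rows and sample columns, probe annotation a BED-like TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from .normalize import ResidualMatrix
from .simulate import ANNOTATION_COLUMNS, BetaMatrix

SEX_CODE = {"male": "1", "female": "2"}
SEX_DECODE = {"1": "male", "2": "female"}


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "family_id": ped["family_id"],
            "individual_id": ped["individual_id"],
            "father_id": ped["father_id"].fillna("0"),
            "mother_id": ped["mother_id"].fillna("0"),
            "sex": ped["sex"].map(SEX_CODE),
            "age": ped["age"],
            "zygosity": ped["zygosity"],
            "twin_pair_id": ped["twin_pair_id"].fillna("0"),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    ped = pd.DataFrame(
        {
            "individual_id": raw["individual_id"],
            "family_id": raw["family_id"],
            "father_id": raw["father_id"].replace("0", np.nan),
            "mother_id": raw["mother_id"].replace("0", np.nan),
            "sex": raw["sex"].map(SEX_DECODE),
            "age": raw["age"].astype(float),
            "zygosity": raw["zygosity"],
            "twin_pair_id": raw["twin_pair_id"].replace("0", np.nan),
        }
    )
    return ped


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV: snp_id, chromosome, position, maf, then one column per
    individual (empty cell = missing)."""
    table = geno.snp_map.set_index("snp_id").join(geno.dosage)
    table.to_csv(path, sep="\t", na_rep="", index_label="snp_id")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", index_col="snp_id")
    map_cols = ["chromosome", "position", "maf"]
    snp_map = table[map_cols].reset_index()
    dosage = table.drop(columns=map_cols)
    return GenotypeMatrix(dosage=dosage, snp_map=snp_map)


def write_matrix(values: pd.DataFrame, path: str | Path, index_label: str = "probe_id") -> None:
    values.to_csv(path, sep="\t", na_rep="", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """BED-like probe annotation TSV: chrom, 1-based CpG position, probe id,
    then probe_type, n_cpg, n_snp, density_class, multimap_flag."""
    out = annotation.reset_index(names="probe_id")[
        ["chromosome", "position", "probe_id", "probe_type", "n_cpg", "n_snp",
         "density_class", "multimap_flag"]
    ]
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    ann = raw.set_index("probe_id")[ANNOTATION_COLUMNS]
    ann["multimap_flag"] = ann["multimap_flag"].astype(bool)
    return ann


def read_beta_matrix(values_path: str | Path, annotation_path: str | Path) -> BetaMatrix:
    values = read_matrix(values_path)
    annotation = read_annotation(annotation_path).loc[values.index]
    return BetaMatrix(values=values, annotation=annotation)


def write_residuals(resid: ResidualMatrix, path: str | Path) -> None:
    write_matrix(resid.values, path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
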