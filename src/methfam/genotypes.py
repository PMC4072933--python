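"""Gene-dropping genotype simulation on twin-family pedigrees.

Founder alleles are drawn independently at the SNP's minor allele frequency;
each child receives one uniformly chosen allele from each parent (Mendelian
transmission) and MZ co-twins copy the same realised gamete pair. Dosages
count minor alleles and therefore lie in {0, 1, 2}; missing entries are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import founders, mz_pairs, topological_order, validate_pedigree


@dataclass
class GenotypeMatrix:
    """SNP dosage matrix (SNPs x individuals) plus a SNP map.

    ``dosage`` rows are indexed by ``snp_id`` and columns by individual id;
    ``snp_map`` has columns ``snp_id``, ``chromosome``, ``position``, ``maf``.
    """

    dosage: pd.DataFrame
    snp_map: pd.DataFrame = field(default=None)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.dosage.columns)


def simulate_genotypes(
    ped: pd.DataFrame,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    missing_rate: float = 0.0,
    chromosome: str = "1",
    chrom_length: int = 100_000_000,
) -> GenotypeMatrix:
    """Drop ``n_snps`` unlinked SNPs through the pedigree.

    MAFs are drawn uniformly from ``maf_range`` (which must lie in (0, 0.5]);
    positions uniformly (then sorted) along one chromosome. With
    ``missing_rate > 0`` entries are masked missing at random.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    validate_pedigree(ped)

    rng = np.random.default_rng(seed)
    ids = ped["individual_id"].tolist()
    idx = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    mafs = rng.uniform(lo, hi, size=n_snps)

    # Paternal/maternal allele per SNP per individual, filled in pedigree order.
    pat = np.zeros((n_snps, n), dtype=np.int8)
    mat = np.zeros((n_snps, n), dtype=np.int8)
    father = ped["father_id"].tolist()
    mother = ped["mother_id"].tolist()
    twin_of: dict[int, int] = {}
    for a, b in mz_pairs(ped):
        twin_of[idx[b]] = idx[a]

    for i in topological_order(ped):
        if i in twin_of:
            j = twin_of[i]
            pat[:, i] = pat[:, j]
            mat[:, i] = mat[:, j]
            continue
        f, m = father[i], mother[i]
        if pd.isna(f) and pd.isna(m):
            pat[:, i] = rng.random(n_snps) < mafs
            mat[:, i] = rng.random(n_snps) < mafs
        else:
            fi, mi = idx[f], idx[m]
            pick_f = rng.integers(0, 2, size=n_snps)
            pick_m = rng.integers(0, 2, size=n_snps)
            pat[:, i] = np.where(pick_f == 0, pat[:, fi], mat[:, fi])
            mat[:, i] = np.where(pick_m == 0, pat[:, mi], mat[:, mi])

    dosage = (pat + mat).astype(float)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan

    snp_ids = [f"snp{k + 1:06d}" for k in range(n_snps)]
    positions = np.sort(rng.integers(1, chrom_length + 1, size=n_snps))
    snp_map = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": chromosome,
            "position": positions,
            "maf": mafs,
        }
    )
    dosage_df = pd.DataFrame(dosage, index=snp_ids, columns=ids)
    return GenotypeMatrix(dosage=dosage_df, snp_map=snp_map)


def mendelian_consistent(geno: GenotypeMatrix, ped: pd.DataFrame) -> bool:
    """Check every non-missing child dosage against its parents' dosages.

    A child dosage is consistent when it can be written as one allele from
    each parent; e.g. parents (0, 0) force dosage 0 and parents (2, x) force
    at least one minor allele from the first parent.
    """
    d = geno.dosage
    for _, row in ped[~founders(ped)].iterrows():
        c = d[row["individual_id"]].to_numpy()
        f = d[row["father_id"]].to_numpy()
        m = d[row["mother_id"]].to_numpy()
        ok = np.isnan(c) | np.isnan(f) | np.isnan(m)
        lo = np.clip(f - 1, 0, 1) + np.clip(m - 1, 0, 1)
        hi = np.clip(f, 0, 1) + np.clip(m, 0, 1)
        ok |= (c >= lo) & (c <= hi)
        if not ok.all():
            return False
    return True
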