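"""Family-aware mQTL association scanning.

SNP dosages are tested against per-probe methylation residuals with a
measured-genotype generalized-least-squares model: the probe's polygenic
covariance Va * A + Ve * I is estimated once under the no-SNP null, then for
every SNP the fixed allelic-dosage effect is estimated by GLS with that
covariance held fixed, giving a Wald test against the standard normal. This
accounts for the phenotypic correlation between relatives, which would
otherwise inflate the association test's type-I error. When residuals are on
the logit (log-odds) scale, the reported effect is the change in the
log-odds of the probe being methylated per copy of the minor allele.

SNP quality control follows standard practice: minor allele frequency,
Hardy-Weinberg equilibrium (exact test on founders, who are unaffected by
the within-family dependence of genotypes) and per-SNP missingness.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix
from .normalize import ResidualMatrix
from .pedigree import KinshipMatrix, founders
from .varcomp import fit_varcomp

logger = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    return alpha / n_tests


def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg equilibrium test from genotype counts.

    Sums the probabilities of all heterozygote counts (conditional on the
    observed allele counts) that are no more likely than the observed one
    (Wigginton-style two-sided exact test).
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    # Possible heterozygote counts share the parity of the minor allele count.
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = int(np.nonzero(hets == n_het)[0][0])
    return float(probs[probs <= probs[obs] * (1.0 + 1e-12)].sum())


def snp_qc(
    geno: GenotypeMatrix,
    ped: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    max_missing: float = 0.10,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Drop SNPs failing MAF, Hardy-Weinberg or missingness filters.

    Removal rules (strict inequalities, applied in sequence with a tally):
    MAF < ``maf_min``; HWE exact p < ``hwe_alpha`` computed on founder hard
    genotypes (all samples when no pedigree is given); missing rate
    > ``max_missing``.
    """
    dosage = geno.dosage.to_numpy(float)
    n_snps = dosage.shape[0]
    tally = {}

    miss_rate = np.isnan(dosage).mean(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    keep = ~(maf < maf_min)
    tally["maf"] = int((~keep).sum())

    if ped is not None:
        cols = [i for i, s in enumerate(geno.dosage.columns)
                if s in set(ped.loc[founders(ped), "individual_id"])]
    else:
        cols = list(range(dosage.shape[1]))
    hwe_p = np.ones(n_snps)
    for k in range(n_snps):
        if not keep[k]:
            continue
        g = dosage[k, cols]
        g = g[~np.isnan(g)]
        g = g[np.isin(g, (0.0, 1.0, 2.0))]  # HWE needs hard calls
        counts = [(g == 0).sum(), (g == 1).sum(), (g == 2).sum()]
        hwe_p[k] = hwe_exact_pvalue(*counts)
    drop = keep & (hwe_p < hwe_alpha)
    tally["hwe"] = int(drop.sum())
    keep &= hwe_p >= hwe_alpha

    drop = keep & (miss_rate > max_missing)
    tally["missingness"] = int(drop.sum())
    keep &= miss_rate <= max_missing
    tally["retained"] = int(keep.sum())

    kept_ids = geno.dosage.index[keep]
    snp_map = geno.snp_map
    if snp_map is not None:
        snp_map = snp_map[snp_map["snp_id"].isin(set(kept_ids))].reset_index(drop=True)
    return GenotypeMatrix(dosage=geno.dosage.loc[kept_ids], snp_map=snp_map), pd.Series(tally)


def _gls_effects(
    ystar: np.ndarray, ones_star: np.ndarray, Gstar: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-SNP GLS effects for design [1, g] with diagonal rotated
    covariance weights ``w`` (= 1/d)."""
    a = float(ones_star * w @ ones_star)
    ty = float(ones_star * w @ ystar)
    Gw = Gstar * w[None, :]
    b = Gw @ ones_star
    c = np.einsum("ij,ij->i", Gw, Gstar)
    gy = Gw @ ystar
    det = a * c - b * b
    det = np.where(det <= 0, np.nan, det)
    effect = (a * gy - b * ty) / det
    se = np.sqrt(a / det)
    return effect, se


def assoc_scan(
    resid_row: pd.Series | np.ndarray,
    geno: GenotypeMatrix,
    kin: KinshipMatrix,
    min_n: int = 30,
    probe_id: str | None = None,
) -> pd.DataFrame:
    """Test every SNP against one probe's residuals (measured-genotype GLS).

    The AE polygenic covariance is estimated once from the no-SNP null,
    then each SNP's allelic effect is a GLS fixed effect with Wald p-value.
    Monomorphic SNPs (after subsetting to complete cases) are skipped with a
    log message. Missing dosages are handled by per-SNP subsetting.
    """
    ids = kin.ids
    y = (
        resid_row.reindex(ids).to_numpy(float)
        if isinstance(resid_row, pd.Series)
        else np.asarray(resid_row, float)
    )
    if y.shape[0] != len(ids):
        raise ValueError("residual row length does not match kinship matrix")
    obs = ~np.isnan(y)
    if int(obs.sum()) < min_n:
        raise ValueError(
            f"need at least {min_n} individuals with phenotype, got {int(obs.sum())}"
        )

    null = fit_varcomp(y, kin, model="AE")
    A = kin.A.to_numpy(float)[np.ix_(obs, obs)]
    lam, U = np.linalg.eigh(A)
    lam = np.clip(lam, 0.0, None)
    d = null.va * lam + null.ve
    w = 1.0 / d
    yo = y[obs]
    ystar = U.T @ yo
    ones_star = U.T @ np.ones(obs.sum())

    G = geno.dosage.loc[:, np.asarray(ids)[obs]].to_numpy(float)
    has_missing = np.isnan(G).any(axis=1)
    mono = np.nanstd(G, axis=1) == 0
    if mono.any():
        logger.info("skipping %d monomorphic SNPs", int(mono.sum()))

    n_used = np.full(G.shape[0], int(obs.sum()))
    effect = np.full(G.shape[0], np.nan)
    se = np.full(G.shape[0], np.nan)

    easy = ~has_missing & ~mono
    if easy.any():
        Gstar = G[easy] @ U
        effect[easy], se[easy] = _gls_effects(ystar, ones_star, Gstar, w)

    for k in np.nonzero(has_missing & ~mono)[0]:
        g = G[k]
        ok = ~np.isnan(g)
        if ok.sum() < min_n or np.std(g[ok]) == 0:
            mono[k] = True
            continue
        Ak = A[np.ix_(ok, ok)]
        lam_k, U_k = np.linalg.eigh(Ak)
        d_k = null.va * np.clip(lam_k, 0.0, None) + null.ve
        eff, s = _gls_effects(
            U_k.T @ yo[ok],
            U_k.T @ np.ones(int(ok.sum())),
            (g[ok] @ U_k)[None, :],
            1.0 / d_k,
        )
        effect[k], se[k] = eff[0], s[0]
        n_used[k] = int(ok.sum())

    keep = ~mono
    z = effect[keep] / se[keep]
    out = pd.DataFrame(
        {
            "snp_id": geno.dosage.index[keep],
            "effect": effect[keep],
            "se": se[keep],
            "p_value": 2.0 * norm.sf(np.abs(z)),
            "n_used": n_used[keep],
        }
    )
    if probe_id is not None:
        out.insert(0, "probe_id", probe_id)
    return out.reset_index(drop=True)


def region_effects(
    lead_snp: str,
    resid: ResidualMatrix | pd.DataFrame,
    geno: GenotypeMatrix,
    kin: KinshipMatrix,
    window_bp: int = 8_000_000,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Signed effect profile of one SNP on every probe in its window.

    Tests the lead SNP against each probe whose CpG position lies within
    ``window_bp / 2`` of the SNP on the same chromosome (the window spans
    ``window_bp`` in total), and flags probes passing the Bonferroni
    threshold ``alpha / n_tests`` (``n_tests`` defaults to the number of
    probes in the residual matrix, i.e. a genome-wide correction).
    """
    if geno.snp_map is None or lead_snp not in set(geno.snp_map["snp_id"]):
        raise ValueError(f"lead SNP {lead_snp!r} not present in the SNP map")
    annotation = resid.annotation if isinstance(resid, ResidualMatrix) else None
    if annotation is None:
        raise ValueError("region_effects requires probe annotation on the residuals")
    values = resid.values if isinstance(resid, ResidualMatrix) else resid

    snp_row = geno.snp_map.set_index("snp_id").loc[lead_snp]
    half = window_bp / 2.0
    in_window = (annotation["chromosome"].astype(str) == str(snp_row["chromosome"])) & (
        (annotation["position"] - snp_row["position"]).abs() <= half
    )
    probes = values.index[in_window.reindex(values.index, fill_value=False)]
    if len(probes) == 0:
        logger.warning("no probes within %d bp of %s", window_bp, lead_snp)

    n_tests = n_tests if n_tests is not None else values.shape[0]
    threshold = bonferroni_threshold(alpha, n_tests)
    lead = GenotypeMatrix(
        dosage=geno.dosage.loc[[lead_snp]],
        snp_map=geno.snp_map[geno.snp_map["snp_id"] == lead_snp].reset_index(drop=True),
    )
    rows = []
    for probe_id in probes:
        res = assoc_scan(values.loc[probe_id], lead, kin, probe_id=probe_id)
        if len(res) == 0:
            continue
        r = res.iloc[0]
        rows.append(
            (probe_id, int(annotation.loc[probe_id, "position"]), r["effect"],
             r["se"], r["p_value"], r["n_used"], r["p_value"] < threshold)
        )
    return pd.DataFrame(
        rows,
        columns=["probe_id", "position", "effect", "se", "p_value", "n_used",
                 "significant"],
    )


class MQTLScanner(BaseEstimator):
    """Family-aware single-probe association scan.

    Parameters
    ----------
    min_n:
        Minimum individuals with both phenotype and genotype.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-SNP effects, standard errors and Wald p-values.
    """

    def __init__(self, min_n: int = 30):
        self.min_n = min_n

    def fit(self, geno: GenotypeMatrix, resid_row: pd.Series, kin: KinshipMatrix = None):
        if kin is None:
            raise ValueError("MQTLScanner.fit requires the kinship matrix")
        self.results_ = assoc_scan(resid_row, geno, kin, min_n=self.min_n)
        return self
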