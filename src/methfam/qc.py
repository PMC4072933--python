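"""Probe-level quality control for beta-value matrices.

Probes are removed when they sit on a sex chromosome, are annotated as
multi-mapping, contain no CpG, or show more missing calls / detection-p
failures than expected under a binomial model of random missingness (0.05
significance with Bonferroni correction over probes).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import binom

from .simulate import BetaMatrix

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY", "23", "24"}


def missingness_threshold(
    avg_rate: float, n_samples: int, n_probes: int, alpha: float = 0.05
) -> int:
    """Smallest integer cutoff k with P(Binomial(n_samples, avg_rate) > k) < alpha/n_probes.

    A probe with more than k affected samples deviates significantly from
    random missingness at level ``alpha`` after Bonferroni correction over
    ``n_probes`` probes.
    """
    if not (0.0 < avg_rate < 1.0):
        raise ValueError("avg_rate must be strictly between 0 and 1")
    if n_samples < 1 or n_probes < 1:
        raise ValueError("n_samples and n_probes must be positive")
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError("alpha must be positive and finite")
    ks = np.arange(n_samples + 1)
    tail = binom.sf(ks, n_samples, avg_rate)  # P(X > k)
    hits = np.nonzero(tail < alpha / n_probes)[0]
    if len(hits) == 0:
        return n_samples
    return int(hits[0])


def average_rate(matrix: pd.DataFrame, condition: str = "missing", detect_p: float = 0.001) -> float:
    """Pooled mean event rate over all probes and samples.

    ``condition="missing"`` counts NaN entries of a beta matrix;
    ``condition="detect"`` counts entries of a detection-p matrix above
    ``detect_p``.
    """
    arr = matrix.to_numpy(float)
    if condition == "missing":
        return float(np.isnan(arr).mean())
    if condition == "detect":
        return float((arr > detect_p).mean())
    raise ValueError("condition must be 'missing' or 'detect'")


def filter_probes(
    beta: BetaMatrix,
    detect: pd.DataFrame | None = None,
    cutoff_missing: int | None = None,
    cutoff_detect: int | None = None,
    detect_p: float = 0.001,
) -> tuple[BetaMatrix, pd.Series]:
    """Apply the probe filters; return the retained matrix and a removal tally.

    Rules, applied in sequence (each tally counts removals at that stage):
    sex-chromosome probes; multi-mapping probes; probes with zero CpGs;
    probes with more than ``cutoff_missing`` missing samples; probes with
    more than ``cutoff_detect`` samples at detection p > ``detect_p``.
    """
    ann = beta.annotation
    values = beta.values
    tally = {}

    keep = ~ann["chromosome"].astype(str).isin(SEX_CHROMOSOMES)
    tally["sex_chromosome"] = int((~keep).sum())

    drop = keep & ann["multimap_flag"].astype(bool)
    tally["multimapping"] = int(drop.sum())
    keep &= ~ann["multimap_flag"].astype(bool)

    drop = keep & (ann["n_cpg"].astype(int) == 0)
    tally["zero_cpg"] = int(drop.sum())
    keep &= ann["n_cpg"].astype(int) > 0

    if cutoff_missing is not None:
        n_missing = values.isna().sum(axis=1)
        drop = keep & (n_missing > cutoff_missing)
        tally["missingness"] = int(drop.sum())
        keep &= n_missing <= cutoff_missing

    if cutoff_detect is not None:
        if detect is None:
            raise ValueError("cutoff_detect given but no detection-p matrix")
        n_fail = (detect.loc[values.index, values.columns] > detect_p).sum(axis=1)
        drop = keep & (n_fail > cutoff_detect)
        tally["detection_p"] = int(drop.sum())
        keep &= n_fail <= cutoff_detect

    retained = BetaMatrix(values=values.loc[keep], annotation=ann.loc[keep])
    tally["retained"] = int(keep.sum())
    if tally["retained"] == 0:
        logger.warning("filter_probes removed every probe")
    return retained, pd.Series(tally)


def exclude_probes_with_snps(beta: BetaMatrix) -> BetaMatrix:
    """Keep only probes with no annotated SNP in the probe sequence
    (annotation filter on ``n_snp == 0``)."""
    keep = beta.annotation["n_snp"].astype(int) == 0
    return BetaMatrix(values=beta.values.loc[keep], annotation=beta.annotation.loc[keep])
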