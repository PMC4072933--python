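"""Per-probe normalization of beta values and outlier masking.

Each probe is normalised across samples with a generalized linear model with
a logistic link on the array/demographic covariates (chip, position on the
chip, sex, age, age^2, sex x age, sex x age^2); downstream analyses use the
residuals. No between-probe or between-probe-type normalization is applied:
variance partitioning is within-probe, so the compressed dynamic range of
Type II probes does not affect it.

Outlying residuals (further than k interquartile ranges from the nearest
quartile, default k=5) are set to missing in a single, non-iterated pass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import BetaMatrix

logger = logging.getLogger(__name__)

CLIP_EPS = 1e-6


@dataclass
class ResidualMatrix:
    """Normalised methylation residuals (probes x samples, unbounded, NaN =
    missing) with the probe annotation carried through and a provenance note
    recording which covariates were removed."""

    values: pd.DataFrame
    annotation: pd.DataFrame | None = None
    provenance: list = field(default_factory=list)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def build_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Design matrix from a sample table with columns ``chip``,
    ``chip_position``, ``sex`` and ``age``.

    Columns: intercept, chip and chip-position dummies (first level dropped),
    female indicator, age, age^2 and the sex interactions. Missing covariate
    columns are simply omitted (e.g. a sheet without chip information).
    """
    X = pd.DataFrame(index=samples.index)
    X["intercept"] = 1.0
    for cat in ("chip", "chip_position"):
        if cat in samples.columns:
            dummies = pd.get_dummies(samples[cat], prefix=cat, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    if "sex" in samples.columns:
        sex = samples["sex"]
        female = (sex == "female").astype(float) if sex.dtype == object else sex.astype(float)
        X["sex"] = female
    if "age" in samples.columns:
        age = samples["age"].astype(float)
        X["age"] = age
        X["age2"] = age**2
        if "sex" in X.columns:
            X["sex_age"] = X["sex"] * age
            X["sex_age2"] = X["sex"] * age**2
    return X


def _drop_degenerate(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop non-intercept columns with no variation in the current subset."""
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    return X[:, keep], [names[j] for j in keep]


def normalize_probe(
    beta_row: np.ndarray | pd.Series,
    design: pd.DataFrame | np.ndarray,
    scale: str = "response",
) -> np.ndarray:
    """Residuals of one probe after removing covariate effects.

    Fits the mean beta value through a logistic link (quasi-likelihood, no
    integer trials) and returns residuals for non-missing entries; missing
    entries stay NaN. ``scale="response"`` gives observed minus fitted on the
    beta scale (default); ``scale="link"`` gives residuals of logit-beta
    against the linear predictor. If the GLM fails to converge or separates,
    an ordinary linear model on logit-transformed values (clipped to
    [1e-6, 1 - 1e-6]) is used instead, with a logged warning.
    """
    if scale not in ("response", "link"):
        raise ValueError("scale must be 'response' or 'link'")
    y = np.asarray(beta_row, dtype=float)
    X_full = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    names = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{j}" for j in range(X_full.shape[1])
    ]
    if X_full.shape[0] != y.shape[0]:
        raise ValueError("design and beta row have different numbers of samples")
    obs = ~np.isnan(y)
    yo = y[obs]
    if yo.size < 2:
        raise ValueError("normalize_probe requires at least 2 non-missing values")
    if np.unique(yo).size < 2:
        # Constant row: the intercept fits perfectly.
        out = np.full_like(y, np.nan)
        out[obs] = 0.0
        return out
    X, _ = _drop_degenerate(X_full[obs], names)

    yc = np.clip(yo, CLIP_EPS, 1.0 - CLIP_EPS)
    fitted_link = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(yc, X, family=sm.families.Binomial()).fit()
        if res.converged and np.all(np.isfinite(res.params)):
            fitted_link = X @ res.params
    except Exception as exc:  # separation, singularities
        logger.warning("GLM normalization failed (%s); falling back to linear logit fit", exc)
    if fitted_link is None:
        logger.warning("falling back to linear model on logit-transformed values")
        ylog = logit(yc)
        coef, *_ = np.linalg.lstsq(X, ylog, rcond=None)
        fitted_link = X @ coef

    out = np.full_like(y, np.nan)
    if scale == "response":
        out[obs] = yo - expit(fitted_link)
    else:
        out[obs] = logit(yc) - fitted_link
    return out


class ProbeNormalizer(BaseEstimator, TransformerMixin):
    """Per-probe logistic-link normalizer over sample covariates.

    Parameters
    ----------
    scale:
        ``"response"`` (beta minus fitted beta; default) or ``"link"``
        (logit-scale residuals).

    Attributes
    ----------
    design_ : pandas.DataFrame
        Design matrix built from the sample table passed to :meth:`fit`.
    """

    def __init__(self, scale: str = "response"):
        self.scale = scale

    def fit(self, X: BetaMatrix | pd.DataFrame, samples: pd.DataFrame = None):
        if samples is None:
            raise ValueError("ProbeNormalizer.fit requires the sample covariate table")
        samples = (
            samples.set_index("individual_id")
            if "individual_id" in samples.columns
            else samples
        )
        values = X.values if isinstance(X, BetaMatrix) else X
        self.design_ = build_design(samples.loc[list(values.columns)])
        return self

    def transform(self, X: BetaMatrix | pd.DataFrame) -> ResidualMatrix:
        if not hasattr(self, "design_"):
            raise ValueError("ProbeNormalizer is not fitted")
        values = X.values if isinstance(X, BetaMatrix) else X
        resid = np.empty(values.shape)
        arr = values.to_numpy(float)
        for k in range(arr.shape[0]):
            resid[k] = normalize_probe(arr[k], self.design_, scale=self.scale)
        out = pd.DataFrame(resid, index=values.index, columns=values.columns)
        annotation = X.annotation if isinstance(X, BetaMatrix) else None
        return ResidualMatrix(
            values=out,
            annotation=annotation,
            provenance=[f"glm_logistic({', '.join(self.design_.columns[1:])})", f"scale={self.scale}"],
        )

    def fit_transform(self, X, samples=None, **kwargs) -> ResidualMatrix:
        return self.fit(X, samples).transform(X)


def logit_values(beta: BetaMatrix, center: bool = True) -> ResidualMatrix:
    """Logit-transform a beta matrix (clipped to [1e-6, 1 - 1e-6]) without
    covariate correction, optionally centering each probe.

    For covariate-free designs this recovers the latent log-odds trait up to
    Type II compression and is the natural scale for variance-component
    analysis of simulated data.
    """
    arr = np.clip(beta.values.to_numpy(float), CLIP_EPS, 1.0 - CLIP_EPS)
    vals = logit(arr)
    vals[np.isnan(beta.values.to_numpy(float))] = np.nan
    if center:
        vals = vals - np.nanmean(vals, axis=1, keepdims=True)
    return ResidualMatrix(
        values=pd.DataFrame(vals, index=beta.values.index, columns=beta.values.columns),
        annotation=beta.annotation,
        provenance=["logit", "centered" if center else "uncentered"],
    )


def mask_outliers(residual_row: np.ndarray | pd.Series, k: float = 5.0) -> np.ndarray:
    """Mask residuals more than ``k`` interquartile ranges beyond the nearest
    quartile (strict inequality), in a single pass.

    Quartiles are computed on the non-missing values before masking with
    linear interpolation. With a zero IQR any value differing from the
    (equal) quartiles is masked.
    """
    x = np.asarray(residual_row, dtype=float).copy()
    obs = ~np.isnan(x)
    if obs.sum() < 4:
        raise ValueError("mask_outliers requires at least 4 non-missing values")
    q1, q3 = np.nanpercentile(x, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        logger.info("zero IQR: masking any value away from the quartiles")
    lo, hi = q1 - k * iqr, q3 + k * iqr
    x[(x < lo) | (x > hi)] = np.nan
    return x


class IQROutlierMasker(BaseEstimator, TransformerMixin):
    """Row-wise k-IQR outlier masking of a residual matrix (default k=5)."""

    def __init__(self, k: float = 5.0):
        self.k = k

    def fit(self, X, y=None):
        return self

    def transform(self, X: ResidualMatrix | pd.DataFrame) -> ResidualMatrix:
        values = X.values if isinstance(X, ResidualMatrix) else X
        arr = values.to_numpy(float)
        out = np.vstack([mask_outliers(row, k=self.k) for row in arr])
        df = pd.DataFrame(out, index=values.index, columns=values.columns)
        annotation = X.annotation if isinstance(X, ResidualMatrix) else None
        prov = list(X.provenance) if isinstance(X, ResidualMatrix) else []
        return ResidualMatrix(
            values=df, annotation=annotation, provenance=prov + [f"iqr_mask(k={self.k})"]
        )
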