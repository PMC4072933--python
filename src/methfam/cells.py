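"""Reference-based cell-type deconvolution of whole-blood methylation.

Whole-blood beta values at cell-type-discriminating ("signature") probes are
modelled as a mixture of reference cell-type profiles; per-sample mixing
weights are recovered by constrained least squares (non-negative, summing to
one) so they can later enter heritability models as covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .simulate import CELL_TYPES, BetaMatrix


def _check_reference(ref: pd.DataFrame) -> None:
    if ref.shape[0] < ref.shape[1]:
        raise ValueError("need at least as many signature probes as cell types")
    if np.linalg.matrix_rank(ref.to_numpy(float)) < ref.shape[1]:
        raise ValueError("cell reference is rank deficient; profiles are collinear")
    arr = ref.to_numpy(float)
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("reference profiles must be beta values in [0, 1]")


def _simplex_lsq(R: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """min ||R p - b|| subject to p >= 0 and sum(p) = 1.

    Solved as non-negative least squares with a strongly weighted
    sum-to-one row appended, then renormalised exactly.
    """
    lam = 1000.0 * max(1.0, np.abs(R).max())
    R_aug = np.vstack([R, lam * np.ones((1, R.shape[1]))])
    b_aug = np.append(b, lam)
    p, _ = nnls(R_aug, b_aug)
    total = p.sum()
    if total <= 0:
        p = np.full(R.shape[1], 1.0 / R.shape[1])
    else:
        p = p / total
    resid = float(np.linalg.norm(R @ p - b))
    return p, resid


def estimate_cell_proportions(
    beta: BetaMatrix | pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample cell-type proportions from signature-probe beta values.

    ``reference`` is a (signature probes x cell types) table of mean beta
    profiles. Returns a DataFrame indexed by sample with one column per cell
    type plus ``residual_norm``. Probes missing in a sample are dropped for
    that sample's fit.
    """
    _check_reference(reference)
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    common = [p for p in reference.index if p in values.index]
    if len(common) < reference.shape[1]:
        raise ValueError("too few signature probes present in the beta matrix")
    R_full = reference.loc[common].to_numpy(float)
    B = values.loc[common].to_numpy(float)

    rows = []
    for j, sample in enumerate(values.columns):
        b = B[:, j]
        obs = ~np.isnan(b)
        if obs.sum() < reference.shape[1]:
            rows.append([np.nan] * reference.shape[1] + [np.nan])
            continue
        p, resid = _simplex_lsq(R_full[obs], b[obs])
        rows.append(list(p) + [resid])
    return pd.DataFrame(
        rows,
        index=values.columns,
        columns=list(reference.columns) + ["residual_norm"],
    )


class CellTypeDeconvolver(BaseEstimator):
    """Constrained-least-squares deconvolution against a cell reference.

    Fit stores the reference; :meth:`predict` returns simplex weights per
    sample of a beta matrix.

    Attributes
    ----------
    reference_ : pandas.DataFrame
        Validated (signature probes x cell types) reference profile table.
    """

    def fit(self, reference: pd.DataFrame, y=None):
        _check_reference(reference)
        self.reference_ = reference.copy()
        return self

    def predict(self, beta: BetaMatrix | pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_"):
            raise ValueError("CellTypeDeconvolver is not fitted")
        return estimate_cell_proportions(beta, self.reference_)


def synthetic_cell_reference(
    n_probes: int = 200, cell_types: list[str] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic stand-in for a measured leukocyte reference panel.

    Draws well-separated beta profiles for the standard six blood cell types;
    useful for simulation studies, not a substitute for a laboratory
    reference in real analyses.
    """
    cell_types = cell_types or CELL_TYPES
    rng = np.random.default_rng(seed)
    profiles = rng.beta(0.4, 0.4, size=(n_probes, len(cell_types)))
    index = [f"sigcg{k + 1:05d}" for k in range(n_probes)]
    return pd.DataFrame(profiles, index=index, columns=cell_types)
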