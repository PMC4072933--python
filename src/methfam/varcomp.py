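"""Pedigree maximum-likelihood variance components for methylation probes.

For one probe with residual vector ``y`` over ``n`` individuals the model is

    y ~ N(X b, Va * A + Vf * H + Ve * I)

with ``A`` the additive relationship matrix (MZ co-twin entries 1), ``H``
the nuclear-household indicator and ``X`` an intercept plus optional fixed
covariates (e.g. estimated cell proportions). Estimation is by maximum
likelihood with the variances constrained non-negative; the fixed effects
are profiled out by generalized least squares at every likelihood
evaluation. Because the constrained estimate can land on the Va = 0
boundary, the likelihood-ratio test of a single variance component is
referred to an equal mixture of a point mass at zero and a chi-square with
one degree of freedom; under a true-zero component about half of all fits
land exactly on the boundary.

Two likelihood backends are used: probes with complete data under the AE
model are rotated by the eigenvectors of ``A`` (covariance becomes diagonal,
O(n) per likelihood evaluation); all other cases exploit the family-block
structure of ``A`` and ``H`` with per-block Cholesky factorizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .normalize import ResidualMatrix
from .pedigree import KinshipMatrix, additive_relationship

_LOG2PI = np.log(2.0 * np.pi)

#: free variance components per model
MODEL_COMPONENTS = {
    "E": (),
    "AE": ("va",),
    "FE": ("vf",),
    "AFE": ("va", "vf"),
}

#: default tested component (the one removed in the nested null)
DEFAULT_TEST = {"E": None, "AE": "va", "FE": "vf", "AFE": "vf"}


@dataclass
class VarCompFit:
    """Per-probe ML variance-component fit."""

    va: float
    vf: float
    ve: float
    loglik: float
    null_loglik: float
    n_used: int
    converged: bool
    p_value: float
    model: str
    test: str | None

    @property
    def h2(self) -> float:
        return self.va / (self.va + self.vf + self.ve)

    @property
    def c2(self) -> float:
        return self.vf / (self.va + self.vf + self.ve)


def _ols_loglik(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """ML fit of the iid model; returns (ve_hat, loglik)."""
    n = y.shape[0]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    ve = float(r @ r) / n
    ve = max(ve, 1e-300)
    loglik = -0.5 * (n * np.log(ve) + n + n * _LOG2PI)
    return ve, loglik


def _gls_negloglik_diag(d: np.ndarray, ystar: np.ndarray, Xstar: np.ndarray) -> float:
    """Negative profile log-likelihood with diagonal covariance ``d``."""
    if np.any(d <= 0):
        return np.inf
    w = 1.0 / d
    Xw = Xstar * w[:, None]
    XtWX = Xstar.T @ Xw
    XtWy = Xw.T @ ystar
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(XtWX, XtWy, rcond=None)
    r = ystar - Xstar @ beta
    n = ystar.shape[0]
    return 0.5 * (np.log(d).sum() + float(r * w @ r) + n * _LOG2PI)


class _AELikelihood:
    """Rotated-space AE likelihood: cov = Va * A + Ve * I."""

    def __init__(self, y: np.ndarray, X: np.ndarray, A: np.ndarray,
                 eig: tuple[np.ndarray, np.ndarray] | None = None):
        if eig is None:
            lam, U = np.linalg.eigh(A)
            lam = np.clip(lam, 0.0, None)
        else:
            lam, U = eig
        self.lam = lam
        self.ystar = U.T @ y
        self.Xstar = U.T @ X

    def negloglik(self, params: np.ndarray) -> float:
        va, ve = params
        return _gls_negloglik_diag(va * self.lam + ve, self.ystar, self.Xstar)


class _BlockLikelihood:
    """Family-block likelihood: cov = Va * A + Vf * H + Ve * I.

    Blocks are grouped by family size and factorized with batched Cholesky
    so one likelihood evaluation is a handful of vectorized operations.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # blocks: (index array into y, A block, H block)
        self.n = y.shape[0]
        self.p = X.shape[1]
        by_size: dict[int, list] = {}
        for idx, Ab, Hb in blocks:
            by_size.setdefault(len(idx), []).append((idx, Ab, Hb))
        self.groups = []
        for s, items in sorted(by_size.items()):
            A_st = np.stack([it[1] for it in items])  # (m, s, s)
            H_st = np.stack([it[2] for it in items])
            idxs = np.stack([it[0] for it in items])  # (m, s)
            y_st = y[idxs]  # (m, s)
            X_st = X[idxs]  # (m, s, p)
            self.groups.append((A_st, H_st, np.eye(s), y_st, X_st))

    def negloglik(self, params: np.ndarray) -> float:
        va, vf, ve = params
        if min(va, vf) < 0 or ve <= 0:
            return np.inf
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        yty = 0.0
        logdet = 0.0
        for A_st, H_st, I_s, y_st, X_st in self.groups:
            C = va * A_st + vf * H_st + ve * I_s
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                return np.inf
            logdet += 2.0 * float(np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
            Vy = np.linalg.solve(C, y_st[..., None])[..., 0]  # (m, s)
            VX = np.linalg.solve(C, X_st)  # (m, s, p)
            XtVX += np.einsum("msp,msq->pq", X_st, VX)
            XtVy += np.einsum("msp,ms->p", X_st, Vy)
            yty += float(np.einsum("ms,ms->", y_st, Vy))
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(XtVX, XtVy, rcond=None)
        quad = yty - 2.0 * float(beta @ XtVy) + float(beta @ XtVX @ beta)
        return 0.5 * (logdet + quad + self.n * _LOG2PI)


def _family_blocks(A: np.ndarray, H: np.ndarray, fam_codes: np.ndarray):
    blocks = []
    for code in np.unique(fam_codes):
        idx = np.nonzero(fam_codes == code)[0]
        blocks.append((idx, A[np.ix_(idx, idx)], H[np.ix_(idx, idx)]))
    return blocks


def _maximize(nll, free: tuple[str, ...], var_y: float, extra_starts=()):
    """Bound-constrained ML over the free components of (va, vf, ve).

    ``nll`` takes the full (va, vf, ve) triple. Returns (va, vf, ve, loglik,
    converged). Multiple restarts: equal split, null-heavy and genetic/
    family-heavy initializations, plus any caller-supplied starts.
    """
    comps = list(free) + ["ve"]
    k = len(comps)
    ub = 50.0 * var_y
    ve_floor = 1e-10 * var_y

    def pack(full):
        return [full[{"va": 0, "vf": 1, "ve": 2}[c]] for c in comps]

    def unpack(x):
        full = [0.0, 0.0, 0.0]
        for c, v in zip(comps, x):
            full[{"va": 0, "vf": 1, "ve": 2}[c]] = v
        return np.asarray(full)

    starts = []
    if k == 1:
        starts = [[var_y]]
    else:
        eq = var_y / k
        starts.append([eq] * k)
        starts.append([0.05 * var_y] * (k - 1) + [0.95 * var_y])  # null-heavy
        starts.append([0.8 * var_y / (k - 1)] * (k - 1) + [0.2 * var_y])  # familial-heavy
    starts += [pack(s) for s in extra_starts]

    bounds = [(0.0, ub)] * (k - 1) + [(ve_floor, ub)]
    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            lambda x: nll(unpack(x)),
            x0=np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    va, vf, ve = unpack(best.x)
    return float(va), float(vf), float(ve), -float(best.fun), converged


def _fit_model(
    y: np.ndarray,
    X: np.ndarray,
    model: str,
    A: np.ndarray,
    H: np.ndarray,
    fam_codes: np.ndarray,
    eig=None,
    extra_starts=(),
) -> tuple[float, float, float, float, bool]:
    """ML fit of one model; returns (va, vf, ve, loglik, converged)."""
    n = y.shape[0]
    var_y = float(np.var(y))
    if var_y <= 0:
        var_y = 1e-12
    if model == "E":
        ve, ll = _ols_loglik(y, X)
        return 0.0, 0.0, ve, ll, True
    if model == "AE":
        lik = _AELikelihood(y, X, A, eig=eig)
        nll = lambda full: lik.negloglik(full[[0, 2]])
    else:  # FE or AFE use the family-block backend
        blocks = _family_blocks(A, H, fam_codes)
        lik = _BlockLikelihood(y, X, blocks)
        nll = lik.negloglik
    free = MODEL_COMPONENTS[model]
    va, vf, ve, ll, conv = _maximize(nll, free, var_y, extra_starts=extra_starts)
    del n
    return va, vf, ve, ll, conv


NULL_MODEL = {("AE", "va"): "E", ("AFE", "vf"): "AE", ("AFE", "va"): "FE", ("FE", "vf"): "E"}


def mixture_lrt_pvalue(lrt: float) -> float:
    """P-value of a one-component boundary LRT against the 50:50 mixture of a
    point mass at zero and chi-square(1)."""
    if lrt <= 1e-12:
        return 1.0
    return float(0.5 * chi2.sf(lrt, df=1))


def fit_varcomp(
    y: pd.Series | np.ndarray,
    kin: KinshipMatrix,
    model: str = "AE",
    covariates: pd.DataFrame | np.ndarray | None = None,
    test: str | None = None,
    _eig=None,
) -> VarCompFit:
    """Maximum-likelihood variance components for one probe.

    Parameters
    ----------
    y:
        Residual values; a Series indexed by individual id (aligned against
        the kinship matrix) or an array in kinship order. NaNs are dropped
        and the relationship matrices subset accordingly.
    kin:
        Additive relationship and household matrices.
    model:
        "E" (noise only), "AE" (additive + noise), "FE" (family + noise) or
        "AFE" (additive + family + noise).
    covariates:
        Optional fixed-effect columns (beyond the intercept), aligned like y.
    test:
        Which component the reported p-value tests ("va" or "vf"); defaults
        to "va" for AE, "vf" for AFE.
    """
    if model not in MODEL_COMPONENTS:
        raise ValueError(f"unknown model {model!r}")
    test = test if test is not None else DEFAULT_TEST[model]
    if test is not None and test not in MODEL_COMPONENTS[model]:
        raise ValueError(f"model {model} has no component {test!r} to test")

    ids = kin.ids
    if isinstance(y, pd.Series):
        y = y.reindex(ids)
        yv = y.to_numpy(float)
    else:
        yv = np.asarray(y, dtype=float)
        if yv.shape[0] != len(ids):
            raise ValueError("y length does not match kinship matrix")
    if covariates is not None:
        C = (
            covariates.reindex(ids).to_numpy(float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, float)
        )
        obs = ~np.isnan(yv) & ~np.isnan(C).any(axis=1)
    else:
        C = None
        obs = ~np.isnan(yv)

    n = int(obs.sum())
    if n < 10:
        raise ValueError(f"need at least 10 non-missing individuals, got {n}")
    n_par = 1 + (0 if C is None else C.shape[1]) + len(MODEL_COMPONENTS[model]) + 1
    if n <= n_par:
        raise ValueError("fewer individuals than model parameters")

    yo = yv[obs]
    X = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C[obs]])
    A = kin.A.to_numpy(float)[np.ix_(obs, obs)]
    H = kin.H.to_numpy(float)[np.ix_(obs, obs)]
    # The family-block backend is only needed when Vf enters the model.
    fam_codes = _household_codes(H) if model in ("FE", "AFE") else None
    eig = _eig if (_eig is not None and obs.all()) else None

    null_model = NULL_MODEL.get((model, test)) if test else None
    extra_starts = []
    if null_model is not None:
        va0, vf0, ve0, ll0, conv0 = _fit_model(yo, X, null_model, A, H, fam_codes, eig=eig)
        # Seed the full model from the null solution so the nesting
        # loglik(full) >= loglik(null) holds by construction.
        extra_starts.append((va0, vf0, ve0))
    va, vf, ve, ll, conv = _fit_model(
        yo, X, model, A, H, fam_codes, eig=eig, extra_starts=extra_starts
    )
    if null_model is not None:
        if ll0 >= ll - 1e-9:
            # Null at least as good: the tested component is on the boundary.
            va, vf, ve, ll = va0, vf0, ve0, max(ll, ll0)
            conv = conv and conv0
        p = mixture_lrt_pvalue(2.0 * (ll - ll0))
        null_ll = ll0
    else:
        p = np.nan
        null_ll = np.nan
    return VarCompFit(
        va=va, vf=vf, ve=ve, loglik=ll, null_loglik=null_ll, n_used=n,
        converged=conv, p_value=p, model=model, test=test,
    )


def _household_codes(H: np.ndarray) -> np.ndarray:
    """Connected-component labels of the household/family block structure."""
    n = H.shape[0]
    codes = -np.ones(n, dtype=int)
    code = 0
    for i in range(n):
        if codes[i] >= 0:
            continue
        members = np.nonzero(H[i] > 0)[0]
        group = set(members.tolist()) | {i}
        frontier = list(group)
        while frontier:
            j = frontier.pop()
            for m in np.nonzero(H[j] > 0)[0]:
                if m not in group:
                    group.add(int(m))
                    frontier.append(int(m))
        codes[list(group)] = code
        code += 1
    return codes


def heritability_screen(
    resid: ResidualMatrix | pd.DataFrame,
    kin: KinshipMatrix,
    model: str = "AE",
    covariates: pd.DataFrame | None = None,
    test: str | None = None,
) -> pd.DataFrame:
    """Fit variance components probe by probe.

    Returns a table indexed by probe id with columns n_used, va, vf, ve, h2,
    c2, loglik, p_value and converged. Probes whose fit is rejected (too few
    non-missing individuals) are reported with NaNs and converged=False.
    """
    values = resid.values if isinstance(resid, ResidualMatrix) else resid
    ids = kin.ids
    values = values.loc[:, [c for c in values.columns if c in set(ids)]]
    if list(values.columns) != ids:
        values = values.reindex(columns=ids)

    # Shared eigendecomposition of A for complete-data probes; used by the
    # AE model and by the AE null of the AFE model.
    lam, U = np.linalg.eigh(kin.A.to_numpy(float))
    eig = (np.clip(lam, 0.0, None), U)

    rows = []
    for probe_id, row in values.iterrows():
        try:
            fit = fit_varcomp(
                row.to_numpy(float), kin, model=model, covariates=covariates,
                test=test, _eig=eig,
            )
            rows.append(
                (probe_id, fit.n_used, fit.va, fit.vf, fit.ve, fit.h2, fit.c2,
                 fit.loglik, fit.p_value, fit.converged)
            )
        except ValueError:
            rows.append((probe_id, int(row.notna().sum()), *[np.nan] * 7, False))
    return pd.DataFrame(
        rows,
        columns=["probe_id", "n_used", "va", "vf", "ve", "h2", "c2", "loglik",
                 "p_value", "converged"],
    ).set_index("probe_id")


class HeritabilityScreen(BaseEstimator):
    """Genome-wide per-probe variance-component screen.

    Parameters
    ----------
    model:
        "AE" (default) or "AFE".
    household:
        Household definition for the family matrix ("family" or "offspring").
    test:
        Component tested by the reported p-values (model default when None).

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-probe estimates (h2, c2, variances, p-values, convergence).
    kinship_ : KinshipMatrix
        Relationship matrices derived from the pedigree given to :meth:`fit`.
    """

    def __init__(self, model: str = "AE", household: str = "family",
                 test: str | None = None):
        self.model = model
        self.household = household
        self.test = test

    def fit(self, resid: ResidualMatrix | pd.DataFrame, ped: pd.DataFrame,
            covariates: pd.DataFrame | None = None):
        self.kinship_ = additive_relationship(ped, household=self.household)
        self.results_ = heritability_screen(
            resid, self.kinship_, model=self.model, covariates=covariates,
            test=self.test,
        )
        return self


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def zero_fraction_bound(h2_estimates, eps: float = 1e-6) -> tuple[float, float]:
    """Lower bound on the percentage of probes with a genetic component.

    ``p0`` is the fraction of estimates at the zero boundary (below ``eps``).
    Because a true-zero component lands on the boundary about half the time,
    the observed boundary fraction is about half the true null fraction, so
    ``bound = max(0, 100 - 2 * p0 * 100)`` percent of probes must carry a
    genetic component.
    """
    h2 = np.asarray(h2_estimates, dtype=float)
    h2 = h2[~np.isnan(h2)]
    if h2.size == 0:
        raise ValueError("no heritability estimates given")
    if np.any((h2 < 0) | (h2 > 1)):
        raise ValueError("h2 estimates must lie in [0, 1]")
    p0 = float((h2 < eps).mean())
    bound = max(0.0, 100.0 - 200.0 * p0)
    return p0, bound
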