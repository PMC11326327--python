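"""Regression engine: cluster-robust OLS and logit, within-family transforms,
and the sibling-difference (conditional logistic) model.

All covariances are CR1 cluster sandwiches,

    V = c · (X'X)^{-1} [ Σ_g (X_g'u_g)(X_g'u_g)' ] (X'X)^{-1},
    c = G/(G−1) · (n−1)/(n−k),

clustered on sibships.  With every observation its own cluster this reduces
exactly to the HC1 heteroskedasticity-robust estimator.  Confidence
intervals are normal-based, estimate ± 1.959964·SE, and p-values use the
normal reference — matching how the study's estimates and CIs are reported.

The family-fixed-effect path demeans every variable within sibship
(singleton families dropped, family-constant columns removed) and charges
the absorbed family means to the degrees of freedom in the small-sample
factor.  The binary-outcome analogue is the conditional logistic likelihood
over outcome-discordant sibships ("sibling difference method").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z975",
    "RegressionResult",
    "ols_cluster",
    "within_transform",
    "ols_fe_cluster",
    "logistic_cluster",
    "sibling_difference_logit",
]

log = logging.getLogger(__name__)

#: the 97.5% normal quantile used for every 95% CI
Z975 = 1.959964


@dataclass
class RegressionResult:
    """Coefficients with cluster-robust uncertainty."""

    params: pd.Series
    se: pd.Series
    n_obs: int
    n_clusters: int
    model: str                       # OLS | LOG | OLS+FE | CLOGIT
    n_dropped: int = 0               # singleton families / concordant sibships
    cov: np.ndarray | None = None

    @property
    def ci_low(self) -> pd.Series:
        return self.params - Z975 * self.se

    @property
    def ci_high(self) -> pd.Series:
        return self.params + Z975 * self.se

    @property
    def pvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.params / self.se, np.inf)
            z = np.where(self.params == 0, 0.0, z)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def coef(self, name: str) -> float:
        return float(self.params[name])


def _as_matrix(X, add_const: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float).copy()
    if add_const and "const" not in X.columns:
        X.insert(0, "const", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    M = X.to_numpy()
    rank = np.linalg.matrix_rank(M)
    if rank < X.shape[1]:
        # identify offenders via the QR diagonal
        _, R = np.linalg.qr(M)
        diag = np.abs(np.diag(R))
        bad = [c for c, d in zip(X.columns, diag) if d < 1e-8 * max(diag.max(), 1.0)]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'unidentified'}"
        )


def _cluster_meat(scores: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Σ_g s_g s_g' where s_g is the within-cluster score sum."""
    k = scores.shape[1]
    sums = np.zeros((codes.max() + 1, k))
    np.add.at(sums, codes, scores)
    return sums.T @ sums


def _cr1(n: int, k: int, G: int) -> float:
    return (G / (G - 1)) * ((n - 1) / (n - k))


def _sandwich(bread: np.ndarray, scores: np.ndarray,
              codes: np.ndarray, n: int, k_dof: int) -> np.ndarray:
    G = codes.max() + 1
    meat = _cluster_meat(scores, codes)
    return _cr1(n, k_dof, G) * bread @ meat @ bread


def ols_cluster(y, X, cluster_ids, add_const: bool = True,
                k_dof: int | None = None, model_tag: str = "OLS",
                n_dropped: int = 0) -> RegressionResult:
    """OLS with a CR1 cluster sandwich covariance.

    ``k_dof`` overrides the parameter count charged in the small-sample
    factor (used by the fixed-effect path to account for absorbed family
    means).
    """
    X = _as_matrix(X, add_const)
    y = np.asarray(y, dtype=float)
    codes, _ = pd.factorize(np.asarray(cluster_ids))
    _check_rank(X)
    M = X.to_numpy()
    n, k = M.shape
    XtX_inv = np.linalg.inv(M.T @ M)
    beta = XtX_inv @ (M.T @ y)
    resid = y - M @ beta
    cov = _sandwich(XtX_inv, M * resid[:, None], codes, n, k_dof or k)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return RegressionResult(
        params=pd.Series(beta, index=X.columns),
        se=pd.Series(se, index=X.columns),
        n_obs=n, n_clusters=int(codes.max() + 1),
        model=model_tag, n_dropped=n_dropped, cov=cov,
    )


def within_transform(y, X, family_ids
                     ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, int]:
    """Demean every variable within family; drop singleton families and
    columns made constant (zero) by the transform.

    Returns ``(y_w, X_w, family_codes, n_singletons_dropped)``.  The
    transformed design carries no intercept: it is absorbed by the family
    means.
    """
    X = pd.DataFrame(X).astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    fam = pd.Series(np.asarray(family_ids), index=X.index)
    sizes = fam.map(fam.value_counts())
    keep = sizes >= 2
    n_singletons = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no families with >= 2 members after restriction")
    y, X, fam = y[keep], X[keep], fam[keep]

    g = X.groupby(fam.to_numpy())
    Xw = X - g.transform("mean")
    yw = (y - y.groupby(fam.to_numpy()).transform("mean")).to_numpy()
    const_cols = [c for c in Xw.columns if np.abs(Xw[c].to_numpy()).max() < 1e-10]
    if const_cols:
        log.info("within_transform: dropping family-constant columns %s", const_cols)
        Xw = Xw.drop(columns=const_cols)
    codes, _ = pd.factorize(fam.to_numpy())
    return yw, Xw, codes, n_singletons


def ols_fe_cluster(y, X, family_ids) -> RegressionResult:
    """Family-fixed-effect OLS: within transform, then cluster-robust OLS
    with clusters = families and degrees of freedom charged for the
    absorbed family means."""
    yw, Xw, codes, n_single = within_transform(y, X, family_ids)
    if Xw.shape[1] == 0:
        raise ValueError("no within-family variation left in the design")
    n_fam = int(codes.max() + 1)
    k_dof = Xw.shape[1] + n_fam
    res = ols_cluster(yw, Xw, codes, add_const=False,
                      k_dof=min(k_dof, len(yw) - 1),
                      model_tag="OLS+FE", n_dropped=n_single)
    return res


def _fit_logit_mle(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    import warnings as _warnings

    model = sm.Logit(y, X)
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=100)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "perfect or quasi-perfect separation: the logistic information "
            "matrix is singular at the maximum-likelihood boundary"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic regression failed to converge")
    p = res.predict(X)
    if np.any(p < 1e-8) or np.any(p > 1 - 1e-8):
        raise RuntimeError(
            "perfect or quasi-perfect separation: fitted probabilities pinned "
            "to 0/1; the log-odds for some covariate pattern are unbounded"
        )
    return res, np.asarray(p)


def logistic_cluster(y, X, cluster_ids, add_const: bool = True) -> RegressionResult:
    """Maximum-likelihood logit with a CR1 cluster sandwich on the score
    contributions ``x_i (y_i − p̂_i)``; coefficients are log-odds."""
    X = _as_matrix(X, add_const)
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    codes, _ = pd.factorize(np.asarray(cluster_ids))
    _check_rank(X)
    res, p = _fit_logit_mle(y, X)
    M = X.to_numpy()
    n, k = M.shape
    W = p * (1 - p)
    bread = np.linalg.inv((M * W[:, None]).T @ M)        # inverse information
    scores = M * (y - p)[:, None]
    cov = _sandwich(bread, scores, codes, n, k)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return RegressionResult(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        se=pd.Series(se, index=X.columns),
        n_obs=n, n_clusters=int(codes.max() + 1),
        model="LOG", cov=cov,
    )


def sibling_difference_logit(y, X, family_ids) -> RegressionResult:
    """Conditional (fixed-effects) logistic regression over sibships.

    Only outcome-discordant families carry information; concordant families
    are dropped with a logged count, as are covariates constant within every
    family (they are conditioned out of the likelihood).  Standard errors
    come from the conditional maximum likelihood; families are independent,
    so these are cluster-valid at the sibship level.
    """
    from statsmodels.discrete.conditional_models import ConditionalLogit

    X = pd.DataFrame(X).astype(float).copy()
    if "const" in X.columns:
        X = X.drop(columns="const")      # absorbed by the family stratum
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    fam = pd.Series(np.asarray(family_ids), index=X.index)

    disc = y.groupby(fam.to_numpy()).transform(lambda s: s.nunique() > 1)
    n_concordant = int(fam[~disc].nunique())
    if not disc.any():
        raise ValueError("no outcome-discordant families: the sibling-"
                         "difference model has no information")
    log.info("sibling_difference_logit: dropping %d concordant families",
             n_concordant)
    y, X, fam = y[disc], X[disc], fam[disc]

    g = X.groupby(fam.to_numpy())
    within_sd = (X - g.transform("mean")).abs().max(axis=0)
    const_cols = within_sd.index[within_sd < 1e-10].tolist()
    if const_cols:
        log.info("sibling_difference_logit: dropping family-constant "
                 "columns %s", const_cols)
        X = X.drop(columns=const_cols)
    if X.shape[1] == 0:
        raise ValueError("no within-family covariate variation")

    model = ConditionalLogit(y.to_numpy(), X.to_numpy(), groups=fam.to_numpy())
    res = model.fit(disp=0, method="newton", tol=1e-12, maxiter=200)
    params = pd.Series(np.asarray(res.params), index=X.columns)
    se = pd.Series(np.asarray(res.bse), index=X.columns)
    return RegressionResult(
        params=params, se=se,
        n_obs=int(len(y)), n_clusters=int(fam.nunique()),
        model="CLOGIT", n_dropped=n_concordant,
        cov=np.asarray(res.cov_params()),
    )
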