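"""One-sample Mendelian randomization: two-stage least squares with optional
family fixed effects, first-stage diagnostics, and a two-stage logistic
variant for binary outcomes.

The estimand is the effect of a 1-SD change in the exposure (years of
education) on the outcome, in outcome-SD units (continuous) or log-odds
(binary).  The instrument is the polygenic score.  In within-sibship mode
all variables are demeaned within family before both stages, which removes
anything shared by siblings — parental genotypes (dynastic effects),
assortative-mating-induced correlations, subpopulation membership, and any
family-level confounder — leaving only the random segregation of alleles
between siblings to identify the effect.

Covariance follows the proper 2SLS form: residuals are taken from the
*observed* exposure at the 2SLS coefficients, while the bread uses the
instrument-projected design.  All standard errors are CR1
sibship-clustered (see :mod:`sibmr.regress`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regress import (
    Z975,
    RegressionResult,
    _as_matrix,
    _check_rank,
    _sandwich,
    logistic_cluster,
    ols_cluster,
    sibling_difference_logit,
    within_transform,
)

__all__ = ["MR1Result", "tsls", "first_stage_diagnostics", "tsps_logit"]

#: conventional weak-instrument warning threshold on the first-stage F
WEAK_F_THRESHOLD = 10.0


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass
class MR1Result:
    """A one-sample MR estimate with first-stage diagnostics."""

    estimate: float            # SD per SD, or log-OR per SD for binary
    se: float
    first_stage_F: float
    first_stage_partial_r2: float
    n_obs: int
    n_families: int
    mode: str                  # "population" | "within-sibship"
    model: str                 # 2SLS | 2SPS-LOGIT | 2SPS-CLOGIT

    @property
    def ci_low(self) -> float:
        return self.estimate - Z975 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z975 * self.se

    @property
    def pvalue(self) -> float:
        if self.se == 0:
            return 0.0 if self.estimate else 1.0
        return float(2 * stats.norm.sf(abs(self.estimate / self.se)))

    @property
    def odds_ratio(self) -> float:
        """exp(estimate); meaningful for the binary-outcome variants."""
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _prepare(y, exposure, instrument, covariates, cluster_ids, family_fe):
    """Assemble (y, x, z, W, cluster codes, dof offset, n_dropped)."""
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    y = np.asarray(y, dtype=float)
    W = (pd.DataFrame(covariates).astype(float).reset_index(drop=True)
         if covariates is not None else pd.DataFrame(index=range(len(y))))
    if x.std() == 0 or z.std() == 0:
        raise ValueError("instrument and exposure must be non-degenerate")

    if family_fe:
        fam = np.asarray(cluster_ids)
        stacked = W.copy()
        stacked["_x"] = x
        stacked["_z"] = z
        yw, Sw, codes, n_single = within_transform(y, stacked, fam)
        if "_z" not in Sw.columns or "_x" not in Sw.columns:
            raise ValueError("exposure or instrument has no within-family variation")
        x, z = Sw.pop("_x").to_numpy(), Sw.pop("_z").to_numpy()
        dof_extra = int(codes.max() + 1)       # absorbed family means
        return yw, x, z, Sw, codes, dof_extra, n_single, False
    codes, _ = pd.factorize(np.asarray(cluster_ids))
    return y, x, z, W, codes, 0, 0, True


def tsls(y, exposure, instrument, covariates=None, cluster_ids=None,
         family_fe: bool = False,
         weak_f_threshold: float = WEAK_F_THRESHOLD) -> MR1Result:
    """Two-stage least squares of ``y`` on ``exposure`` instrumented by
    ``instrument``, with exogenous ``covariates`` and sibship-clustered CR1
    standard errors.

    With ``family_fe`` every variable is within-family demeaned first and
    clusters are the families.  A first-stage cluster-robust F below
    ``weak_f_threshold`` raises a :class:`WeakInstrumentWarning` (never an
    error).
    """
    if cluster_ids is None:
        cluster_ids = np.arange(len(np.asarray(y)))
    yv, x, z, W, codes, dof_extra, n_dropped, add_const = _prepare(
        y, exposure, instrument, covariates, cluster_ids, family_fe)

    D = _as_matrix(W.assign(exposure=x)[["exposure", *W.columns]], add_const)
    Zm = _as_matrix(W.assign(instrument=z)[["instrument", *W.columns]], add_const)
    _check_rank(Zm)
    Z_ = Zm.to_numpy()
    D_ = D.to_numpy()
    n, k = D_.shape

    ZtZ_inv = np.linalg.inv(Z_.T @ Z_)
    Dhat = Z_ @ (ZtZ_inv @ (Z_.T @ D_))         # instrument-projected design
    bread = np.linalg.inv(Dhat.T @ D_)
    beta = bread @ (Dhat.T @ yv)
    resid = yv - D_ @ beta                       # residuals at observed exposure
    cov = _sandwich(bread, Dhat * resid[:, None], codes, n,
                    min(k + dof_extra, n - 1))
    j = list(D.columns).index("exposure")
    est = float(beta[j])
    se = float(np.sqrt(max(cov[j, j], 0.0)))

    F, pr2 = _first_stage(x, z, W, codes, dof_extra, add_const)
    if F < weak_f_threshold:
        warnings.warn(f"first-stage F = {F:.2f} < {weak_f_threshold:g}: "
                      "possible weak-instrument bias", WeakInstrumentWarning)
    return MR1Result(
        estimate=est, se=se, first_stage_F=F, first_stage_partial_r2=pr2,
        n_obs=n, n_families=int(codes.max() + 1),
        mode="within-sibship" if family_fe else "population", model="2SLS",
    )


def _first_stage(x, z, W: pd.DataFrame, codes, dof_extra, add_const):
    """Cluster-robust Wald F for the instrument plus its partial r²."""
    design = W.assign(instrument=z)[["instrument", *W.columns]]
    res = ols_cluster(x, design, codes, add_const=add_const,
                      k_dof=min(design.shape[1] + add_const + dof_extra,
                                len(x) - 1))
    b, s = res.coef("instrument"), float(res.se["instrument"])
    F = float((b / s) ** 2) if s > 0 else np.inf

    # partial r²: squared correlation of x and z after partialling out W
    def _resid(v):
        if W.shape[1] == 0 and not add_const:
            return v
        M = _as_matrix(W, add_const).to_numpy()
        coef, *_ = np.linalg.lstsq(M, v, rcond=None)
        return v - M @ coef

    rx, rz = _resid(x), _resid(z)
    denom = np.sqrt((rx**2).sum() * (rz**2).sum())
    pr2 = float((rx @ rz) ** 2 / denom**2) if denom > 0 else 0.0
    return F, pr2


def first_stage_diagnostics(exposure, instrument, covariates=None,
                            cluster_ids=None, family_fe: bool = False
                            ) -> tuple[float, float]:
    """(cluster-robust Wald F, partial r²) of the instrument in the first
    stage, under the same transform/covariate handling as :func:`tsls`."""
    if cluster_ids is None:
        cluster_ids = np.arange(len(np.asarray(exposure)))
    dummy_y = np.asarray(exposure, dtype=float)
    _, x, z, W, codes, dof_extra, _, add_const = _prepare(
        dummy_y, exposure, instrument, covariates, cluster_ids, family_fe)
    return _first_stage(x, z, W, codes, dof_extra, add_const)


def tsps_logit(y_binary, exposure, instrument, covariates=None,
               cluster_ids=None, family_fe: bool = False,
               weak_f_threshold: float = WEAK_F_THRESHOLD) -> MR1Result:
    """Two-stage predictor substitution for a binary outcome.

    Stage 1 is the linear first stage of :func:`tsls`; stage 2 is a logistic
    regression of the outcome on the fitted exposure (cluster-robust), or a
    conditional logistic within sibships when ``family_fe``.  The estimate
    is a log-odds ratio per SD of exposure; ``odds_ratio``/``or_ci`` give the
    exponentiated scale.  As with any two-stage logit the estimand is an
    approximate, non-collapsible OR.
    """
    if cluster_ids is None:
        cluster_ids = np.arange(len(np.asarray(y_binary)))
    yb = np.asarray(y_binary, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    W = (pd.DataFrame(covariates).astype(float).reset_index(drop=True)
         if covariates is not None else pd.DataFrame(index=range(len(yb))))
    fam = np.asarray(cluster_ids)

    if family_fe:
        _, xw, zw, Ww, codes, dof_extra, _, _ = _prepare(
            yb, x, z, W, fam, True)
        design = Ww.assign(instrument=zw)[["instrument", *Ww.columns]]
        first = ols_cluster(xw, design, codes, add_const=False)
        xhat_w = design.to_numpy() @ first.params.to_numpy()
        # conditional logit needs rows aligned with the (non-singleton) sample
        sizes = pd.Series(fam).map(pd.Series(fam).value_counts())
        keep = (sizes >= 2).to_numpy()
        stage2 = pd.DataFrame({"exposure_hat": xhat_w})
        for c in Ww.columns:
            stage2[c] = Ww[c].to_numpy()
        res: RegressionResult = sibling_difference_logit(
            yb[keep], stage2, fam[keep])
        model = "2SPS-CLOGIT"
        n_fam = res.n_clusters
        F, pr2 = _first_stage(xw, zw, Ww, codes, dof_extra, False)
    else:
        codes, _ = pd.factorize(fam)
        design = W.assign(instrument=z)[["instrument", *W.columns]]
        first = ols_cluster(x, design, codes, add_const=True)
        M = _as_matrix(design, True).to_numpy()
        xhat = M @ first.params.to_numpy()
        stage2 = W.assign(exposure_hat=xhat)[["exposure_hat", *W.columns]]
        res = logistic_cluster(yb, stage2, codes, add_const=True)
        model = "2SPS-LOGIT"
        n_fam = int(codes.max() + 1)
        F, pr2 = _first_stage(x, z, W, codes, 0, True)

    if F < weak_f_threshold:
        warnings.warn(f"first-stage F = {F:.2f} < {weak_f_threshold:g}: "
                      "possible weak-instrument bias", WeakInstrumentWarning)
    return MR1Result(
        estimate=res.coef("exposure_hat"), se=float(res.se["exposure_hat"]),
        first_stage_F=F, first_stage_partial_r2=pr2,
        n_obs=res.n_obs, n_families=n_fam,
        mode="within-sibship" if family_fe else "population", model=model,
    )
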