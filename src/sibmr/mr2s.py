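"""Two-sample Mendelian randomization from GWAS summary statistics.

Operates on harmonized per-variant pairs (exposure beta/SE, outcome beta/SE,
effect-allele frequency, per-trait sample sizes).  Estimators:

* **IVW** — inverse-variance-weighted slope through the origin; the reported
  SE switches to a multiplicative random-effects (overdispersed) form when
  Cochran's Q exceeds its degrees of freedom.
* **MR-Egger** — weighted regression with an intercept; a nonzero intercept
  indicates directional pleiotropy.  Pairs are oriented so every exposure
  beta is non-negative before fitting.
* **Weighted median / weighted mode** — robust estimators over per-variant
  Wald ratios, with bootstrap standard errors.
* **Steiger directionality** — compares instrument variance explained in the
  exposure vs the outcome.

A small generative model for summary statistics (``simulate_summary_stats``)
provides desk-scale inputs with controllable causal effect, pleiotropy and
heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regress import Z975

__all__ = [
    "MR2Estimate",
    "harmonize",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "steiger",
    "simulate_summary_stats",
]

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

PAIR_COLUMNS = ["variant_id", "effect_allele", "other_allele", "eaf",
                "beta_exp", "se_exp", "beta_out", "se_out", "n_exp", "n_out"]


@dataclass
class MR2Estimate:
    method: str
    estimate: float
    se: float
    n_variants: int
    Q: float | None = None
    Q_p: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

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


def harmonize(exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame,
              palindrome_maf_limit: float = 0.42) -> pd.DataFrame:
    """Align outcome betas to the exposure's effect allele.

    Variants whose outcome coding is swapped get ``beta`` negated and ``eaf``
    complemented; palindromic (A/T, C/G) variants with intermediate frequency
    (eaf strictly between ``palindrome_maf_limit`` and its complement) are
    dropped as strand-ambiguous, as are variants absent from either table or
    with irreconcilable alleles.  Applying the procedure to an already
    harmonized pair changes nothing.
    """
    exp = exposure_stats.set_index("variant_id")
    out = outcome_stats.set_index("variant_id")
    rows = []
    for vid in exp.index:
        if vid not in out.index:
            continue
        e, o = exp.loc[vid], out.loc[vid]
        ea, oa = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        if (ea, oa) in PALINDROMIC:
            f = float(e["eaf"])
            if palindrome_maf_limit < f < 1 - palindrome_maf_limit:
                continue
        o_ea, o_oa = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        if (o_ea, o_oa) == (ea, oa):
            b_out, f_out = float(o["beta"]), float(o.get("eaf", np.nan))
        elif (o_ea, o_oa) == (oa, ea):
            b_out = -float(o["beta"])
            f_out = 1 - float(o.get("eaf", np.nan))
        else:
            continue
        rows.append({
            "variant_id": vid, "effect_allele": ea, "other_allele": oa,
            "eaf": float(e["eaf"]),
            "beta_exp": float(e["beta"]), "se_exp": float(e["se"]),
            "beta_out": b_out, "se_out": float(o["se"]),
            "n_exp": float(e.get("n", np.nan)), "n_out": float(o.get("n", np.nan)),
            "eaf_out": f_out,
        })
    if not rows:
        raise ValueError("no variants overlap after harmonization")
    return pd.DataFrame(rows)


def _weights(pairs: pd.DataFrame) -> np.ndarray:
    return 1.0 / pairs["se_out"].to_numpy() ** 2


def ivw(pairs: pd.DataFrame) -> MR2Estimate:
    """Inverse-variance-weighted estimate: the slope of a
    weights-through-origin regression of outcome betas on exposure betas
    with weights 1/se_out².

    With a single variant this is the Wald ratio.  When Q/df > 1 the SE is
    inflated by sqrt(Q/df) (multiplicative random effects); otherwise the
    fixed-effect SE is reported.
    """
    bx = pairs["beta_exp"].to_numpy()
    by = pairs["beta_out"].to_numpy()
    w = _weights(pairs)
    denom = np.sum(w * bx**2)
    beta = float(np.sum(w * bx * by) / denom)
    se_fixed = float(np.sqrt(1.0 / denom))
    J = len(pairs)
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    if J >= 2:
        df = J - 1
        Q_p = float(stats.chi2.sf(Q, df))
        se = se_fixed * max(1.0, np.sqrt(Q / df))
    else:
        Q_p, se = None, se_fixed
    return MR2Estimate("IVW", beta, se, J, Q=Q if J >= 2 else None, Q_p=Q_p)


def mr_egger(pairs: pd.DataFrame) -> MR2Estimate:
    """MR-Egger: weighted regression of outcome on exposure betas *with* an
    intercept; the intercept estimates the average directional pleiotropy.

    Pairs are oriented so every exposure beta is non-negative (outcome betas
    flipped along with them).  SEs scale with the estimated residual
    dispersion (plain weighted least squares) and tests use the t
    distribution on J−2 df, so the intercept test holds its nominal size
    under no pleiotropy.
    """
    J = len(pairs)
    if J < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    sign = np.where(pairs["beta_exp"].to_numpy() < 0, -1.0, 1.0)
    bx = pairs["beta_exp"].to_numpy() * sign
    by = pairs["beta_out"].to_numpy() * sign
    w = _weights(pairs)

    X = np.column_stack([np.ones(J), bx])
    WX = X * w[:, None]
    XtWX_inv = np.linalg.inv(X.T @ WX)
    coef = XtWX_inv @ (WX.T @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (J - 2))
    cov = XtWX_inv * sigma2
    se = np.sqrt(np.diag(cov))
    tdist = stats.t(J - 2)
    if se[0] > 0:
        intercept_p = float(2 * tdist.sf(abs(coef[0] / se[0])))
    else:
        intercept_p = 1.0 if coef[0] == 0 else 0.0
    return MR2Estimate(
        "MR-Egger", float(coef[1]), float(se[1]), J,
        intercept=float(coef[0]), intercept_se=float(se[0]),
        intercept_p=intercept_p,
    )


def _wald_ratios(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx = pairs["beta_exp"].to_numpy()
    by = pairs["beta_out"].to_numpy()
    sx = pairs["se_exp"].to_numpy()
    sy = pairs["se_out"].to_numpy()
    ratio = by / bx
    # first-order delta-method SE of the per-variant ratio
    se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return ratio, se


def _weighted_median(ratio: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratio)
    r, w = ratio[order], w[order]
    cum = np.cumsum(w) - 0.5 * w        # midpoint cumulative weights
    cum /= w.sum()
    return float(np.interp(0.5, cum, r))


def weighted_median(pairs: pd.DataFrame, n_boot: int = 200,
                    seed: int | None = None) -> MR2Estimate:
    """Weighted median of per-variant Wald ratios (weights = inverse ratio
    variance); consistent when at least half the total weight comes from
    valid instruments.  SE by parametric bootstrap."""
    if len(pairs) < 3:
        raise ValueError("weighted median requires at least 3 variants")
    ratio, se_r = _wald_ratios(pairs)
    w = 1.0 / se_r**2
    est = _weighted_median(ratio, w)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    bx, by = pairs["beta_exp"].to_numpy(), pairs["beta_out"].to_numpy()
    sx, sy = pairs["se_exp"].to_numpy(), pairs["se_out"].to_numpy()
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        r = bys / bxs
        s = np.sqrt(sy**2 / bxs**2 + bys**2 * sx**2 / bxs**4)
        boot[b] = _weighted_median(r, 1.0 / s**2)
    return MR2Estimate("weighted median", est, float(boot.std()), len(pairs))


def weighted_mode(pairs: pd.DataFrame, bandwidth_factor: float = 1.0,
                  n_boot: int = 200, seed: int | None = None) -> MR2Estimate:
    """Mode of the weighted kernel-smoothed density of Wald ratios.

    Normal kernel; bandwidth = ``bandwidth_factor`` × a MAD-based normal
    reference rule.  Consistent when the largest group of variants sharing a
    ratio are the valid ones.  Invariant to duplicating every pair.  SE by
    parametric bootstrap.
    """
    if len(pairs) < 3:
        raise ValueError("weighted mode requires at least 3 variants")
    ratio, se_r = _wald_ratios(pairs)
    w = 1.0 / se_r**2

    def _mode(r: np.ndarray, wt: np.ndarray) -> float:
        mad = np.median(np.abs(r - np.median(r)))
        scale = max(1.4826 * mad, 1e-6 * max(np.abs(r).max(), 1.0))
        h = bandwidth_factor * 1.06 * scale * len(r) ** (-0.2)
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
        dens = np.sum(
            wt[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2),
            axis=1,
        )
        return float(grid[np.argmax(dens)])

    est = _mode(ratio, w)
    rng = np.random.default_rng(seed)
    bx, by = pairs["beta_exp"].to_numpy(), pairs["beta_out"].to_numpy()
    sx, sy = pairs["se_exp"].to_numpy(), pairs["se_out"].to_numpy()
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        r = bys / bxs
        s = np.sqrt(sy**2 / bxs**2 + bys**2 * sx**2 / bxs**4)
        boot[b] = _mode(r, 1.0 / s**2)
    return MR2Estimate("weighted mode", est, float(boot.std()), len(pairs))


def steiger(pairs: pd.DataFrame, n_exp: float | None = None,
            n_out: float | None = None) -> tuple[bool, float]:
    """Steiger directionality test.

    Per-variant variance explained is approximated on the standardized-trait
    scale as ``2·eaf·(1−eaf)·beta²``; totals are compared as correlations via
    a Fisher-z test using the smaller of the two sample sizes.  Returns
    ``(direction_ok, p)`` where ``direction_ok`` means the instruments
    explain more variance in the exposure than in the outcome (the assumed
    causal direction).
    """
    if pairs["eaf"].isna().any():
        raise ValueError("Steiger test needs effect-allele frequencies")
    eaf = pairs["eaf"].to_numpy()
    het = 2 * eaf * (1 - eaf)
    r2_exp = float(np.sum(het * pairs["beta_exp"].to_numpy() ** 2))
    r2_out = float(np.sum(het * pairs["beta_out"].to_numpy() ** 2))
    n_exp = float(n_exp if n_exp is not None else np.nanmin(pairs["n_exp"]))
    n_out = float(n_out if n_out is not None else np.nanmin(pairs["n_out"]))
    if not (np.isfinite(n_exp) and np.isfinite(n_out)):
        raise ValueError("Steiger test needs per-trait sample sizes")
    r_exp = np.sqrt(min(r2_exp, 1.0 - 1e-12))
    r_out = np.sqrt(min(r2_out, 1.0 - 1e-12))
    n = min(n_exp, n_out)
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(2.0 / (n - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return bool(r2_exp > r2_out), p


def simulate_summary_stats(n_variants: int = 50, theta: float = -0.2,
                           n_exp: int = 200_000, n_out: int = 50_000,
                           pleiotropy_intercept: float = 0.0,
                           heterogeneity_sd: float = 0.0,
                           mean_beta: float = 0.08, sd_beta: float = 0.02,
                           seed: int | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate exposure/outcome GWAS summary-statistic tables.

    True exposure effects are positive (effect alleles oriented
    trait-increasing, as published score files are), drawn
    ``|N(mean_beta, sd_beta)|``; true outcome effects are
    ``theta·beta_exp + pleiotropy_intercept + N(0, heterogeneity_sd)``.
    Observed betas add sampling noise at SE ≈ 1/√n on the standardized
    scale.  Alleles are non-palindromic; tables are keyed for
    :func:`harmonize`.
    """
    rng = np.random.default_rng(seed)
    vid = [f"rs{j:05d}" for j in range(n_variants)]
    eaf = rng.uniform(0.1, 0.9, n_variants)
    se_exp = np.full(n_variants, 1.0 / np.sqrt(n_exp))
    se_out = np.full(n_variants, 1.0 / np.sqrt(n_out))
    true_bx = np.abs(rng.normal(mean_beta, sd_beta, n_variants))
    true_by = (theta * true_bx + pleiotropy_intercept
               + heterogeneity_sd * rng.standard_normal(n_variants))
    exposure = pd.DataFrame({
        "variant_id": vid, "effect_allele": "A", "other_allele": "G",
        "eaf": eaf, "beta": true_bx + rng.normal(0, se_exp),
        "se": se_exp, "n": n_exp,
    })
    outcome = pd.DataFrame({
        "variant_id": vid, "effect_allele": "A", "other_allele": "G",
        "eaf": eaf, "beta": true_by + rng.normal(0, se_out),
        "se": se_out, "n": n_out,
    })
    return exposure, outcome
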