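"""Cross-cohort meta-analysis with a heterogeneity-gated model choice.

Per-study estimates are pooled by fixed-effect inverse-variance weighting
unless heterogeneity is detected — Cochran's Q p-value below ``q_alpha``
*and* I² above ``i2_threshold`` — in which case a DerSimonian–Laird
random-effects model is used.  Odds ratios are pooled on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .regress import Z975

__all__ = [
    "MetaResult",
    "se_from_ci",
    "fixed_effect_meta",
    "random_effects_meta_dl",
    "select_and_pool",
]


@dataclass
class MetaResult:
    pooled: float
    se: float
    Q: float
    Q_p: float
    I2: float                      # percent, in [0, 100]
    tau2: float
    model: str                     # "fixed" | "random-DL"
    n_studies: int

    @property
    def ci_low(self) -> float:
        return self.pooled - Z975 * self.se

    @property
    def ci_high(self) -> float:
        return self.pooled + Z975 * self.se

    @property
    def pvalue(self) -> float:
        if self.se == 0:
            return 0.0 if self.pooled else 1.0
        return float(2 * stats.norm.sf(abs(self.pooled / self.se)))


def se_from_ci(lci: float, uci: float, level: float = 0.95,
               scale: str = "identity") -> float:
    """Recover a standard error from a symmetric confidence interval.

    ``scale="log"`` treats the bounds as an odds-ratio interval and works on
    the natural-log scale (both bounds must be positive).
    """
    if uci <= lci:
        raise ValueError("upper CI bound must exceed the lower bound")
    if scale == "log":
        if lci <= 0 or uci <= 0:
            raise ValueError("odds-ratio CI bounds must be positive on log scale")
        lci, uci = np.log(lci), np.log(uci)
    elif scale != "identity":
        raise ValueError(f"unknown scale {scale!r}")
    z = stats.norm.ppf(0.5 + level / 2)
    return float((uci - lci) / (2 * z))


def _validate(b: np.ndarray, s: np.ndarray) -> None:
    if len(b) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    if np.any(s <= 0):
        raise ValueError("study standard errors must be positive")


def _q_i2(b: np.ndarray, w: np.ndarray) -> tuple[float, float, float, float]:
    pooled = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - pooled) ** 2))
    df = len(b) - 1
    Q_p = float(stats.chi2.sf(Q, df))
    I2 = float(max(0.0, (Q - df) / Q) * 100) if Q > 0 else 0.0
    return pooled, Q, Q_p, I2


def fixed_effect_meta(b: Sequence[float], se: Sequence[float]) -> MetaResult:
    """Fixed-effect inverse-variance pooling: weights 1/s²."""
    b, s = np.asarray(b, float), np.asarray(se, float)
    _validate(b, s)
    w = 1.0 / s**2
    pooled, Q, Q_p, I2 = _q_i2(b, w)
    return MetaResult(pooled, float(np.sum(w) ** -0.5), Q, Q_p, I2,
                      tau2=0.0, model="fixed", n_studies=len(b))


def random_effects_meta_dl(b: Sequence[float], se: Sequence[float]) -> MetaResult:
    """DerSimonian–Laird random effects.

    τ² = max(0, (Q − df) / (Σw − Σw²/Σw)) from the fixed-effect weights;
    studies are re-weighted by 1/(s² + τ²).  Reduces exactly to the
    fixed-effect result when Q ≤ df.
    """
    b, s = np.asarray(b, float), np.asarray(se, float)
    _validate(b, s)
    w = 1.0 / s**2
    _, Q, Q_p, I2 = _q_i2(b, w)
    df = len(b) - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = float(max(0.0, (Q - df) / denom))
    w_star = 1.0 / (s**2 + tau2)
    pooled = float(np.sum(w_star * b) / np.sum(w_star))
    return MetaResult(pooled, float(np.sum(w_star) ** -0.5), Q, Q_p, I2,
                      tau2=tau2, model="random-DL", n_studies=len(b))


def select_and_pool(b: Sequence[float], se: Sequence[float],
                    q_alpha: float = 0.05,
                    i2_threshold: float = 50.0) -> MetaResult:
    """Pool with the study's model-selection rule: random effects only when
    *both* the Q test rejects (p < ``q_alpha``) and I² exceeds
    ``i2_threshold`` percent; otherwise fixed effect."""
    fixed = fixed_effect_meta(b, se)
    if fixed.Q_p < q_alpha and fixed.I2 > i2_threshold:
        return random_effects_meta_dl(b, se)
    return fixed
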