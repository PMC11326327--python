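"""Polygenic-score construction and ancestry principal components.

The polygenic score is the weighted sum of effect-allele dosages over a
variant weight table, mean-imputing missing dosages at the per-variant mean
(≈ 2·allele frequency) and standardized on the analysis sample, so the
instrument enters every model in SD units.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .phenotypes import standardize

__all__ = ["filter_variants", "compute_pgs", "genotype_pca"]

log = logging.getLogger(__name__)

WEIGHT_COLUMNS = ("variant_id", "effect_allele", "other_allele", "weight")


def filter_variants(weights: pd.DataFrame, quality_threshold: float = 0.0,
                    quality_column: str = "quality") -> pd.DataFrame:
    """Keep variants whose imputation quality is at least the threshold.

    A threshold of 0 is the identity.  The counts before and after are
    logged; an empty result raises (no usable instrument).
    """
    if weights["variant_id"].duplicated().any():
        raise ValueError("variant ids in the weight table must be unique")
    if quality_threshold <= 0.0:
        return weights.copy()
    if quality_column not in weights.columns:
        raise ValueError(f"weight table lacks a {quality_column!r} column")
    kept = weights[weights[quality_column] >= quality_threshold].copy()
    log.info("variant filter: %d -> %d at quality >= %g",
             len(weights), len(kept), quality_threshold)
    if kept.empty:
        raise ValueError("no variants survive the quality filter")
    return kept


def compute_pgs(cohort: pd.DataFrame, weights: pd.DataFrame,
                variant_info: pd.DataFrame,
                standardized: bool = True) -> pd.Series:
    """Weighted allele score per individual.

    ``variant_info`` maps each cohort genotype column to its variant id and
    allele coding (columns: variant_id, effect_allele, other_allele, column).
    Weight-table alleles are aligned against it: matching coding uses the
    dosage as-is, swapped effect/other alleles use ``2 − dosage``, and
    incompatible or absent variants are skipped with a warning.  More than
    50% absent variants aborts (instrument too degraded).  Missing dosages
    are mean-imputed per variant before weighting.
    """
    info = variant_info.set_index("variant_id")
    score = np.zeros(len(cohort))
    n_used = 0
    skipped: list[str] = []
    for row in weights.itertuples(index=False):
        if row.variant_id not in info.index:
            skipped.append(row.variant_id)
            continue
        meta = info.loc[row.variant_id]
        g = cohort[meta["column"]].astype(float).to_numpy()
        if np.isnan(g).any():
            g = np.where(np.isnan(g), np.nanmean(g), g)
        if (row.effect_allele == meta["effect_allele"]
                and row.other_allele == meta["other_allele"]):
            dose = g
        elif (row.effect_allele == meta["other_allele"]
                and row.other_allele == meta["effect_allele"]):
            dose = 2.0 - g
        else:
            skipped.append(row.variant_id)
            continue
        score += row.weight * dose
        n_used += 1
    if skipped:
        warnings.warn(f"{len(skipped)} weight-table variants skipped "
                      f"(absent or allele-incompatible)")
    if n_used < 0.5 * len(weights):
        raise ValueError(
            f"only {n_used}/{len(weights)} weight variants usable; "
            "instrument too degraded"
        )
    out = pd.Series(score, index=cohort.index, name="pgs")
    return standardize(out) if standardized else out


def genotype_pca(genotypes: np.ndarray | pd.DataFrame, k: int = 10
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of the centered, unit-variance dosage matrix.

    Monomorphic (zero-variance) columns are dropped first.  Returns
    ``(scores, explained_variance_ratio)``; component scores are mutually
    orthogonal and ordered by explained variance.
    """
    G = np.asarray(genotypes, dtype=float)
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
    sd = G.std(axis=0)
    G = G[:, sd > 0]
    if G.shape[1] == 0:
        raise ValueError("all genotype columns are monomorphic")
    if k > min(G.shape[0] - 1, G.shape[1]):
        raise ValueError(f"k={k} too large for matrix of shape {G.shape}")
    Z = (G - G.mean(axis=0)) / G.std(axis=0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * s[:k]
    evr = (s**2 / np.sum(s**2))[:k]
    return scores, evr
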