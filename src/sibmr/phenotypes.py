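"""Measurement layer: symptom-scale scoring, caseness, education years,
and SD-unit standardization.

Scales are scored as plain item sums.  Any missing item makes the score
missing: no half-rule or prorating is applied, and downstream models are
complete-case within their own variable set.  Caseness uses a strict
``score > threshold`` rule (default threshold 10, matching the usual
HADS/GAD-7/PHQ-9 screening cut-off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "SCALES",
    "score_scale",
    "classify_case",
    "ea_years",
    "standardize",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A fixed-length symptom questionnaire scored as the sum of its items."""

    name: str
    n_items: int
    item_range: tuple[int, int]

    @property
    def max_score(self) -> int:
        return self.n_items * self.item_range[1]


#: the instruments used across the two cohorts: HADS anxiety/depression
#: subscales, GAD-7, PHQ-9, and the 6- and 12-item EPQ neuroticism forms
SCALES: dict[str, ScaleDefinition] = {
    s.name: s
    for s in (
        ScaleDefinition("HADS-A", 7, (0, 3)),
        ScaleDefinition("HADS-D", 7, (0, 3)),
        ScaleDefinition("GAD7", 7, (0, 3)),
        ScaleDefinition("PHQ9", 9, (0, 3)),
        ScaleDefinition("EPQ-N-6", 6, (0, 1)),
        ScaleDefinition("EPQ-N-12", 12, (0, 1)),
    )
}


def score_scale(item_responses, scale: ScaleDefinition | str):
    """Sum item responses into a scale score.

    ``item_responses`` is either a single response vector (length
    ``scale.n_items``) or a DataFrame/2-D array with one row per respondent.
    Rows containing any missing item score as missing (NaN); out-of-range
    items raise.
    """
    if isinstance(scale, str):
        scale = SCALES[scale]
    arr = np.asarray(item_responses, dtype=float)
    one_row = arr.ndim == 1
    if one_row:
        arr = arr[None, :]
    if arr.shape[1] != scale.n_items:
        raise ValueError(
            f"{scale.name} expects {scale.n_items} items, got {arr.shape[1]}"
        )
    lo, hi = scale.item_range
    finite = np.isfinite(arr)
    if np.any((arr[finite] < lo) | (arr[finite] > hi) | (arr[finite] % 1 != 0)):
        raise ValueError(f"item responses outside {scale.name} range [{lo}, {hi}]")
    scores = arr.sum(axis=1)
    scores[~finite.all(axis=1)] = np.nan
    return float(scores[0]) if one_row else scores


def classify_case(score, threshold: float = 10):
    """Caseness: 1 if ``score > threshold`` (strict), 0 otherwise; missing
    scores yield missing classes."""
    arr = np.asarray(score, dtype=float)
    out = np.where(arr > threshold, 1.0, 0.0)
    out = np.where(np.isfinite(arr), out, np.nan)
    if np.ndim(score) == 0:
        return float(out) if np.isfinite(out) else np.nan
    return out


def ea_years(category, mapping: Mapping[str, float]):
    """Map an education category label to years of education.

    ``mapping`` is an ISCED-style lookup (label → positive years).  Unmapped
    labels raise, naming the offending label; the mapping must be total over
    the data it is applied to.
    """
    bad = [lab for lab, yrs in mapping.items() if not yrs > 0]
    if bad:
        raise ValueError(f"education years must be positive; offending: {bad}")
    if isinstance(category, (pd.Series, np.ndarray, list, tuple)):
        cats = pd.Series(category)
        unknown = sorted(set(cats.dropna()) - set(mapping))
        if unknown:
            raise KeyError(f"unmapped education categories: {unknown}")
        return cats.map(mapping).to_numpy(dtype=float)
    if category not in mapping:
        raise KeyError(f"unmapped education category: {category!r}")
    return float(mapping[category])


def standardize(values):
    """Scale to mean 0, SD 1 (population SD) over non-missing entries.

    Missing values propagate; a constant (zero-variance) input raises.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        raise ValueError("standardize needs at least 2 non-missing values")
    mean = arr[finite].mean()
    sd = arr[finite].std()
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance vector")
    out = (arr - mean) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
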