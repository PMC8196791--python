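"""Empirical transition model between period categories.

At each anchor time of day the transitions from the category of the past
24-h period to the category of the following 6-h period are counted and
expressed as row-conditional probabilities.  Estimation is per patient and
per anchor: the categories are patient-specific and the model is meant to
be read individually, not pooled across patients.  Probabilities are raw
empirical frequencies by default (71.43% = 5/7); optional Laplace
smoothing is available but off by default.  Rows never observed are
reported as undefined rather than as zeros.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedTransitionError(KeyError):
    """No observed transition from this 24-h category at this anchor."""


@dataclass(frozen=True)
class TransitionModel:
    """Count and probability matrices for one anchor time.

    ``counts`` is a (rows = 24-h categories, cols = 6-h categories)
    DataFrame of non-negative integers; ``probabilities`` are row
    percentages, NaN for rows with no observations.
    """

    anchor: dt.time
    counts: pd.DataFrame
    alpha: float = 0.0

    @property
    def row_categories(self) -> tuple:
        return tuple(self.counts.index)

    @property
    def col_categories(self) -> tuple:
        return tuple(self.counts.columns)

    @property
    def probabilities(self) -> pd.DataFrame:
        return transition_probabilities(self.counts, alpha=self.alpha)


def count_transitions(pairs, row_categories, col_categories) -> pd.DataFrame:
    """Contingency counts of (24-h category, following 6-h category) pairs.

    ``pairs`` is an iterable of 2-tuples of labels drawn from the declared
    category sets; an unknown label raises ``ValueError``.
    """
    counts = pd.DataFrame(
        0, index=list(row_categories), columns=list(col_categories), dtype=int
    )
    for r, c in pairs:
        if r not in counts.index:
            raise ValueError(f"unknown 24-h category {r!r}")
        if c not in counts.columns:
            raise ValueError(f"unknown 6-h category {c!r}")
        counts.loc[r, c] += 1
    return counts


def transition_probabilities(counts: pd.DataFrame, alpha: float = 0.0) -> pd.DataFrame:
    """Row-normalized transition percentages.

    Rows with zero counts are emitted as NaN (undefined), never as zeros.
    ``alpha`` adds Laplace pseudocounts before normalizing (default 0:
    raw empirical frequencies).
    """
    c = counts.to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    defined = c.sum(axis=1) > 0
    c = c + alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 100.0 * c / c.sum(axis=1, keepdims=True)
    p[~defined] = np.nan
    return pd.DataFrame(p, index=counts.index, columns=counts.columns)


def estimate_transition_model(
    pairs, anchor: dt.time, row_categories, col_categories, alpha: float = 0.0
) -> TransitionModel:
    """Build a :class:`TransitionModel` from observed category pairs."""
    counts = count_transitions(pairs, row_categories, col_categories)
    return TransitionModel(anchor=anchor, counts=counts, alpha=alpha)


def predict_next(model: TransitionModel, category_24h) -> pd.Series:
    """Probability distribution (in %) over 6-h categories given the past
    24-h category; raises :class:`UndefinedTransitionError` for rows with
    no observed transitions."""
    if category_24h not in model.counts.index:
        raise ValueError(f"unknown 24-h category {category_24h!r}")
    row = model.probabilities.loc[category_24h]
    if row.isna().all():
        raise UndefinedTransitionError(
            f"no data for transitions from {category_24h!r} at "
            f"{model.anchor.strftime('%H:%M')}"
        )
    return row


def format_table(models: dict[dt.time, TransitionModel]) -> pd.DataFrame:
    """Wide per-patient table: rows = 24-h categories, nested columns =
    anchor x 6-h category, percentages rounded to 2 decimals; undefined
    rows are blank."""
    blocks = []
    for anchor, model in models.items():
        p = model.probabilities.round(2)
        p.columns = pd.MultiIndex.from_product(
            [[anchor.strftime("%H:%M")], p.columns]
        )
        blocks.append(p)
    return pd.concat(blocks, axis=1)
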