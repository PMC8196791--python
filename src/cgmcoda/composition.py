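"""Time-in-range compositions of CGM windows.

A glucose profile over a finite period is summarised by the minutes spent
in five clinical glucose ranges (level 2 hypoglycemia <54 mg/dL, level 1
hypoglycemia 54-70, normoglycemia 70-180, level 1 hyperglycemia 180-250,
level 2 hyperglycemia >250).  Because the period length is fixed, these
five times carry only relative information and form a composition closed
to the window duration; all downstream analysis treats them with the
Aitchison (log-ratio) geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cgm_io import PeriodWindow, is_valid

#: canonical part labels, ordered from lowest to highest glucose range
PART_LABELS = ("t_lt54", "t_54_70", "t_70_180", "t_180_250", "t_gt250")
PART_PRETTY = ("<54", "54-70", "70-180", "180-250", ">250")
N_PARTS = 5


class DegenerateCompositionError(ValueError):
    """All parts are zero; closure is undefined."""


@dataclass(frozen=True)
class GlucoseRangeScheme:
    """Consensus glucose range boundaries in mg/dL.

    The boundary conventions follow the international consensus levels:
    level 1 hypoglycemia is ``54 <= BG < 70``, normoglycemia is
    ``70 <= BG <= 180`` (both bounds inclusive), level 1 hyperglycemia is
    ``180 < BG <= 250`` and level 2 hyperglycemia is ``BG > 250``.
    """

    boundaries: tuple[float, float, float, float] = (54.0, 70.0, 180.0, 250.0)

    def __post_init__(self) -> None:
        b = tuple(float(v) for v in self.boundaries)
        if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
            raise ValueError("boundaries must be 4 strictly increasing values")
        object.__setattr__(self, "boundaries", b)


DEFAULT_SCHEME = GlucoseRangeScheme()


@dataclass(frozen=True)
class Composition:
    """A 5-part composition of times in glucose ranges.

    ``parts`` are non-negative minutes (or proportions after closure) in
    the order of :data:`PART_LABELS`; their sum is the closure constant.
    """

    parts: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.parts, dtype=float)
        if p.shape != (N_PARTS,):
            raise ValueError(f"expected {N_PARTS} parts, got shape {p.shape}")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("parts must be finite and non-negative")
        p = p.copy()
        p.flags.writeable = False
        object.__setattr__(self, "parts", p)

    @property
    def total(self) -> float:
        """Closure constant (sum of parts)."""
        return float(self.parts.sum())

    @property
    def D(self) -> int:
        return N_PARTS

    def close(self, C: float = 1.0) -> "Composition":
        return close(self, C)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.parts, dtype=dtype)


def classify_glucose(value, scheme: GlucoseRangeScheme = DEFAULT_SCHEME):
    """Map glucose values (mg/dL) to range indices 0-4.

    ``v < 54 -> 0``, ``54 <= v < 70 -> 1``, ``70 <= v <= 180 -> 2``,
    ``180 < v <= 250 -> 3``, ``v > 250 -> 4``.  Accepts scalars or arrays.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v <= 0):
        raise ValueError("glucose values must be positive")
    b1, b2, b3, b4 = scheme.boundaries
    idx = np.select([v < b1, v < b2, v <= b3, v <= b4], [0, 1, 2, 3], default=4)
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(idx)
    return idx.astype(int)


def range_counts(values, scheme: GlucoseRangeScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Sample counts per glucose range for an array of glucose values."""
    if len(values) == 0:
        return np.zeros(N_PARTS, dtype=int)
    return np.bincount(classify_glucose(values, scheme), minlength=N_PARTS)


def window_to_composition(
    window: PeriodWindow,
    scheme: GlucoseRangeScheme = DEFAULT_SCHEME,
    threshold: float = 0.70,
) -> Composition:
    """Minutes spent per glucose range in a validated window.

    Each observed sample contributes one cadence interval (nominally 5 min)
    to the range its glucose value falls in.  The time corresponding to
    missing samples is split in equal shares among the ranges that contain
    at least one observed sample, so the parts always sum to the window
    duration.

    Raises ``ValueError`` if the window fails the validity rule.
    """
    if not is_valid(window, threshold):
        raise ValueError(
            f"window starting {window.start} fails the {threshold:.0%} validity rule"
        )
    counts = range_counts(window.glucose, scheme)
    minutes = counts.astype(float) * window.cadence
    missing = window.duration - minutes.sum()
    occupied = counts > 0
    if missing > 0:
        minutes[occupied] += missing / occupied.sum()
    return Composition(minutes)


def close(x, C: float = 1.0) -> Composition:
    """Close a composition (or raw positive vector) to the constant ``C``.

    Closure rescales the parts to sum to ``C``; ratios between parts are
    preserved, which is the only information the Aitchison geometry uses.
    """
    if C <= 0:
        raise ValueError("closure constant must be positive")
    p = np.asarray(x, dtype=float)
    s = p.sum()
    if s <= 0:
        raise DegenerateCompositionError("cannot close an all-zero composition")
    return Composition(p * (C / s))


def composition_matrix(compositions) -> np.ndarray:
    """Stack compositions into an (n, 5) float array."""
    return np.asarray([np.asarray(c, dtype=float) for c in compositions])
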