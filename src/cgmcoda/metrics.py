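"""Clinical outcome summaries of CGM windows.

Average glucose, glucose variability and the Kovatchev blood-glucose risk
indices.  The risk transform maps glucose (mg/dL) onto a symmetric scale,

    f(BG) = 1.509 * ((ln BG)^1.084 - 5.381),

which is negative in hypoglycemia and positive in hyperglycemia, crossing
zero near 112.5 mg/dL.  The per-sample risk is ``r = 10 f(BG)^2``; the Low
(High) Blood Glucose Index is the mean of ``r`` over all samples counting
only those with ``f < 0`` (``f > 0``), so LBGI summarizes hypoglycemic and
HBGI hyperglycemic exposure.  An LBGI between 2.5 and 5 is conventionally
read as moderate hypoglycemic risk; an HBGI above 9 as high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OutcomeSummary:
    avg_bg: float    # arithmetic mean, mg/dL
    bgv: float       # sample standard deviation, mg/dL
    lbgi: float
    hbgi: float
    n_samples: int


def glucose_risk(bg) -> np.ndarray | float:
    """Symmetrized risk scale f(BG); negative below ~112.5 mg/dL."""
    v = np.asarray(bg, dtype=float)
    if np.any(v <= 0):
        raise ValueError("glucose must be positive")
    return 1.509 * (np.log(v) ** 1.084 - 5.381)


def lbgi(bg) -> float:
    """Low Blood Glucose Index: mean over all samples of 10 f^2 for f < 0."""
    f = np.asarray(glucose_risk(bg))
    r = 10.0 * f**2
    return float(np.where(f < 0, r, 0.0).mean())


def hbgi(bg) -> float:
    """High Blood Glucose Index: mean over all samples of 10 f^2 for f > 0."""
    f = np.asarray(glucose_risk(bg))
    r = 10.0 * f**2
    return float(np.where(f > 0, r, 0.0).mean())


def outcome_summary(bg) -> OutcomeSummary:
    """Avg BG, BGV (sample SD), LBGI and HBGI for one window's samples."""
    v = np.asarray(bg, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 glucose samples")
    return OutcomeSummary(
        avg_bg=float(v.mean()),
        bgv=float(v.std(ddof=1)),
        lbgi=lbgi(v),
        hbgi=hbgi(v),
        n_samples=len(v),
    )
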