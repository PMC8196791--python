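"""Zero handling ahead of log-ratio analysis.

A zero minute-count in a glucose range does not mean the range is
impossible for the patient — only that no 5-min sample fell in it during
the window, i.e. the true time is below one observable sample period.
Zeros are therefore treated as values censored below a detection limit
(a fraction of the 5-min cadence) and replaced before taking logarithms:
either by the log-ratio Expectation-Maximization algorithm (lrEM), which
imputes each censored cell from the multivariate normal model of the
log-ratio coordinates, or by simple multiplicative replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .composition import N_PARTS, Composition

logger = logging.getLogger(__name__)


class UnidentifiableZeroError(ValueError):
    """A part is zero in every row; its log-ratio structure cannot be
    estimated.  Amalgamate the part or use multiplicative replacement."""


@dataclass(frozen=True)
class ZeroPattern:
    """Summary of where zeros occur in a compositional matrix."""

    masks: np.ndarray           # (n, D) boolean, True where the part is zero
    part_counts: np.ndarray     # (D,) zeros per part
    patterns: tuple             # distinct row masks, as tuples of bool
    pattern_counts: np.ndarray  # rows per distinct pattern

    @property
    def n_zero_rows(self) -> int:
        return int(self.masks.any(axis=1).sum())

    @property
    def has_zeros(self) -> bool:
        return bool(self.masks.any())


def _as_matrix(compositions) -> np.ndarray:
    X = np.asarray([np.asarray(c, dtype=float) for c in compositions])
    if X.ndim != 2:
        raise ValueError("expected a sequence of compositions")
    return X


def zero_pattern(compositions) -> ZeroPattern:
    """Boolean zero masks, per-part zero counts and distinct row patterns."""
    X = _as_matrix(compositions)
    if X.shape[0] < 1:
        raise ValueError("need at least one composition")
    masks = X == 0
    uniq, counts = np.unique(masks, axis=0, return_counts=True)
    nontrivial = uniq.any(axis=1)
    return ZeroPattern(
        masks=masks,
        part_counts=masks.sum(axis=0),
        patterns=tuple(tuple(bool(v) for v in row) for row in uniq[nontrivial]),
        pattern_counts=counts[nontrivial],
    )


def detection_limits(n_rows: int, fraction=1.0, cadence: float = 5.0) -> np.ndarray:
    """Per-cell detection limits in minutes: ``fraction x cadence``.

    ``fraction`` may be a scalar or a per-part vector of length 5 (the
    limit may depend on the position of the zero in the composition); the
    default of 1.0 reads a zero as "less than one 5-min sample".
    """
    frac = np.asarray(fraction, dtype=float)
    if np.any(frac <= 0):
        raise ValueError("detection-limit fraction must be positive")
    if frac.ndim == 0:
        frac = np.full(N_PARTS, float(frac))
    elif frac.shape != (N_PARTS,):
        raise ValueError(f"fraction must be scalar or length-{N_PARTS}")
    return np.tile(frac * cadence, (n_rows, 1))


def multiplicative_replacement(x, dl, delta_frac: float = 0.65) -> Composition:
    """Replace zeros by ``delta_frac x dl`` and rescale the non-zero parts.

    Non-zero parts are multiplied by ``(C - sum(imputed)) / C`` so the
    closure constant is preserved exactly and ratios between non-zero
    parts are untouched.
    """
    p = np.asarray(x, dtype=float)
    dl = np.broadcast_to(np.asarray(dl, dtype=float), p.shape)
    if not np.any(p > 0):
        raise ValueError("all parts are zero; replacement is undefined")
    zero = p == 0
    if not zero.any():
        return Composition(p)
    C = p.sum()
    imputed = delta_frac * dl[zero]
    out = p * ((C - imputed.sum()) / C)
    out[zero] = imputed
    return Composition(out)


def _trunc_norm_moments(cut: float, mean: float, var: float) -> tuple[float, float]:
    """Mean and variance of N(mean, var) truncated to values below ``cut``."""
    sd = np.sqrt(var)
    a = (cut - mean) / sd
    logphi = norm.logpdf(a) - norm.logcdf(a)
    h = -np.exp(logphi)                      # E[z | z < a] for standard normal
    m = mean + sd * h
    v = var * max(1.0 - a * (-h) - h * h, 1e-12)
    return float(m), float(v)


def lrem_replace(
    compositions,
    dl=None,
    tol: float = 1e-8,
    max_iter: int = 200,
    delta_frac: float = 0.65,
    return_info: bool = False,
):
    """Log-ratio EM replacement of zeros below detection limits.

    The rows are expressed in additive log-ratio coordinates with respect
    to a zero-free part; zero cells become coordinates censored below
    ``ln(dl / x_ref)``.  An EM algorithm for the multivariate normal with
    censored entries alternates (E) replacing each censored coordinate by
    its conditional truncated-normal expectation given the observed
    coordinates and (M) re-estimating the mean and covariance including
    the conditional truncation variances.  Imputed parts are strictly
    below their detection limits and non-zero parts keep their within-row
    ratios; each row's closure constant is preserved.

    Falls back to :func:`multiplicative_replacement` (with a logged
    warning) when there are fewer than D+1 rows or no zero-free reference
    part.  Raises :class:`UnidentifiableZeroError` if some part is zero
    in every row.

    With ``return_info=True`` also returns a dict with the iteration
    count, convergence flag and the observed-data log-likelihood trace.
    """
    X = _as_matrix(compositions)
    n, D = X.shape
    if np.any(~np.any(X > 0, axis=1)):
        raise ValueError("every row needs at least one non-zero part")
    mask = X == 0
    info = {"n_iter": 0, "converged": True, "loglik": [], "method": "lrem"}
    if not mask.any():
        out = X.copy()
        return (out, info) if return_info else out
    if np.any(mask.all(axis=0)):
        bad = int(np.flatnonzero(mask.all(axis=0))[0])
        raise UnidentifiableZeroError(
            f"part {bad} is zero in all rows; amalgamate it or use "
            "multiplicative replacement"
        )
    if dl is None:
        dl = detection_limits(n)
    dl = np.broadcast_to(np.asarray(dl, dtype=float), X.shape)
    if np.any(dl <= 0):
        raise ValueError("detection limits must be strictly positive")

    zero_free = np.flatnonzero(~mask.any(axis=0))
    if n < D + 1 or len(zero_free) == 0:
        reason = "fewer than D+1 rows" if n < D + 1 else "no zero-free part"
        logger.warning("lrEM not applicable (%s); falling back to "
                       "multiplicative replacement", reason)
        out = np.asarray(
            [np.asarray(multiplicative_replacement(row, drow, delta_frac))
             for row, drow in zip(X, dl)]
        )
        info["method"] = "multiplicative"
        return (out, info) if return_info else out

    # reference part: zero-free column with the largest geometric mean
    ref = zero_free[np.argmax([np.log(X[:, j]).mean() for j in zero_free])]
    cols = np.array([j for j in range(D) if j != ref])

    # multiplicative start gives a feasible completed data set
    X0 = np.asarray(
        [np.asarray(multiplicative_replacement(row, drow, delta_frac))
         for row, drow in zip(X, dl)]
    )
    Y = np.log(X0[:, cols] / X0[:, [ref]])
    cuts = np.log(dl[:, cols] / X[:, [ref]])
    cens = mask[:, cols]

    row_var = [np.zeros((len(cols), len(cols))) for _ in range(n)]
    logliks: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        mu = Y.mean(axis=0)
        R = Y - mu
        Sigma = (R.T @ R + sum(row_var)) / n
        # keep Sigma invertible on degenerate fixtures
        Sigma += np.eye(len(cols)) * (1e-12 * max(np.trace(Sigma), 1.0))

        loglik = 0.0
        max_change = 0.0
        for i in range(n):
            c = np.flatnonzero(cens[i])
            o = np.flatnonzero(~cens[i])
            row_var[i][:] = 0.0
            if len(o):
                So = Sigma[np.ix_(o, o)]
                resid_o = Y[i, o] - mu[o]
                sign, logdet = np.linalg.slogdet(So)
                loglik += -0.5 * (
                    len(o) * np.log(2 * np.pi) + logdet
                    + resid_o @ np.linalg.solve(So, resid_o)
                )
            if len(c) == 0:
                continue
            if len(o):
                Soi = np.linalg.inv(Sigma[np.ix_(o, o)])
                B = Sigma[np.ix_(c, o)] @ Soi
                m_c = mu[c] + B @ (Y[i, o] - mu[o])
                V_c = Sigma[np.ix_(c, c)] - B @ Sigma[np.ix_(o, c)]
            else:
                m_c, V_c = mu[c], Sigma[np.ix_(c, c)]
            # cellwise truncation (exact for a single censored cell per row)
            for idx, j in enumerate(c):
                v = max(V_c[idx, idx], 1e-12)
                m_t, v_t = _trunc_norm_moments(cuts[i, j], m_c[idx], v)
                max_change = max(max_change, abs(Y[i, j] - m_t))
                Y[i, j] = m_t
                row_var[i][j, j] = v_t
                loglik += float(norm.logcdf((cuts[i, j] - m_c[idx]) / np.sqrt(v)))
        logliks.append(float(loglik))
        if max_change < tol:
            converged = True
            break
    if not converged:
        logger.warning("lrEM reached max_iter=%d without converging "
                       "(last change %.3g)", max_iter, max_change)

    out = X.astype(float).copy()
    for i in range(n):
        c = np.flatnonzero(cens[i])
        if len(c) == 0:
            continue
        imput = np.exp(Y[i, c]) * X[i, ref]
        imput = np.minimum(imput, dl[i, cols[c]] * (1 - 1e-12))
        C = X[i].sum()
        nz = ~mask[i]
        out[i, nz] = X[i, nz] * ((C - imput.sum()) / C)
        out[i, cols[c]] = imput

    info.update(n_iter=len(logliks), converged=converged, loglik=logliks)
    return (out, info) if return_info else out
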