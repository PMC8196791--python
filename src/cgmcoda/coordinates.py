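"""Log-ratio geometry: clr, SBP-derived ilr balances, distances, centers.

Compositions live on the simplex, where ratios — not absolute values —
carry the information.  The centered log-ratio (clr) maps a composition to
a zero-sum real vector, and an orthonormal basis built from a sequential
binary partition (SBP) of the parts gives isometric log-ratio (ilr)
coordinates whose Euclidean geometry equals the Aitchison geometry of the
simplex.

The default SBP encodes the clinical reading of the five glucose ranges:

=====  =====  ======  =======  ========  ======
row    <54    54-70   70-180   180-250   >250
=====  =====  ======  =======  ========  ======
1      +1     +1      -1       -1        -1
2      +1     -1      0        0         0
3      0      0       -1       +1        +1
4      0      0       0        -1        +1
=====  =====  ======  =======  ========  ======

so balance 1 opposes hypoglycemic to normo/hyperglycemic time, balance 2
level 2 to level 1 hypoglycemia, balance 3 hyperglycemic to normoglycemic
time, and balance 4 level 2 to level 1 hyperglycemia.  Each balance equals
``sqrt(r*s/(r+s)) * ln(gm(plus parts)/gm(minus parts))`` with ``r`` plus
parts and ``s`` minus parts; natural logarithms throughout.
"""

from __future__ import annotations

import numpy as np

from .composition import PART_LABELS, Composition, close

#: clinical sequential binary partition (rows = balances, columns = parts)
DEFAULT_SBP = np.array(
    [
        [1, 1, -1, -1, -1],
        [1, -1, 0, 0, 0],
        [0, 0, -1, 1, 1],
        [0, 0, 0, -1, 1],
    ],
    dtype=int,
)

BALANCE_LABELS = ("ilr_1", "ilr_2", "ilr_3", "ilr_4")


class DomainError(ValueError):
    """A log-ratio operation received a non-positive part."""


def validate_sbp(sbp: np.ndarray) -> np.ndarray:
    """Check that a sign matrix is a valid sequential binary partition.

    Each row must split exactly one group left unsplit by the previous
    rows into a non-empty plus and a non-empty minus subset; with D parts
    there are D-1 rows and the final groups are singletons.
    """
    sbp = np.asarray(sbp, dtype=int)
    if sbp.ndim != 2:
        raise ValueError("SBP must be a 2-D sign matrix")
    n_rows, D = sbp.shape
    if n_rows != D - 1:
        raise ValueError(f"SBP must have D-1={D - 1} rows, got {n_rows}")
    if not np.all(np.isin(sbp, (-1, 0, 1))):
        raise ValueError("SBP entries must be in {-1, 0, +1}")
    groups = [frozenset(range(D))]
    for i, row in enumerate(sbp):
        plus = frozenset(np.flatnonzero(row > 0))
        minus = frozenset(np.flatnonzero(row < 0))
        if not plus or not minus:
            raise ValueError(f"SBP row {i + 1} needs at least one +1 and one -1")
        support = plus | minus
        if support not in groups:
            raise ValueError(
                f"SBP row {i + 1} does not split a group produced by earlier rows"
            )
        groups.remove(support)
        groups.extend(g for g in (plus, minus) if len(g) > 1)
    return sbp


def sbp_basis(sbp: np.ndarray = DEFAULT_SBP) -> np.ndarray:
    """Orthonormal ilr basis (contrast matrix) from an SBP sign matrix.

    Returns a (D-1, D) matrix whose rows are orthonormal, zero-sum clr
    vectors: plus parts get ``sqrt(s / (r (r+s)))``, minus parts get
    ``-sqrt(r / (s (r+s)))``.
    """
    sbp = validate_sbp(sbp)
    psi = np.zeros(sbp.shape, dtype=float)
    for i, row in enumerate(sbp):
        r = int((row > 0).sum())
        s = int((row < 0).sum())
        psi[i, row > 0] = np.sqrt(s / (r * (r + s)))
        psi[i, row < 0] = -np.sqrt(r / (s * (r + s)))
    return psi


DEFAULT_BASIS = sbp_basis(DEFAULT_SBP)


def _as_positive_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    bad = ~(a > 0)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        part = PART_LABELS[idx[-1]] if a.shape[-1] == len(PART_LABELS) else str(idx[-1])
        raise DomainError(f"log-ratio transforms need strictly positive parts; "
                          f"part {part!r} is not positive")
    return a


def clr_transform(x) -> np.ndarray:
    """Centered log-ratio: ``ln(x_i / g(x))`` with g the geometric mean.

    Accepts a single composition or an (n, D) matrix; rows sum to zero.
    """
    a = _as_positive_array(x)
    la = np.log(a)
    return la - la.mean(axis=-1, keepdims=True)


def clr_inverse(z, C: float = 1.0) -> Composition | np.ndarray:
    """Inverse clr: exponentiate and close to ``C``."""
    z = np.asarray(z, dtype=float)
    e = np.exp(z)
    if z.ndim == 1:
        return close(e, C)
    return np.asarray([np.asarray(close(row, C)) for row in e])


def ilr_transform(x, basis: np.ndarray | None = None) -> np.ndarray:
    """ilr coordinates: inner products of clr(x) with the basis rows."""
    psi = DEFAULT_BASIS if basis is None else basis
    return clr_transform(x) @ psi.T


def ilr_inverse(y, basis: np.ndarray | None = None, C: float = 1.0):
    """Map ilr coordinates back to a composition closed to ``C``."""
    psi = DEFAULT_BASIS if basis is None else basis
    return clr_inverse(np.asarray(y, dtype=float) @ psi, C)


def aitchison_distance(x, y) -> float:
    """Aitchison distance: Euclidean distance between clr (or ilr) vectors."""
    return float(np.linalg.norm(clr_transform(x) - clr_transform(y)))


def compositional_center(matrix, C: float = 1.0) -> Composition:
    """Center of a compositional sample: closed componentwise geometric mean.

    This is the compositional analogue of the mean; closing the geometric
    means to 1440 min (or 360 min) gives the representative day (or 6-h
    period) of a group.
    """
    X = _as_positive_array(np.atleast_2d(np.asarray(matrix, dtype=float)))
    if X.shape[0] == 0:
        raise ValueError("cannot take the center of an empty sample")
    gm = np.exp(np.log(X).mean(axis=0))
    return close(gm, C)


def clr_biplot_coords(matrix):
    """Form-biplot coordinates of a compositional sample.

    The column-centered clr matrix is decomposed by SVD; row scores
    ``U @ diag(S)`` preserve inter-row Aitchison distances (form scaling),
    part loadings are the right singular vectors, and the explained
    variance fractions are the normalised squared singular values.

    Returns ``(scores, loadings, explained)`` with all axes kept; slice
    the first two columns for plotting.  Requires at least 3 rows and a
    clr rank of at least 2.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[0] < 3:
        raise ValueError("biplot needs at least 3 compositions")
    Z = clr_transform(X)
    Zc = Z - Z.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S[0] > 0 else 0
    if rank < 2:
        raise ValueError("clr matrix has rank < 2; biplot is degenerate")
    scores = U * S
    loadings = Vt.T
    explained = S**2 / (S**2).sum()
    return scores, loadings, explained
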