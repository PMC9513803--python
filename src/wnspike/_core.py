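"""Shared numerical primitives: seeding, fast rank correlation, Toeplitz solves.

All randomness in the package flows through :func:`derive_rng`, which builds a
`numpy.random.Generator` (PCG64) from a master seed plus an arbitrary tuple of
small non-negative integers.  Streams derived with different keys are
statistically independent, so adding units/trials to an experiment does not
perturb the draws of existing ones.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from scipy.stats import rankdata

__all__ = [
    "derive_rng",
    "standardized_ranks",
    "spearman",
    "spearman_matrix",
    "toeplitz_solve",
]


def derive_rng(seed: int, *key: int) -> np.random.Generator:
    """Return a PCG64 generator for the stream identified by ``(seed, *key)``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def standardized_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks of ``x``, centered and scaled to unit norm.

    The dot product of two such vectors is the Spearman rank correlation
    (with average-rank tie handling).  Returns a zero vector for constant
    input, which makes downstream correlations 0 rather than NaN.
    """
    r = rankdata(x, method="average").astype(np.float64)
    r -= r.mean()
    nrm = np.sqrt(r @ r)
    if nrm == 0.0:
        return r
    return r / nrm


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average-rank ties (0 if either is constant)."""
    return float(standardized_ranks(np.asarray(x)) @ standardized_ranks(np.asarray(y)))


def spearman_matrix(rows: np.ndarray) -> np.ndarray:
    """All pairwise Spearman correlations between the rows of a 2-D array."""
    R = np.vstack([standardized_ranks(row) for row in rows])
    return R @ R.T


def toeplitz_solve(first_col: np.ndarray, b: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Solve ``T x = b`` for the symmetric Toeplitz matrix with first column
    ``first_col``, regularized against near-singularity.

    The fast Levinson path is used when the operator is diagonally dominant
    enough to be safely well conditioned; otherwise the solve falls back to
    an eigendecomposition with eigenvalues floored at ``eig_floor`` times
    the largest, which keeps near-singular autocorrelation operators
    invertible without amplifying noise.  Shared by the modified Wiener
    filter and the cross-correlogram deconvolution.
    """
    c = np.asarray(first_col, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if c[0] > 0:
        try:
            x = linalg.solve_toeplitz(c, b)
            ok = np.all(np.isfinite(x))
            if ok:
                resid = linalg.matmul_toeplitz((c, c), x) - b
                nb = np.linalg.norm(b)
                ok = nb == 0 or np.linalg.norm(resid) <= 1e-8 * max(nb, 1.0)
            if ok:
                return x
        except np.linalg.LinAlgError:
            pass
    T = linalg.toeplitz(c)
    w, V = linalg.eigh(T)
    wmax = float(np.max(np.abs(w)))
    if wmax == 0.0:
        raise np.linalg.LinAlgError("all-zero Toeplitz operator")
    w = np.maximum(w, eig_floor * wmax)
    return V @ ((V.T @ b) / w)
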