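"""Column-stochastic transition kernels and their stationary analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import InvalidModelError, ReducibleChainError
from .states import BivariateTable, CategoricalRange, PROB_TOL


@dataclass(frozen=True)
class TransitionMatrix:
    """One-step kernel with entries P[i, j] = P(X_t = s_i | X_{t-1} = s_j).

    Columns (not rows) are the conditional distributions, matching the
    convention that the stationary distribution solves P p = p.
    """

    P: np.ndarray
    range: Optional[CategoricalRange] = None

    def __init__(self, P, range: Optional[CategoricalRange] = None):
        P = np.asarray(P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise InvalidModelError("transition matrix must be square")
        if np.any(P < -PROB_TOL) or np.any(P > 1 + PROB_TOL):
            raise InvalidModelError("transition probabilities outside [0,1]")
        colsums = P.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > PROB_TOL * P.shape[0]):
            raise InvalidModelError(f"columns must sum to 1, got {colsums}")
        if range is not None and range.n_states != P.shape[0]:
            raise InvalidModelError("range size does not match matrix")
        object.__setattr__(self, "P", np.clip(P, 0.0, 1.0))
        object.__setattr__(self, "range", range)

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    def column(self, j: int) -> np.ndarray:
        """Conditional distribution of X_t given X_{t-1} = s_j."""
        return self.P[:, j].copy()

    def power(self, h: int) -> np.ndarray:
        return np.linalg.matrix_power(self.P, int(h))


def is_irreducible(P: TransitionMatrix | np.ndarray) -> bool:
    """Strong connectivity of the positive-entry digraph."""
    A = P.P if isinstance(P, TransitionMatrix) else np.asarray(P)
    n, labels = connected_components(csr_matrix(A > 0), directed=True, connection="strong")
    return n == 1


def stationary_distribution(P: TransitionMatrix | np.ndarray) -> np.ndarray:
    """The unique p solving the invariance equation P p = p, sum p_i = 1.

    Solved as a least-squares problem on (P - I) stacked with the
    normalization row; raises for reducible chains, where uniqueness fails.
    """
    A = P.P if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    if not is_irreducible(A):
        raise ReducibleChainError("transition matrix is reducible; stationary law not unique")
    n = A.shape[0]
    M = np.vstack([A - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(M, b, rcond=None)
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    resid = np.max(np.abs(A @ p - p))
    if resid > 1e-10:
        raise ReducibleChainError(f"invariance residual {resid:.2e} exceeds 1e-10")
    return p


def model_bivariate(P: TransitionMatrix | np.ndarray, h: int = 1) -> BivariateTable:
    """Model-implied lag-h bivariate table under stationarity:
    joint[i, j] = (P^h)[i, j] * p_j with p the stationary distribution."""
    A = P.P if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    if h < 1:
        raise InvalidModelError("lag must be >= 1")
    p = stationary_distribution(A)
    joint = np.linalg.matrix_power(A, int(h)) * p[np.newaxis, :]
    return BivariateTable(joint, int(h), p)
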