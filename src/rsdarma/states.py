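"""State spaces, partitions, and validated probability containers.

A categorical time series takes values in a finite range
``S = {s0, ..., sm}``.  The listed order of the states is the coordinate
system for every probability vector in the package; for ordinal ranges the
listed order is the natural order of the categories (never inferred by
sorting labels).  A ``RangePartition`` splits S into K non-empty regimes
and is the structural ingredient of every regime-switching model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateDistributionError, InvalidModelError

#: absolute tolerance for "sums to one" checks on probability vectors
PROB_TOL = 1e-10


@dataclass(frozen=True)
class CategoricalRange:
    """An ordered finite state set with an ordinal/nominal flag.

    Parameters
    ----------
    states
        Distinct state labels; position in this sequence is the stable
        integer index of the state.
    ordinal
        Whether the listed order is a natural order on the categories.
    """

    states: tuple = ()
    ordinal: bool = False

    def __init__(self, states: Sequence, ordinal: bool = False):
        states = tuple(states)
        if len(states) < 2:
            raise InvalidModelError("a categorical range needs at least 2 states")
        if len(set(states)) != len(states):
            raise InvalidModelError(f"state labels must be distinct: {states!r}")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "ordinal", bool(ordinal))

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def m(self) -> int:
        """Number of states minus one (the conventional dispersion scale)."""
        return len(self.states) - 1

    def index(self, label) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise InvalidModelError(f"unknown state {label!r}; range is {self.states!r}")

    def __len__(self) -> int:
        return len(self.states)


DNA_RANGE = CategoricalRange(("a", "c", "g", "t"), ordinal=False)

#: five ordinal cloudiness states, eighths of sky covered ("okta"), low to high
CLOUDINESS_RANGE = CategoricalRange(("SKC", "FEW", "SCT", "BKN", "OVC"), ordinal=True)


@dataclass(frozen=True)
class RangePartition:
    """A partition of the state set into K non-empty regimes.

    ``regime_of[i]`` is the 0-based regime index of state i; regime indices
    must cover 0..K-1 with no gaps (every regime non-empty).
    """

    range: CategoricalRange
    regime_of: tuple = ()

    def __init__(self, range: CategoricalRange, regime_of: Sequence[int]):
        regime_of = tuple(int(k) for k in regime_of)
        if len(regime_of) != range.n_states:
            raise InvalidModelError(
                f"regime map has {len(regime_of)} entries for {range.n_states} states"
            )
        k_set = set(regime_of)
        K = max(k_set) + 1
        if min(k_set) < 0 or k_set != set(np.arange(K).tolist()):
            raise InvalidModelError(f"regime indices must cover 0..{K - 1}: {regime_of}")
        object.__setattr__(self, "range", range)
        object.__setattr__(self, "regime_of", regime_of)

    @classmethod
    def from_blocks(cls, rng: CategoricalRange, blocks: Sequence[Sequence]) -> "RangePartition":
        """Build from explicit blocks of state labels, e.g. [("a","g"), ("c",), ("t",)]."""
        regime_of = [-1] * rng.n_states
        for k, block in enumerate(blocks):
            if not block:
                raise InvalidModelError(f"regime {k} is empty")
            for label in block:
                i = rng.index(label)
                if regime_of[i] != -1:
                    raise InvalidModelError(f"state {label!r} assigned to two regimes")
                regime_of[i] = k
        if -1 in regime_of:
            missing = [rng.states[i] for i, k in enumerate(regime_of) if k == -1]
            raise InvalidModelError(f"states not covered by any regime: {missing}")
        return cls(rng, regime_of)

    @classmethod
    def trivial(cls, rng: CategoricalRange) -> "RangePartition":
        """The single-regime partition (K=1, the ordinary non-switching case)."""
        return cls(rng, (0,) * rng.n_states)

    @classmethod
    def singletons(cls, rng: CategoricalRange) -> "RangePartition":
        """Each state its own regime (K = m+1)."""
        return cls(rng, tuple(np.arange(rng.n_states)))

    @property
    def K(self) -> int:
        return max(self.regime_of) + 1

    def blocks(self) -> list:
        out: list = [[] for _ in range(self.K)]
        for i, k in enumerate(self.regime_of):
            out[k].append(self.range.states[i])
        return [tuple(b) for b in out]

    def describe(self) -> str:
        return " | ".join(",".join(map(str, b)) for b in self.blocks())


def validate_pmf(p, name: str = "p", strict: bool = False) -> np.ndarray:
    """Validate and return a probability vector as a float array.

    ``strict`` additionally requires every entry in the open interval (0,1),
    the regularity condition for likelihood-based inference; boundary zeros
    are otherwise allowed (they arise in model evaluation).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise InvalidModelError(f"{name} must be a vector of length >= 2")
    if np.any(p < -PROB_TOL) or np.any(p > 1 + PROB_TOL):
        raise InvalidModelError(f"{name} has entries outside [0,1]: {p}")
    if abs(p.sum() - 1.0) > PROB_TOL * max(1, p.size):
        raise InvalidModelError(f"{name} sums to {p.sum():.12f}, not 1")
    if strict and (np.any(p <= 0) or np.any(p >= 1)):
        raise InvalidModelError(f"{name} must lie in the open simplex (no 0/1 entries)")
    return np.clip(p, 0.0, 1.0)


def validate_cumulative(f) -> np.ndarray:
    """Validate a cumulative vector (f0,...,f_{m-1}): monotone, in [0,1]."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or f.size < 1:
        raise InvalidModelError("cumulative vector must be a non-empty 1-d array")
    if np.any(f < -PROB_TOL) or np.any(f > 1 + PROB_TOL):
        raise InvalidModelError(f"cumulative entries outside [0,1]: {f}")
    if np.any(np.diff(f) < -PROB_TOL):
        raise InvalidModelError(f"cumulative vector not monotone: {f}")
    return np.clip(f, 0.0, 1.0)


def cumulative_from_pmf(p) -> np.ndarray:
    """Cumulative vector (f0,...,f_{m-1}) of a pmf; the trailing 1 is dropped."""
    p = validate_pmf(p)
    return np.cumsum(p)[:-1]


@dataclass(frozen=True)
class BivariateTable:
    """Joint distribution of (X_t, X_{t-h}) plus the marginal used by measures.

    ``joint[i, j] = P(X_t = s_i, X_{t-h} = s_j)``.  For model-implied tables
    the marginal ``p`` equals both the row and the column sums; for sample
    tables ``p`` is by convention estimated from the full series of length T
    while ``joint`` is estimated from the T-h lag pairs, so the two may
    differ by O(1/T).
    """

    joint: np.ndarray
    lag: int
    p: np.ndarray

    def __init__(self, joint, lag: int, p=None):
        joint = np.asarray(joint, dtype=float)
        if joint.ndim != 2 or joint.shape[0] != joint.shape[1]:
            raise InvalidModelError("joint must be a square matrix")
        if np.any(joint < -PROB_TOL):
            raise InvalidModelError("joint has negative entries")
        if abs(joint.sum() - 1.0) > PROB_TOL * joint.size:
            raise InvalidModelError(f"joint sums to {joint.sum():.12f}, not 1")
        if int(lag) < 1:
            raise InvalidModelError("lag must be a positive integer")
        if p is None:
            p = joint.sum(axis=1)
        p = validate_pmf(p, "marginal")
        if p.size != joint.shape[0]:
            raise InvalidModelError("marginal length does not match joint")
        object.__setattr__(self, "joint", joint)
        object.__setattr__(self, "lag", int(lag))
        object.__setattr__(self, "p", p)

    @property
    def n_states(self) -> int:
        return self.joint.shape[0]

    def row_marginal(self) -> np.ndarray:
        """Marginal of X_t (row sums)."""
        return self.joint.sum(axis=1)

    def col_marginal(self) -> np.ndarray:
        """Marginal of X_{t-h} (column sums)."""
        return self.joint.sum(axis=0)

    def cumulative_joint(self) -> np.ndarray:
        """Double-cumulated joint f_ij(h) = P(X_t <= s_i, X_{t-h} <= s_j)."""
        return np.cumsum(np.cumsum(self.joint, axis=0), axis=1)


def darma_bivariate(p, kappa: float, lag: int = 1) -> BivariateTable:
    """The bivariate table of any discrete ARMA process with marginal ``p``
    and Cohen's kappa ``kappa`` at the given lag:
    ``p_ij(h) = (1-kappa) p_i p_j + kappa delta_ij p_j``.

    Useful as an analytic fixture: tables of this form make the nominal and
    ordinal kappa coincide.
    """
    p = validate_pmf(p)
    joint = (1.0 - kappa) * np.outer(p, p) + kappa * np.diag(p)
    if np.any(joint < -PROB_TOL):
        raise DegenerateDistributionError(
            f"kappa={kappa} below the admissible lower bound for this marginal"
        )
    return BivariateTable(np.clip(joint, 0.0, None), lag, p)
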