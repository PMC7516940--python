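"""Regime-switching discrete ARMA models.

The state set is partitioned into K regimes; the mixture weights rho and/or
the innovation distribution p_eps of the discrete ARMA recursion depend on
which regime the delayed observation X_{t-d} (default d = 1) fell into.
This observation-driven ("self-exciting") switching parallels threshold AR
models for ordinal series and similarity groupings (e.g. purines/pyrimidines)
for nominal ones.  K = 1 recovers the ordinary discrete ARMA model.

The first-order pure-AR case, RS-DAR(1), is a parsimoniously parameterized
Markov chain with kernel

    p_{i|j} = (1 - phi(pi(j))) p_eps,i(pi(j)) + phi(pi(j)) delta_ij,

where pi maps states to regimes.  Two interpretable restrictions are the
*marginal-regime* variant (shared phi, regime-specific innovations; K <= m
for identifiability; can produce negative serial dependence) and the
*dependence-regime* variant (regime-specific phi, shared innovations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .darma import DarmaSpec, _simulate_core
from .exceptions import InvalidModelError
from .markov import TransitionMatrix, model_bivariate, stationary_distribution
from .states import (
    BivariateTable,
    CategoricalRange,
    PROB_TOL,
    RangePartition,
    validate_pmf,
)

VARIANTS = ("general", "marginal_regimes", "dependence_regimes")

_range = range  # the builtin; spec dataclasses use `range` as a field name


@dataclass(frozen=True)
class RsDarmaSpec:
    """Regime-switching discrete ARMA(p, q) parameters.

    ``rho_by_regime`` holds the K mixture-weight vectors (each length
    p+q+1), ``p_eps_by_regime`` the K innovation distributions, and
    ``delay`` the lag d of the observation that selects the regime.
    """

    range: CategoricalRange
    partition: RangePartition
    p: int
    q: int
    rho_by_regime: np.ndarray
    p_eps_by_regime: np.ndarray
    delay: int = 1

    def __init__(self, range: CategoricalRange, partition: RangePartition,
                 p: int, q: int, rho_by_regime, p_eps_by_regime, delay: int = 1,
                 allow_boundary: bool = False):
        if partition.range is not range and partition.range.states != range.states:
            raise InvalidModelError("partition is defined on a different range")
        K = partition.K
        rho_by_regime = np.atleast_2d(np.asarray(rho_by_regime, dtype=float))
        p_eps_by_regime = np.atleast_2d(np.asarray(p_eps_by_regime, dtype=float))
        if rho_by_regime.shape != (K, p + q + 1):
            raise InvalidModelError(
                f"rho_by_regime must be {K}x{p + q + 1}, got {rho_by_regime.shape}")
        if p_eps_by_regime.shape != (K, range.n_states):
            raise InvalidModelError(
                f"p_eps_by_regime must be {K}x{range.n_states}, got {p_eps_by_regime.shape}")
        for k in _range(K):
            if abs(rho_by_regime[k].sum() - 1.0) > PROB_TOL * (p + q + 1):
                raise InvalidModelError(f"rho of regime {k} does not sum to 1")
            if not allow_boundary and rho_by_regime.shape[1] > 1 and (
                    np.any(rho_by_regime[k] <= 0) or np.any(rho_by_regime[k] >= 1)):
                raise InvalidModelError(
                    f"rho of regime {k} must lie in (0,1); allow_boundary=True to override")
            validate_pmf(p_eps_by_regime[k], f"p_eps of regime {k}")
        if int(delay) < 1:
            raise InvalidModelError("delay must be >= 1")
        object.__setattr__(self, "range", range)
        object.__setattr__(self, "partition", partition)
        object.__setattr__(self, "p", int(p))
        object.__setattr__(self, "q", int(q))
        object.__setattr__(self, "rho_by_regime", rho_by_regime)
        object.__setattr__(self, "p_eps_by_regime", p_eps_by_regime)
        object.__setattr__(self, "delay", int(delay))

    @property
    def K(self) -> int:
        return self.partition.K


@dataclass(frozen=True)
class RsDar1Spec:
    """RS-DAR(1) parameters: per-regime persistence and innovations.

    ``variant`` is one of 'general' (both regime-specific),
    'marginal_regimes' (shared phi; requires K <= m) or
    'dependence_regimes' (shared innovation distribution).  Boundary zeros
    in the innovation vectors are allowed; admissibility of a model for
    stationary analysis is decided by irreducibility of its kernel, not by
    blanket positivity.
    """

    range: CategoricalRange
    partition: RangePartition
    variant: str
    phi_by_regime: np.ndarray
    p_eps_by_regime: np.ndarray
    delay: int = 1

    def __init__(self, range: CategoricalRange, partition: RangePartition,
                 variant: str, phi_by_regime, p_eps_by_regime, delay: int = 1):
        if variant not in VARIANTS:
            raise InvalidModelError(f"variant must be one of {VARIANTS}, got {variant!r}")
        K = partition.K
        phi_by_regime = np.atleast_1d(np.asarray(phi_by_regime, dtype=float))
        p_eps_by_regime = np.atleast_2d(np.asarray(p_eps_by_regime, dtype=float))
        if phi_by_regime.size == 1:
            phi_by_regime = np.repeat(phi_by_regime, K)
        if p_eps_by_regime.shape[0] == 1:
            p_eps_by_regime = np.repeat(p_eps_by_regime, K, axis=0)
        if phi_by_regime.size != K or p_eps_by_regime.shape != (K, range.n_states):
            raise InvalidModelError("parameter shapes do not match the partition")
        if variant == "marginal_regimes":
            if K > range.m:
                raise InvalidModelError(
                    f"marginal-regime model needs K <= m = {range.m} for an "
                    f"identifiable phi, got K = {K}")
            if np.ptp(phi_by_regime) > PROB_TOL:
                raise InvalidModelError("marginal-regime variant shares a single phi")
        if variant == "dependence_regimes":
            if np.any(np.ptp(p_eps_by_regime, axis=0) > PROB_TOL):
                raise InvalidModelError(
                    "dependence-regime variant shares a single innovation distribution")
        if np.any(phi_by_regime <= 0) or np.any(phi_by_regime >= 1):
            raise InvalidModelError("phi values must lie in (0,1)")
        for k in _range(K):
            validate_pmf(p_eps_by_regime[k], f"p_eps of regime {k}")
        if int(delay) < 1:
            raise InvalidModelError("delay must be >= 1")
        object.__setattr__(self, "range", range)
        object.__setattr__(self, "partition", partition)
        object.__setattr__(self, "variant", variant)
        object.__setattr__(self, "phi_by_regime", phi_by_regime)
        object.__setattr__(self, "p_eps_by_regime", p_eps_by_regime)
        object.__setattr__(self, "delay", int(delay))

    @classmethod
    def marginal(cls, rng: CategoricalRange, partition: RangePartition,
                 phi: float, p_eps_by_regime, delay: int = 1) -> "RsDar1Spec":
        return cls(rng, partition, "marginal_regimes", phi, p_eps_by_regime, delay)

    @classmethod
    def dependence(cls, rng: CategoricalRange, partition: RangePartition,
                   phi_by_regime, p_eps, delay: int = 1) -> "RsDar1Spec":
        return cls(rng, partition, "dependence_regimes", phi_by_regime,
                   np.atleast_2d(p_eps), delay)

    @property
    def K(self) -> int:
        return self.partition.K

    @property
    def n_model(self) -> int:
        """Free parameters: Km+1 (marginal), m+K (dependence), Km+K (general)."""
        m, K = self.range.m, self.K
        if self.variant == "marginal_regimes":
            return K * m + 1
        if self.variant == "dependence_regimes":
            return m + K
        return K * m + K

    def to_rs_darma(self) -> RsDarmaSpec:
        """The equivalent (p, q) = (1, 0) regime-switching ARMA spec."""
        rho = np.column_stack([self.phi_by_regime, 1.0 - self.phi_by_regime])
        return RsDarmaSpec(self.range, self.partition, 1, 0, rho,
                           self.p_eps_by_regime, self.delay)


def rs_dar1_transition_matrix(spec: RsDar1Spec) -> TransitionMatrix:
    """The RS-DAR(1) kernel
    p_{i|j} = (1 - phi(pi(j))) p_eps,i(pi(j)) + phi(pi(j)) delta_ij.

    Covers all three variants (they differ only in which parameters are
    shared).  Only meaningful as a one-step kernel when delay = 1; for
    d > 1 the chain is Markov of order d.
    """
    n = spec.range.n_states
    P = np.empty((n, n))
    for j in range(n):
        k = spec.partition.regime_of[j]
        P[:, j] = (1.0 - spec.phi_by_regime[k]) * spec.p_eps_by_regime[k]
        P[j, j] += spec.phi_by_regime[k]
    return TransitionMatrix(P, spec.range)


def rs_darp_transition_prob(spec: RsDarmaSpec, i: int, past: Sequence[int]) -> float:
    """p-th-order Markov transition probability of a pure-AR (q = 0)
    regime-switching model, with the innovation marginalized out:

    P(X_t = s_i | past) = sum_r delta(i, past_r) phi_r(k) + vphi_0(k) p_eps,i(k),

    where k is the regime of the delayed observation past[d-1].
    """
    if spec.q != 0:
        raise InvalidModelError("exact transition probabilities require q = 0")
    past = np.asarray(past, dtype=int)
    need = max(spec.p, spec.delay)
    if past.size < need:
        raise InvalidModelError(f"need the last {need} states, got {past.size}")
    n = spec.range.n_states
    if not 0 <= i < n or np.any(past < 0) or np.any(past >= n):
        raise InvalidModelError("state index outside the range")
    k = spec.partition.regime_of[past[spec.delay - 1]]
    rho = spec.rho_by_regime[k]
    prob = float(np.sum(rho[: spec.p][past[: spec.p] == i]))
    prob += float(rho[spec.p] * spec.p_eps_by_regime[k, i])
    return prob


def simulate_rs_darma(spec: Union[RsDarmaSpec, RsDar1Spec], T: int,
                      burn_in: int = 500,
                      seed: Union[int, np.random.Generator, None] = None) -> np.ndarray:
    """Simulate a regime-switching discrete ARMA path (integer-coded).

    With K = 1 this is distributionally — and, at equal seed, bitwise —
    identical to :func:`rsdarma.darma.simulate_darma`.
    """
    if isinstance(spec, RsDar1Spec):
        spec = spec.to_rs_darma()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate_core(
        spec.rho_by_regime, spec.p_eps_by_regime,
        np.asarray(spec.partition.regime_of, dtype=int),
        spec.p, spec.q, spec.delay, T, burn_in, rng,
    )


# ---------------------------------------------------------------------------
# closed forms for two analytically tractable families
# ---------------------------------------------------------------------------

def boundary_marginal_spec(phi: float, p1: float, p2: float,
                           ordinal: bool = False) -> RsDar1Spec:
    """The 4-state, 2-regime marginal-regime model whose innovations always
    cross regimes: regimes {s0, s1} and {s2, s3} with

        p_eps^(1) = (0, 0, p1, 1-p1),   p_eps^(2) = (p2, 1-p2, 0, 0),

    so p_eps,i(pi(i)) = 0 for every state.  The extreme construction that
    yields negative serial dependence for small phi.
    """
    rng = CategoricalRange(("s0", "s1", "s2", "s3"), ordinal=ordinal)
    part = RangePartition(rng, (0, 0, 1, 1))
    pe = np.array([[0.0, 0.0, p1, 1.0 - p1], [p2, 1.0 - p2, 0.0, 0.0]])
    return RsDar1Spec.marginal(rng, part, phi, pe)


def boundary_marginal_stationary(p1: float, p2: float) -> np.ndarray:
    """Stationary law of the boundary cross-feeding model:
    p = (p2, 1-p2, p1, 1-p1) / 2."""
    return 0.5 * np.array([p2, 1.0 - p2, p1, 1.0 - p1])


def boundary_marginal_kappa(phi: float, p1: float, p2: float) -> tuple:
    """Closed-form lag-1 dependence of the boundary cross-feeding model:

        kappa(1)     = 1 - 2(1 - phi) / (1 + p1(1-p1) + p2(1-p2)),
        kappa_ord(1) = 1 - 2(1 - phi)(2 + p2 - p1)
                          / (2 + p2 - p1 + p1(1-p1) + p2(1-p2)).

    Both can be negative; here (unlike for non-switching discrete ARMA) the
    nominal and ordinal kappa genuinely differ.
    """
    w = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    k1 = 1.0 - 2.0 * (1.0 - phi) / (1.0 + w)
    a = 2.0 + p2 - p1
    kord = 1.0 - 2.0 * (1.0 - phi) * a / (a + w)
    return float(k1), float(kord)


def per_state_dependence_spec(phi_by_state, p_eps,
                              ordinal: bool = True) -> RsDar1Spec:
    """Dependence-regime model with the all-singletons partition: each state
    s_j carries its own persistence phi(j), innovations shared."""
    phi_by_state = np.asarray(phi_by_state, dtype=float)
    p_eps = validate_pmf(p_eps)
    labels = tuple(f"s{i}" for i in range(p_eps.size))
    rng = CategoricalRange(labels, ordinal=ordinal)
    part = RangePartition.singletons(rng)
    return RsDar1Spec.dependence(rng, part, phi_by_state, p_eps)


def per_state_stationary(phi_by_state, p_eps) -> np.ndarray:
    """Closed-form stationary law under per-state persistence:
    p_j = [p_eps,j / (1 - phi(j))] / sum_l [p_eps,l / (1 - phi(l))]."""
    phi = np.asarray(phi_by_state, dtype=float)
    pe = validate_pmf(p_eps)
    w = pe / (1.0 - phi)
    return w / w.sum()


def per_state_bivariate(phi_by_state, p_eps) -> BivariateTable:
    """Closed-form lag-1 joint under per-state persistence:
    p_ij = [p_eps,i p_eps,j + delta_ij phi(i) p_eps,i / (1 - phi(i))] / Z,
    Z = sum_l p_eps,l / (1 - phi(l))."""
    phi = np.asarray(phi_by_state, dtype=float)
    pe = validate_pmf(p_eps)
    Z = np.sum(pe / (1.0 - phi))
    joint = (np.outer(pe, pe) + np.diag(phi / (1.0 - phi) * pe)) / Z
    return BivariateTable(joint, 1, per_state_stationary(phi, pe))


__all__ = [
    "RsDarmaSpec", "RsDar1Spec", "VARIANTS",
    "rs_dar1_transition_matrix", "rs_darp_transition_prob", "simulate_rs_darma",
    "stationary_distribution", "model_bivariate", "TransitionMatrix",
    "boundary_marginal_spec", "boundary_marginal_stationary", "boundary_marginal_kappa",
    "per_state_dependence_spec", "per_state_stationary", "per_state_bivariate",
]
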