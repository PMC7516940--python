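"""Discrete ARMA (NDARMA) processes for categorical time series.

A discrete ARMA(p, q) process generates X_t by *randomly selecting* either
one of the past p observations or one of the q+1 most recent i.i.d.
innovations eps_t, ..., eps_{t-q}:

    X_t = a_{t,1} X_{t-1} + ... + a_{t,p} X_{t-p}
          + b_{t,0} eps_t + ... + b_{t,q} eps_{t-q},

where the 0/1 selection vector D_t = (a_{t,1..p}, b_{t,0..q}) is multinomial
with mixture weights rho = (phi_1..phi_p, vphi_0..vphi_q) summing to one.
X_t and eps_t then share the same stationary marginal distribution, and
Cohen's kappa obeys Yule-Walker-type equations, but only non-negative serial
dependence is possible; sample paths show long constant stretches ended by
abrupt jumps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import InvalidModelError
from .markov import TransitionMatrix
from .states import CategoricalRange, PROB_TOL, validate_pmf


@dataclass(frozen=True)
class DarmaSpec:
    """Parameters of a discrete ARMA(p, q) process.

    Parameters
    ----------
    range
        The categorical state space.
    p, q
        Autoregressive and moving-average orders (p = q = 0 is i.i.d.
        sampling from ``p_eps``).
    rho
        Mixture weights (phi_1..phi_p, vphi_0..vphi_q), length p+q+1,
        entries in the open interval (0,1) summing to one.  Boundary
        weights (exact 0/1) break the identifiability conditions for
        likelihood inference and are rejected unless ``allow_boundary``.
    p_eps
        Innovation distribution on the range (also the stationary marginal).
    """

    range: CategoricalRange
    p: int
    q: int
    rho: np.ndarray
    p_eps: np.ndarray

    def __init__(self, range: CategoricalRange, p: int, q: int, rho, p_eps,
                 allow_boundary: bool = False):
        p, q = int(p), int(q)
        if p < 0 or q < 0:
            raise InvalidModelError("orders p, q must be non-negative")
        rho = np.asarray(rho, dtype=float)
        if rho.size != p + q + 1:
            raise InvalidModelError(f"rho must have length p+q+1 = {p + q + 1}, got {rho.size}")
        if abs(rho.sum() - 1.0) > PROB_TOL * rho.size:
            raise InvalidModelError(f"rho sums to {rho.sum():.12f}, not 1")
        if not allow_boundary and (np.any(rho <= 0) or np.any(rho >= 1)):
            if rho.size > 1:
                raise InvalidModelError(
                    "rho entries must lie in (0,1); pass allow_boundary=True to override"
                )
        p_eps = validate_pmf(p_eps, "p_eps")
        if p_eps.size != range.n_states:
            raise InvalidModelError("p_eps length does not match the range")
        object.__setattr__(self, "range", range)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "p_eps", p_eps)

    @property
    def phi(self) -> np.ndarray:
        """AR selection weights (phi_1, ..., phi_p)."""
        return self.rho[: self.p]

    @property
    def varphi(self) -> np.ndarray:
        """MA selection weights (vphi_0, ..., vphi_q)."""
        return self.rho[self.p:]

    @property
    def n_model(self) -> int:
        """Free parameters: m for the marginal plus p+q mixture weights."""
        return self.range.m + self.p + self.q


def dar1(range: CategoricalRange, phi: float, p_eps) -> DarmaSpec:
    """Convenience constructor for the DAR(1) model,
    X_t = a_t X_{t-1} + (1 - a_t) eps_t with a_t ~ Bin(1, phi)."""
    return DarmaSpec(range, 1, 0, np.array([phi, 1.0 - phi]), p_eps)


def darma_transition_prob(spec: DarmaSpec, i0: int,
                          past: Sequence[int], innovations: Sequence[int]) -> float:
    """Conditional probability
    P(X_t = s_{i0} | X_{t-1..t-p} = past, eps_{t..t-q} = innovations)
    = sum_r delta(i0, past_r) phi_r + sum_r delta(i0, innov_r) vphi_r.

    Empty sums (p = 0 or q = 0) contribute zero.
    """
    past = np.asarray(past, dtype=int)
    innovations = np.asarray(innovations, dtype=int)
    if past.size != spec.p:
        raise InvalidModelError(f"expected {spec.p} past states, got {past.size}")
    if innovations.size != spec.q + 1:
        raise InvalidModelError(f"expected {spec.q + 1} innovations, got {innovations.size}")
    n = spec.range.n_states
    for v in np.concatenate([[i0], past, innovations]):
        if not 0 <= v < n:
            raise InvalidModelError(f"state index {v} outside 0..{n - 1}")
    prob = float(np.sum(spec.phi[past == i0]) + np.sum(spec.varphi[innovations == i0]))
    return prob


def dar1_transition_matrix(phi: float, p_eps,
                           rng: Optional[CategoricalRange] = None) -> TransitionMatrix:
    """DAR(1) kernel p_{i|j} = (1 - phi) p_eps,i + phi delta_ij."""
    p_eps = validate_pmf(p_eps, "p_eps")
    P = (1.0 - phi) * np.tile(p_eps[:, None], (1, p_eps.size)) + phi * np.eye(p_eps.size)
    return TransitionMatrix(P, rng)


@dataclass(frozen=True)
class YuleWalkerSolution:
    """kappa(0..H) and the auxiliary r(0..q) sequence."""

    kappas: np.ndarray
    r: np.ndarray

    def __getitem__(self, h: int) -> float:
        return float(self.kappas[h])


def yule_walker_kappa(spec: DarmaSpec, H: int) -> YuleWalkerSolution:
    """Solve the Yule-Walker equations for Cohen's kappa of a discrete
    ARMA(p, q) process:

        kappa(h) = sum_{j=1..p} phi_j kappa(|h - j|)
                   + sum_{i=0..q-h} vphi_{i+h} r(i),   h >= 1,

    with kappa(0) = 1 and the forward recursion
    r(i) = sum_{j=max(0, i-p)}^{i-1} phi_{i-j} r(j) + vphi_i for 0 <= i <= q.

    For DAR(1) this collapses to kappa(h) = phi^h; for DMA(q), kappa(h) = 0
    beyond lag q.  Because the measures coincide for this model class, the
    same sequence is the ordinal kappa of the process.

    For h < p the |h - j| terms make the equations implicit in kappa(1..p-1)
    (e.g. for p = 2, kappa(1) = phi_1 + phi_2 kappa(1)), so the lag equations
    are solved jointly as a linear system rather than by forward recursion.
    """
    if H < 1:
        raise InvalidModelError("H must be >= 1")
    p, q = spec.p, spec.q
    phi, varphi = spec.phi, spec.varphi
    r = np.zeros(q + 1)
    for i in range(q + 1):
        acc = varphi[i]
        for j in range(max(0, i - p), i):
            acc += phi[i - j - 1] * r[j]  # phi_{i-j} is 1-based
        r[i] = acc
    # linear system A k = b for k = (kappa(1), ..., kappa(H)), kappa(0) = 1
    A = np.eye(H)
    b = np.zeros(H)
    for h in range(1, H + 1):
        for j in range(1, p + 1):
            lag = abs(h - j)
            if lag == 0:
                b[h - 1] += phi[j - 1]
            else:
                A[h - 1, lag - 1] -= phi[j - 1]
        for i in range(0, q - h + 1):
            b[h - 1] += varphi[i + h] * r[i]
    kappas = np.concatenate([[1.0], np.linalg.solve(A, b)])
    return YuleWalkerSolution(kappas, r)


# ---------------------------------------------------------------------------
# simulation core (shared with the regime-switching module)
# ---------------------------------------------------------------------------

def _simulate_core(rho_by_regime: np.ndarray, peps_by_regime: np.ndarray,
                   regime_of: np.ndarray, p: int, q: int, d: int,
                   T: int, burn_in: int, rng: np.random.Generator) -> np.ndarray:
    """Shared recursion for discrete ARMA and its regime-switching extension.

    At each step the regime k is read off X_{t-d}; the selection vector D_t
    is drawn from Mult(1, rho^(k)) first and eps_t from p_eps^(k) second
    (one generator, fixed draw order, hence bit-reproducible by seed).
    Pre-sample X and eps values are i.i.d. from the equal-weight average of
    the K innovation distributions (equal to p_eps itself when K = 1) and a
    burn-in prefix is discarded.
    """
    if T < 1:
        raise InvalidModelError("T must be >= 1")
    if burn_in < 0:
        raise InvalidModelError("burn_in must be >= 0")
    total = burn_in + T
    npre = max(p, d, 1)
    cum_rho = np.cumsum(rho_by_regime, axis=1)
    cum_pe = np.cumsum(peps_by_regime, axis=1)
    init_cum = np.cumsum(peps_by_regime.mean(axis=0))

    u_init = rng.random(npre + q)
    x = np.empty(npre + total, dtype=np.int64)
    e = np.empty(q + total + 1, dtype=np.int64)
    x[:npre] = np.searchsorted(init_cum, u_init[:npre], side="right")
    e[:q] = np.searchsorted(init_cum, u_init[npre:], side="right")

    u = rng.random((total, 2))
    for t in range(total):
        k = regime_of[x[npre + t - d]]
        sel = int(np.searchsorted(cum_rho[k], u[t, 0], side="right"))
        eps = int(np.searchsorted(cum_pe[k], u[t, 1], side="right"))
        e[q + t] = eps
        if sel < p:  # select X_{t - (sel+1)}
            x[npre + t] = x[npre + t - 1 - sel]
        else:  # select eps_{t - (sel - p)}
            x[npre + t] = e[q + t - (sel - p)]
    return x[npre + burn_in:]


def simulate_darma(spec: DarmaSpec, T: int, burn_in: int = 500,
                   seed: Union[int, np.random.Generator, None] = None) -> np.ndarray:
    """Simulate a discrete ARMA(p, q) path of length T (integer-coded).

    Pre-sample values are i.i.d. draws from ``p_eps`` (the stationary
    marginal of both X and eps), followed by ``burn_in`` discarded steps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate_core(
        spec.rho[None, :], spec.p_eps[None, :],
        np.zeros(spec.range.n_states, dtype=int),
        spec.p, spec.q, 1, T, burn_in, rng,
    )
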