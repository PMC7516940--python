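"""Conditional maximum-likelihood inference, model selection, forecasting.

For first-order Markov families the conditional log-likelihood of a series
x_1, ..., x_T is

    l(theta) = sum_{t=2..T} ln p_{x_t | x_{t-1}}(theta),

maximized numerically over an unconstrained reparameterization (log-odds
for persistence parameters, multinomial logits for probability vectors), so
every iterate stays in the open parameter cube and the likelihood is finite
throughout the search.  The maximized value is corrected for conditioning,
l_max = T/(T-d) * l(theta_hat), and information criteria are

    AIC = -2 l_max + 2 n_model,      BIC = -2 l_max + n_model ln T.

The BIC is the consistent criterion for selecting among Markov models; the
AIC tends to overfit.  The full Markov chain is fitted in closed form from
transition counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .darma import DarmaSpec, dar1, dar1_transition_matrix
from .exceptions import InvalidModelError, ZeroLikelihoodError
from .markov import TransitionMatrix, is_irreducible
from .regime import RsDar1Spec, rs_dar1_transition_matrix
from .states import CategoricalRange, RangePartition

#: reported probabilities are clipped away from exact 0/1 at this level
CLIP = 1e-12

FAMILY_KINDS = ("dar1", "rs_dar1_marginal", "rs_dar1_dependence",
                "rs_dar1_general", "full_mc")


@dataclass(frozen=True)
class ModelFamily:
    """A candidate family for fitting: kind + partition (+ regime delay)."""

    kind: str
    partition: Optional[RangePartition] = None
    delay: int = 1

    def __post_init__(self):
        if self.kind not in FAMILY_KINDS:
            raise InvalidModelError(f"unknown family kind {self.kind!r}")
        if self.kind.startswith("rs_") and self.partition is None:
            raise InvalidModelError(f"family {self.kind!r} needs a partition")

    def label(self) -> str:
        if self.partition is None or self.kind in ("dar1", "full_mc"):
            return self.kind
        return f"{self.kind}[{self.partition.describe()}]"


@dataclass
class FitResult:
    """Outcome of a conditional ML fit.

    ``spec`` is the fitted model object (DarmaSpec for DAR(1), RsDar1Spec
    for regime-switching families, TransitionMatrix for the full MC);
    ``loglik_max`` carries the T/(T-d) conditioning correction.
    """

    family: ModelFamily
    spec: object
    theta: np.ndarray
    loglik_conditional: float
    loglik_max: float
    n_model: int
    T: int
    aic: float
    bic: float
    converged: bool
    n_restarts_used: int

    def transition_matrix(self) -> TransitionMatrix:
        return _spec_matrix(self.spec)

    def summary(self) -> str:
        lines = [
            f"family          : {self.family.label()}",
            f"n_model         : {self.n_model}",
            f"loglik (cond.)  : {self.loglik_conditional:.4f}",
            f"loglik_max      : {self.loglik_max:.4f}",
            f"AIC             : {self.aic:.4f}",
            f"BIC             : {self.bic:.4f}",
            f"converged       : {self.converged}",
        ]
        if isinstance(self.spec, RsDar1Spec):
            lines.append(f"phi by regime   : {np.round(self.spec.phi_by_regime, 4)}")
            for k in range(self.spec.K):
                lines.append(f"p_eps regime {k + 1}  : "
                             f"{np.round(self.spec.p_eps_by_regime[k], 4)}")
        elif isinstance(self.spec, DarmaSpec):
            lines.append(f"phi             : {self.spec.rho[0]:.4f}")
            lines.append(f"p_eps           : {np.round(self.spec.p_eps, 4)}")
        return "\n".join(lines)


def information_criteria(loglik_max: float, n_model: int, T: int) -> tuple:
    """AIC = -2 l_max + 2 n_model and BIC = -2 l_max + n_model ln T."""
    if T < 2:
        raise InvalidModelError("T must be >= 2")
    aic = -2.0 * loglik_max + 2.0 * n_model
    bic = -2.0 * loglik_max + n_model * np.log(T)
    return float(aic), float(bic)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _spec_matrix(spec) -> TransitionMatrix:
    if isinstance(spec, TransitionMatrix):
        return spec
    if isinstance(spec, RsDar1Spec):
        return rs_dar1_transition_matrix(spec)
    if isinstance(spec, DarmaSpec):
        if (spec.p, spec.q) != (1, 0):
            raise InvalidModelError("Markov likelihood requires a DAR(1) spec (p=1, q=0)")
        return dar1_transition_matrix(spec.rho[0], spec.p_eps, spec.range)
    raise InvalidModelError(f"cannot build a transition matrix from {type(spec).__name__}")


def _count_stats(x: np.ndarray, regime_of: np.ndarray, d: int, n: int, K: int):
    """Sufficient statistics for RS-DAR(1) likelihoods with regime delay d:
    A[k, i] = #{t : regime k, x_t = i = x_{t-1}} (persistence-compatible),
    B[k, i] = #{t : regime k, x_t = i != x_{t-1}}."""
    T = x.size
    if T < d + 1:
        raise InvalidModelError(f"series of length {T} too short for delay {d}")
    reg = regime_of[x[: T - d]]
    prev = x[d - 1: T - 1]
    cur = x[d:]
    same = cur == prev
    idx = reg * n + cur
    A = np.bincount(idx[same], minlength=K * n).reshape(K, n).astype(float)
    B = np.bincount(idx[~same], minlength=K * n).reshape(K, n).astype(float)
    return A, B


def _loglik_from_stats(A, B, phi_by_regime, pe_by_regime) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        base = (1.0 - phi_by_regime[:, None]) * pe_by_regime
        lsame = np.log(base + phi_by_regime[:, None])
        ldiff = np.log(base)
    tot = 0.0
    for C, L in ((A, lsame), (B, ldiff)):
        mask = C > 0
        if np.any(np.isneginf(L[mask])):
            return -np.inf
        tot += float(np.sum(C[mask] * L[mask]))
    return tot


def log_likelihood(spec, x: np.ndarray, delay: Optional[int] = None) -> float:
    """Conditional log-likelihood sum_{t>d} ln p_{x_t|x_{t-1}} of an
    integer-coded series under a DAR(1)/RS-DAR(1) spec or an explicit
    transition matrix (d is the spec's regime delay, 1 otherwise).

    Raises :class:`ZeroLikelihoodError`, naming the offending transition,
    if an observed transition has model probability zero.
    """
    x = np.asarray(x, dtype=int)
    d = delay if delay is not None else getattr(spec, "delay", 1)
    if isinstance(spec, RsDar1Spec):
        regime_of = np.asarray(spec.partition.regime_of, dtype=int)
        n, K = spec.range.n_states, spec.K
        phi, pe = spec.phi_by_regime, spec.p_eps_by_regime
    else:
        P = _spec_matrix(spec).P
        n, K = P.shape[0], P.shape[1]
        # treat each source state as its own "regime" with kernel column
        regime_of = np.arange(n)
        phi = np.zeros(n)
        pe = P.T.copy()
        d = 1
    A, B = _count_stats(x, regime_of, d, n, K)
    ll = _loglik_from_stats(A, B, phi, pe)
    if np.isneginf(ll):
        _raise_zero(spec, x, d)
    return ll


def _raise_zero(spec, x, d):
    P = _spec_matrix(spec).P if not isinstance(spec, RsDar1Spec) else None
    labels = getattr(getattr(spec, "range", None), "states", None)
    for t in range(d, x.size):
        if isinstance(spec, RsDar1Spec):
            k = spec.partition.regime_of[x[t - d]]
            prob = (1.0 - spec.phi_by_regime[k]) * spec.p_eps_by_regime[k, x[t]]
            prob += spec.phi_by_regime[k] if x[t] == x[t - 1] else 0.0
        else:
            prob = P[x[t], x[t - 1]]
        if prob <= 0.0:
            prev = labels[x[t - 1]] if labels else int(x[t - 1])
            cur = labels[x[t]] if labels else int(x[t])
            raise ZeroLikelihoodError(t + 1, prev, cur)
    raise AssertionError("zero likelihood reported but no zero transition found")


# ---------------------------------------------------------------------------
# parameter transforms: open cube <-> unconstrained space
# ---------------------------------------------------------------------------

def _softmax_full(z: np.ndarray) -> np.ndarray:
    """m free logits -> pmf of length m+1 (last category is the reference)."""
    z = np.concatenate([z, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _theta_dim(kind: str, K: int, m: int) -> int:
    return {"dar1": 1 + m,
            "rs_dar1_marginal": 1 + K * m,
            "rs_dar1_dependence": K + m,
            "rs_dar1_general": K + K * m}[kind]


def _unpack(kind: str, z: np.ndarray, K: int, m: int):
    """Unconstrained vector -> (phi_by_regime, pe_by_regime)."""
    if kind == "dar1":
        phi = np.repeat(expit(z[0]), 1)
        pe = _softmax_full(z[1:])[None, :]
    elif kind == "rs_dar1_marginal":
        phi = np.repeat(expit(z[0]), K)
        pe = np.stack([_softmax_full(z[1 + k * m: 1 + (k + 1) * m]) for k in range(K)])
    elif kind == "rs_dar1_dependence":
        phi = expit(z[:K])
        pe = np.tile(_softmax_full(z[K:]), (K, 1))
    else:  # general
        phi = expit(z[:K])
        pe = np.stack([_softmax_full(z[K + k * m: K + (k + 1) * m]) for k in range(K)])
    return phi, pe


def _pack(kind: str, phi_by_regime: np.ndarray, pe_by_regime: np.ndarray) -> np.ndarray:
    def logits(pvec):
        p = np.clip(pvec, CLIP, 1.0)
        return np.log(p[:-1]) - np.log(p[-1])

    if kind == "dar1":
        return np.concatenate([[logit(phi_by_regime[0])], logits(pe_by_regime[0])])
    if kind == "rs_dar1_marginal":
        return np.concatenate([[logit(phi_by_regime[0])],
                               *[logits(row) for row in pe_by_regime]])
    if kind == "rs_dar1_dependence":
        return np.concatenate([logit(phi_by_regime), logits(pe_by_regime[0])])
    return np.concatenate([logit(phi_by_regime),
                           *[logits(row) for row in pe_by_regime]])


def _build_spec(family: ModelFamily, rng: CategoricalRange,
                phi_by_regime: np.ndarray, pe_by_regime: np.ndarray):
    phi = np.clip(phi_by_regime, CLIP, 1.0 - CLIP)
    pe = np.clip(pe_by_regime, CLIP, 1.0)
    pe = pe / pe.sum(axis=1, keepdims=True)
    if family.kind == "dar1":
        return dar1(rng, float(phi[0]), pe[0])
    variant = {"rs_dar1_marginal": "marginal_regimes",
               "rs_dar1_dependence": "dependence_regimes",
               "rs_dar1_general": "general"}[family.kind]
    return RsDar1Spec(rng, family.partition, variant, phi, pe, family.delay)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_full_mc(x: np.ndarray, rng: CategoricalRange, family: ModelFamily) -> FitResult:
    """Closed-form ML for the unrestricted Markov chain:
    p_hat[i|j] = N(j -> i) / N(j -> .)."""
    n = rng.n_states
    T = x.size
    counts = np.zeros((n, n))
    np.add.at(counts, (x[1:], x[:-1]), 1.0)
    colsum = counts.sum(axis=0)
    P = np.where(colsum > 0, counts / np.where(colsum > 0, colsum, 1.0), 1.0 / n)
    with np.errstate(divide="ignore"):
        ll = float(np.sum(counts[counts > 0] * np.log(P[counts > 0])))
    n_model = n * (n - 1)
    lmax = T / (T - 1) * ll
    aic, bic = information_criteria(lmax, n_model, T)
    return FitResult(family, TransitionMatrix(P, rng), P[:-1].ravel().copy(),
                     ll, lmax, n_model, T, aic, bic, True, 0)


def _start_heuristic(x: np.ndarray, family: ModelFamily, rng: CategoricalRange) -> np.ndarray:
    """Moment-flavoured starting point: regime-conditional next-state
    frequencies for the innovations, a mildly positive persistence."""
    n = rng.n_states
    part = family.partition or RangePartition.trivial(rng)
    K = part.K if family.kind != "dar1" else 1
    d = family.delay
    regime_of = np.asarray(part.regime_of if family.kind != "dar1" else [0] * n)
    reg, cur = regime_of[x[: x.size - d]], x[d:]
    pe = np.full((K, n), 1.0 / n)
    for k in range(K):
        sel = cur[reg == k]
        if sel.size:
            pe[k] = (np.bincount(sel, minlength=n) + 0.5) / (sel.size + 0.5 * n)
    phi0 = 0.3
    kind = family.kind if family.kind != "dar1" else "dar1"
    phi = np.full(K if kind != "dar1" else 1, phi0)
    if kind == "rs_dar1_dependence":
        pe = np.tile(pe.mean(axis=0), (K, 1))
    return _pack(kind, phi, pe)


def fit_ml(family: ModelFamily, x: np.ndarray, rng: CategoricalRange,
           restarts: int = 10, seed: Union[int, np.random.Generator, None] = None,
           tol: float = 1e-9) -> FitResult:
    """Conditional ML fit of one model family by quasi-Newton multistart.

    The first start is data-driven; the remaining ``restarts - 1`` are drawn
    from a seeded generator in the unconstrained space.  The best maximizer
    over all starts is returned; ``converged`` is False when no start
    converged (the best iterate is still reported).  The full-MC family is
    fitted in closed form from transition counts.
    """
    x = np.asarray(x, dtype=int)
    T = x.size
    if T < 2:
        raise InvalidModelError("need at least 2 observations")
    if family.kind == "full_mc":
        return _fit_full_mc(x, rng, family)

    part = family.partition or RangePartition.trivial(rng)
    n, m = rng.n_states, rng.m
    K = 1 if family.kind == "dar1" else part.K
    if family.kind == "rs_dar1_marginal" and K > m:
        raise InvalidModelError(f"marginal-regime family needs K <= m = {m}")
    d = family.delay
    regime_of = np.asarray(part.regime_of if family.kind != "dar1" else [0] * n)
    A, B = _count_stats(x, regime_of, d, n, K)

    def neg_ll(z):
        phi, pe = _unpack(family.kind, z, K, m)
        return -_loglik_from_stats(A, B, phi, pe)

    gen = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dim = _theta_dim(family.kind, K, m)
    starts = [_start_heuristic(x, family, rng)]
    starts += [gen.normal(0.0, 1.5, size=dim) for _ in range(max(0, restarts - 1))]

    best = None
    converged = False
    for z0 in starts:
        res = minimize(neg_ll, z0, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": tol})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    phi, pe = _unpack(family.kind, best.x, K, m)
    spec = _build_spec(family, rng, phi, pe)
    ll = -float(best.fun)
    n_model = spec.n_model
    lmax = T / (T - d) * ll
    aic, bic = information_criteria(lmax, n_model, T)
    return FitResult(family, spec, best.x.copy(), ll, lmax, n_model, T,
                     aic, bic, converged, len(starts))


@dataclass
class SelectionReport:
    """Fits of all candidate families ranked by an information criterion."""

    criterion: str
    candidates: list = field(default_factory=list)  # (family, FitResult|None, error|None)
    winner: Optional[int] = None

    def best(self) -> FitResult:
        if self.winner is None:
            raise InvalidModelError("no candidate could be fitted")
        return self.candidates[self.winner][1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam, fit, err in self.candidates:
            rows.append({
                "family": fam.label(),
                "n_model": fit.n_model if fit else None,
                "loglik_max": fit.loglik_max if fit else None,
                "aic": fit.aic if fit else None,
                "bic": fit.bic if fit else None,
                "error": err,
            })
        df = pd.DataFrame(rows)
        df["selected"] = [i == self.winner for i in range(len(rows))]
        return df


def select_model(x: np.ndarray, candidates: Sequence[ModelFamily],
                 rng: CategoricalRange, criterion: str = "bic",
                 restarts: int = 10,
                 seed: Union[int, np.random.Generator, None] = None) -> SelectionReport:
    """Fit every candidate family and rank by AIC or BIC (lower is better).

    Candidates whose fit raises are recorded with their error message, not
    silently dropped.
    """
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise InvalidModelError("criterion must be 'aic' or 'bic'")
    if not candidates:
        raise InvalidModelError("need at least one candidate family")
    gen = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    report = SelectionReport(criterion=criterion)
    scores = []
    for fam in candidates:
        try:
            fit = fit_ml(fam, x, rng, restarts=restarts, seed=gen)
            report.candidates.append((fam, fit, None))
            scores.append(getattr(fit, criterion))
        except Exception as exc:  # noqa: BLE001 - reported to the user
            report.candidates.append((fam, None, str(exc)))
            scores.append(np.inf)
    if np.isfinite(min(scores)):
        report.winner = int(np.argmin(scores))
    return report


# ---------------------------------------------------------------------------
# regularity diagnostics
# ---------------------------------------------------------------------------

@dataclass
class RegularityReport:
    """Runtime checks mirroring the classical ML regularity conditions for
    Markov chains: irreducibility of the fitted kernel, full rank of the
    Jacobian of transition probabilities w.r.t. the parameters
    (identifiability), and distance of parameters from the boundary."""

    irreducible: bool
    jacobian_rank: int
    n_model: int
    boundary_params: list

    @property
    def full_rank(self) -> bool:
        return self.jacobian_rank >= self.n_model

    @property
    def ok(self) -> bool:
        return self.irreducible and self.full_rank and not self.boundary_params

    def summary(self) -> str:
        return (f"irreducible={self.irreducible}, "
                f"jacobian rank {self.jacobian_rank}/{self.n_model} "
                f"({'full' if self.full_rank else 'DEFICIENT'}), "
                f"boundary params: {self.boundary_params or 'none'}")


def _natural_theta(spec) -> tuple:
    """(theta vector on the natural scale, rebuild function)."""
    if isinstance(spec, RsDar1Spec):
        K, m = spec.K, spec.range.m
        if spec.variant == "marginal_regimes":
            theta = np.concatenate([[spec.phi_by_regime[0]],
                                    spec.p_eps_by_regime[:, 1:].ravel()])

            def rebuild(th):
                phi = np.repeat(th[0], K)
                tails = th[1:].reshape(K, m)
                pe = np.column_stack([1.0 - tails.sum(axis=1), tails])
                return phi, pe
        elif spec.variant == "dependence_regimes":
            theta = np.concatenate([spec.phi_by_regime, spec.p_eps_by_regime[0, 1:]])

            def rebuild(th):
                phi = th[:K]
                tail = th[K:]
                pe = np.tile(np.concatenate([[1.0 - tail.sum()], tail]), (K, 1))
                return phi, pe
        else:
            theta = np.concatenate([spec.phi_by_regime, spec.p_eps_by_regime[:, 1:].ravel()])

            def rebuild(th):
                phi = th[:K]
                tails = th[K:].reshape(K, m)
                pe = np.column_stack([1.0 - tails.sum(axis=1), tails])
                return phi, pe
        part = spec.partition
        n = spec.range.n_states

        def matrix(th):
            phi, pe = rebuild(th)
            P = np.empty((n, n))
            for j in range(n):
                k = part.regime_of[j]
                P[:, j] = (1.0 - phi[k]) * pe[k]
                P[j, j] += phi[k]
            return P

        return theta, matrix
    if isinstance(spec, DarmaSpec):
        theta = np.concatenate([[spec.rho[0]], spec.p_eps[1:]])

        def matrix(th):
            pe = np.concatenate([[1.0 - th[1:].sum()], th[1:]])
            return (1.0 - th[0]) * np.tile(pe[:, None], (1, pe.size)) + th[0] * np.eye(pe.size)

        return theta, matrix
    raise InvalidModelError("regularity checks need a DAR(1) or RS-DAR(1) spec")


def check_regularity(spec, boundary_tol: float = 1e-3,
                     rank_tol: float = 1e-7) -> RegularityReport:
    """Diagnostics on a (fitted) spec: irreducibility of its kernel,
    numerical rank of d vec(P) / d theta against n_model, and parameters
    within ``boundary_tol`` of {0, 1}.

    The transition probabilities are quadratic in the parameters, so central
    differences are exact up to cancellation noise (~1e-10 at step 1e-6);
    ``rank_tol`` sits above that floor and far below any genuine singular
    value of an identifiable model.
    """
    theta, matrix = _natural_theta(spec)
    P = matrix(theta)
    irreducible = is_irreducible(P)
    h = 1e-6
    J = np.empty((P.size, theta.size))
    for j in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (matrix(tp) - matrix(tm)).ravel() / (2 * h)
    rank = int(np.linalg.matrix_rank(J, tol=rank_tol))
    boundary = []
    if isinstance(spec, RsDar1Spec):
        named = ([(f"phi({k + 1})", v) for k, v in enumerate(spec.phi_by_regime)]
                 + [(f"p_eps({k + 1})[{spec.range.states[i]}]", spec.p_eps_by_regime[k, i])
                    for k in range(spec.K) for i in range(spec.range.n_states)])
        n_model = spec.n_model
    else:
        named = [("phi", spec.rho[0])] + [
            (f"p_eps[{spec.range.states[i]}]", v) for i, v in enumerate(spec.p_eps)]
        n_model = spec.n_model - (spec.p + spec.q - 1)
    for name, v in named:
        if v < boundary_tol or v > 1.0 - boundary_tol:
            boundary.append(name)
    return RegularityReport(irreducible, rank, n_model, boundary)


# ---------------------------------------------------------------------------
# forecasting
# ---------------------------------------------------------------------------

def _as_state_index(rng: Optional[CategoricalRange], state) -> int:
    if isinstance(state, (int, np.integer)):
        return int(state)
    if rng is None:
        raise InvalidModelError("state labels need a range")
    return rng.index(state)


def forecast_distribution(spec, current_state, horizon: int = 1) -> np.ndarray:
    """h-step-ahead conditional distribution: the ``current_state`` column
    of P^h.  As horizon grows this converges to the stationary law."""
    if horizon < 1:
        raise InvalidModelError("horizon must be >= 1")
    tm = _spec_matrix(spec)
    j = _as_state_index(tm.range, current_state)
    return tm.power(horizon)[:, j]


def prediction_set(spec, current_state, level: float = 0.95,
                   horizon: int = 1, contiguous: bool = False) -> list:
    """Smallest set of states whose h-step-ahead probability mass reaches
    ``level``, given the current state.

    States are accumulated by decreasing probability (ties: lower state
    index), so the set has minimal cardinality; with ``contiguous`` the
    shortest contiguous run of states reaching the level is returned
    instead (sensible for ordinal ranges).  Returns state labels when the
    spec carries a range, else indices, in range order.
    """
    if not 0.0 < level < 1.0:
        raise InvalidModelError("level must be in (0, 1)")
    dist = forecast_distribution(spec, current_state, horizon)
    n = dist.size
    eps = 1e-12
    if contiguous:
        best = None
        for a in range(n):
            acc = 0.0
            for b in range(a, n):
                acc += dist[b]
                if acc >= level - eps:
                    cand = (b - a + 1, -acc, a)
                    if best is None or cand < best:
                        best = cand
                    break
        if best is None:
            idx = list(range(n))
        else:
            idx = list(range(best[2], best[2] + best[0]))
    else:
        order = sorted(range(n), key=lambda i: (-dist[i], i))
        acc = 0.0
        idx = []
        for i in order:
            idx.append(i)
            acc += dist[i]
            if acc >= level - eps:
                break
        idx.sort()
    tm_range = _spec_matrix(spec).range
    if tm_range is not None:
        return [tm_range.states[i] for i in idx]
    return idx
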