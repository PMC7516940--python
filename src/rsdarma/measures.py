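"""Dispersion and serial-dependence measures for categorical series.

Nominal dispersion (IQV, normalized entropy) is maximal at the uniform
distribution; ordinal dispersion (IOV, CPE) is maximal at the extreme
two-point distribution with all cumulative probabilities equal to 0.5.
Serial dependence at lag h is measured by Cohen's kappa (signed, from the
diagonal excess of the lag-h bivariate distribution), its ordinal analogue
built from cumulative bivariate probabilities, and the unsigned Cramer's v.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .exceptions import (
    DegenerateDistributionError,
    InvalidModelError,
    NominalRangeError,
)
from .states import (
    BivariateTable,
    CategoricalRange,
    validate_cumulative,
    validate_pmf,
)


def _xlogx(v: np.ndarray) -> np.ndarray:
    """x*ln(x) with the 0*ln(0) := 0 convention."""
    out = np.zeros_like(v, dtype=float)
    pos = v > 0
    out[pos] = v[pos] * np.log(v[pos])
    return out


def iqv(p) -> float:
    """Index of qualitative variation (Gini index), (m+1)/m * (1 - sum p_i^2).

    Equals 0 at a one-point distribution and 1 at the uniform distribution.
    """
    p = validate_pmf(p)
    m = p.size - 1
    return float((m + 1) / m * (1.0 - np.sum(p**2)))


def entropy_norm(p) -> float:
    """Entropy normalized to [0,1]: -sum p_i ln p_i / ln(m+1)."""
    p = validate_pmf(p)
    return float(-np.sum(_xlogx(p)) / np.log(p.size))


def _require_ordinal(rng: Optional[CategoricalRange], what: str) -> None:
    if rng is not None and not rng.ordinal:
        raise NominalRangeError(f"{what} is defined for ordinal ranges only")


def iov(f, rng: Optional[CategoricalRange] = None) -> float:
    """Index of ordinal variation, 4/m * sum_i f_i (1 - f_i), from the
    cumulative vector (f_0, ..., f_{m-1})."""
    _require_ordinal(rng, "IOV")
    f = validate_cumulative(f)
    m = f.size
    return float(4.0 / m * np.sum(f * (1.0 - f)))


def cpe(f, rng: Optional[CategoricalRange] = None) -> float:
    """Cumulative paired entropy,
    -1/(m ln 2) * sum_i [f_i ln f_i + (1-f_i) ln(1-f_i)]."""
    _require_ordinal(rng, "CPE")
    f = validate_cumulative(f)
    m = f.size
    return float(-(np.sum(_xlogx(f)) + np.sum(_xlogx(1.0 - f))) / (m * np.log(2.0)))


def kappa(table: BivariateTable) -> float:
    """Cohen's kappa at the table's lag:
    (sum_i p_ii(h) - sum_i p_i^2) / (1 - sum_i p_i^2).

    Positive values indicate a tendency to stay in (or return to) the same
    state after h steps; the lower bound is -sum p_i^2 / (1 - sum p_i^2).
    """
    p = table.p
    s2 = float(np.sum(p**2))
    if 1.0 - s2 <= 1e-12:
        raise DegenerateDistributionError("marginal is degenerate; kappa undefined")
    return float((np.trace(table.joint) - s2) / (1.0 - s2))


def kappa_ord(table: BivariateTable, rng: Optional[CategoricalRange] = None) -> float:
    """Ordinal Cohen's kappa: sum_{i<m} (f_ii(h) - f_i^2) / sum_{i<m} f_i(1-f_i),
    where f_ij(h) is the double-cumulated joint."""
    _require_ordinal(rng, "ordinal kappa")
    f = np.cumsum(table.p)[:-1]
    den = float(np.sum(f * (1.0 - f)))
    if den <= 1e-12:
        raise DegenerateDistributionError("marginal is degenerate; ordinal kappa undefined")
    fii = np.diag(table.cumulative_joint())[:-1]
    return float(np.sum(fii - f**2) / den)


def cramers_v(table: BivariateTable) -> float:
    """Cramer's v at the table's lag:
    sqrt( (1/m) * sum_{i,j} (p_ij(h) - p_i p_j)^2 / (p_i p_j) ).

    An unsigned dependence measure; under a first-order discrete AR model
    v(h) coincides with kappa(h), so a gap between the two is diagnostic of
    richer transition structure.
    """
    p = table.p
    if np.any(p <= 0):
        raise DegenerateDistributionError("Cramer's v requires strictly positive marginals")
    m = p.size - 1
    outer = np.outer(p, p)
    return float(np.sqrt(np.sum((table.joint - outer) ** 2 / outer) / m))


def sample_bivariate(x, h: int, n_states: Optional[int] = None) -> BivariateTable:
    """Empirical lag-h bivariate table of an integer-coded series.

    The joint frequencies use the T-h lag pairs,
    ``joint[i, j] = #{t : x_t = i, x_{t-h} = j} / (T - h)``,
    while the marginal ``p`` stored for the dependence-measure denominators
    uses all T observations (the mismatch is O(1/T)).
    """
    x = np.asarray(x)
    if x.dtype.kind not in "iu":
        raise InvalidModelError("sample_bivariate expects an integer-coded series")
    T = x.size
    if h < 1:
        raise InvalidModelError("lag must be >= 1")
    if T < h + 2:
        raise InvalidModelError(f"series of length {T} too short for lag {h}")
    n = int(n_states) if n_states is not None else int(x.max()) + 1
    cur, prev = x[h:], x[:-h]
    counts = np.bincount(cur * n + prev, minlength=n * n).reshape(n, n).astype(float)
    joint = counts / (T - h)
    p = np.bincount(x, minlength=n).astype(float) / T
    return BivariateTable(joint, h, p)


def sample_marginal(x, n_states: Optional[int] = None) -> np.ndarray:
    """Relative frequencies of an integer-coded series."""
    x = np.asarray(x)
    n = int(n_states) if n_states is not None else int(x.max()) + 1
    return np.bincount(x, minlength=n).astype(float) / x.size
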