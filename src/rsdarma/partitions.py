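"""Set-partition combinatorics for regime enumeration.

The number of ways to split the m+1 states into exactly K non-empty regimes
is the Stirling number of the second kind S(m+1, K); the total over all K is
the Bell number B_{m+1}.  Enumeration follows restricted-growth-string order
(blocks sorted by smallest member index), so output order is reproducible.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterator, Optional

from .exceptions import InvalidModelError, PartitionBlowupError
from .states import CategoricalRange, RangePartition


@lru_cache(maxsize=None)
def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind via the standard recursion
    S(n,k) = k*S(n-1,k) + S(n-1,k-1), with S(0,0)=1 and S(n,0)=S(0,n)=0."""
    if n < 0 or k < 0:
        raise InvalidModelError("stirling2 requires non-negative arguments")
    if n == 0 and k == 0:
        return 1
    if n == 0 or k == 0:
        return 0
    if k > n:
        return 0
    return k * stirling2(n - 1, k) + stirling2(n - 1, k - 1)


def bell(n: int) -> int:
    """Bell number B_n = sum_K S(n, K); B_0 = 1."""
    if n < 0:
        raise InvalidModelError("bell requires a non-negative argument")
    if n == 0:
        return 1
    return sum(stirling2(n, k) for k in range(1, n + 1))


def _rgs(n: int, k: Optional[int]) -> Iterator[tuple]:
    """Yield restricted growth strings of length n (optionally with exactly
    k distinct values).  a[0]=0 and a[i] <= max(a[:i]) + 1."""
    a = [0] * n

    def rec(i: int, mx: int):
        if i == n:
            if k is None or mx + 1 == k:
                yield tuple(a)
            return
        for v in range(mx + 2):
            a[i] = v
            yield from rec(i + 1, max(mx, v))

    yield from rec(1, 0)


def enumerate_partitions(
    rng: CategoricalRange, k: Optional[int] = None, cap: int = 100_000
) -> Iterator[RangePartition]:
    """Yield every partition of the state set, each exactly once.

    If ``k`` is given, only partitions into exactly k regimes are yielded
    (there are S(m+1, k) of them); otherwise all B_{m+1}.  Refuses to start
    when the total count exceeds ``cap``.
    """
    n = rng.n_states
    if k is not None and not 1 <= k <= n:
        raise InvalidModelError(f"k must be in 1..{n}, got {k}")
    total = bell(n) if k is None else stirling2(n, k)
    if total > cap:
        raise PartitionBlowupError(
            f"{total} partitions exceed the cap of {cap}; raise `cap` explicitly"
        )
    for code in _rgs(n, k):
        yield RangePartition(rng, code)
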