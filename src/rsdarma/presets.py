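"""Reference fitted models used by the fixture generator and the examples.

Two case studies anchor the package.  The first is the genome of the bovine
leukemia virus (a nominal sequence of T = 8419 bases over {a, c, g, t}),
where the best-scoring parsimonious Markov model is a three-regime RS-DAR(1)
with regime-specific innovation distributions: purines {a, g} grouped, the
pyrimidines c and t each their own regime.  The second is an hourly ordinal
cloudiness series (T = 744, one month at a north-German weather station)
over the okta-based states SKC < FEW < SCT < BKN < OVC, with a threshold-style
two-regime model (at most scattered clouds vs broken/overcast); a
three-regime refinement is the AIC-preferred alternative.

All parameters below are the published point estimates rounded to three
decimals; innovation vectors are renormalized to machine precision.
"""

from __future__ import annotations

import numpy as np

from .regime import RsDar1Spec
from .states import CLOUDINESS_RANGE, DNA_RANGE, RangePartition


def _rows(rows) -> np.ndarray:
    a = np.asarray(rows, dtype=float)
    return a / a.sum(axis=1, keepdims=True)


def dna_three_regime_model(delay: int = 1) -> RsDar1Spec:
    """Three-regime marginal RS-DAR(1) for the bovine leukemia virus genome:
    partition {a,g} | {c} | {t}, phi = 0.061."""
    part = RangePartition.from_blocks(DNA_RANGE, [("a", "g"), ("c",), ("t",)])
    pe = _rows([
        [0.244, 0.299, 0.245, 0.211],
        [0.216, 0.352, 0.143, 0.289],
        [0.181, 0.360, 0.240, 0.219],
    ])
    return RsDar1Spec.marginal(DNA_RANGE, part, 0.061, pe, delay)


DNA_SERIES_LENGTH = 8419


def cloudiness_two_regime_model(delay: int = 1) -> RsDar1Spec:
    """Two-regime marginal RS-DAR(1) for hourly cloudiness:
    partition {SKC,FEW,SCT} | {BKN,OVC} (threshold at SCT), phi = 0.547."""
    part = RangePartition.from_blocks(
        CLOUDINESS_RANGE, [("SKC", "FEW", "SCT"), ("BKN", "OVC")])
    pe = _rows([
        [0.091, 0.395, 0.238, 0.269, 0.006],
        [0.000, 0.050, 0.195, 0.560, 0.194],
    ])
    return RsDar1Spec.marginal(CLOUDINESS_RANGE, part, 0.547, pe, delay)


def cloudiness_three_regime_model(delay: int = 1) -> RsDar1Spec:
    """Three-regime marginal RS-DAR(1) for hourly cloudiness:
    partition {SKC,FEW} | {SCT} | {BKN,OVC} (thresholds at FEW and SCT),
    phi = 0.592.  The AIC-preferred refinement of the two-regime model."""
    part = RangePartition.from_blocks(
        CLOUDINESS_RANGE, [("SKC", "FEW"), ("SCT",), ("BKN", "OVC")])
    pe = _rows([
        [0.154, 0.414, 0.302, 0.130, 0.000],
        [0.031, 0.486, 0.001, 0.464, 0.018],
        [0.000, 0.055, 0.204, 0.361, 0.380],
    ])
    return RsDar1Spec.marginal(CLOUDINESS_RANGE, part, 0.592, pe, delay)


CLOUDINESS_SERIES_LENGTH = 744
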