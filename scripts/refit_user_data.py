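#!/usr/bin/env python
"""Refit the candidate model table on a user-supplied categorical series.

The original external series behind the two case studies (an NCBI viral
genome and a national weather-service cloudiness record) are not bundled;
users holding such a series can reproduce the full analysis with this
script: sample dispersion/dependence statistics, conditional ML fits of
DAR(1), partition-based RS-DAR(1) candidates and the full Markov chain, and
the AIC/BIC ranking table.

Examples
--------
    python scripts/refit_user_data.py genome.fasta
    python scripts/refit_user_data.py cloudiness.txt \\
        --range SKC,FEW,SCT,BKN,OVC --ordinal
"""

from __future__ import annotations

import argparse

import numpy as np

import rsdarma as rd
from rsdarma.fit import ModelFamily


def default_candidates(rng: rd.CategoricalRange) -> list:
    """DAR(1), full MC, and every 2- and 3-block partition as marginal-regime
    RS-DAR(1) candidates (capped for large ranges)."""
    cands = [ModelFamily("dar1")]
    m = rng.m
    for k in (2, 3):
        if k <= m and rd.stirling2(rng.n_states, k) <= 30:
            for part in rd.enumerate_partitions(rng, k):
                cands.append(ModelFamily("rs_dar1_marginal", part))
    cands.append(ModelFamily("full_mc"))
    return cands


def main() -> None:
    ap = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter)
    ap.add_argument("series", help="FASTA / token / one-column CSV series file")
    ap.add_argument("--range", dest="range_csv", default=None,
                    help="comma-separated state labels in range order")
    ap.add_argument("--ordinal", action="store_true")
    ap.add_argument("--criterion", choices=("aic", "bic"), default="bic")
    ap.add_argument("--restarts", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    states = ([s.strip() for s in args.range_csv.split(",")]
              if args.range_csv else None)
    x, rng = rd.read_series(args.series, states=states, ordinal=args.ordinal)
    print(f"T = {x.size}, range = {rng.states} ({'ordinal' if rng.ordinal else 'nominal'})")

    p = rd.sample_marginal(x, rng.n_states)
    tab = rd.sample_bivariate(x, 1, rng.n_states)
    print(f"marginal: {np.round(p, 3)}")
    print(f"IQV = {rd.iqv(p):.3f}, entropy = {rd.entropy_norm(p):.3f}")
    print(f"kappa_hat(1) = {rd.kappa(tab):.3f}", end="")
    if np.all(p > 0):
        print(f", v_hat(1) = {rd.cramers_v(tab):.3f}", end="")
    print()
    if rng.ordinal:
        f = rd.cumulative_from_pmf(p)
        print(f"f_hat = {np.round(f, 3)}")
        print(f"IOV = {rd.iov(f, rng):.3f}, CPE = {rd.cpe(f, rng):.3f}, "
              f"kappa_ord_hat(1) = {rd.kappa_ord(tab, rng):.3f}")

    report = rd.select_model(x, default_candidates(rng), rng,
                             criterion=args.criterion,
                             restarts=args.restarts, seed=args.seed)
    df = report.to_frame()[["family", "n_model", "loglik_max", "aic", "bic",
                            "selected"]]
    print()
    print(df.to_string(index=False, float_format="%.1f"))
    best = report.best()
    print(f"\nselected by {args.criterion.upper()}: {best.family.label()}")
    print(best.summary())
    if best.family.kind != "full_mc":
        print("regularity: " + rd.check_regularity(best.spec).summary())


if __name__ == "__main__":
    main()
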