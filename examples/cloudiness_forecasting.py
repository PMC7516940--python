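"""Forecast hourly cloudiness with a threshold-style two-regime model.

The ordinal okta-based states SKC < FEW < SCT < BKN < OVC are split at SCT:
below the threshold the sky tends to produce low-cloud innovations, above it
mostly broken/overcast ones.  The script prints the stationary ordinal
dispersion, the lag-1 ordinal kappa, and the 95% prediction-set rules that a
forecaster would apply given the current state.
"""

import numpy as np

import rsdarma as rd

spec = rd.cloudiness_two_regime_model()
print(f"partition: {spec.partition.describe()}   phi = {spec.phi_by_regime[0]:.3f}")

tm = rd.rs_dar1_transition_matrix(spec)
p = rd.stationary_distribution(tm)
f = rd.cumulative_from_pmf(p)
tab = rd.model_bivariate(tm, 1)

print("\ncumulative stationary distribution f:", np.round(f, 3))
print(f"IOV = {rd.iov(f, spec.range):.3f}, CPE = {rd.cpe(f, spec.range):.3f}"
      "  (1 would mean an extreme two-point sky: half clear, half overcast)")
print(f"ordinal kappa(1) = {rd.kappa_ord(tab, spec.range):.3f}"
      "  (strong hour-to-hour persistence)")

print("\n95% one-hour-ahead prediction sets:")
for s in spec.range.states:
    dist = rd.forecast_distribution(spec, s, 1)
    mode = spec.range.states[int(np.argmax(dist))]
    ps = rd.prediction_set(spec, s, 0.95)
    print(f"  now {s:>3}: point forecast {mode:>3}, set {{{', '.join(ps)}}}")
print("\n(the point forecast is always the current state; the sets say how"
      "\n far the sky can plausibly move within one hour)")
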