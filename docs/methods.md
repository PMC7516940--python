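# Methods

## Model class

The package implements the "NDARMA" flavour of discrete ARMA models — each
observation is a multinomial random selection among the past p observations
and the q+1 most recent i.i.d. innovations — and its observation-driven
regime-switching extension, where the selection weights ρ and/or the
innovation distribution p_ε depend on the regime (partition block) of the
delayed observation X_{t−d}.  The nested alternative family defined through
backshift recursions is out of scope, as are hidden-Markov and
mixture-transition constructions on top of RS-DAR(1) and smooth/hysteresis
regime transitions.

Key structural facts used throughout:

- For K = 1 the switching model reduces exactly to the ordinary discrete
  ARMA model; simulation is routed through one core recursion so the
  reduction holds bitwise at equal seeds.
- For q = 0 the process is Markov of order max(p, d) and transition
  probabilities are available in closed form (`rs_darp_transition_prob`);
  for q > 0 the process is not Markov in X alone, so model-implied
  dependence measures are obtained by simulation and the exact
  kernel/bivariate route is restricted to q = 0.
- Discrete ARMA bivariate tables have the form
  p_ij(h) = (1−κ)p_i p_j + κ δ_ij p_j, which forces the nominal and ordinal
  Cohen's κ to coincide; regime switching breaks this identity, and the
  package exposes both measures so the gap can be used diagnostically
  (likewise κ vs Cramér's v, which coincide under DAR(1)).

## Measures

Table-style measures operate on validated containers: probability vectors
(sum to 1 within 1e-10), cumulative vectors (monotone, in [0,1]) and
bivariate tables (non-negative, sum to 1).  Entropy-type measures use the
0·ln 0 := 0 convention.  IQV and normalized entropy are nominal dispersion
measures maximal at the uniform distribution; IOV and CPE are ordinal
measures maximal at f ≡ 0.5.  Cramér's v is implemented as
v(h) = [(1/m) Σ_ij (p_ij − p_i p_j)² / (p_i p_j)]^{1/2}, the convention under
which v(1) = κ(1) holds exactly for a DAR(1); this is validated against the
reference pair (κ, v) ≈ (0.080, 0.111) of the DNA model.

Sample estimators use the T−h lag pairs for the joint table and all T
observations for the marginal entering the denominators; the mismatch is
O(1/T) and one convention is fixed so tests are unambiguous.  Degenerate
denominators (one-point marginals) raise a typed error rather than
returning NaN.

## Yule–Walker equations

Cohen's κ of a discrete ARMA(p, q) process satisfies

    κ(h) = Σ_{j=1..p} ϕ_j κ(|h−j|) + Σ_{i=0..q−h} φ_{i+h} r(i),  h ≥ 1,

with r(i) given by a forward recursion in the weights.  For h < p the
|h−j| terms make the system implicit in κ(1..p−1) — for DAR(2),
κ(1) = ϕ1 + ϕ2 κ(1) — so the lag equations are solved jointly as one linear
system over lags 1..H rather than by forward substitution.  The solution is
cross-checked in the test suite against sample κ̂(h) from T = 10^6 simulated
paths for (p,q) ∈ {(1,0), (2,0), (0,1), (1,1)}, with Monte-Carlo standard
errors estimated by batch means (200 batches), which accounts for the
serial correlation of the paths.

## Simulation

One seeded `numpy` generator per call; per step the selection vector D_t is
drawn before ε_t, making paths bit-reproducible by seed.  ε_t is drawn at
every step (whether or not it is selected), as the recursion requires.
Initialization: the pre-sample X and ε values are i.i.d. from the
equal-weight average of the K innovation distributions — exactly the
stationary marginal p_ε when K = 1, and a neutral starting law otherwise —
followed by a discarded burn-in (default 500 steps), which is ample for the
geometric mixing of these chains.

The generator's default study conditions mirror the two reference analyses:
`dna_like` simulates the fitted three-regime DNA model (ϕ = 0.061,
partition {a,g}|{c}|{t}) at T = 8419, and `cloudiness_like` the fitted
two-regime cloudiness model (ϕ = 0.547, threshold at SCT) at T = 744.
These fixtures reproduce the serial-dependence *structure* of the real
series (weak nominal dependence with a κ–v gap; strong ordinal persistence
with piecewise behaviour) but not their idiosyncrasies — real genomes have
long-range compositional heterogeneity and real weather has diurnal cycles
that no first-order chain emulates — so passing tests validate the method
pipeline, not those scientific conclusions about new data.

## Inference

The conditional likelihood ℓ(θ) = Σ_{t>d} ln p_{x_t|x_{t−1}}(θ) is computed
from sufficient counts (regime, previous state, current state), making each
evaluation O(K(m+1)) after one pass over the data.  Optimization runs on an
unconstrained reparameterization — log-odds for persistence, multinomial
logits (last category as reference) for each probability vector — so every
iterate lies in the open parameter cube and ℓ is finite throughout; fits
that genuinely want a boundary (published cloudiness estimates contain
0.000 entries) surface as large negative logits and are clipped at 1e-12
for reporting, with `check_regularity` flagging any parameter within 1e-3
of {0,1}.  L-BFGS-B multistart (default 10 starts: one data-driven,
the rest drawn from a seeded generator) guards against local maxima; the
best value wins and non-convergence is reported, never silently discarded.
The full Markov chain is fitted in closed form from transition counts.

ℓ_max applies the T/(T−d) conditioning correction (T/(T−1) for d = 1); for
delayed-regime models the likelihood conditions on the first d observations
by direct analogy.  AIC/BIC follow the standard formulas; parameter counts
are m+1 (DAR(1)), Km+1 (marginal regimes), m+K (dependence regimes), Km+K
(general), m(m+1) (full chain).  BIC is the consistent criterion for
Markov-model selection and is the default.

`check_regularity` mirrors the classical ML regularity conditions as
runtime diagnostics: strong connectivity of the positive-entry digraph of
the fitted kernel (irreducibility), and the numerical rank of
d vec(P)/dθ at θ̂ against n_model (identifiability; e.g. a marginal-regime
model with every state its own regime is flagged rank-deficient because ϕ
is no longer identifiable).  The transition probabilities are quadratic in
θ, so central differences are exact up to cancellation noise; the rank
tolerance (1e-7) sits above that noise floor and far below genuine singular
values of identifiable models.

## Stationary analysis and forecasting

Stationary distributions solve the invariance equation P p = p as a
least-squares problem on (P − I) stacked with the normalization row —
deterministic and tolerance-controlled (residual required < 1e-10), unlike
power iteration.  Irreducibility is checked first (strong connectivity via
`scipy.sparse.csgraph`); boundary zeros in innovation vectors are allowed
as long as the kernel remains irreducible.  Model-implied lag-h tables are
p_ij(h) = (P^h)_ij p_j.

Forecasts are columns of P^h.  Prediction sets take states in decreasing
probability (ties broken toward lower state index) until the requested
level is reached, giving the smallest-cardinality set; an optional
contiguous mode returns the shortest interval of states instead, which is
the natural presentation for ordinal ranges.  The highest-mass rule
reproduces the three published 95% forecasting rules of the cloudiness
model, which happen to be contiguous anyway.

## Closed-form oracles

Two analytically tractable families serve as independent oracles for the
generic kernel → stationary → bivariate route, each verified to 1e-10 on
100+ randomized parameter draws: the 4-state cross-feeding two-regime
model (stationary law ½(p2, 1−p2, p1, 1−p1), closed-form κ(1) and
κ_ord(1), negative for small ϕ) and the per-state dependence-regime model
(stationary law ∝ p_ε,j/(1−ϕ(j)) with an explicit lag-1 joint).

## Numerical and design choices

- Probability tolerance 1e-10 for all "sums to one" checks; stationary
  residual tolerance 1e-10.
- Partition enumeration in restricted-growth-string order (blocks ordered
  by smallest member), refusing to start past a configurable cap (default
  1e5 partitions) to signal combinatorial blow-up.
- Mixture weights ρ are validated to the open interval (0,1) — boundary
  weights break identifiability — with an explicit `allow_boundary`
  override for degenerate study cases.
- Ordinal ranges are always declared, never inferred by sorting labels;
  ordinal-only measures raise a typed error on nominal ranges.
- State indices are 0-based internally; user-facing output uses labels.
- Test problem sizes: Yule–Walker validation uses T = 10^6 paths; the
  selection study uses 50 replicates at T = 5000 with ϕ = 0.5 and clearly
  separated regime innovation distributions — sizes chosen to make
  Monte-Carlo error small relative to the tolerances being asserted.

## Known limitations

- Exact model-implied dependence measures require q = 0 (first-order
  kernels); moving-average switching models are simulated, not solved.
- No standard errors or confidence intervals are reported for ML
  estimates; the regularity diagnostics justify asymptotic normality but
  interval construction is left to the user.
- The BIC/AIC values of the original external series (genome and weather
  records) require those data; `scripts/refit_user_data.py` reruns the
  analysis when a user supplies them.
- Likelihood evaluation and fitting are restricted to the Markov families
  (DAR(1), RS-DAR(1) variants, full chain); general DARMA(p, q) likelihoods
  would require a hidden-state representation and are not implemented.
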