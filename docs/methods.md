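# Methods

## Model and assumptions

Release is described by a two-pathway reaction scheme. Each fast-pool
(RRP) vesicle carries `N` independent SNARE assemblies; each assembly
completes a calcium-triggered conformational step as an exponential clock
of rate `k1`, and the vesicle fuses when all `N` have fired. Slow-pool
vesicles prepend one exponential step of rate `k2` (reserve-to-RRP
replenishment in vivo; escape from the hemifusion diaphragm in vitro —
because the steps are independent exponentials, the fusion-time law is the
same whether the slow step precedes or follows the fast ones, and the
simulator implements the slow-step-first ordering). A scheme with `N`
concurrent clocks is equivalent to a sequential cascade with rates
`N k1, (N-1) k1, ..., k1`; both forms are implemented and tested against
each other.

Assumptions inherited from this picture:

- Calcium rises instantaneously at the action potential and is constant
  during fusion; time-varying calcium waveforms within a pulse are out of
  scope.
- `k2` is calcium-independent (its measured sensitivity is weak); the
  asynchronous release dominant under tetanic stimulation is out of scope.
- Vesicles are independent except where the finite-capacity variant
  introduces a shared docking-site counter.
- The peak postsynaptic current is linear in released vesicles
  (`psc_peak = gamma * n`), so PPR of currents equals PPR of release, and
  receptor saturation is neglected.

Units package-wide: time in ms, rates in 1/ms, calcium in μM, energies in
kBT (kBT = 1 internally). These match the natural scales of the problem
(T ~ 1 ms, k1 of order 1-10/ms, μM calcium).

## Closed forms and numerics

- The alternating sums in the exact rate/cumulative solutions are evaluated
  directly in double precision and restricted to `N <= 15`; beyond that
  cancellation makes them unreliable, and no biological estimate comes
  close.
- Removable singularities at `j k1 = k2` (and `(j+1) k1 = k2`) switch to
  their analytic limits (`t e^{-k2 t}`-type) when `|j k1 - k2| < 1e-9 k1`.
- The `0^0 = 1` convention applies to the `N = 1` factors
  `(1 - 1/N)^{N-1}` and `(1 - e^{-k1·0})^{N-1}`, their analytic limits.
- Exact peak search brackets `[1e-6/k1, 50/k1]`, uses bounded scalar
  minimisation with relative tolerance 1e-10 in t, and checks the `t = 0`
  boundary (the `N = 1` rate decays monotonically).
- The closed-form peak (`tmax ≈ k1^{-1}[ln N + (ntot2/ntot1)((N-1)/N^3)(k2/k1)]`,
  peak `≈ ntot1 k1 (1-1/N)^{N-1}(1 + ntot2(N-1)/(ntot1 N) k2/k1)`) assumes
  `k2 << k1`; a `TimescaleSeparationWarning` is emitted above
  `k2/k1 = 0.1`. Within `k2/k1 <= 0.01` it agrees with exact maximisation
  to better than 1%.
- Pool sizes are stored as reals (fits return non-integer sizes); the
  count distribution and the simulator require integers and refuse to
  round silently.
- The release-count distribution is the convolution of two independent
  binomials, `Binomial(ntot1, F1(t)) * Binomial(ntot2, F2(t))`, which
  follows from pathway independence; it is validated against Gillespie
  histograms by chi-square.

## Calcium-dependent rate and the collapse

`k1([Ca]) = k0 sqrt(1-c) exp[dG (1-(1-c)^{3/2})]` with
`c = (2 nCa / 3 dG) ln([Ca]/[Ca]0)`. At `c >= 1` the barrier vanishes and
the function raises instead of clamping — silent clamping would corrupt
fits. `nCa` is treated as continuous (a transition-state property, not a
site count).

Two slope conventions matter and are both exposed
(`snare.log_log_slope`): the power-law limit statement concerns the
exponential activation factor, whose log-log slope at the reference
concentration is exactly `nCa`; the full rate includes the Kramers
prefactor `sqrt(1-c)`, which shifts the slope to `nCa (1 - 1/(3 dG))`
(about 1.7% at dG = 20). The acceptance check of the power-law limit uses
the activation-factor slope.

The dimensionless peak is computed as
`r = (a (1-c)^{-1/2} peak)^{1/dG}` — i.e. the `(1-c)^{1/2}` prefactor is
divided out. Under this reading the collapse onto
`r = exp[1-(1-c)^{3/2}]` is an exact algebraic identity in the
`k2/k1 -> 0` limit (verified numerically to ~1e-16); the small reserve-pool
correction factor in the peak is therefore excluded from the collapse and
collapse tolerances scale with `k2/k1`.

## Stochastic simulator

Baseline trials sample per-vesicle fusion times directly (maximum of `N`
exponentials, plus an `Exp(k2)` for slow-pool vesicles) — exact in law for
independent vesicles and far faster than an event loop. The event-driven
Gillespie loop is used where vesicles couple: in the finite-capacity
variant, replenishment fires at rate `k2 * reserve` only while the docked
count is strictly below the capacity (a global counter; with capacity 0
only the initially docked vesicles fuse). The heterogeneous-calcium
variant assigns each vesicle a release-site concentration by weight and
uses `k1 = snare_rate(site)`.

Reproducibility: per-trial generators derive from
`SeedSequence(seed, spawn_key=(trial,))`, so results are bit-identical for
a fixed seed and earlier trials are unaffected when `n_trials` changes.
Summaries use a geometric time grid (200 points from `1e-3/k1` to
`t_end`); count histograms are recorded at five checkpoints to bound
memory.

The fixture generator emits dose-response, cumulative-trace and PPR tables
with multiplicative lognormal noise of specified coefficient of variation
(rates are positive and span decades; additive Gaussian is available).
What the synthetic data do not emulate: correlated measurement errors,
baseline drift, finite sampling of the calcium concentration itself, and
digitisation artefacts of published figures — so passing recovery tests
demonstrates estimator correctness under the stated noise model, not
robustness to every failure mode of real recordings.

## Fitting

All fits minimise squared residuals of log-transformed observables (rates
span ten orders of magnitude across synapses; an offset of 1e-12 guards
zero counts), in bounded transformed coordinates (log amplitudes and
timescales; `dG` in [1, 100] kBT, `nCa` in (0, 12]). Multi-start
optimisation uses Latin-hypercube starts (16 by default; 6 for the joint
trace fits, which begin from asymptotics-based heuristics), is
deterministic for a fixed seed, and breaks ties toward the first best
solution at 1e-10 relative. Confidence half-widths come from the
Gauss-Newton curvature at the optimum and are approximate by construction.

Identifiability is reported, never resolved silently: dose-response fits
return the amplitude `A = ntot1 k0` as a single parameter; traces that end
before the slow phase trigger a warning, pin `k2` to its prior
(0.01/ms by default) and leave `ntot2` identified only through the
product `k2 ntot2`. Model selection over `N` compares raw residual sums of
squares (candidates 1-5 by default, ties toward smaller `N`); no
information criterion is used because the candidates have equal parameter
counts. The reference concentration defaults to the geometric mean of the
data, centring `c` near zero.

The recovery studies use 12-point dose-response tables over 1-100 μM at 5%
noise and four 20-point cumulative traces at 3% noise — designs a
single-synapse experiment can realistically produce. The paired-pulse
recovery design uses 25 intervals over 2 ms - 2 s at moderate release
probability (`k1 T = 1`): a Fisher-information analysis shows that sparser
designs, saturated release (which masks `sigma`), or very weak depletion
(which leaves `tau_RRP` unconstrained) put the timescale parameters'
Cramér-Rao bound above the tested tolerance.

## Plasticity conventions

PPR is defined on cumulative release at pulse end,
`<n_f(T)>/<n_i(T)>`; the slow pool is neglected within a single pulse
(`k2 T << 1`). In the buffer model both the depression bracket and the
facilitation factor use `k1([Ca]_f)` evaluated at the incremented
second-pulse concentration, exactly as the model is stated; whether the
bracket should instead carry the first-pulse rate is left as an open
reading, and the expression as implemented is what all tests check.
Interval grids are logarithmic, 1 ms - 10 s by default; the
optimal-interval search refines the best interior grid point by bounded
maximisation of `|PPR - 1|` in log-interval and flags boundary extrema
(monotone curves).

## Transmission metrics

A response requires strictly more than `M` vesicles (failure sums
`m = 0..M` inclusive). Binomial tails are evaluated through the
regularized incomplete beta function (scipy), stable to RRP sizes of
thousands, and the error-read term uses the survival function directly —
never `1 - cdf`, which cancels catastrophically when the resting tail is
below machine precision.

The failure bound is the Poisson-dominated lower-tail Chernoff bound,
`exp[-alpha n (F/alpha + ln(alpha/F) - 1)]`. For the total-error bound two
forms are provided. The default reproduces the commonly quoted error-read
exponent `-(1-alpha) n ((1-alpha)/Frest + ln(Frest/(1-alpha)) - 1)`;
cross-checking against the standard Chernoff argument shows this exponent
is not a bound on the binomial upper tail as `alpha` approaches `Frest`
(a dedicated test documents the violation), while in the operating regime
`Frest << alpha < FAP` both forms are astronomically small and the total
inequality holds. `form="derived"` gives the guaranteed bound on the whole
domain: the lower-tail bound applied to the complement count,
`-(1-alpha) n ((1-Frest)/(1-alpha) + ln((1-alpha)/(1-Frest)) - 1)`.

The closed-form optimal RRP size balances the leading exponentials of the
two error terms (continuous relaxation plus ceiling). The exact discrete
optimum balances the one-vesicle increments of the two binomial tails
instead, `n = M + ((M+1)K + ln(q/(1-q)))/L` with `K = ln(FAP/Frest)`,
`L = ln((1-Frest)/(1-FAP))`; the two differ by about `K/L` vesicles, which
is negligible when resting release is appreciable (`K <= L`) but reaches
several vesicles for high-sensitivity synapses. Both are available
(`balance="continuous"` / `"discrete"`); the ±1 brute-force agreement of
the continuous form is checked in the `K <= L` regime, the discrete form
everywhere.

## Problem sizes used in validation

Oracle-equivalence checks integrate the master equations with LSODA at
rtol 1e-11 and run 10^4 Gillespie trials per parameter set (15 sets across
`N = 1..5`, `k2/k1 = 1e-4..0.1`); Monte-Carlo comparisons use 3 standard
errors and require at least 10 expected events per grid point (the
Gaussian-regime rule, as in chi-square practice). Recovery studies use 50
seeds. The residual-calcium PPR bound sweeps 300+ residual levels over
0.01-0.3 μM. These sizes make the full suite run in a few minutes on one
CPU while keeping every statistical check in its valid regime.

## Known limitations

- Single-synapse scope: no multi-synapse integration, dendritic
  nonlinearity, or trans-synaptic coupling.
- No spatial calcium microdomains or channel-gating stochasticity; the
  heterogeneous-calcium variant is a static mixture over sites.
- Two-pulse protocols only; trains and post-tetanic potentiation are not
  modelled (they would require calcium-dependent `k2` and variable `T`).
- Confidence intervals are Gauss-Newton approximations; bootstrap is not
  run by default.
- The finite-capacity variant uses a single global docking-site counter;
  per-site refilling rules would need a richer state space.
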