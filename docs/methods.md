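# Methods

## Decision problem and belief model

A decision-maker samples three independent evidence streams, one per option
i ∈ {1, 2, 3}; option values x̄ᵢ are unknown, with a shared Gaussian prior
N(x̄ₚ, σₚ²). Momentary evidence in a step of length dt is
xₜ,ᵢ ~ N(x̄ᵢ dt, σₐ² dt). The running sum Σxₜ,ᵢ and elapsed time t are
sufficient statistics; the conjugate posterior over x̄ᵢ has

    mean  (x̄ₚ σₐ² + σₚ² Σx) / (σₐ² + σₚ² t),   variance  1 / (1/σₚ² + t/σₐ²).

Only this form satisfies both sanity limits: with no data (t = 0) the prior
is returned unchanged, and in the flat-prior limit σₚ² → ∞ the posterior
mean is the running evidence rate Σx/t. Conditional on the current belief,
the posterior mean a step δt later is Normal around the current mean with
variance equal to the drop in posterior variance over the step (the
martingale property of conjugate posterior means); this one-step law,
`transition_std`, is the only stochastic ingredient the dynamic program
needs. Evidence streams are assumed independent across options, and all
options share (σₚ², σₐ²) by default; per-option values are accepted by the
belief type but not exercised by the solver, which assumes exchangeable
options.

## Subjective utility and the stop reward

Utility is linear (identity) or logistic U(x) = m(2/(1+e^{−sx}) − 1) =
m·tanh(sx/2), with half-range m > 0 and slope s > 0 (strictly; s = 0 is
rejected rather than silently treated as linear). Small s is near-linear
(U ≈ (ms/2)x), large s near-stepwise (U → m·sign(x)).

Two conventions are supported for the expected reward rᵢ of stopping on
option i, and the choice matters:

* `reward_mode="expected"` (default): rᵢ = E[U(Xᵢ) | belief], the posterior
  expectation of utility, computed by Gauss–Hermite quadrature (41 nodes).
  This is the Bayes-consistent expected reward and is time-dependent: early
  in a trial the posterior is wide, so a bounded utility is pulled toward
  its mean over both tails. It is what allows the geometric-discounting
  policy to keep sampling at the prior point even when U(x̄ₚ) is already
  close to the cap m — and hence what produces magnitude-sensitive reaction
  times for sharply nonlinear utilities.
* `reward_mode="mean"`: rᵢ = U(x̂ᵢ), utility of the posterior-mean estimate.
  Time-independent. Under this convention a step-like utility with linear
  time costs makes immediate "choose the best" optimal at the prior point
  (sampling cannot raise a reward already at the cap, and waiting costs
  (c+ρ)δt), the classic magnitude-insensitive limit.

The two conventions reproduce complementary qualitative regimes and both
are exposed in configuration; tests exercise each where its prediction is
well-posed.

## Dynamic program

Backward induction runs on a regular grid over x̂ ∈ [−5, 5]³ (41 points per
axis by default; prior mass beyond ±5 is negligible for the default prior
N(1.5, 5)), from horizon T = 3 time units down to 0 in steps δt = 0.05,
with a forced argmax choice at T. Time units are arbitrary throughout. The
horizon is a numerical device, not a model assumption: the transition std
decays like 1/t, boundaries freeze, and results are insensitive to T
beyond roughly 2 units at the default parameters.

The continuation expectation factorizes across options, so it is computed
as three sequential 1-D Gaussian convolutions with the common
time-dependent std s(t). The step kernel is row-normalized on the grid,
i.e. probability mass that would diffuse beyond an edge is reassigned to
the boundary nodes; a constant value function is therefore preserved
exactly. For s(t) below 1e-12 the kernel is the identity.

Cost regimes:

* linear (Bayes Risk): V = max(maxᵢ rᵢ − ρ t_w, ⟨V⟩ − (c+ρ)δt). The
  terminal slice also subtracts ρ t_w, so that stopping value and terminal
  value agree. If ρ is not supplied it is calibrated by bisection on
  ρ ∈ (10⁻⁶, max U / t_w) until |V(0, prior point)| < 10⁻³ — the
  self-consistent reward rate for an indefinite sequence of trials, with
  the residual directly bounding the policy error where trials start. A
  degenerate everywhere-zero utility yields ρ* = 0. Failure to bracket a
  sign change raises a calibration error reporting both bracket values.
* geometric: V = max(maxᵢ rᵢ, ⟨V⟩ γ^δt), with γ ∈ (0, 1) per unit time and
  the per-step factor γ^δt.

Each policy slice stores the value function, the greedy action, and the
signed margin (continuation minus stop value). Ties at the stop argmax are
stored as the lowest option index (deterministic); permutation equivariance
of the stored actions therefore holds everywhere except on the
measure-zero tie set of grid points with equal coordinates, where the
deterministic rule must pick one label. The simulator re-breaks ties
uniformly at random instead. Exact equality of continuation and stop value
is labelled "stop", so the decide region satisfies V = stop exactly.

Boundary triangles are planar cuts orthogonal to the equal-value diagonal:
grid points within half a grid spacing (perpendicular distance) of the
plane x̂₁+x̂₂+x̂₃ = 3v, mapped to the in-plane orthonormal basis
u = (1,−1,0)/√2, w = (1,1,−2)/√6.

Binary problems (n_options = 2) run through the same code path as a
degenerate configuration for cross-checks; more than three options are out
of scope.

## Simulation

Trials accumulate evidence at sim_dt = 5e-3 (much finer than the DP's
δt = 0.05) and update posterior means in closed form. The stop/continue
decision interpolates the margin field trilinearly at the nearest policy
time slice: interpolating a signed scalar rather than looking up the
nearest node's action label avoids staircase aliasing of the boundary at
sim_dt ≪ δt. Estimates that drift off the grid are clamped to the edge for
the lookup (counted and logged, not an error). On stopping, the choice is
the argmax of the posterior means with uniform random tie-breaking; at
t = 0 all three means equal the prior mean, so a policy that decides
immediately chooses uniformly. Trials reaching the horizon take the forced
argmax choice and are flagged censored; censored trials are included in
mean RT (conservative) and the censoring fraction is always reported.
Non-decision time is zero.

Randomness uses one independent generator per option, seeded by (seed,
option key), plus a separate tie-breaking stream. Permuting the true
values together with the option keys therefore permutes choices and leaves
reaction times bit-identical, which is how the symmetry tests assert
equivariance exactly rather than statistically.

The magnitude sweep solves one policy and simulates equal-value triples
(v, v, v) across a value range (default −4 to 4, covering the logistic
saturation at m = 4; the default 17-point grid is a documented choice).
Magnitude sensitivity is summarised by the OLS slope of mean RT on v; its
standard error pools the per-value Monte-Carlo uncertainty, so "slope
excludes zero" is a statement about simulation noise, not about residual
lack of fit of the linear summary.

## Synthetic experimental designs

The fixtures module regenerates the *structure* of two behavioural designs:
a ternary brightness-discrimination schedule (all 4³ = 64 ordered triples
over levels {0.3, 0.4, 0.5, 0.6}; 10 repeats of each of the 4 equal
triples plus 1 of each of the 60 unequal triples → 100 trials; inter-trial
intervals drawn from {0.5, 1.0, 1.5} s; per-frame luminance noise with SD
0.25 × mean brightness, giving a constant signal-to-noise ratio across
magnitudes — noisy frames are deliberately not clipped to [0, 1], since
clipping would break that constancy) and a balanced slime-mould foraging
design (4 egg-yolk concentrations, 20–80 g/L, × 50 replicates = 200 runs).
Schedule order is a uniform shuffle; no further pseudo-randomisation
constraints are imposed.

The synthetic RT generator produces rt = intercept + slope·magnitude +
subject intercept (Normal) + a lognormal residual (shape 0.5, standardised
to a requested SD) to mimic RT skewness. It exists for parameter-recovery
and pipeline tests only: it encodes the linear mean-trend structure by
construction, so recovering a slope from it validates the estimation
plumbing, not any behavioural theory. None of these generators models
sensory, motor or chemotactic mechanism, and passing tests on them says
nothing about real subjects beyond the combinatorics being right.

## Problem sizes and verification

Unit oracles: the belief model is checked against a brute-force discretized
Bayes rule on a fine value grid (<10⁻³ relative error) and a 10⁴-path
Monte-Carlo martingale check (5%); the solver is checked against direct
3-D-quadrature recursion over a 5³ grid with 3 backward steps (<10⁻⁶),
independently of the separable-convolution implementation. Behavioural
checks run the standard 41³ grid with 2,000 trials per sweep value and
10⁴ trials for symmetry; these sizes keep the full suite around half a
minute while leaving Monte-Carlo error well below the effects being
asserted.

## Known limitations

* The grid bounds, resolution, horizon and δt trade accuracy for memory;
  edge renormalization slightly distorts policies near ±5, visible only
  for sweep values near the grid edge.
* Reward-rate calibration assumes the value at the prior point is
  decreasing in ρ with a sign change on the bracket; exotic utilities may
  require a manual ρ.
* Censored trials bias mean RT downward-bounded at the horizon for very
  low-value geometric configurations; the censoring fraction quantifies
  the exposure.
* No fitting to empirical data is provided or attempted; time units are
  arbitrary and no calibration to seconds is made.
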