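# valuedp

Optimal stopping policies and stochastic simulation for **multi-alternative
value-based decisions**, built to study *magnitude sensitivity*: why
reaction times depend on the overall value of the options even when all
options are equally good.

A decision-maker watches three noisy evidence streams, one per option, and
must decide when to stop sampling and which option to take; the reward is
the (subjective) value of the chosen option, and time is costly. `valuedp`
solves this optimal stopping problem by backward-induction dynamic
programming on a 3-D grid of posterior-mean value estimates, for two ways
of costing time and two utility families, and then simulates Bayes-optimal
agents applying those policies to measure their reaction times.

**Who it is for:** computational and behavioural scientists comparing
normative accounts of decision times (humans, other animals, even
unicellular foragers) against sequential-sampling model predictions.

## Model

Each option i has an unknown value rate x̄ᵢ with shared Gaussian prior
N(x̄ₚ, σₚ²). Momentary evidence accumulates as xₜ,ᵢ ~ N(x̄ᵢ dt, σₐ² dt), so
the posterior over x̄ᵢ stays Gaussian with mean

    x̂ᵢ(t) = (x̄ₚ σₐ² + σₚ² Σ xₜ,ᵢ) / (σₐ² + σₚ² t)

Subjective utility is either linear (U(x) = x) or logistic,
U(x) = m (2 / (1 + e^{−sx}) − 1), spanning near-linear (small s) to
near-stepwise (large s) shapes. The value function on the estimate vector
x̂ = (x̂₁, x̂₂, x̂₃) satisfies one of two Bellman equations:

* **linear time cost (Bayes Risk)**, with cost rate c, reward rate ρ and
  inter-trial wait t_w (ρ is calibrated to the self-consistent fixed point
  V(0, prior) = 0 when not supplied):

      V(t, x̂) = max( maxᵢ rᵢ − ρ t_w , ⟨V(t+δt, x̂(t+δt))⟩ − (c+ρ) δt )

* **geometric discounting**, with per-unit-time discount factor γ ∈ (0, 1):

      V(t, x̂) = max( maxᵢ rᵢ , ⟨V(t+δt, x̂(t+δt))⟩ γ^δt )

where rᵢ is the expected reward of taking option i now (by default the
posterior expectation of utility; optionally the utility of the posterior
mean — see `docs/methods.md`), and ⟨·⟩ integrates the diffusion of the
posterior means over the next δt. The resulting policy divides estimate
space, per time slice, into a "wait" region and three "choose" regions;
projections onto planes orthogonal to the equal-value diagonal
x̂₁ = x̂₂ = x̂₃ give the familiar boundary triangles.

The headline contrast: with linear time costs the optimal policy is at most
weakly magnitude-sensitive, while geometric discounting makes both the
boundaries and the simulated reaction times strongly magnitude-sensitive —
decisions are postponed for low-value option sets and accelerate as the
common value grows.

## Worked example

```python
import valuedp as vd

utility = vd.logistic_utility(m=4.0, s=3.5)
cfg = vd.BellmanConfig(cost_regime="geometric", gamma=0.1, utility=utility)
policy = vd.solve_policy(cfg)

res = vd.magnitude_sweep(cfg, values=[-4, -2, 0, 2, 4], n_per_v=2000, seed=1, policy=policy)
print(res.curve[["v", "mean_rt", "ci_lo", "ci_hi"]].round(4).to_string(index=False))

est = vd.magnitude_slope(res.curve)
print(f"magnitude slope: {est.slope:.4f} +/- {est.se:.4f}")

sl = vd.project_boundary_slice(policy, t=0.5, v=-2.0)
print(f"wait fraction at v=-2, t=0.5: {sl.wait_fraction():.3f}")
```

Output:

```
   v  mean_rt  ci_lo  ci_hi
-4.0   0.4567 0.4127 0.5008
-2.0   0.1370 0.1163 0.1577
 0.0   0.0446 0.0425 0.0467
 2.0   0.0345 0.0333 0.0356
 4.0   0.0299 0.0291 0.0308
magnitude slope: -0.0478 +/- 0.0023
wait fraction at v=-2, t=0.5: 0.488
```

Mean reaction time (arbitrary time units) falls monotonically as the common
value v of three equal options rises — strong magnitude sensitivity under
geometric discounting — and the policy's "wait" region occupies about half
of the low-value boundary triangle while vanishing entirely at v = +2.

The same sweep with `cost_regime="linear", c=0.0` (reward rate calibrated
automatically) yields a slope roughly four times shallower, and with linear
utility a slope statistically indistinguishable from zero.

## Command line

```bash
valuedp solve --config cfg.json --out policy.h5
valuedp boundaries --policy policy.h5 --t 0.5 --v 1.0 --out slice.csv
valuedp simulate --policy policy.h5 --values "1.5,1.5,1.5" --n 10000 --seed 1 --out trials.csv
valuedp sweep --config cfg.json --vmin -4 --vmax 4 --points 17 --n 10000 --seed 1 --out curve.csv
valuedp fixtures schedule --seed 1 --out schedule.csv
```

Configs are JSON (e.g. `{"regime": "geometric", "gamma": 0.1}`); every run
writes its fully-resolved configuration beside its outputs. Exit codes: 0
success, 2 configuration error, 3 numerical failure.

The `fixtures` subcommands regenerate the structure of the accompanying
behavioural designs: a 100-trial ternary brightness-discrimination schedule
(4 levels, 10 repeats of each equal triple, 1 of each of the 60 unequal
triples, constant-SNR frame noise) and a 200-run slime-mould foraging
design (4 food concentrations × 50 replicates), plus a synthetic RT dataset
generator for pipeline tests.

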