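# Methods

## Model

The simulator implements a four-compartment emotional-contagion model of
SIR lineage. A crowd of normalised size 1 is divided into emotionally
susceptible (*S*), optimistic (*O*), pessimistic (*P*) and emotionally
stable (*U*) fractions. The stable compartment represents trained
personnel (responders, managers); it is absorbing — individuals cured
into *U* never leave, which makes *U(t)* non-decreasing and, whenever all
cure rates are positive and U(0) > 0, makes U = 1 the only long-run
attractor. The model's distinguishing structural features are:

* **Contact functions.** Positive and stable emotional contact is linear
  in the partner fraction, g₁(x) = k·x. Pessimist contact saturates,
  g₂(P) = k·P/(1 + a·P²): the risk coefficient *a* encodes how strongly
  individuals avoid panic carriers in a severe emergency. a = 0 recovers
  the linear (mass-action) limit; increasing *a* monotonically damps
  pessimist contact.
* **Absorbing cure channel.** S, O and P are cured into U at rates
  θ_s, θ_o, θ_p, each proportional to the contact factor g₁(U) = k·U, so
  curing accelerates as the stable group grows but is very slow while U
  is small.
* **Reduction.** Setting all θ to zero removes the stable compartment's
  influence; with U(0) = 0 this is the three-compartment
  optimist/pessimist contagion model the full model extends. The
  package exposes it as the `reduced` variant, and
  `compare_with_without_u` folds U(0) back into S(0) so the two variants
  start from comparable totals.

The vector field is assembled from one-directional flows, each entering
two compartments with opposite signs, so the components cancel to within
one or two units in the last place (the tests bound the residual by
1e-15) and population conservation holds along every trajectory to 1e-8.

## Parameters

| symbol | meaning | default |
|---|---|---|
| α_o, α_p | spontaneous S→O, S→P conversion | 0.18, 0.04 |
| β_o, β_p | contact-driven S→O, S→P infection | 0.02, 0.04 |
| r_o, r_p | recovery O→S, P→S | 0.088, 0.13 |
| l_o, l_p | O→S after O–P contact, P→S after P–O contact | 0.13, 0.07 |
| m_o, m_p | O→P, P→O conversion on contact | 0.09, 0.009 |
| θ_s, θ_o, θ_p | cure of S, O, P into U | 0.02, 0.01, 0.005 |
| k | contact coefficient (all contact terms) | 1.0 |
| a | risk coefficient (pessimist-contact saturation) | 1.0 |

All probability-rates are validated to [0, 1]; k must be positive, a
nonnegative. Time is dimensionless model time; no calendar mapping is
attempted.

**The calibration caveat.** The published rate table stops at θ_p; the
contact coefficient k and the baseline risk coefficient a appear only
inside the contact functions and are never given numerically. The
package defaults to the neutral k = 1 (k rescales every contact process
identically) and a = 1 (the emergency regime is nonlinear, and small a
barely perturbs trajectories). This choice has real consequences,
measured by the calibration report the acceptance script writes:

* At k = 1 the baseline pessimist peak is 16.6%, the settling time is
  ≈ 419, and the critical initial-pessimist fraction is ≈ 0.21.
* The peak reaches ~30% only near k ≈ 5; the shape-flip threshold
  reaches ~0.34 near k ≈ 4; a settling time of ~70 would need k ≈ 8.
  No single (k, a) cell reproduces all of the narrative figures at once,
  so the defaults were left at the neutral choice rather than tuned to
  any one of them.
* The peak-vs-a response is exactly flat at k ≤ 3.5 (the uniform-start
  pessimist curve is monotone-decreasing, so its maximum is P(0) for
  every a), rises with a in a narrow band around k ≈ 4, and falls with a
  for k ≳ 4.5. The saturation rule below therefore only applies near
  k = 4.

## Numerical choices

* **Integrator.** Classical fixed-step RK4, default dt = 0.01, default
  horizon t_end = 200. Fixed-step keeps runs bit-reproducible across
  machines and runs; the system is non-stiff at the published magnitudes
  (step-halving tests confirm the order-4 error signature). The
  forward-Euler reference integrator (dt = 1e-4) is an independent
  coding of the same field used only as a test oracle; a scipy adaptive
  solve is a second, external cross-check in the suite.
* **Nonnegativity.** The integrator asserts every component ≥ −1e-9 and
  total drift ≤ 1e-8 at every step and fails loudly with the offending
  time; nothing is clamped, because the continuous field preserves
  nonnegativity for valid parameters.
* **Settling time.** "The dynamics have settled" is operationalised as
  the smallest grid time after which the sup-norm of the derivative
  vector across all four compartments stays below tol = 1e-3. The
  all-compartment reading is symmetric and matches the figure-level
  notion of a flat curve; a single-compartment reading (e.g. S only) is
  available via the `compartment` argument. Tolerance 1e-3 on a
  quantity of magnitude ≲ 1 sits above integration error and below
  plotting resolution. At the default calibration the baseline run
  settles at t ≈ 419, far beyond the default horizon; analyses that need
  the settling time therefore use t_end = 1500, and that horizon is the
  package's choice for every settling-time comparison.
* **Curve shapes.** A compartment's trajectory is labelled
  increase-then-decrease / monotone-decrease / monotone-increase / other
  with an absolute tolerance δ = 1e-3: a rise or fall smaller than δ is
  ignored. The label is invariant to appending a settled tail.
* **Peaks.** Grid maxima without interpolation, ties to the earliest
  time; at dt = 0.01 sub-grid refinement is immaterial at reporting
  precision.
* **Critical initial-pessimist fraction.** P(0) is scanned with S(0)
  absorbing the complement (O(0) = 0.1, U(0) = 0.05 held at baseline);
  the increase-then-decrease → monotone-decrease flip is bracketed on a
  0.05 coarse grid and bisected to resolution 0.005 (finer than the
  two-decimal reporting convention). If no flip exists (e.g. P has no
  inflow), the finder raises rather than extrapolating.
* **Risk-coefficient saturation.** Peak P is computed on the decade grid
  a ∈ {0, 10, …, 100}; the saturation point is the smallest grid value
  where the per-unit-a increase of the peak drops below 10% of the
  first-interval increase. The rule's premise — a rising first interval
  — fails when the response is flat or decreasing; the finder then
  raises, and a documented `magnitude=True` variant applies the same
  flattening rule to |Δpeak| for damping-dominated regimes. The
  detection rule, grid and tolerances are recorded verbatim in the
  returned estimate so results are auditable.
* **Initial-condition sweeps** rebalance S to preserve the unit total
  and refuse grids that would drive S negative, listing the offending
  values.

## What the presets do and do not emulate

The presets are the study conditions: a sudden emergency hitting a crowd
with a fixed emotional mix, homogeneous mixing, no network structure, no
stochasticity, no inflow/outflow of people. Passing tests show the
deterministic mean-field machinery is implemented correctly and that the
documented qualitative orderings (more spontaneous pessimism ⇒ higher
pessimist peak; faster pessimist recovery ⇒ earlier settling; larger
initial panic share ⇒ later settling) hold at the default calibration.
They do not show that any particular real crowd follows these curves —
the rate constants derive from a social-network study of emotional
states, not from measured panic events, and the k/a calibration is
unconstrained by data.

## Known limitations

* No analytic equilibrium or stability analysis; all statements are
  simulation-based.
* The absorbing stable compartment makes every full-variant run end at
  U = 1 eventually; "final composition" at a finite horizon is a
  quasi-stationary snapshot, not a true equilibrium (the reduced variant
  does reach a genuine interior equilibrium).
* Fixed-step integration wastes effort on the long, slow tail of
  full-variant runs; acceptable here because a 150,000-step run takes
  well under a second.
* The qualitative claims tied to specific numeric values (peak 30%,
  settling near 70, threshold 0.34, saturation at 20) are reproducible
  only under calibrations of k that are mutually inconsistent; the
  acceptance harness reports all of them against the neutral default
  rather than choosing a different calibration per quantity.
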