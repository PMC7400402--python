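# usospa

A deterministic simulator for the **U-SOSPa-SPSOa** model of group
emotional contagion — panic spreading through a crowd during a public
health emergency — together with the sensitivity-experiment layer used to
analyse it: parameter sweeps, critical-threshold detection and the
with/without-stable-group model comparison.

It is aimed at researchers in crowd dynamics and emergency management who
want a reproducible, tested implementation of this SIR-family emotional
contagion model rather than a one-off simulation script.

## The model

A population normalised to 1 is split into four emotional compartments:
susceptible *S*, optimistic *O*, pessimistic *P*, and emotionally stable
*U* (trained personnel; absorbing). Contact with optimists or stable
individuals is linear, g₁(x) = k·x; contact with pessimists saturates
with the emergency's risk coefficient, g₂(P) = k·P/(1 + a·P²) — under
high risk people shun panic carriers. The dynamics are

```
dS/dt = r_o O + r_p P − (α_o + α_p) S + g₁(O)(l_o P − β_o S)
        + g₂(P)(l_p O − β_p S) − θ_s g₁(U) S
dO/dt = α_o S − r_o O − (m_o + l_o) g₁(O) P + β_o g₁(O) S
        + m_p g₂(P) O − θ_o g₁(U) O
dP/dt = α_p S − r_p P − (m_p + l_p) g₂(P) O + β_p g₂(P) S
        + m_o g₁(O) P − θ_p g₁(U) P
dU/dt = θ_s g₁(U) S + θ_o g₁(U) O + θ_p g₁(U) P
```

with spontaneous conversion rates α, contact-infection rates β,
recoveries r, O↔P cross-conversions m and l, and cure rates θ into the
absorbing stable group. S+O+P+U = 1 is conserved exactly by
construction. Integration is fixed-step classical RK4 (dt = 0.01 by
default), bit-reproducible; an independent forward-Euler reference
integrator serves as an internal oracle in the tests.

Two presets ship with the package: `baseline_sec3` (initials
S, O, P, U = 0.7, 0.1, 0.15, 0.05 with the published rate constants) and
`uniform_sec4` (0.33, 0.33, 0.33, 0.01, used for sensitivity analysis).
The published parameter set does not include the contact coefficient `k`
or a baseline risk coefficient `a`; the package defaults are the neutral
`k = 1, a = 1`, and both are ordinary parameters you can set. See
`docs/methods.md` for what does — and does not — depend on this choice.

## Worked example

```python
import usospa as u

bundle = u.preset("baseline_sec3")
traj = u.integrate(bundle.params, bundle.initial, t_end=1500.0)
print(u.peak(traj, "P"))                  # (3.17, 0.16603336583795666)
print(u.equilibrium_time(traj, tol=1e-3)) # 419.43
print(u.final_composition(traj).U)        # 0.9999998600269813
```

The pessimist share rises from 15% to a peak of 16.6% at t ≈ 3.2, then
declines while the stable group slowly absorbs the whole crowd; all
compartment rates stay below 1e-3 from t ≈ 419 on. The same run from the
shell:

```
usospa simulate --preset baseline_sec3 --out runs/
usospa threshold --target initial-p            # critical P(0): 0.2128 at defaults
usospa figure fig17 --out runs/                # risk-coefficient sweep CSV
```

Each `examples/*.py` script is a short narrative of one capability
(baseline run, panic threshold, risk sweep, model comparison) and prints
the numbers it computes.

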