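# immobead

Kinetics and reaction–diffusion modelling for enzymes immobilized in
spherical hydrogel beads and operated in a fixed-bed (packed-bed) reactor.
The reference system is starch hydrolysis by α-amylase entrapped in
calcium-alginate beads, but every routine is parameterized and applies to
any bead-entrapped biocatalyst with Michaelis–Menten kinetics.

## Who this is for

Biochemical engineers and enzymologists who need to

* estimate Michaelis–Menten parameters (K<sub>m</sub>, V<sub>max</sub>,
  k<sub>2</sub>) from fixed-bed conversion measurements,
* translate those parameters into the dimensionless groups governing
  intraparticle transport (Thiele modulus φ, saturation parameter β), and
* simulate substrate/product concentration fields inside a bead to judge
  whether operation is reaction-rate or diffusion controlled.

## The model

**Kinetics.** Substrate consumption follows the Michaelis–Menten rate law
v = V<sub>max</sub>·S/(K<sub>m</sub> + S). Integrating over a plug-flow
residence time *t* gives the exact relation

```
Km·ln(S0/St) + (S0 − St) = Vmax·t,
```

which links the inlet concentration S₀, outlet concentration S<sub>t</sub>
and residence time t = ε·V<sub>R</sub>/Q (bed voidage × reactor volume /
flow rate). Dividing by K<sub>m</sub>·t and writing X = (S₀ − S<sub>t</sub>)/S₀
linearizes it:

```
ln(1 − X)/t = (S0/Km)·(X/t) − Vmax/Km,
```

a straight line in the (X/t, ln(1−X)/t) plane with slope S₀/K<sub>m</sub>
and intercept −V<sub>max</sub>/K<sub>m</sub>; ordinary least squares on
that line is the estimator. Because the linearization is an algebraic
rearrangement, noiseless data return the generating parameters to
round-off.

**Bead transport.** Inside a bead of radius R with effective diffusivities
D<sub>s</sub>, D<sub>p</sub>, the dimensionless steady state obeys

```
∇²Cs = 9φ²·Cs/(1 + β·Cs),      φ = (R/3)·√(Vmax/(Km·Ds)),  β = S0/Km,
```

with Cs = 1 on the surface, solved on the axisymmetric quarter
cross-section by linear finite elements (and by a 1-D radial scheme for
the radially symmetric case). The transient adds ∂Cs/∂τ and a product
equation with diffusivity ratio λ = D<sub>p</sub>/D<sub>s</sub>; at λ = 1
the sum W = Cs + Cp relaxes to exactly 1, a built-in conservation check.
The effectiveness factor η (volume-averaged rate over the surface rate)
quantifies diffusion limitation: η → 1 means kinetic control.

## Worked example

```python
from immobead import (MMKinetics, ReactorSpec, BeadTransport, residence_time,
                      scenario_table1_like, generate_series, estimate_km_vmax,
                      make_groups, steady_sphere_1d, effectiveness_factor)

# 1. operating point: 60 cm^3 bed, voidage 0.42, 5.04 mL/min feed
spec = ReactorSpec(vr=60.0, epsilon=0.42, q=5.04)
print(f"residence time: {residence_time(spec):.2f} min")

# 2. synthetic conversion campaign (5 % noise) and parameter recovery
series = generate_series(scenario_table1_like(noise_cv=0.05, seed=42))
fit = estimate_km_vmax(series[2], on_complete="drop")   # S0 = 10 g/L
print(f"Km  = {fit.km_hat:.3f} g/L   (truth 3.38)")
print(f"Vmax = {fit.vmax_hat:.3f} g/(L*min)  (truth 8.04)")

# 3. dimensionless groups and a bead simulation
groups = make_groups(BeadTransport(),
                     MMKinetics(km=fit.km_hat, vmax=fit.vmax_hat), s0=10.0)
print(f"phi = {groups.phi:.1f}, beta = {groups.beta:.2f}")
eff = effectiveness_factor(steady_sphere_1d(2.0, groups.beta, 64))
print(f"eta(phi=2) = {eff.eta:.3f}, center Cs = {eff.center_concentration:.3f}")
```

prints

```
residence time: 5.00 min
Km  = 3.282 g/L   (truth 3.38)
Vmax = 7.850 g/(L*min)  (truth 8.04)
phi = 184.6, beta = 3.05
eta(phi=2) = 0.807, center Cs = 0.107
```

The fitted K<sub>m</sub> and V<sub>max</sub> land within a few percent of
the generating truth despite 5 % measurement noise; the effectiveness
factor at φ = 2 says the bead converts at 81 % of its surface-condition
rate, with the center already down to Cs ≈ 0.11 — mild internal diffusion
limitation.

The same workflow is available from the shell:

```
immobead synth --km 3.38 --vmax 8.04 --noise-cv 0.05 --out conv.csv
immobead fit conv.csv --e0 0.081 --out fits.csv
immobead residence-time --flow-rate 0.21        # -> 120 min
immobead simulate-steady --phi 2 --beta 3 --n 64 --out field.csv
immobead run --out results/                     # full pipeline + manifest
```

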