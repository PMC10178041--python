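# Methods

## Model and assumptions

poddry simulates thin-layer convective drying of a single peanut pod as a
rigid, isotropic, two-region continuum: a kernel spheroid (semi-axes
5 × 8 mm) in perfect thermal and hygric contact with a 1 mm shell (the
shell–kernel air gap is neglected). Shrinkage, cracking and porosity
evolution are outside the model, as is any internal vapor-pressure-driven
transport: all internal moisture motion is lumped into a constant effective
diffusivity per tissue. The drying air is an infinite reservoir at fixed
temperature, velocity and humidity. Evaporation happens inside the tissue,
so the latent heat appears as a volumetric sink tied to the local drying
rate rather than as a surface term.

Initial states are uniform per tissue: shell 1.24, kernel 0.74 g/g d.b.
(whole-pod homogeneous runs use 0.83), all at 20 °C. Where the shell and
kernel meet, shared interface nodes start at the mean of the two values; the
jump relaxes within the first few steps and component averages are
insensitive to it at default resolution.

The moisture equation is solved in the conservative composite form
ρ ∂M/∂t = ∇·(ρ D ∇M) with region-wise constant ρ and D. Inside a region
this is exactly Fick's second law; across the interface it makes the
*water-mass* flux ρD ∂M/∂n continuous (with M itself continuous), which is
the choice under which the discrete water balance closes identically —
the per-step change in ∫ρM dV equals the surface flux integral to linear-
solver precision.

## Parameters

| Parameter | Default | Units | Source/rationale |
|---|---|---|---|
| Air temperature / velocity / RH | 42 / 0.75 / 0.08 | °C, m/s, – | study drying condition |
| Air ρ, c, k, μ, D_v | quadratic polynomials in T(°C) | SI | handbook fits |
| Shell ρ / kernel ρ | 560 / 1000 | kg/m³ | measured dry-solid densities, used both in PDE coefficients and averaging weights |
| k_shell(M), k_kernel(M) | 0.17062 M + 0.07753; 0.32528 M + 0.12559 | W/(m·K) | transient-plane-source fits |
| c_p,shell(M), c_p,kernel(M) | 4.04506 M + 2.05226; 1.96152 M + 1.15307 | kJ/(kg·K) | same; interpreted as kJ because the magnitudes bracket liquid water (≈4.18), converted to SI internally |
| D_shell, D_kernel, D_pod | 1.63249e-10, 2.91731e-10, 5.7512e-10 | m²/s | slab inverse method on measured curves; treated as inputs, not re-derived |
| h_g | 2,256,267 | J/kg | latent heat of vaporization |
| M_e | 0.02 | g/g d.b. | modified-Henderson peanut isotherm at 42 °C / 8 % RH |
| d | volume-equivalent sphere of the mode's outer body (0.01374 m pod, 0.0117 m bare kernel) | m | correlation length scale, configurable |
| f_s | 7.466733e-06 | – | frozen calibration (below) |
| dt / t_end | 60 / 73,800 | s | reference numerical settings |
| mesh h | 5e-4 | m | resolves the shell with ≥2 layers; region areas within 0.05 % of analytic |

Property laws are clamped to M ∈ [0, M0] — the fits are not extrapolated
above the initial moisture. The Nusselt correlation keeps its printed
Reynolds exponent 0.53 while the Sherwood form uses ½; the asymmetry is
preserved as given, with `bc.nu_exponent = 0.5` available to harmonize.

## Numerics

Mapped structured triangulation from concentric elliptical rings: fully
deterministic, conforming at the interface (shared nodes), convex half-
section so no element crosses a region boundary. Axisymmetric P1 finite
elements with the r-weight; mass and Robin matrices are lumped (row-sum),
which together with backward-Euler stepping preserves the discrete maximum
principle observed on the default run. The moisture system is constant in
time and factorized once (sparse LU); the heat system is reassembled each
step with k(M), c_p(M) evaluated at the start-of-step element-mean moisture
(single-pass lagged/Picard update) and the interval's ∂M/∂t as the latent
sink. Operator split per step: moisture first, then heat. Linear solves are
direct, so "tolerance" is machine precision; there is no randomness
anywhere in the solver.

Backward Euler is first order: halving dt=60 s changes the kernel-average
curve by ≤0.04 % but the shell-average curve by up to 0.24 % (the shell's
initial transient is the fastest resolved scale), slightly above the 0.2 %
band used in the acceptance suite — reported as measured, with the
convergence *order* verified separately by successive halvings.

## Calibration design

The Sherwood h_m (m/s, vapor-concentration basis) cannot multiply a
dry-basis moisture difference without a units conversion; used raw it gives
a mass Biot number ~1e8 and near-instant surface equilibrium. The
dimensionless factor f_s absorbs that conversion: h_m,eff = f_s·h_m. f_s is
identified from a single scalar condition — the two-component whole-pod
drying rate equals 3.53 %/h over 1230 min — by a monotonicity-checked
bracketing sweep plus Brent root find in log10 f_s (deterministic,
bit-reproducible; 13 simulation evaluations). M_e stays at its isotherm
value 0.02: one target cannot identify two parameters. The result is frozen
into the package defaults; nothing else is fitted.

## What the model reproduces, and what it cannot

With the frozen calibration the model reproduces the pod rate exactly (by
construction), and predicts the single-component shell and kernel rates
within 5 % and 10 % and the kernel's 17 h safe-moisture bound comfortably.

It does *not* reproduce the reference early-drying component fields (shell
average 0.1063 at 2 h; kernel 0.3131 at 4 h / 0.0992 at 20.5 h; shell-only
safe moisture by 2.5 h). The reason is structural, not numerical: the
simulated pod rate saturates at ≈3.92 %/h as f_s → ∞ (interior-diffusion
limit), so holding the 20.5 h rate at 3.53 %/h forces an O(1) mass Biot
number whose surface resistance slows *early* drying far below fields that
show the shell nearly equilibrated within 2 h. A linear Fickian model with
one (f_s, M_e) pair cannot produce both the observed early/late decay-rate
contrast; physically that contrast is attributed to shrinkage, cracking and
porosity growth, which this model class excludes by assumption.

Similarly, the energy balance bounds how uniform the temperature field can
be while drying is fast: at 60 min the calibrated shell still loses
~0.2 d.b./h, and supplying the corresponding latent heat through
h_T ≈ 32.6 W/(m²K) over the ~6 cm² surface requires the tissue to sit
roughly 3–4 K below the air — the simulation gives max|T − T_a| ≈ 3.7 K at
60 min, not ≈0.1 K. With h_g = 0 the field equilibrates within minutes.
A near-isothermal field at 60 min is incompatible with this latent-sink
formulation at this drying rate; the discrepancy is reported, not tuned
away.

## Synthetic data

`poddry.slab.synthesize_curve` generates drying curves from the slab series
(optionally with seeded multiplicative Gaussian noise) and is the fixture
generator for the estimator tests: noiseless curves are recovered to 0.1 %
across four decades of D; 1 % noise yields ~0.6 % median error over 20
seeded replicates. These curves share the estimator's own model family, so
such tests verify parameter recovery and numerical conditioning — not the
adequacy of the slab idealization for real pods (finite geometry,
moisture-dependent D, measurement drift are absent).

## Problem sizes

Default runs use ~1,000 nodes / ~2,000 triangles and 1,230 steps (seconds
per run); oracle checks use a 5 mm sphere at h = 0.25 mm against
independently coded series solutions (agreement 0.16 % moisture, 0.07 %
heat); convergence and long-time checks use shortened horizons or coarser
meshes chosen to keep the whole suite around a minute while leaving the
measured quantities mesh- and step-insensitive at the stated levels.
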