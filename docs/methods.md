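# Methods

## The problem

Catheter-laboratory physiology is built on pressure: a wire measures the
aortic/proximal pressure Pa and the distal pressure Pd across an
epicardial stenosis, and ratio indices (FFR = hyperaemic Pd/Pa) grade the
lesion. Pressure alone cannot give the absolute volumetric flow Q
(mL/min), and therefore cannot separate epicardial from microvascular
disease or quantify either in absolute terms. `coroflow` closes that gap
computationally: given the vessel lumen geometry (from two angiographic
projections) and the measured translesional gradient ΔP = Pa − Pd, it
computes the unique steady flow Q_CFD that reproduces ΔP through a
Navier–Stokes model of the lesion, and from (Pa, Pd, Q) derives

* microvascular resistance MVR = (Pd − Pv)/Q, with Pv an optional venous
  back-pressure (default 0 mmHg);
* stenosis resistance SR = (Pa − Pd)/Q;
* coronary flow reserve CFR = Q_hyp/Q_base across states;
* pressure-derived CFR, CFR_P-D = √(ΔP_hyp/ΔP_base);
* FFR / resting Pd/Pa.

The resistances are reported in mmHg per (mL/min), the unit consistent
with per-case arithmetic on clinical tables.

## Flow model

**Assumptions.** Steady, incompressible, Newtonian flow; rigid walls; a
straight-axis axisymmetric lumen described by its radius profile R(s);
no side-branch outflow between the two pressure planes. These mirror the
standard modelling assumptions for translesional haemodynamics; their
consequences are discussed under Limitations.

**Formulation.** The axisymmetric Navier–Stokes equations are solved in
streamfunction–vorticity form,

    E²ψ = −rω,          E²ψ = ψ_zz + ψ_rr − ψ_r/r,
    u·∇ω − (u_r/r)ω = ν(∇²ω − ω/r²),

with u_z = ψ_r/r, u_r = −ψ_z/r. Mass conservation is exact by
construction. Boundary conditions: a parabolic (Poiseuille) inlet profile
scaled to Q; no-slip walls with the wall vorticity tied to the near-wall
streamfunction (Thom's relation along the local wall normal); symmetry on
the axis (ψ = ω = 0); streamwise-invariant outlet.

**Discretisation.** The body-fitted structured mesh maps the lumen to a
rectangle via ξ = z, η = r/R(z); metric terms use a cubic-spline radius
profile. Finite differences on the (nonuniform) tensor grid: second-order
central stencils for diffusion and the streamfunction equation,
second-order upwind-biased stencils for advection. The upwind side is
selected by a smooth tanh blend of width 0.05 (nondimensional velocity)
rather than a hard sign switch: recirculating flow otherwise makes the
residual non-differentiable and stalls the Newton iteration. A
first-order upwind scheme is available as a setting.

**Mesh.** Axial nodes are equidistributed against a density weight
(R_max/R)^1.5, carried downstream by a decaying maximum filter
(e-folding 12 mm) so the post-stenotic jet and recirculation zone stay
refined, and the throat itself holds ≥ 20 axial nodes at the default
resolution. Radial nodes use a mild tanh stretching toward the wall
(β = 0.5, adjacent-spacing growth ≤ 1.2). The stretching is deliberately
mild: a grid-convergence study during development showed the dominant
discretisation error for severe stenoses at high Reynolds number lives in
the mid-radius jet shear layer, not the wall layer, so aggressive wall
clustering *degrades* the pressure drop. Named resolutions are
coarse (120×24), standard (200×48) and fine (320×64) nodes; the
standard/fine pair is used by `mesh_convergence_check`, which passes when
their inverse-mode flows agree within 0.5%.

**Nonlinear solve.** The coupled (ψ, ω) system is nondimensionalised by
the inlet radius and mean velocity — the problem then depends on Q only
through the Reynolds number, so converged states warm-start neighbouring
flows directly — and solved by damped Newton iteration with
pseudo-transient continuation on the vorticity rows (switched-evolution
relaxation: the pseudo-time step grows as the residual falls, initial
Δt* = 2). The sparse Jacobian is assembled by colored finite differences
over the known stencil (50 colors) and factorised directly (LU) at every
iteration — refreshing the factorisation each step proved necessary to
keep the iteration on the physical solution branch for severe stenoses
at high Reynolds number.
Convergence requires the scaled steady-state residual — RMS equation
residual over the RMS magnitude of its advective/elliptic terms — to
fall below 10⁻⁶. Cold starts use the local-Poiseuille (lubrication)
fields, exact for a straight tube; severe cases are reached by geometric
continuation in Re, preferring warm starts from *below* in Re (growing a
recirculation bubble continues more easily than shrinking one; if a warm
start stagnates the solver falls back to a cold start automatically).
The solver path contains no randomness: identical inputs give identical
outputs bit for bit.

**Pressure recovery.** ΔP is obtained by integrating the axial momentum
balance along the symmetry axis between the two pressure planes. On the
axis the viscous term reduces to −2μ·(ω/r)|axis, using the identity
u_rr|axis = −½u₀″ − (ω/r)|axis: this form cancels the ill-conditioned
second radial derivative of the axial velocity (a naive two-node quartic
fit of ψ amplifies near-axis discretisation error into a mesh-independent
~30% bias) and leaves only well-conditioned solved quantities.

**Inverse mode (Q_CFD).** ΔP(Q) is strictly increasing on a fixed
geometry, so the measured gradient determines a unique flow. The root is
found by a bracketed secant iteration in log–log space, seeded by a
reduced-order loss model (fully developed viscous term (8μQ/π)·∫ds/R⁴
plus a Borda–Carnot expansion loss (ρQ²/2)(1/A_min − 1/A_out)²) and
reusing every previously solved (Q, ΔP) pair on the same mesh as
brackets. Tolerance: 0.1 mL/min absolute or 0.1% relative, whichever is
larger. The reduced-order model is a seed and sanity oracle only; every
reported flow comes from the full solver.

**Pulsatile mode.** A quasi-steady approximation: the steady model is
inverted sample-by-sample along the measured Pa(t)/Pd(t) waveform and the
flow averaged over whole periods. This is justified by the near-linearity
of the ΔP–Q response over a physiological gradient swing — the package's
own check on a 60% stenosis with a two-harmonic waveform (±30% gradient
swing, 33 samples/period) finds the quasi-steady mean within 1 mL/min of
the steady solve at the mean gradient — and avoids a full transient
solver. Negative-gradient samples are clipped to zero flow and flagged,
never silently repaired.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| blood viscosity μ | 0.0035 | Pa·s | typical value for whole blood at high shear |
| blood density ρ | 1056 | kg/m³ | typical whole blood |
| analogue fluid μ, ρ | 0.0035, 1082 | Pa·s, kg/m³ | 40/60 glycerol/water bench analogue |
| residual target | 1e−6 | — | scaled steady residual |
| inverse tolerance | max(0.1 mL/min, 0.1%) | — | below clinical resolution |
| venous pressure Pv | 0 | mmHg | configurable; 5 mmHg is a common convention |
| mesh (standard) | 200×48 | nodes | grid-convergence study (see above) |
| stenosis length | 20 | mm | typical focal coronary lesion |
| mmHg | 133.322 | Pa | unit convention |

**Validity flags.** Panels are computed but flagged when the driving
gradient is below 4 mmHg (too small to constrain the inversion reliably)
or the hyperaemic Pd/Pa exceeds 0.95 — equivalently, near-normal vessels
are outside the validated range. A stenosis Reynolds number
(ρVD/μ at the minimal lumen, V = Q/A there) below 500 is treated as the
physiological laminar regime; accuracy reports are additionally given for
that subset, and Re > 2000 raises a model-validity warning on the
solution. Degenerate inputs short-circuit: Q = 0 and ΔP = 0 return the
hydrostatic solution; %DS ≥ 100, non-positive dimensions, lumens below
0.05 mm radius, Pd > Pa states, and sub-period waveforms raise errors
rather than being repaired.

## The packaged case table

`coroflow.io.load_table1()` ships a checksummed transcription of a
published 40-patient catheter-laboratory dataset (per-case Pa, Pd, ΔP and
computed flows in both states, plus derived index columns printed at 1–2
decimals). `validate_table1()` recomputes every derived cell from the
printed inputs. Three transcription-level findings are encoded in the
fixture rather than silently patched:

1. the source's MVR cells for cases 17–40 follow (Pd − 5)/Q — a 5 mmHg
   venous back-pressure — while cases 1–16 use Pd/Q; the per-case
   `venous_pressure_mmHg` column records this, and the cohort means only
   reproduce the published summary values under the source's own mixed
   convention;
2. the % delta columns were computed from the rounded printed MVR/SR
   cells, not from full precision;
3. three cells (case 22 baseline MVR, case 33 baseline MVR and SR) are
   misprints inconsistent with their own row inputs under any convention;
   they are enumerated as `KNOWN_ERRATA` and excluded (and asserted to be
   the *only* exclusions) by the replication tests.

The pressure-derived CFR column matches the square-root of the printed
gradient ratio in all 40 cases (plain-ratio values disagree wildly), so
the square-root form is the default; both forms are computed.

## Synthetic data and the virtual bench

The stenosis generator produces straight tubes with a C¹ cosine-bell
narrowing, parameterised by reference diameter, vessel length, %DS,
lesion length and centre, with optional seeded station-level roughness
(off by default; generation is bit-for-bit reproducible). The default
bench phantoms span 46–72% DS and 68–84 mm length at 2.8–3.2 mm reference
diameter — the range a printed-phantom validation study covers — with a
20 mm lesion.

The virtual bench imposes 50–180 mL/min in 10 mL/min steps, three repeats
per rate, across the five phantoms (210 records), using the analogue
fluid. Truth pressures come from a fine-mesh forward solve; recovery
inverts them on the standard mesh, so with the default zero transducer
noise the disagreement isolates discretisation error — the bench is
explicitly *not* a circular self-inversion. Optional Gaussian transducer
noise (e.g. 0.5 mmHg) is available for realism studies. With zero noise
the three repeats of a cell are identical by determinism and the
inversion is computed once and reused. Agreement is summarised on
per-rate means by Bland–Altman bias and ±1.96·SD limits (sample SD, n−1)
plus Pearson r/R²; the Re < 500 subset is reported separately.

The Doppler comparator converts a simulated average-peak-velocity reading
to flow via Q = A·APV/2 (parabolic-profile assumption). Its error model
is deliberately simple: a Gaussian transducer-misalignment angle
(default mean 15°, SD 5°, clipped to [0°, 90°)) scaling velocity by
cos θ, and multiplicative noise with CoV 6.4% at the inlet wire position
and 17.4% distal to the stenosis. The misalignment parameters are a
modelling choice tuned only to the qualitative facts that Doppler flow is
biased low and substantially noisier than the pressure-based method;
they are configurable and carry no claim about any specific rig.

**What the synthetic studies do and do not show.** The generator emulates
idealised concentric lesions with smooth walls and exactly known
geometry; it does not model lumen eccentricity, vessel curvature and
tortuosity, segmentation/reconstruction error, wall compliance,
side-branch flow, or non-Newtonian rheology. Passing the bench therefore
demonstrates that the *inverse pipeline is self-consistent and
discretisation-accurate under known geometry* — the in-silico analogue of
a printed-phantom rig — not that reconstruction from real angiograms is
accurate; in clinical use the reconstruction is the dominant error
source.

## Problem sizes used by the test suite

The shipped tests run the bench at its full 5×14×3 design on the
fine/standard mesh pair, the Poiseuille sweep at 10–100 mL/min, the
forward–inverse round trip at three severities × three rates, one
33-sample pulsatile waveform, and 1000-draw Doppler variability samples —
sizes chosen to exercise every regime the method claims (Re ≈ 40–1400)
while staying comfortably runnable on a laptop CPU.

## Known limitations

* Steady laminar modelling: above throat Re ≈ 500 the real flow is
  transitional; the solver still returns the steady laminar solution
  (flagged), which is how such cases are conventionally treated, but
  accuracy degrades — hence the separate Re < 500 reporting.
* Straight-axis axisymmetry: curvature-induced secondary flows (Dean
  vortices) are absent; eccentric lesions are represented only by their
  equivalent circular area.
* No side-branch outflow: flow proximal to an unmodelled branch is
  underestimated.
* Rigid walls: compliance effects are neglected (small for diseased
  vessels under steady conditions).
* The pressure-derived CFR square-root convention assumes a near-quadratic
  gradient–flow relation; in nearly unobstructed vessels (viscous-
  dominated, near-linear) it is biased.
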