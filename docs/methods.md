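# Methods

This note documents the modelling and numerical choices behind `cowflow`,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Governing model

Each vessel is a 1-D compliant tube carrying hydrostatic pressure `P(z,t)`,
volumetric flow `Q(z,t)` and lumen area `A(z,t)`:

- mass: `C_A ∂P/∂t + ∂Q/∂z = 0`, with `C_A = ∂A/∂P`;
- momentum: `(ρ/A) ∂Q/∂t + (ρ/A) ∂(Q²/A)/∂z + ∂P/∂z + 8πμ Q/A² = 0`;
- tube law: `P = P_ext + P_0 + (β/A_0)(√A − √A_0)` with
  `β = (4/3)√π E h`.

The advective flux is the flat-profile form `Q²/A` with no momentum
correction coefficient, and the friction term `8πμQ/A²` corresponds to a
parabolic velocity profile. Blood is Newtonian and incompressible
(ρ = 1.04 g/cm³, μ = 0.04 poise). The tube law inverts in closed form,
`A = (√A_0 + (P − P_ext − P_0) A_0/β)²`, giving the analytic compliance
`C_A = 2√A A_0/β` and linearized wave speed `c = √(β √A_0 / (2ρA_0))`; at
cohort β and radii c is 4–15 m/s, so cerebral transit times are a few
milliseconds and terminal behaviour dominates the flow split.

## Parameters

| Parameter | Units | Default | Meaning |
|---|---|---|---|
| γ | – | 0.01 | per-segment smoothness bound of the mesh reduction |
| Δt | s | 2·10⁻⁴ | time step |
| cycles | – | 10 (last 2 analysed) | cardiac cycles to periodicity |
| element cap | cm | 0.1 | maximum finite-volume element length |
| T | s | 1.0 | cardiac period (not fixed by the protocol; configurable) |
| P_ext | mmHg | 15 | external wall load in the tube law |
| P_v | mmHg | 10 | venous pressure behind every Windkessel |
| P_0 | mmHg | 100 / 90 | reference pressure: carotids, basilar, ophthalmics / all smaller vessels |
| split | – | 0.20 | impedance share R₁/R_t of the terminal resistance |

Per-vessel wall thickness, Young's modulus, β, P₀ and the terminal (R_t,
C_t) pairs ship as a packaged CSV mirroring the cohort parameter table. The
internal carotid row of that table quotes β = 4529.48 Pa·cm, which is
inconsistent with (4/3)√π·E·h ≈ 1.05·10⁵ Pa·cm from its own (h = 0.05 cm,
E = 0.89 MPa); every other row matches the product to ~10⁻⁵ relative. By
default the loader derives β from (h, E) and logs the discrepancy;
`use_table_beta=True` forces the quoted value. Terminal compliances are
taken at their quoted magnitudes (10⁻⁷–10⁻⁸ cm³/Pa), which makes the
terminal RC time constants ~10⁻³ s — the Windkessels behave almost
resistively, and periodic convergence is correspondingly fast.

## Inflow waveform

The protocol constrains inlet flow by two power laws of the inlet's mean
reference area (peak 70.80·Ā₀^1.7, mean 48.21·Ā₀^1.84 cm³/s) without fixing
a shape. The default template is a C¹-periodic systolic bump on a diastolic
plateau, `q(t) = a + b sin²(πu/s)` for cycle fraction `u < s` (s = 0.35),
constant otherwise; `a` and `b` are solved so the cycle mean and maximum hit
both laws exactly. The template family is pluggable; a `constant` template
(mean law only) supports steady verification runs. Waveforms whose
peak/mean ratio would force negative diastolic flow are rejected.

## Discretization and solution

Space: staggered finite volumes — pressures on nodes, flows on elements of
at most 1 mm, the element count per segment being `ceil(length/0.1 cm)`.
Nodal reference areas follow the monotonic linear radius profile of the
reduced mesh. The mass balance is integrated in conserved-volume form
`d/dt ∫A dz + ΔQ = 0` so wall storage is tracked exactly; nodal advective
fluxes use averaged element flows (one-sided at junctions and boundaries).

Junctions: all incident artery ends share a single pressure node (static
pressure continuity), and the junction's mass row is the zero-storage
balance `Σ signed Q = 0`. This is the same constraint set a
Lagrange-multiplier formulation would impose, with the multipliers
eliminated; because those rows are linear, junction mass conservation holds
to linear-solver precision (~10⁻¹⁶ relative in practice). Total-pressure
continuity is not imposed — with cerebral velocities of a few cm/s the
dynamic head is negligible against ~10⁴ dyn/cm² pressure drops.

Time: BDF2 with a backward-Euler start-up step and constant-extrapolation
predictor. Each step solves the monolithic nonlinear system (nodal P,
element Q, outlet flows, Windkessel capacitor pressures) by Newton
iteration: analytic sparse Jacobian, direct LU factorization, scaled
residual tolerance 10⁻⁹ (mass rows scaled by the peak total inflow,
momentum rows by 100 mmHg), at most 20 iterations. The factorization is
reused across iterations and steps and rebuilt only when convergence
stalls, which keeps typical steps at two residual evaluations and one or
two triangular solves. A backtracking line search guards against lumen
collapse (non-positive √A), which raises a dedicated error if unavoidable.

Measured behaviour on the verification battery: observed temporal order
2.0 on a smooth single-vessel problem; rigid-limit pressure drop within
10⁻⁵ of 8πμLQ/A²; small-pulse propagation speed within 0.4 % of the
linearized c; steady states identical (≤4·10⁻⁹ relative) to an independent
root-finder solution of the same algebraic system.

## Mesh reduction

Candidate segments reconstruct radius linearly in arc length between the
centerline radii at their end points (monotonic by construction — the
simplest family satisfying the monotonic-taper requirement). If a
candidate's γ exceeds the threshold it is split at the covered point of
maximum absolute relative radius error and both halves recurse; the
midpoint is used if that point is an endpoint. Split points are independent
of the threshold, so the segmentations produced by two thresholds nest —
tightening γ refines, never rearranges. Note γ divides by the point count
`n_c` (not √n_c), so for fixed pointwise noise the coefficient shrinks as
segments lengthen; both endpoints are counted in `n_c`.

## Longitudinal comparison

α is identified from the three inlet mean reference areas through the
mean-inflow law and applied as a uniform area factor (radii × √α) on the
follow-up network; lengths, β and P₀ are untouched. Vessel matching between
scans is by label only. Mean quantities average nodal values in time over
the final cycle and length-weighted in space; peaks are maxima of the
space-averaged signal. Relative variations with a baseline below
10⁻¹² cm³/s (near-zero communicating-artery flows) are replaced by the
absolute change and flagged, rather than reported as unbounded ratios. The
sensitivity battery reruns the comparison with α forced to 1, all terminal
resistances halved/doubled, and all Young's moduli halved/doubled,
classifying |η| into three bands (<0.25, 0.25–0.5, >0.5). On a duplicated
scan the reference ε^sc is exactly zero; perturbations applied to both
scans symmetrically leave the comparison untouched and are reported as
η = 0 instead of a 0/0.

## Synthetic anatomies

The generator draws per-vessel axial length and mean radius from the cohort
morphometry table (mean, SD per vessel and scan), truncating at ±2 SD, and
synthesizes straight centerlines at ~1 point/mm with a symmetric ±5 %
linear taper (which keeps the length-weighted mean radius exactly at the
sampled value; with SDs zeroed the vessel summaries reproduce the cohort
means exactly). Wiring follows a fixed canonical 30-artery topology with
named junctions; missing communicating arteries degrade their junctions to
serial connections. Aneurysms are smooth axisymmetric sin² bumps (peak
factor 1 + enlargement over a central axial window), with optional growth
in the follow-up scan. Scan pairs add per-vessel lognormal radius
(σ = 0.10) and length (σ = 0.05) perturbations — magnitudes in line with
the cohort's printed inter-scan relative differences — and a global area
distortion k emulating a resolution change, recorded as ground truth for
recovery tests. An optional radius waviness term (off by default) emulates
segmentation noise; the smoothness-level comparison uses amplitude 0.15 so
that the six γ levels produce genuinely different meshes.

What the generator does *not* emulate: vessel tortuosity and real 3-D
geometry, inter-vessel correlation of sizes (no covariance is published),
fetal-PCA and other anatomical variants beyond missing communicating
arteries, and non-axisymmetric aneurysm sacs. Passing tests on these
anatomies therefore validate the pipeline's mechanics and conservation
properties, not patient-level predictions.

## Problem sizes

The defaults reproduce the full protocol (10 cycles at Δt = 2·10⁻⁴ s on the
complete anatomy, ~50 000 steps over ~1100 unknowns, about half a minute on
one CPU). Multi-run studies use deliberately smaller runs: the γ sweep and
the sensitivity probes in the acceptance script run 4 cycles with the last
2 analysed — ample for periodicity given the millisecond terminal time
constants — and small verification problems use Δt = 10⁻³ s.

## Known limitations

- Newtonian rheology and an elastic (non-viscoelastic) wall; no alternative
  tube laws.
- Aneurysms enter only through the host vessel's area profile; no sac
  sub-model or 3-D coupling.
- Static-pressure junction coupling (no junction loss models).
- The cardiac period and inflow waveform shape are package choices
  constrained only by the peak/mean laws.
- No statistical machinery across patients; the package quantifies one
  patient's scan pair at a time.
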