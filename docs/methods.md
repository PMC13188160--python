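# Methods

## Governing system

The stratum corneum is modeled as a homogeneous slab with Fickian
diffusion and first-order bulk neutralization. In dimensionless
variables (depth x = z/h, time τ = t·D_SC/h², concentration scaled so
the deposit has unit mass):

    ∂c/∂τ = ∂²c/∂x² − Da·c,          x ∈ (0, 1)
    ∂c/∂x(0, τ) = π_surf·c(0, τ)     (Robin surface loss)
    c(1, τ) = 0                      (perfect sink)
    c(x, 0) = 1/β on [0, β], else 0  (finite dose)

Assumptions: intact skin, constant coefficients (no barrier damage, no
temperature drift), uniform decontaminant coverage, a single rate-
limiting layer, and a perfect systemic sink at the inner face. The
perfect-sink idealization is conservative for absorption; the Robin
coefficient lumps evaporation and interfacial reaction into one
clearance velocity.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| D_sc | barrier diffusivity | cm²/s | — (per agent) |
| h | barrier thickness | μm | — (typically 10–20) |
| k_bulk | bulk neutralization rate | s⁻¹ | 0 |
| k_surf, k_evap | interfacial reaction / evaporation velocities | cm/s | 0 |
| β | deposit depth fraction | — | 0.1 |
| Da = k_bulk·h²/D_sc | bulk reaction vs diffusion | — | derived |
| π_surf = (k_evap + k_surf)·h/D_sc | surface clearance vs diffusion | — | derived |

Thickness is converted to cm internally; the diffusion time h²/D_sc is
reported in minutes. Vapor pressure is carried as metadata only — no
evaporation correlation is implemented, so evaporative clearance must be
supplied as a mass-transfer velocity (or κ_evap directly). β defaults
to 0.1 (a shallow finite dose) and is overridable.

## Analytical solution

Separation of variables gives eigenfunctions φ_n(x) = sin(λ_n(1−x))
with λ_n the unique root of λ·cos λ + π_surf·sin λ = 0 in each interval
((n−½)π, nπ); μ_n = λ_n² + Da are the decay rates. Roots are found by
bracketed Brent iteration (xtol 1e-14) — the bracket endpoints provably
change sign, so no root can be missed — with a residual guard scaled by
the local derivative magnitude (a machine-accurate root of order λ
carries a residual ~λ²·eps, so an absolute residual bound is meaningful
only for low-order roots). π_surf = 0 returns (n−½)π exactly.

Projection of the deposit gives A_n = [cos(λ_n(1−β)) − cos λ_n]/(β λ_n N_n),
N_n = ½ − sin(2λ_n)/(4λ_n). Cumulative pathway fractions are exact
per-mode integrals (never flux quadrature):

    M_p(τ) = Σ_n (r_n/μ_n)(1 − e^(−μ_n τ)),
    r_abs = A_n λ_n,  r_surf = π_surf A_n sin λ_n,  r_reac = Da A_n (1−cos λ_n)/λ_n

The eigenvalue identity makes the four series (including the remaining
mass) sum to the truncated deposit mass at every τ, so the conservation
error equals the truncation shortfall of the initial condition. The
default series length is 400 terms, which keeps that shortfall below
1e-6 even for strongly loss-dominated surfaces (π_surf > 10, the
slowest-converging case; 200 terms leaves ~4e-6 there). Times below
τ ≈ 1e-4 are series-limited (Gibbs-type slow convergence against the
discontinuous deposit) and are validated against the finite-difference
solver instead; tiny negative truncation noise (≲1e-8) in the
pre-breakthrough cumulative fractions is floored to zero.

## Steady-state partitioning

Asymptotic fractions come from the splitting-probability boundary-value
problems (u'' = Da·u with the matching boundary pair), averaged exactly
over the deposit: with q = √Da and D = π_surf·sinh q + q·cosh q,

    M_abs(∞)  = [π_surf(cosh(qβ)−1)/q + sinh(qβ)] / (β·D)
    M_surf(∞) = π_surf·[cosh q − cosh(q(1−β))] / (q·β·D)
    M_reac(∞) = 1 − M_abs(∞) − M_surf(∞)

evaluated in an exp(−q)-rescaled form (expm1/sinh identities) so the
formulas neither overflow at large Da nor cancel at small Da; Da = 0
uses the linear splitting solution. These closed forms — not series
truncations — are the production values; the series asymptotes agree
with them to ~1e-8 at 400 terms and serve as a cross-check.

## Time constants and the decontamination window

Each pathway's effective time constant is the first moment of its
residual curve,

    τ_eff = [Σ r_n/μ_n²] / [Σ r_n/μ_n],

which equals 1/μ₁ for a single exponential, making 4·τ_eff the ≈98%
completion point for near-exponential kinetics. The literal 98% time
t98 is solved separately by bracketed root finding on the monotone
normalized cumulative curve. The two are deliberately distinct outputs:
for the S-shaped (lagged) absorption curve t98/τ_eff runs ~2.5–3.2, for
the front-loaded surface curve ~4.6–5.4, and only the near-exponential
reacted pathway sits at the textbook 3.91. A pathway with vanishing
asymptote (below 1e-12) reports its constants as absent rather than
zero.

The decontamination window is the strict ordering
4τ_eff,surf < 4τ_eff,reac < 4τ_eff,abs: the upstream surface and bulk
pathways complete while absorption — which must traverse the full
barrier — is still ongoing. Ties within 1e-9 are flagged and fail the
ordering, since it is defined by strict inequalities. The reported
window *extent* (4τ_abs − 4τ_reac) is a summary convention of this
package; only the ordering is intrinsic. The no-decontamination
baseline sets Da = 0 and, when the evaporation/surface-reaction split
of π_surf is known, retains the evaporation part only (recorded in
output metadata); without a split π_surf is kept unchanged.

Regime thresholds: Da < 3 diffusion-dominated, 3–8 intermediate, > 8
bulk reaction-dominated. The risk map labels grid nodes "safer" below
a 20% steady absorbed fraction and "high-risk" above 50% (the point at
which the majority of the dose is absorbed); both thresholds are
configurable, the grid is deterministic (default 101×101 over
Da ∈ [0,10], π_surf ∈ [0.4,2.0]).

## Finite-difference cross-check

An independent θ-scheme solver (default Crank–Nicolson, n_x = 201,
dt = 2.5e-5 with 10× finer steps through τ < 1e-3) discretizes the same
system: central differences, ghost-node Robin condition
(c₋₁ = c₁ − 2Δx·π_surf·c₀), Dirichlet sink, and trapezoidal
accumulation of boundary fluxes and the bulk-reaction integral. The
deposit edge at x = β is volume-averaged onto its cell so the discrete
initial mass is exactly 1. Conservation is *not* built in — the
four-way balance closing to <5e-4 is a diagnostic of the scheme. The
test suite verifies agreement with the series solution to <5e-4 across
a 3×3 (Da, π_surf) grid spanning {0,1,10}×{0,0.4,11.2} and clean
second-order convergence under mesh refinement (deviation ratio 4.0 on
halving Δx and dt).

## What the fixtures emulate — and what they do not

The preset scenarios encode literature-derived parameter estimates
(VX/RSDL transport and kinetics; Tabun evaporation for the volatile
high-π_surf case), not new measurements. The VX surface-loss number
(≈0.17, evaporation only) is stored as the published dimensionless
value because the underlying evaporation inputs are not republished
here. Passing tests demonstrate internal consistency of the
transport–reaction mathematics and faithful reproduction of the
regime/window structure; they do not validate the model against
in vitro or in vivo absorption data, and real skin adds multilayer
structure, shunt pathways, occlusion, temperature dependence, and
nonuniform decontaminant coverage that this framework deliberately
omits.

## Numerical conventions

* Default τ grid: 400 log-spaced points on [1e-3, 6/μ₁] (CLI curve
  export extends to 10/μ₁ so final rows sit within 1e-4 of the
  asymptotes).
* CSV output: comma-separated, header row, `%.17g` floats — reruns are
  byte-identical.
* Everything is deterministic; there is no random number generation
  anywhere in the model.
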