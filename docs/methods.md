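# Methods

## Model

`fracno` simulates the radial transport of nitric oxide (NO) across a
cross-section of a small cerebral vessel and its surroundings. The domain
is four concentric layers: the lumen (radius *a* = 25 µm), the endothelium
(thickness *h* = 0.5 µm), the remaining vascular structures plus
extracellular space (*d* = 4 µm), and a layer of neurons (*g* = 5 µm).
Axial symmetry reduces the problem to one radial coordinate
r ∈ [0, R], R = a + h + d + g, with concentration C(r, t) in mol/m³.

The balance law on the interior of the domain is

    ∂C/∂t = −(1/r) ∂/∂r ( r F(r,t) )
            + v₁ (1 − e^{−k₁ t}) e^{−k₂ t} · 1_neuronal(r)
            − v_max C / (K_max + C) · 1_{r ≥ a+h}(r)
            + w(r, t) C · 1_endothelium(r)
            − λ C · 1_lumen(r)
            − λ̃ C · 1_extracellular(r)

with zero initial data and zero Dirichlet values at r = 0 and r = R.
The six right-hand terms are: anomalous diffusion; neuronal synthesis (a
transient pulse shaped like Ca²⁺–calmodulin binding kinetics, peaking at
t* = ln(1 + k₁/k₂)/k₁ ≈ 0.42 s); saturable (Michaelis–Menten)
inactivation; shear-mechanotransduction production at the endothelium;
hemoglobin scavenging in the blood; and the reaction with extracellular
superoxide at rate λ̃ = k_O2⁻ · C_O2⁻ · f_SOD (half the superoxide pool is
assumed to survive superoxide dismutase, f_SOD = 0.5), giving
λ̃ = 6532.5 s⁻¹ in normal conditions and 13065 s⁻¹ with ischemic
superoxide levels.

Note the synthesis envelope: a literal reading of the source model uses a
*growing* exponential e^{+k₂t}, which is unbounded and inconsistent with
the transient calcium kinetics it is meant to mimic; the package defaults
to the decaying convention and retains the growing one behind
`k2_sign_positive` for auditing.

### Anomalous diffusion

Diffusion follows a generalized (nonlocal) Fick law built from left- and
right-sided Riemann–Liouville derivatives of order ε ∈ (0, 1]:
heavy-tailed (Lévy-flight) jump lengths with tail exponent −(ε+1), with
probabilities p and q = 1 − p of jumping toward and away from the vessel
axis. ε = 1 with p = q = ½ recovers classical Fickian diffusion. The
generalized diffusivity D has units m^{ε+1}/s and keeps its tabulated
numerical value 3.3×10⁻⁹ across ε.

**Direction convention.** `p` weights the transport component whose
long jumps point *toward the axis* — the forward direction of NO
signalling, from the neuronal source toward the blood — realized by the
right-sided fractional derivative; `q` weights the outward component
(left-sided derivative). At ε = 1 this reduces to a forward first
difference for p = 1, a backward one for q = 1, and the exact central
scheme for p = q = ½. The convention was fixed by requiring the
discretization to reproduce the model's published phenomenology (the
endothelial-peak maximum near ε = 0.85 for forward-dominant transport);
the opposite assignment makes the forward-dominant endothelial signal
collapse by hundreds of orders of magnitude as ε decreases, because all
mass leaving the neuronal layer then jumps outward into the absorbing
outer boundary.

### Discretization

Space is discretized on N equispaced intervals (default N = 300,
Δr = 1.15×10⁻⁷ m; concentrations live on nodes, the two end nodes carry
the Dirichlet data). The fractional derivatives are realized by
Grünwald–Letnikov (GL) sums: unshifted for the order-ε terms, shifted by
one node for the order-(ε+1) terms (the shift is required for stability
of orders in (1, 2]). The GL weights g_j = (−1)^j C(ν, j) are computed
by the multiplicative recurrence g_j = g_{j−1}(1 − (ν+1)/j), which is
overflow-free; a log-gamma evaluation cross-checks it in the tests.
Because everything is linear in the nodal values, the whole cylindrical
flux divergence collapses to one dense (N−1)×(N−1) matrix, assembled
once per parameter set and reused at every step. Dense storage is
deliberate: fractional operators are inherently nonlocal (lower/upper
Hessenberg-type structure), and at N ≈ 300 the matrix is small.

Accuracy: applying the unshifted GL sum to (r−L)² and comparing with the
exact Riemann–Liouville derivative Γ(3)/Γ(3−ε)·(r−L)^{2−ε} shows
first-order convergence, with the empirical order approaching 1 from
below (0.990 → 0.999 over four mesh halvings at ε ∈ {0.25, 0.5, 0.85}).
Claims of second-order accuracy for shifted GL schemes apply only to
specially corrected variants, not to the plain scheme used here.

### Wall mechanics

The endothelium is a homogeneous Maxwell (spring–dashpot in series)
layer, driven at the blood interface r = a by an axial oscillation
ξ₀e^{iωt} and tethered at r = a + h. In phasor form the displacement
profile satisfies f″ = k²f with k² = (ρω²/E)(−1 + i/γ), where γ = ωμ/E
is the loss factor; hence

    ξ(r, t) = ξ₀ sinh(k(a+h−r)) / sinh(kh) · e^{iωt},   k = α + iβ,

with α, β given by α², β² = (ρω²/2E)(√(1+1/γ²) ∓ 1). The
mechanotransduction production factor is the real part of the
normalized viscous dissipation (σ_rx/τ_W)·∂ε_rx/∂t, which the analytic
solution reduces to

    w(r, t) = Re[ −i ξ₀ ω k cosh²(k(a+h−r)) / (sinh(kh) cosh(kh)) · e^{iωt} ].

This "derived" form is the package default (`wall_formula="derived"`).
A second, widely circulated closed form of the same quantity — with
numerator bracket e^{2α(h−r+a)} + e^{−2α(h−r+a)} + 2, denominator
(α−iβ)e^{2αh} − (α+iβ)e^{−2αh} + 2iβ and phase e^{i(ωt−2β(r−a))} — is
implemented verbatim as `wall_formula="printed"`. The two are *not*
equivalent: the second keeps only the α² part of k² = α² − β² + 2iαβ in
its denominator (≈ 4α²h vs. the exact ≈ 4k²h for thin walls), which
inflates the amplitude by (α²+β²)/|k²| — a factor 5 at γ = 0.75 and 9 at
γ = 1.25 — and thereby manufactures a loss-factor dependence the exact
solution does not have at leading order (the exact thin-wall amplitude
is ωξ₀/h, independent of E and γ up to O((kh)²) ≈ 10⁻¹⁶ here). The
default follows the boundary-value problem; tests verify |ξ(a,t)| = ξ₀,
ξ(a+h,t) = 0, the dispersion relation, and both closed forms against a
40-digit complex-arithmetic oracle. The printed denominator is evaluated
through the exact identity 2α sinh(2αh) − 4iβ sinh²(αh) because the
naive expression cancels catastrophically in double precision.

**Stability limitation (important).** The production term multiplies the
local concentration, so w(r, t) — a zero-mean oscillation of amplitude
ωξ₀/h ≈ 2×10³ s⁻¹ with the tabulated ξ₀ = 10⁻³ m (printed variant:
≈ 10⁴ s⁻¹) — acts as an intermittent exponential growth rate on the
thin endothelial strip. Fractional diffusion drains that strip at a rate
that falls rapidly with ε (≈ D/Δr^{1+ε} on the grid; the continuum
analogue D/h^{1+ε} is below 1 s⁻¹ by ε = 0.25). Consequently the coupled
system is linearly unstable for small ε under *any* faithful realization
of the wall term: with the default derived coupling, runs at ε ≤ 0.75
grow past double-precision range and the integrator aborts with a
diagnostic error; with the printed coupling the same happens for every
configuration except classical diffusion with the compliant wall. This
is a genuine property of the model equations with the tabulated
parameters, not of the solver: the instability survives grid refinement
at small ε and tighter tolerances. Runs that do complete are unaffected
(the realized amplification at ε ≥ 0.85 is at most a few tens of
percent). Setting ξ₀ several orders smaller, or ε ≥ 0.85, keeps the
model in its stable regime.

### Time integration

The semi-discrete system is stiff (λ̃ ∼ 10⁴ s⁻¹ and diffusion rates up to
∼10⁵ s⁻¹ against second-scale dynamics), so it is integrated with
SciPy's BDF method and the exact dense Jacobian — the diffusion matrix
plus the diagonal reaction derivative. Defaults: rtol 10⁻⁶, atol 10⁻¹²
mol/m³ (three orders below the picomolar solution scale); halving both
moves the endothelial peak by < 10⁻⁷ relative. Output is sampled on 401
equispaced instants over 10.04 s, i.e. 400 steps of 0.0251 s.
Non-negativity is enforced by clipping the state at zero inside the
reaction terms (so a transient negative excursion cannot create mass —
the linear diffusion term sees the raw state, keeping the Jacobian
exact) and by clipping the reported output; this emulates a constrained
stiff solver's non-negative option with the same fixed points.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| a, h, d, g | layer thicknesses | 25, 0.5, 4, 5 ×10⁻⁶ | m |
| D | generalized diffusivity | 3.3×10⁻⁹ | m^{ε+1}/s |
| ε | fractional order | 0.85 | — |
| p (q = 1−p) | forward-jump probability | 0.75 | — |
| v₁, k₁, k₂ | synthesis pulse | 1.6×10⁻³, 2, 1.5 | mol/(m³s), s⁻¹, s⁻¹ |
| v_max, K_max | saturable inactivation | 2×10⁻³, 10⁻⁵ | mol/(m³s), mol/m³ |
| λ | hemoglobin scavenging | 2.3×10² | s⁻¹ |
| k_O2⁻, C_O2⁻, f_SOD | superoxide reaction | 6.7×10⁹, 1.95×10⁻⁶, 0.5 | M⁻¹s⁻¹, M, — |
| ρ, E, γ, ω, ξ₀ | Maxwell wall | 1, 6×10³, 0.75, 1, 10⁻³ | kg/m³, N/m, —, s⁻¹, m |
| N | grid intervals | 300 | — |

The wall units are taken at face value from the source tabulation even
though E in N/m and ρ = 1 kg/m³ are unusual for a continuum layer; no
unit repair is attempted. ω is read literally as 1 s⁻¹ ("1 Hz" in the
tabulation); `frequency_is_hz: true` multiplies by 2π for users who read
it as cyclic frequency. λ̃ is derived from (k_O2⁻, C_O2⁻, f_SOD); a
`lambda_tilde` override exists and warns if inconsistent with the
derived product.

Stiff-wall / ischemic variants used by the scenario presets:
E = 6×10⁴ N/m with γ = 1.25, and C_O2⁻ = 3.9×10⁻⁶ M (λ̃ = 13065 s⁻¹).

## What the simulations show

With the defaults (derived wall coupling), the endothelial readout —
the time series at the node nearest r = a + h, index 222 at 25.53 µm on
the canonical grid — behaves as follows. All values are computed by the
test suite or the CLI; concentrations are in mol/m³ (10⁻⁹ mol/m³ = 1 pM·10³,
i.e. nmol/m³).

* Classical limit ε = 1: peak ≈ 1.256×10⁻⁹ at t ≈ 0.45 s; the forward,
  backward and central skew variants agree within 1%.
* Sweeping ε at p = 1: 1.26×10⁻⁹ (ε = 1) → 1.91×10⁻⁹ (0.95) →
  4.39×10⁻⁹ (0.85); the ε ≤ 0.75 members of the sweep diverge (see the
  stability limitation above). With the wall term suppressed the full
  sweep completes and the maximum falls at ε = 0.85.
* Raising superoxide to ischemic levels lowers the endothelial peak
  (ε = 1: 1.256×10⁻⁹ → 9.58×10⁻¹¹; ε = 0.85, p = 0.75 with the stiff
  wall as well: 3.19×10⁻⁹ → 1.71×10⁻⁹).
* Wall stiffening alone does not change the peak under the derived
  coupling (relative change ∼10⁻¹³, i.e. round-off), because the exact
  thin-wall dissipation amplitude is stiffness-independent; a stiffness
  response appears only under the printed coupling, whose γ-dependence
  originates in the α²-for-k² substitution, and that coupling is
  unstable at the stiff-wall amplitude.
* Backward-dominant transport (ε = 0.85, p = 0.25) under normal
  conditions shows two endothelial maxima — a delayed second peak —
  which disappears at elevated superoxide.

## Numerical and design choices

* Interfaces use the right-continuous Heaviside convention H(0) = 1: a
  node exactly on an interface belongs to the outer region, so the
  bracketed Heaviside differences partition the nodes with no double
  counting; membership comparisons use a 10⁻¹² relative tolerance on r.
* Boundary columns of the GL matrices are dropped, which is exact for
  homogeneous Dirichlet data.
* `peak_metrics` counts local maxima above a prominence floor of 1% of
  the global maximum (configurable) so solver-level ripples do not
  register; an endpoint that strictly dominates its neighbour counts as
  one maximum.
* Degenerate inputs: v₁ = 0 is allowed (switches synthesis off; with
  zero initial data the solution is then identically zero, an invariant
  the tests assert exactly).
* Determinism: the package contains no randomness; reruns are
  bit-stable up to the floating-point environment.

## Known limitations

* The small-ε instability described above is inherited from the model's
  structure (production proportional to concentration with a fixed
  oscillation amplitude); the package reports it as an integration error
  rather than silently regularizing.
* Peak values at the canonical N = 300 are not grid-converged (the
  endothelium spans only ~4 nodes; doubling N roughly doubles the
  ε = 0.85 peak). N is configurable; the defaults reproduce the study
  grid.
* The Michaelis–Menten inactivation region includes the neuronal layer,
  as the region indicator in the balance law specifies.
* O₂-modulated synthesis, autoxidation, hemoglobin-preserver dynamics,
  blood-flow coupling and any feedback of NO on wall parameters are out
  of scope.
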