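# Methods

## Model

The tissue is a 1D homogenized continuum of length L = 300 µm with two
interpenetrating compartments: the astrocyte syncytium (ICS, volume
fraction α_i) and the extracellular space (ECS, α_e), with
α_i + α_e = 0.6 pointwise (neurons hold the remaining 0.4 and appear only
through source terms).  The unknown fields are α_i, the Na⁺/K⁺/Cl⁻
concentrations and electrical potential in each compartment, and the ECS
hydrostatic pressure p_e; α_e and p_i follow algebraically (volume
closure; membrane force balance p_i − p_e = K_m (α_i − α_i,init) +
p_m,init).

Ion transport combines diffusion (effective diffusivity D_k/λ_r², with
tortuosity λ_r), electric drift, and advection by the compartmental fluid
velocity u_r.  Charge relaxation is effectively instantaneous at tissue
scale, so instead of a membrane-capacitor charge relation the model
enforces bulk electroneutrality of each compartment; this leaves the
potentials defined up to one common constant, pinned by a zero-mean
constraint on φ_e through a scalar Lagrange multiplier c_e (which is zero
at any solution and only absorbs the gauge).  p_e is likewise pinned by a
Dirichlet condition at the right boundary.  All boundaries are sealed (no
ionic or fluid flux).

Membrane mechanisms are a Na⁺ leak, a Cl⁻ leak, an inward-rectifying K⁺
channel, and a saturating 3:2 Na⁺/K⁺ pump.  The Kir rectification factor
uses the classic astrocyte parameterization
f_Kir = sqrt([K⁺]_e/[K⁺]_e,init) · A·B/(C·D) with fixed sigmoid constants
(0.1186 V, 0.0441 V, 0.0185 V, 0.0425 V, and the dimensionless 18.4/42.4);
[K⁺]_e,init and E_K,init are frozen from the run's initial state.  The
square-root concentration dependence is the form this membrane model
family inherits from its source; it also reproduces the shipped
post-calibrated baseline noticeably better than a linear prefactor when
the unstimulated system is relaxed from the pre-calibrated seed (maximum
deviation 0.4 % vs 0.7 %).

Water crosses the membrane at w_m = η_m (p_i − p_e + iRT (O_e − O_i)),
with osmolarities including immobile anions a_r (constant per total
tissue volume, so swelling dilutes them).  The anion content (a_i, a_e)
and average charge z_0 are re-solved in closed form at every simulator
start so that the configured initial state is exactly electroneutral and
in osmotic equilibrium; two degenerate seeds are rejected (iso-osmotic but
charge-imbalanced states have no finite solution) and one is gauged
(fully symmetric states fix only the products z_0·a_r, resolved with
z_0 = −1).

Fluid scenarios: M0 freezes all flow; M1 is Darcy flow u_r = −κ_r ∇p_r in
both compartments; M2 adds the intracellular osmotic drive
+κ_i iRT ∇(a_i/α_i) — mobile ions exchange freely through gap junctions
and contribute no intra-syncytium osmosis, only the immobile anions do;
M3 adds Helmholtz–Smoluchowski electro-osmosis −(ε_r ε_0 ζ/μ)∇φ_e in the
ECS.  The κ_r enter exactly as written, without tortuosity scaling.
Inserting the constitutive laws into ∇·(α_i u_i + α_e u_e) = 0 yields an
elliptic equation for p_e; in 1D with sealed ends this forces the two
superficial fluxes to cancel pointwise, which the tests assert.

Neuronal activity is a K⁺ input flux into the ECS with an equal and
opposite Na⁺ flux (charge- and osmolarity-neutral by construction) in the
input zone [135, 165] µm during t ∈ [10, 210] s, with constant, 1 Hz
("slow"), or 0.05 Hz ("ultraslow") waveforms, plus a domain-wide decay
flux −k_dec([K⁺]_e − [K⁺]_e,init) standing in for neuronal reuptake.  The
sinusoid phase references absolute time (the waveform formula uses bare
t); a `phase_at_onset` switch re-references it to stimulus onset, since
onset-aligned cycles are the natural alternative reading.

## Parameters

Defaults are the reference parameterization (SI units internally;
mol/m³ ≡ mM): D_Na/K/Cl = 1.33/1.96/2.03·10⁻⁹ m²/s, λ_i = 3.2, λ_e = 1.6,
γ_m = 8·10⁶ 1/m, ḡ_Na/K/Cl = 1/16.96/0.5 S/m², ρ_pump = 1.12·10⁻⁶
mol/(m²s) with thresholds P_Nai = 10, P_Ke = 1.5 mol/m³, η_m = 8.14·10⁻¹⁴
m/(Pa·s), κ_i = κ_e = 1.8375·10⁻¹⁴ m²/(Pa·s), ζ = −22.8 mV, μ = 6.4·10⁻⁴
Pa·s, k_dec = 2.9·10⁻⁸ m/s, p_m,init = 1 kPa, T = 310.15 K.  The membrane
stiffness K_m = E/(3(1 − 2ν)) = 2.294 kPa derives from astrocyte
indentation data (mean Young's modulus 413 Pa, ν = 0.47).  Stimulus
amplitudes are per scenario (8.28/8.0/9.15/9.05 ·10⁻⁷ mol/(m²s) for
M0–M3), chosen so peak [K⁺]_e reaches ≈10 mM.  Parameters load from YAML
with unknown keys rejected.

## Baseline and calibration

The shipped baseline is the post-calibrated steady state (e.g. [K⁺]_e =
3.216 mM, [K⁺]_i = 99.892 mM, φ_m ≈ −85.9 mV, recovered here by solving
net membrane charge flux = 0).  Because only printed digits of that state
are available, runs started from it settle within a few tenths of a
second to a nearby true fixed point (≲0.2 % away); all "change from
baseline" diagnostics use the run's own initial state.

The `relax` calibration mode reproduces the original two-step procedure:
start from the pre-calibrated seed, set η_m = 0, turn input *and* decay
off (the pre/post compartmental ion totals 0.4·c_i + 0.2·c_e agree to
~10⁻⁵ relative, which pins down that both sources were off), and
integrate the spatially uniform system with implicit steps growing from
0.1 s to 10⁴ s until the largest relative rate of change falls below
10⁻¹²/s — the same fixed point as a fixed very long horizon, reached in
under a second of wall time.  The endpoint matches the shipped
post-calibrated values to ≤0.4 % (the residue is consistent with the
truncated printed digits of the seed).  `self_consistent_baseline`
additionally iterates relax → re-freeze Kir constants to a jointly
self-consistent fixed point, used by the drift tests (<0.1 % over an
unstimulated 250 s run) and available as `init="steady"`.

## Discretization and solver

Fields live on the N+1 nodes of a uniform grid.  Fluxes are evaluated at
cell faces from two-point gradients and arithmetic-mean face values, and
conservation is enforced on node-centered control volumes (half-width at
the sealed ends) — the lumped-mass variant of piecewise-linear finite
elements.  Velocities use the same discrete gradient as transport, so the
divergence-free closure holds discretely and the superficial fluxes
cancel to solver tolerance.  The input-zone indicator is applied as the
exact overlap fraction of each control volume with [L1, L2], so the
injected total is exactly (L2 − L1)·j_in on every grid.  No advection
stabilization is used: cell Péclet numbers are ≪1 at physiological
velocities (a runtime warning fires if they are not).

Time stepping is backward Euler with a monolithic Newton solve over all
10·(N+1)+1 unknowns.  The Jacobian is built by forward finite differences
over a 30-color partition (node index mod 3 × field), with the multiplier
column and constraint row filled analytically; rows and columns are
equilibrated by per-equation characteristic magnitudes and per-field
typical scales to tame the ~20-decade coefficient spread before sparse LU.
The factorization is reused across iterations and steps until convergence
degrades (refresh after 4 stale iterations, at most 3 rebuilds per step).
Convergence requires the scaled residual below 10⁻¹⁰ within 25 iterations;
trial states leaving physical bounds (α_i outside (0, 0.6), non-positive
concentrations) are rejected by step damping, and a non-convergent step
falls back to halving Δt (at most 8 levels).  Newton typically needs 0–3
iterations per step after onset transients.

Resolution: the refinement study anchors N = 200, Δt = 10⁻² s for the
convergence pair at t = 20 s (peak ECS superficial velocity 0.271 µm/min,
peak [K⁺]_e 9.185 mM); the 200 s scenario runs default to N = 100,
Δt = 10⁻² s, where the headline quantities sit within a fraction of a
percent of their converged values.  The finer N = 400, Δt = 10⁻³ s
resolution remains available through `RunConfig`.  At very coarse N
(≤50) this scheme differs from other discretizations mainly through the
input-zone quadrature (at N = 25 the zone spans 2.5 cells), so coarse-grid
table entries are scheme-specific even though both refine to the same
values; the tests therefore assert shrinking error under refinement plus
the anchored fine-grid values.

## Diagnostics

All reporting conversions live in one module: velocities in µm/min
(×6·10⁷), potentials in mV, pressures in Pa/kPa.  "Osmotic pressure"
denotes iRT(O_e − O_i), equal to −p_m,init (−1 kPa) at baseline.  Point
summaries are taken at the input-zone center (x = 150 µm); velocity
summaries are spatial maxima over faces.  Flux decompositions split each
superficial flux α_r j_r^k into diffusive, drift, and advective face
components; the advection fractions F_diff = |adv/diff| and
F_drift = |adv/drift| are evaluated at the face of peak |total flux| (the
primary convention), with the alternative convention (each component's own
spatial peak) reported alongside, since the two differ by ~10 % for the
strongly advective ICS K⁺ flux.  Phase shifts for pulsatile stimuli are
measured as the lag of the output's cycle maximum behind the input's over
the final full cycle, with quadratic sub-sample refinement.

## Verification scaffolding and what it shows

Unit oracles freeze independently evaluated values (Nernst potentials,
pump rates, anion solve, unit-gradient velocities); a toy single-species
diffusion problem checks the face-flux/divergence primitive against a
loop-assembled dense matrix to 10⁻¹²; one implicit step on a 5-node mesh
is cross-checked against an independent dense root-finder on the same
residual; and property tests (seeded/derandomized hypothesis) cover
conservation, electroneutrality maintenance, source neutrality, and
monotonicity of the membrane mechanisms.  There is no synthetic-data
component in the statistical sense: all inputs are the model's own
parameters and stimulus protocols, so passing tests demonstrate correct
and convergent solution of the stated model, not agreement with
experimental recordings.

## Known limitations

1D only, with spatially uniform parameters; no NKCC1/NBC cotransporters,
no explicit neurons, no AQP4 localization; closed boundaries (no coupling
to perivascular spaces); first-order time integration; the pulsatile
phase-shift metrics need a fine output cadence relative to the cycle
period.  Hydrostatic pressures should be read as model-internal quantities
— the localized kPa-scale extracellular pressure differences exceed
measured intracranial pressure gradients, as the underlying model itself
notes.
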