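# Methods

## Spin model

The engine models one backbone amide as an isolated, weakly coupled
¹H–¹⁵N spin-1/2 pair.  The density operator is expanded in the 16
orthonormal product operators {E/2, Hx, Hy, Hz, Nx, Ny, Nz, 2HxNz, …,
2HzNz}; every propagation step is the exact matrix exponential of a
piecewise-constant generator acting on the real coefficient vector.  The
coherent part contains the rotating-frame offsets (Hz, one per channel),
the secular one-bond coupling 2π·J·HzNz (exact for heteronuclei), and
arbitrary rf fields per channel (amplitude in Hz, phase, carrier
offset).  Rotations are right-handed: a 90°x pulse takes Mz to −My.

Relaxation is phenomenological: R₂ on single-quantum coherences, R₁ on
Hz/Nz, and sums of the constituent single-spin rates on two-spin terms
(e.g. R₂H+R₁N for 2HxNz, R₂H+R₂N for multiple-quantum terms, R₁H+R₁N
for 2HzNz).  Longitudinal cross relaxation couples Hz and Nz with the
Solomon rate σ, and an affine recovery term returns Hz/Nz to thermal
equilibrium, which makes the steady-state nOe simulable.  Full Redfield
treatment (CSA/dipolar cross-correlation, explicit solvent) is outside
the model.

**Sign conventions.**  Equilibrium is normalized per channel: Hz = 1 and
Nz = 1/|γH/γN| ≈ 0.101, both positive, so simulated signals are positive
on both channels.  Because the physical ¹⁵N equilibrium magnetization is
proportional to its (negative) γ, expressing both channels with positive
equilibria transforms the Solomon cross term: the engine uses
sign(γH/γN)·σ as the Hz↔Nz coupling.  With that convention the
steady-state nOe ratio is exactly 1 + (γH/γN)·σ/R₁N with the *signed*
ratio γH/γN = −9.87, as it must be.

Chemical exchange replicates the 16-operator block per chemical state
(each with its own offsets) and couples the blocks with a first-order
rate matrix applied identically to every operator (chemical exchange
without spin-state change).  Populations must satisfy detailed balance
with the rate matrix.

An independent oracle — direct Runge–Kutta integration of the 4×4
density matrix built from Pauli operators, with the same relaxation
model applied through operator projections — verifies the engine to
1×10⁻⁸ on randomized systems and pulse trains in the test suite.

## Experiments

All experiments share one skeleton: equilibrium ¹H polarization →
matched selective transfer to in-phase ¹⁵N → storage along z (purge
gradient = projection onto the longitudinal subspace) →
chemical-shift-selective filter → relaxation encoding → readout
transfer back to in-phase transverse ¹H, whose amplitude at acquisition
start is the signal (no lineshape is needed for relaxation
quantification).

* **Matched transfers.**  Simultaneous (Hartmann–Hahn) irradiation at
  ω₁ = ½·J on both channels transfers Hx → Nx nearly completely at the
  numerically located optimum (≈ 0.986 at t ≈ 3/(π·J) for J = 92 Hz).
  The consecutive single-field variant uses the closed-form fact that
  under H = ω₁Hx + 2πJ·HzNz with ω₁ = πJ (i.e. ω₁/2π = J/2) the
  coefficient vector (Hx, 2HyNz, 2HzNz) precesses about the (1,0,1)
  axis, so Hx converts *fully* to two-spin order at τ = 1/(J√2); the
  refocusing delay then costs only 2HzNz relaxation, and a mirrored
  ¹⁵N period completes the transfer.  Both realizations reproduce the
  tens-of-Hz selectivity in each dimension; the complete experiment
  applies the transfer twice (preparation and readout), and its
  transfer-only response profile has FWHM ≈ 44 Hz at J = 92 Hz.
* **Selective filter.**  90°y – ζ – 90°−y on longitudinal ¹⁵N during ¹H
  CW decoupling (default 2 kHz, explicitly simulated so decoupling
  imperfections are representable), followed by a purge.  With ideal
  pulses and ideal decoupling the retained Nz is exactly cos(2πΔνζ);
  with 2 kHz CW a ~3×10⁻⁸ residual deviation remains.  Replacing the
  first 90° by a long shaped pulse is what turns the filter
  ultra-selective.
* **R₁.**  The relaxation delay acts on stored Nz with cross relaxation
  and recovery suppressed, the idealization of the ¹H-inversion /
  difference scheme used experimentally to isolate the pure R₁N decay;
  the fitted mono-exponential rate therefore equals R₁N (recovered to
  better than 0.1% in the tests; the 2% contract bound is loose).
* **Constant-time R₁ρ.**  The stored Nz is tilted by θ = atan2(ω₁, Ω)
  onto the effective-field axis, locked, tilted back, and read out.
  The constant-time bookkeeping fills the complement of the window with
  a far-off-resonance temperature-compensation lock *before* the
  selection step; such a lock only balances sample heating (a hardware
  concern outside the spin model), so the signal decay encodes R₁ρ
  directly and the tilted-frame relation R₁ρ = R₁cos²θ + R₂sin²θ
  applies.  J during the lock is truncated by the 1.5 kHz default lock
  field.  Alignment pulses matched to θ remove the oscillatory
  component (< 1% residual versus > 5% unaligned).
* **nOe.**  Saturation clamps Hz to 0 (its evolution row zeroed) while
  the longitudinal system relaxes with recovery; the readout compares
  the ¹⁵N signal against the unsaturated reference.  The simulated
  steady-state ratio matches 1 + (γH/γN)σ/R₁N to < 1%.
* **zz-exchange.**  After state-selective preparation the longitudinal
  block evolves under exchange + R₁ (recovery suppressed, as in the
  difference scheme) and each state's Nz is reported.  `prepare="all"`
  moves the carrier onto each state in turn, producing the full
  auto/cross matrix the 2D experiment records.

## The relaxation-aware selective pulse

The designer (`design_golem`) optimizes per-slice amplitude and phase of
a long (default 300 ms, 240 slices) ¹⁵N excitation pulse by maximizing

  |mean over passband of the complex transverse response|
  − w_stop · mean over stopband of |Mxy|²
  − λ · mean squared amplitude fraction,

propagating the single-spin Bloch equations *including R₁/R₂* (valid
while the proton is CW-decoupled; the final shape is always re-evaluated
with the full two-spin engine, which agrees to ~3×10⁻⁵).  Including
relaxation in the objective is the point: stopband trajectories that
linger transverse are damped at R₂, which sharpens the transition band
beyond what the time–bandwidth product alone allows, while passband
magnetization that stays longitudinal until late in the pulse loses
signal at a rate much closer to R₁ than R₂.

Numerics: Strang-split analytic propagation (half relaxation · Rodrigues
rotation · half relaxation) per slice, vectorized over the offset grid;
adjoint-recursion gradients evaluated at the rotation midpoint
(second-order accurate); L-BFGS-B ascent with bound constraints
amplitude ∈ [0,1]; initialization from the calibrated Half-Gauss of the
same duration plus a small seeded perturbation, so the optimized pulse
can only improve on the classical shape.  The design grid spans the
±2 Hz passband (7 points) and a three-tier stopband from 4 Hz out to
250 Hz — the far tier exists because any unconstrained spectral region
acquires comb-like artifacts.  The run is deterministic for a fixed
seed; the accepted-iterate objective trace is monotone.

Measured behavior of the default design (J = 92 Hz, R₁ = 1.5 s⁻¹,
R₂ = 6 s⁻¹): excitation-magnitude FWHM ≈ 8 Hz; the *complete*
experiment's response profile has FWHM ≈ 3.9 Hz with ≈ 4.8% response at
8 Hz, because the filter's hard back-rotation passes only the
phase-aligned component, converting the pulse's off-resonance phase
roll into additional amplitude selectivity.  On-resonance log-loss is
≈ 1.7–1.9× the R₁ prediction and ≈ 0.45× the R₂ prediction — dominated
by R₁, as expected for a shape whose transverse-residence fraction is
only a few percent of the pulse.

Two documented deviations from idealized expectations: (i) passband
phase uniformity within 10° is not attainable for any ≥ 100 ms pulse at
this time–bandwidth product (~0.8); measured spreads are 75–130° of
essentially linear phase roll, reported in the diagnostics, and harmless
because the filter converts them into the amplitude attenuation above.
(ii) The loss cannot be brought *within 25%* of the pure-R₁ prediction
while keeping ≤ 8 Hz selectivity: discriminating ±4 Hz requires on the
order of 100 ms of transverse evolution, so some R₂ exposure is
irreducible.  The comparative claim (closer to R₁ than to R₂) holds
with a wide margin and is what the tests assert.

## Fitting and uncertainties

Mono-exponential fits use scipy least squares; 95% CIs come from a
seeded parametric bootstrap (1000 resamples by default) when the curve's
noise level is known, using a vectorized two-parameter Gauss–Newton
solver so thousands of resample fits stay cheap, and from the asymptotic
covariance otherwise.  Monte-Carlo coverage at 2% noise is 93–97% in the
tests.  Two-site exchange is fitted on the full auto/cross matrix with
both states prepared: a Cramér–Rao analysis shows the single-preparation
design bounds σ(k_ex)/k_ex at ~13% under 2% noise (too weak to certify
10% recovery), while both preparations bound it at ~4%.  Delay sampling
is optimized in the dimensionless variable u = R·t (making the design
scale exactly as 1/R) by minimizing the Cramér–Rao variance of the
fitted rate with deterministic cyclic coordinate descent from fixed
starting designs.

## The synthetic panel and what it does (not) show

`make_polyq_panel` emulates a 16-residue glutamine-repeat scenario: ¹⁵N
offsets packed with a minimum spacing (default 8 Hz, one pair exactly at
it, target residue on the carrier), R₁ ∈ [1.0, 1.8] s⁻¹,
R₂ ∈ [4, 9] s⁻¹, nOe ∈ [0.25, 0.65] (converted to σ), 2% observation
noise.  Two scenario-defining choices: the target draws the largest
sampled R₁ and its 8 Hz neighbor the smallest (the motivating residue is
among the fastest-relaxing), and the pair is also near-degenerate in ¹H
(Δ = 15 Hz), so the proton dimension cannot separate it.  The
observation model contaminates the target's decay with every neighbor's
own decay weighted by the experiment's response in *both* dimensions
(the matched transfer is selective in ¹H and ¹⁵N alike) and adds seeded
Gaussian noise.

The headline experiment fits the contaminated decay: with the
relaxation-aware filter the contamination-induced bias stays below the
95% CI half-width, while the transfer-only experiment (≈ 92% response at
8 Hz) fails that criterion by a factor ≈ 4.

What passing this does *not* show about real data: the panel has no
lineshape overlap, no B₁ inhomogeneity, no phase-cycling artifacts, no
solvent or temperature effects, and its contamination is strictly
additive in the profile weights; real contamination also carries the
neighbors' frequencies, which a lineshape analysis could partially
separate.  The panel certifies the selectivity arithmetic and the
statistical pipeline, not spectrometer performance.

## Problem sizes and tolerances

Profiles use 81–401 offset points (FWHM stable to < 1% under 2× grid
refinement); engine-versus-oracle agreement is asserted at 1×10⁻⁸ with
the oracle integrated at rtol 1×10⁻¹²; piecewise-propagation
associativity at 1×10⁻¹⁰; bootstrap defaults to 1000 resamples (500 in
the Monte-Carlo coverage loops); the pulse design uses 240 slices over
300 ms with ≤ 400 L-BFGS-B iterations.  Degenerate inputs (zero-length
evolution, zero rf, ζ = 0, empty grids, non-decaying signals, singular
mixing-time designs) are either exact identities or explicit errors, as
the tests document.
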