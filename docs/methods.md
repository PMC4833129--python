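# Methods

## Scope and purpose

`noddisim` is a computer-experiment pipeline that asks whether a
five-shell hybrid diffusion imaging (HYDI) acquisition — and nested
subsets of its shells — supports fitting the NODDI three-compartment
tissue model as well as the two-shell acquisition originally recommended
for NODDI. Everything is simulated: acquisition schemes, tissue ground
truth, noise, and fitting. No scanner data enters the pipeline; a
packaged table of white-matter reference values (48 atlas ROIs) is used
only to motivate which corners of the parameter space count as
"realistic" for white matter.

## Acquisition schemes

The HYDI scheme has one b=0 measurement and five shells at
b = 375, 1500, 3375, 6000, 9375 s/mm² with 6, 21, 24, 24, 50 encoding
directions (126 measurements total). Shell-combination protocols
p12…p12345 take the first two to five shells, always keeping the b=0
measurement; they are nested measurement-for-measurement because subsets
reuse the parent directions. The NODDI reference protocol (`NODDI-p14`)
has one b=0, 30 directions at b=711 and 60 at b=2855 s/mm².

Direction tables are not published for the original acquisitions, so
each shell's directions are generated by electrostatic-repulsion
optimization: minimize the Coulomb energy of the point set doubled with
its antipodes by projected gradient descent from a seeded random start
(300 iterations, geometrically decaying step). The construction is
deterministic given (n, seed); each shell gets an independent set. The
resulting designs have near-isotropic second moments (mean outer product
within 0.02 of I/3 at n=250) and minimum pairwise angles well above
random designs; results of the study depend only weakly on the exact
point set. Schemes round-trip through FSL-style `.bval`/`.bvec` text
files.

Units: b in s/mm², diffusivities in mm²/s, so b·d is dimensionless.

## Signal model

For a measurement (b, g) the normalized signal is

    E = (1 − f_iso)·[f_ic·E_ic + (1 − f_ic)·E_ec] + f_iso·exp(−b·d_iso)

with fixed diffusivities d_par = 1.7×10⁻³ mm²/s (intrinsic neurite
axial) and d_iso = 3.0×10⁻³ mm²/s (free water). Orientation dispersion
follows a Watson distribution W(n; μ, κ) ∝ exp(κ(μ·n)²) with
concentration κ ≥ 0; the dispersion index is ODI = (2/π)·arctan(1/κ).

* Intracellular: Watson-averaged sticks,
  E_ic = ∫ W(n)·exp(−b·d_par·(g·n)²) dn.
* Extracellular: Gaussian tensor with the Watson orientation average,
  ⟨D⟩ = (d_par − d_perp)·⟨nnᵀ⟩_W + d_perp·I, where
  d_perp = d_par·(1 − f_ic) (tortuosity) and ⟨nnᵀ⟩_W has eigenvalue
  τ₁(κ) = ⟨(μ·n)²⟩ along μ and (1 − τ₁)/2 perpendicular.
* Free water: exp(−b·d_iso).

S0 is normalized to exactly 1; b=0 measurements return exactly 1.

### Numerics

E_ic is evaluated by a Funk–Hecke/Legendre expansion: both the Watson
density and the stick kernel exp(−a·t²) are axially symmetric, so

    E_ic = Σ_{l even} (2l+1)/(4Z) · I_W(l) · I_K(l) · P_l(g·μ)

with I_W(l) = ∫₋₁¹ e^{κt²} P_l(t) dt, I_K(l) = ∫₋₁¹ e^{−at²} P_l(t) dt,
a = b·d_par, and Z = ∫₀¹ e^{κt²} dt. The 1-D integrals use fixed
192-node Gauss–Legendre quadrature with the Watson exponent shifted by
−κ for overflow safety; the expansion is truncated at l = 32 (worst-case
truncation tail ≈ 5×10⁻⁹ at κ=64, b=9375 s/mm²). Special cases are
exact branches, not limits of the generic path: κ=0 uses the
direction-free spherical stick mean; κ > 10⁴ uses the delta-dispersion
stick (relative error O(b·d_par/κ)); f_ic ∈ {0, 1} skip the absent
compartment. The fast path is validated against an independent
product-grid spherical quadrature (Gauss–Legendre × uniform azimuth,
200×400 nodes, no shared kernels) to 10⁻⁶ on randomized cases; observed
agreement is ~10⁻¹⁰.

`SignalModel` precomputes everything scheme-dependent (stick
coefficients per unique b, isotropic attenuations) so optimizer-loop
evaluations cost one Watson quadrature plus small matrix products.

## Noise

Magnitude MRI noise is Rician: S → sqrt((S+n₁)² + n₂²) with n₁, n₂
independent N(0, σ). SNR is defined at b=0, so σ = 1/SNR_b0 with S0=1.
Simulated levels: SNR_b0 ∈ {20, 30, 40, 50, ∞}. The per-shell SNR
report divides the *noise-free* signal by σ (deterministic by
construction) and pools directions × tissue-grid conditions × fiber
orientations with equal weight. Pooling across tissue conditions makes
the reported spread larger than a per-condition across-direction spread
would be; the pooled *mean* is the quantity of interest. The b=0
measurement is also noised during experiments.

## Fitting

Estimation of (f_ic, κ, f_iso, μ) with d_par, d_iso fixed:

1. **Direction**: principal eigenvector of a log-linear tensor fit on
   measurements with 0 < b ≤ 1600 s/mm² (≥ 7 required).
2. **Scalars**: coarse grid argmin over 5 f_ic × 5 κ × 4 f_iso levels
   at the fixed direction (batched evaluation).
3. **Refinement**: local optimization of all five degrees of freedom.
   Bounds are enforced by smooth reparameterization rather than
   clipping: logit for f_ic and f_iso, scaled logit for κ/κ_max
   (κ_max = 64, ODI ≈ 0.01 — above the κ=16 grid maximum, preventing
   runaway κ on noise-free near-parallel signals), spherical angles for
   μ. κ = 64·sigmoid(z) cannot reach 0 exactly; at the κ=0 boundary the
   optimizer drives z far negative and the recovered ODI is within
   ~10⁻⁹ of 1 in practice.

Two objectives:

* **Gaussian least squares** (default for `fit_noddi` and for all
  noise-free fits): trust-region reflective on the transformed
  variables, tolerances 10⁻¹⁰.
* **Rician log-likelihood** (requires σ): L-BFGS-B on
  Σ [E²/(2σ²) − log I₀(S·E/σ²)] (data-only terms dropped), with
  log I₀ computed stably via the exponentially scaled Bessel function.
  Gradient tolerance 10⁻⁵ is sized to the likelihood scale (~10²);
  tighter polishing moves estimates far below the Monte-Carlo scatter.

Multi-start is available (seeded perturbations of the initial guess;
lowest objective wins, ties to the earliest start); the default is a
single start, which suffices because the grid initializer already lands
in the right basin for this model family. Failure of every start
returns `converged=False` with the initial guess rather than raising.

**Objective choice in the experiment.** The experiment pipeline fits
noisy signals by Rician maximum likelihood and noise-free signals by
least squares. At SNR_b0 = 20 the b=9375 shell sits at an effective SNR
≈ 2, where the Rician noise floor (E[magnitude] ≈ sqrt(S² + 2σ²))
inflates a Gaussian least-squares fit, and the inflation differs between
protocols that include the outermost shell and those that do not —
enough to create a spurious systematic ICVF difference (~0.05) between
p12345 and NODDI-p14. The Rician likelihood models the floor and
removes the discrepancy; it is also what the reference NODDI
implementation uses. On noise-free data the two objectives coincide at
the optimum.

## Experiment design

Ground-truth grid: ICVF ∈ {0.2, 0.4, 0.5, 0.8} × κ ∈ {0, 0.25, 1, 4,
16}, FISO = 0; 250 uniformly distributed fiber orientations (one seeded
design shared by all conditions); 30 noise trials per condition;
protocols {NODDI-p14, p12, p123, p1234, p12345}; SNR_b0 ∈ {20, 30, 40,
50, ∞}. Per-condition noise seeds derive from a CRC32 hash of
(master seed, protocol, SNR, ICVF, κ, orientation, trial), so the run
is deterministic and order-independent; protocols receive independent
noise draws (their measurement sets differ, so matched noise is not
definable). At infinite SNR all trials of a condition are identical and
the fit is computed once and replicated.

Aggregation reports mean ± std of each estimate per (protocol, SNR,
grouped truth level), pooling everything else — trials, orientations,
and the non-grouped truth parameters. Scheme equivalence is tested by a
two-sided paired t-test on estimates paired by (truth condition,
orientation, trial); a Wilcoxon signed-rank alternative is available.
Note the pairing does not cancel noise (the protocols' draws are
independent); it aligns the conditions.

The full design is 750,000 fits. The `desk` preset scales it to the
white-matter-realistic corner — ICVF {0.5, 0.8} × κ {1, 4}, 50
orientations, 5 trials, SNR {20, 30}, protocols {NODDI-p14, p12345}
(4,000 fits, minutes on one CPU) — for CI and acceptance runs. A
scaled-down run tests the same null hypothesis with less power;
the paired test on 1,000 pairs per SNR still resolves mean differences
of ~0.005, so a non-significant result is informative.

### What the desk-scale comparison shows

At the desk preset (master seed 1) the paired test finds no ODI
difference between NODDI-p14 and p12345 (p ≈ 0.81 at SNR 20, 0.96 at
SNR 30). For ICVF it detects a difference of ≈ 0.003–0.004 (p ≈ 0.007
and 0.015): with truth FISO = 0, the FISO ≥ 0 boundary induces a small
positive FISO bias that compensates into ICVF, and the effect is
slightly larger for the protocol carrying the SNR ≈ 2–3 outer shells.
The Rician objective shrinks this gap roughly tenfold relative to least
squares but does not eliminate it; it is an estimator property, not an
optimizer artifact (multi-start refits reproduce it to 10⁻⁴). The
magnitude — Cohen's d ≈ 0.1, about 1% of the true value and a tenth of
the single-fit scatter — is practically negligible, but a 1,000-pair
paired test is powered to see it. Equivalence here is practical, not
exact.

## What the generator does and does not emulate

Simulated voxels are exact members of the model family: single fiber
population, Watson dispersion, fixed diffusivities, FISO = 0, perfect
S0 normalization, spatially independent Rician noise. Real data violate
all of these (crossing fibers, diffusivity variation, CSF partial
volume, coil-combined noise, motion, eddy currents). A green scheme
equivalence test therefore establishes that the *acquisitions* carry
equivalent information about the model parameters under ideal
conditions — not that the protocols perform identically on brains.

## Known limitations

* Signals depend on b only; gradient timing (δ, Δ) is not modelled.
* One Watson fiber population; no Bingham dispersion, crossing fibers,
  dot compartment, exchange, or relaxation weighting.
* The per-shell SNR spread (std) pools tissue conditions and is larger
  than a fixed-condition across-direction spread.
* The printed reference SNR list is linear in SNR_b0 for the 20/40/50
  entries but not the 30 entry; the implementation asserts linearity
  (it follows from SNR = S/σ) and does not target the inconsistent
  value.
* κ estimates are capped at 64 (ODI ≈ 0.01); truths with κ > 64 would
  be reported at the cap.
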