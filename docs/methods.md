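# Methods

This note documents the statistical models behind each module, the
defaults and their units, what the synthetic generators emulate, and
the numerical choices made where the design was genuinely open. No
empirical number appears here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Composition enrichment

For query set Q (disordered) and background set B (folded), residues
are pooled over all sequences of a set and the per-amino-acid
enrichment is

    e(a) = (f_Q(a) − f_B(a)) / f_B(a),

i.e. the frequency difference normalized to the background frequency.
Confidence intervals are percentile intervals from a nonparametric
bootstrap (default 50,000 iterations, α = 0.05) that resamples **whole
sequences** with replacement, independently in Q and B. The sequence,
not the residue, is the exchangeable unit: residues within one protein
are strongly dependent, and protein databases are collections of
sequences. An amino acid is "significant" when its interval excludes
zero; no multiple-testing correction is applied across the 20 letters
(each bar stands on its own, as is conventional for composition
profiles), and amino acids absent from the background have undefined
enrichment and are reported as missing.

Percentile (rather than BCa) intervals keep the procedure deterministic
given a seed and match the plain bootstrap the profile is meant to
represent. The test suite verifies ~95% coverage empirically on
generated populations (coverage of the true enrichment in 93–97% of
200 replicate datasets at 500 bootstrap iterations).

## Secondary chemical shifts and fractional helicity

SCS = δ_observed − δ_random-coil per residue and nucleus, computed on
the intersection of the two tables (unmatched entries are dropped with
a logged count; imputation is never attempted). Random-coil shifts are
consumed as an input table from any external predictor.

Fractional helicity of a residue window is the mean Cα SCS over the
(inclusive) window divided by the Cα SCS of a fully formed helix.
The literature bracket for that reference is 3.1–3.8 ppm; because no
single combination rule is canonical, the reference is an explicit
parameter with default **3.45 ppm** (the midpoint), and both endpoints
are exposed as constants. Helicity is linear in the SCS, so the choice
rescales all reported percentages uniformly and cancels entirely in
relative comparisons between variants.

Relative changes between two helicities are reported as
100·(h_var − h_ref)/h_ref — e.g. 27.7% → 29.3% is a +5.8% (≈6%) gain
and 27.7% → 20% a −27.8% (≈28%) loss.

## Binding

CSP = √(ΔδH² + 0.1·ΔδN²) combines the proton and nitrogen dimensions
with the conventional 0.1 nitrogen scaling. The 1:1 isotherm is the
single-site quadratic

    CSP(L₀) = Δδ_max · (P₀+L₀+K_D − √((P₀+L₀+K_D)² − 4P₀L₀)) / (2P₀),

the exact solution of the mass balance P + L ⇌ PL (verified in tests
against a numerical root of the equilibrium equations).

Two-stage scheme for unsaturated titrations: `fit_reference` fits K_D
and one Δδ_max per residue jointly on the reference protein;
`fit_relative` then fits a **single** free K_D to all of a variant's
residues with Δδ_max frozen at the reference values, reporting the
fold-change K_D(variant)/K_D(reference). This is the estimable
quantity when saturation cannot be reached. Named residues are fitted
jointly by default (a per-residue mode exists); residuals are
unweighted, since per-point CSP uncertainties are rarely available.
Points flagged `disappeared` (intermediate exchange) are excluded
point-wise, keeping the remaining points of that residue.

Optimization: bounded least squares (K_D ∈ (0, 10⁶] µM,
Δδ_max ∈ (0, 10] ppm) with three log-spaced K_D starts (10, 300,
5000 µM), because far from saturation the χ² surface in K_D is
shallow. Standard errors come from the Jacobian at the optimum.

## Diffusion and hydrodynamic radius

Stejskal–Tanner decay I(g) = I₀·exp(−D·γ²g²δ²(Δ−δ/3)), with γ the
proton gyromagnetic ratio (2.675×10⁸ rad s⁻¹ T⁻¹), δ the gradient
length and Δ the diffusion time (defaults 3 ms and 200 ms). The fit is
performed on the dimensionless decay u = D·b_max: b spans ~10¹⁰ s m⁻²
while D is ~10⁻¹⁰ m² s⁻¹, and rescaling to O(1) is required for the
trust-region optimizer to move at all. Flat data (total modeled decay
< 0.1%) returns D = 0 with a warning. Gradient percentages convert to
absolute units via a user-supplied maximum gradient; no instrument
default is hard-coded.

R_H = (D_reference/D_protein)·R_H(reference): the Stokes–Einstein
ratio against an internal standard cancels viscosity and temperature.
The 1,4-dioxane reference radius defaults to 2.12 Å, the standard
literature value; it is an explicit, overridable parameter.

## Guinier analysis

ln I is fitted against q² with weights 1/σ_lnI², σ_lnI = σ/I
(first-order propagation). The q window is determined
self-consistently: starting from the 10 lowest-q points (widened
automatically if noise leaves that window without net decay), the fit
is iterated on q ≤ 0.9/R_g until R_g changes by < 10⁻⁴ relative. The
0.9 bound is the customary one for disordered chains (globular
analysis uses 1.3).

**Known estimator bias.** On exact Guinier data the fit is exact. On
Gaussian-chain (Debye) scattering the Guinier approximation
underestimates R_g; with the self-consistent 0.9 window the bias is
−3.1% (deterministic; reproduced by the test suite, which flags it
against a 3% expectation — the assertion documents the size of the
effect rather than a defect in the data). The bias arises because the
fitted R_g is low, which widens the window (q_max = 0.9/R_g_fit),
which feeds back into a slightly lower R_g than a window placed at the
true R_g would give (−2.9%).

## Ensemble analysis

**Reweighting.** For a static bias V_f (kJ/mol) at temperature T
(default 283 K, matching cold-temperature simulations of yeast
proteins), unbiased weights are w_f ∝ exp(V_f/k_BT), computed with a
max-shift before exponentiation. Constant bias gives exactly uniform
weights. Time-dependent bias corrections (c(t)-style estimators) are
out of scope: the bias is taken as static after an equilibration
discard, which is a caller-facing parameter (default: none).

**Radius of gyration.** Per frame over Cα atoms by default (matching
the collective variable typically biased), unweighted masses unless
requested; reported in nm.

**Secondary structure.** The hydrogen-bond dictionary: an H-bond
between CO(i) and NH(j) is scored by the four-point Coulomb energy
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol and
accepted below −0.5 kcal/mol; close approaches (< 0.5 Å) count as
bonded. Two consecutive n-turns (i→i+n bonds at i−1 and i) mark a
minimal 3₁₀ (n=3), α (n=4) or π (n=5) helix over residues i..i+n−1.
Classic precedence α > 3₁₀ > π is the default (matching DSSP v2-era
behavior); a flag switches to the modern π-over-α ordering. Amide
hydrogens, when absent, are placed 1.02 Å from N anti-parallel to the
preceding carbonyl — the same reconstruction the reference programs
use. Any of the three helix classes counts as "helical" in the census,
which averages per-residue helical flags with the reweighted frame
weights.

The test suite compares assignments residue-for-residue against the
independent DSSP implementation shipped with MDAnalysis on 50
generated structures (full helix / partial helix / coil). That
reference distinguishes only α-helix, strand and loop, so agreement is
scored on the helical/not binary; observed agreement on the builder's
structures is 100%, with the ≥95% test threshold allowing for terminal
ambiguities.

**Contact maps.** Indicator d_Cα(i,j) ≤ 8.5 Å averaged over every
10th frame (both defaults overridable) with weights renormalized over
the strided subset. The diagonal is 1 by construction. Difference
maps are natural-log ratios log((f_var+p)/(f_ref+p)) with pseudocount
p = 1/(2·n_frames_used) (half a count) so never-observed contacts stay
finite; the map is antisymmetric under swapping variant and reference.

**Block averaging.** The error of the mean of a correlated series is
estimated from block means at sizes 2^k (k = 0 up to the largest size
leaving ≥ 8 blocks). The reported value is taken at the smallest block
size where the estimate changes by < 5% over the next two doublings.
When sampling noise in the error curve defeats that strict rule, the
fallback is the maximum of the curve over block sizes retaining ≥ 32
blocks — a conservative plateau proxy, since the theoretical curve
rises monotonically to its plateau. On AR(1) series with ρ = 0.9 and
n = 2¹⁵ the estimate lands within ~20% of the analytic correlated
standard error √((1+ρ)/(1−ρ))·σ/√n across seeds.

**Debye scattering.** One bead per residue at the Cα position with a
uniform form factor: I(q) = Σ_f w_f Σ_ij sin(qr_ij)/(qr_ij). This is
a deliberate coarse stand-in for atomistic predictors with fitted
hydration layers — adequate for validating the analysis chain on
synthetic ensembles, **not** comparable in absolute terms to
experimental profiles. Reduced χ² between a model and data first fits
a scale (and optionally a constant background, off by default) by
linear least squares; experimental σ may be multiplied by a
user-supplied error-correction factor (never computed internally).

## Synthetic generators: the stated world

All generators are pure functions of their seed.

- **Sequences**: i.i.d. residues from stated frequency vectors,
  lengths uniform in a range (default 50–250, bracketing small IDPs).
  Real proteomes have composition correlations along the chain; i.i.d.
  residues make the bootstrap's coverage target exact rather than
  approximate, so a green coverage test validates the bootstrap
  machinery, not database realism.
- **Titrations**: exact isotherm plus additive Gaussian CSP noise
  (truncated at zero; a CSP is a magnitude). Default ligand series
  1:1, 1:3, 1:6, 1:9, 1:20, 1:40 molar equivalents at P₀ = 50 µM —
  the standard design for weak (hundreds of µM) affinities.
- **Ensembles**: backbone (N, CA, C, O, H) built from (φ,ψ) by NeRF
  with ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
  ω = 180°). A two-state along-chain Markov chain (nucleation
  probability p_nucleate, extension probability p_stay, restricted to
  a stated helix region) produces contiguous helical runs with tunable
  mean length — the simplest cooperative model, chosen over
  Zimm–Bragg for transparency. Helical residues take (−57°, −47°) plus
  Gaussian noise; coil residues sample a β/PPII/α_R basin mixture
  (weights 0.35/0.45/0.20, 15° jitter), a plausible disordered
  backbone. Chains may self-intersect (disordered chains in this
  model are not excluded-volume corrected). Ground-truth helical flags
  are retained per frame. Note the census and the truth differ at run
  boundaries by construction: the dictionary requires two consecutive
  i→i+4 H-bonds, so runs shorter than ~4 residues are generated
  "helical" but not assignable — censuses therefore sit below the raw
  Markov-chain occupancy, and tests compare interior residues with a
  tolerance.
- **Bias**: default quadratic in per-frame R_g (κ = 50 kJ mol⁻¹ nm⁻²
  around the ensemble mean), emulating the shape of a converged
  metadynamics bias along a global-dimension collective variable.
- **Scattering / diffusion**: exact Guinier (or Debye) and
  Stejskal–Tanner forward models with multiplicative (scattering) or
  additive (diffusion) Gaussian noise; at zero noise each generator is
  a fixed point of the corresponding fit.

## Known limitations

- The Debye forward model has no form-factor q-dependence, hydration
  layer or excluded-volume term; only synthetic-data validation is
  supported.
- The secondary-structure dictionary implements the helix classes
  only; strand/bridge/turn/bend classes are not assigned (they are
  irrelevant to a helix census and would require the full
  bridge-partner bookkeeping).
- Sequence-level bootstrap treats sequences as exchangeable; database
  redundancy (homologs) must be handled upstream (an exact-duplicate
  dropper is provided, clustering is not).
- Ensemble readers accept multi-model PDB only; binary trajectory
  formats are out of scope.
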