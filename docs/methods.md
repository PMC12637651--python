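# Methods

## Model

`bfbdna` represents double-stranded DNA with one interaction bead per
nucleotide.  The potential energy of a configuration `r` is

    V(r) = V_seqspec + V_dhelix + V_elec

**Sequence-specific term.**  Every interior base pair (i, j) contributes a
trimer potential selected by the three strand-A bases centred on the pair:

* intra-strand bonds `U_C2(r_{i,i+1})`, `U_C2(r_{j,j-1})` and angles
  `U_C2(θ_{i-1,i,i+1})`, `U_C2(θ_{j-1,j,j+1})`, each a Class-2 polynomial
  `U_C2(x) = k2 (x-x0)^2 + k3 (x-x0)^3 + k4 (x-x0)^4`;
* a cross-strand Class-2 bond `U_C2(r_{ij})`;
* four harmonic cross-strand angles sharing two references — `θ^m` for the
  5'-side pair {θ(i,j,j-1), θ(i-1,i,j)} and `θ^p` for the 3'-side pair
  {θ(i,j,j+1), θ(i+1,i,j)};
* two cosine dihedrals `k_φ [1 + cos(φ(j-1,j,i,i-1) + φ^m)]` and
  `k_φ [1 + cos(φ(j+1,j,i,i+1) + φ^p)]` (IUPAC sign convention, φ ∈ (-π, π]).

Terminal pairs that lack a required neighbour contribute nothing.  A trimer
and its reverse complement are one physical motif, so 64 raw contexts reduce
to 32 canonical classes (lexicographic minimum of {trimer, revcomp}; no
trimer is self-complementary, so the classes pair exactly 2:1).  Sites whose
strand-A trimer is non-canonical are evaluated in the flipped orientation —
the complementary strand becomes the "centre" strand, with neighbour roles
assigned along each strand's own 5'→3' direction.  Under this rule the total
energy of a sequence equals that of its reverse complement on relabelled
coordinates *exactly* (verified to ~1e-16 relative in the tests), because
the oriented six-bead tuples are identical point sets: the two θ^m angles
exchange with each other under strand exchange, as do the θ^p angles, and a
dihedral is invariant under reversal of its four-bead tuple.

**Double-helix term (breakable fan bonds).**  Each strand-A bead i interacts
with the l = ±1…±5 neighbours (partner-strand 5'→3' steps) of its
Watson-Crick partner:

    V_dhelix = Σ_i Σ_{l≠0, |l|≤5}  -k_l · exp(-U_pair(i, j+l))

where the dimensionless exponent holds a harmonic bond `k^b_l (r - r^o_l)^2`
plus angular and dihedral modulation of the same form as the cross-strand
trimer terms, with per-offset parameters.  Sub-terms whose neighbour beads
fall off a strand end are omitted, mirroring the terminal rule.  The term is
bounded in `[-Σ k_l, 0]`: rupturing a fan contact costs the finite depth
`k_l` and the restoring force *plateaus* at large extension (the residual
decay is algebraic, through the angular modulation of neighbouring pairs'
exponents, ~1/x² in the pulled coordinate).  The `class2` comparison mode
replaces each fan bond with a Class-2 polynomial in the pair distance — the
unbreakable form used by earlier one-bead models — whose restoring force
grows without bound.  This pair of modes is the heart of the kink
experiment below.

**Electrostatics.**  Debye-Hückel over all bead pairs,
`V = Σ_{i<j} C q_i q_j exp(-r/λ_D) / (κ r)` with `C = e²N_A/(4πε0)` and
`λ_D = sqrt(ε0 κ k_B T / (2 N_A I e²))` (0.785 nm at 150 mM, 300 K,
κ = 78.5).  Charge defaults: -0.6 e per nucleotide for free linear DNA
(counterion condensation), -1 e in nucleosome-mode runs.  Pairs beyond
4 λ_D are dropped unshifted (truncation < e⁻⁴ of the pair scale;
configurable).  No bonded exclusions: the model's bonded terms are fitted in
the presence of the (small) intramolecular screened repulsion.

**Units.**  kJ/mol, nm, rad, ps, K, amu, elementary charges throughout;
k_B = 0.008314 kJ/mol/K.  Conversions happen only at I/O boundaries.

## Geometry conventions and the ideal-helix builder

The builder places a duplex along an arbitrary axis polyline with
parallel-transported (rotation-minimizing) frames: rise 0.34 nm/bp, twist
34.3°/bp, bead radius 0.94 nm.  Paired beads are placed **antipodally**
(strand phase offset π), so base-pair midpoints lie exactly on the axis.
This was a genuine design choice: an asymmetric groove phase (e.g. 138°)
puts the midpoints on a wobble helix of radius ~0.3 nm, which alone drags
the local chain angle of a *straight* duplex from 180° down to ~137° and
pre-kinks the wrapped fixture before any dynamics.  With antipodal phasing
the midpoint-chain diagnostics measure pure axis bending; helical
handedness and groove structure are carried by the ±l asymmetry of the
fan-bond network (the measured ideal-helix fan distances differ strongly
between +l and -l).  `groove_phase` remains a builder parameter for
non-default geometries.

## Default parameter set

The shipped defaults are a *plausibility* set, not a trained force field.
Equilibrium values (bond lengths, angles, dihedral phases, per-offset fan
distances) are measured from the ideal-helix builder, so a built duplex sits
at an exact minimum of every bonded term; stiffnesses are uniform, physically
reasonable magnitudes (bonds 200 kJ/mol/nm², angles 50 kJ/mol/rad²,
cross-strand angles 25, dihedrals 12 kJ/mol; fan depths taper 14→6 kJ/mol
from |l|=1 to 5, fan exponent kb = 20 nm⁻², kθ = 2, kφ = 1).  All 32 trimer
records are identical until a fitting run differentiates them.  The Class-2
comparison coefficients per offset match the curvature of the Gaussian well
at its minimum (k2 = depth·kb) with an equal quartic term.  Every test uses
either this set, analytic toy models, or parameters fitted inside the test.

## Dynamics

Langevin "middle" (BAOAB) splitting in the NVT ensemble: half kick, half
drift, full Ornstein-Uhlenbeck velocity update, half drift, half kick — one
force evaluation per step.  Defaults: 10 fs step, friction 1 ps⁻¹, uniform
bead mass 325 amu (≈ mean nucleotide mass).  Identical seed and inputs give
bit-identical trajectories.  Forces are analytic for every term (verified
against central finite differences to ≤1e-4 relative); degenerate geometry
(coincident beads, collinear dihedral frames) raises a structured error
rather than silently clamping.  Equilibrium observables are independent of
mass and friction, so fixture experiments use light beads (30 amu) and a
20 fs step to accelerate configurational diffusion; the heaviest oscillation
in the default set (ω ≈ 5 ps⁻¹ at 30 amu) remains far below the stability
limit.

Sampling correctness is cross-checked against an independent single-bead
Metropolis oracle (move size auto-tuned to 30–50% acceptance during burn-in,
then frozen; many independent walkers evaluated as one batched energy call):
bond-length marginals of a 4-bp duplex agree at the 1% Kolmogorov-Smirnov
level, and a single bead in `U = k|r|²` reproduces `<|Δr|²> = 3k_BT/(2k)`.

## Nucleosome-like wrapping fixture

147 bp are initialized on a left-handed superhelix (radius 4.2 nm, pitch
2.4 nm, ≈1.9 turns, arc length 0.34 nm/bp).  The histone octamer is
approximated by:

* fixed scaffold beads on an inner superhelix 1.8 nm inside the DNA path
  (the octamer surface), charge +10 e each — screened electrostatic adhesion
  that holds the wrap (at +3 the DNA peels off within 100 ps; at +15 both
  modes are crushed onto the scaffold) — plus a purely repulsive WCA term
  (σ = 0.9 nm, ε = 3 kJ/mol);
* stiff position restraints (k = 1000 kJ/mol/nm²) on the five dyad base
  pairs, in place of a rigid-body constraint;
* weak anchors (k = 5 kJ/mol/nm²) every 10 bp, standing in for the ~14
  discrete histone-DNA binding patches.  Without them the wrap slides as a
  whole and bending strain collects into a single deep kink instead of
  several distinct ones.

Nucleosome-mode runs enable the optional DNA-DNA WCA repulsion
(σ = 0.45 nm — below every bonded equilibrium distance, so it only acts on
crushed geometries) and use -1 e per nucleotide.

**Kink experiment.**  The same wrapped start, scaffold, restraints and
non-fan parameters are relaxed with Gaussian fan bonds and with the Class-2
comparison mode, three independent thermal replicas per mode (how many kinks
nucleate in a 200 ps window is a property of the noise realization).
Statistics are taken over the final third of each replica's frames: the
fraction of midpoint-chain sites with local chain angle below 120°
(averaged over replicas), and the number of distinct kinks — local minima
of the tail-mean LCA profile below 120°, separated by at least the metric's
5-site half-window (the LCA at site k integrates bending over k±5, so two
kinks ~10 bp apart merge into one contiguous below-threshold run; counting
minima deconvolves that footprint), reported as the maximum any replica
exhibits.  The breakable form lets strained long-range fan contacts rupture
at finite cost and keeps the curvature smooth; the unbreakable form
resolves the frustration by sharp localized kinks separated by straight
segments.  The DNA-DNA excluded-volume radius matters here: σ = 0.45 nm
measurably suppresses kink formation, σ = 0.30 nm (below every bonded
equilibrium distance) only guards against geometric collapse.

## Diagnostics

* **Midpoint chain / local chain angle (LCA).**  Virtual beads at base-pair
  midpoints; the LCA at site k is the vertex angle of (k-5, k, k+5), defined
  where both neighbours exist.  π for a straight chain; beads on a circle
  with per-step central angle Δ give exactly π - 5Δ.
* **Fan-bond distributions.**  Per-offset distance samples pooled over sites
  and frames; broadening between a linear and a bent ensemble is reported as
  Δvar = var_bent - var_linear per offset.
* **Persistence length.**  Tangents are unit chords between midpoint beads
  5 apart (suppressing residual wobble); the mean correlation versus contour
  separation is fitted as `exp(-s/L_p)` by weighted least squares on the log
  over the window where the correlation lies in [0.3, 0.95] (above the noise
  floor, below the trivial zero-separation regime), with delta-method
  weights C²/(1-C²) so the noisy far tail does not dominate the slope.
  The point estimate pools all
  frames; 95% confidence intervals come from Student-t on 5 equal frame
  blocks.  Rod-like inputs (correlation everywhere above the window) are
  flagged rather than fitted.
* **KL divergence.**  Shared equal-width bins spanning the pooled range,
  pseudocount 1/N per bin; finite, ≥0 up to the pseudocount, asymmetric.
* **RMSD.**  Optimal rigid superposition (Kabsch SVD) per frame.

## Synthetic ground truth

* **Worm-like chains.**  Polar bend angles are drawn from the exact density
  p(θ) ∝ exp(κ cos θ) sin θ with κ solving the Langevin-function equation
  coth κ - 1/κ = exp(-b/L_p), so the bond-vector correlation is
  *exactly* exp(-kb/L_p) per step and the tangent-correlation estimator has
  a closed-form target.  The discrete mean-squared end-to-end formula is used
  as a second closed-form check.
* **Metropolis oracle** (above) provides Boltzmann samples independent of
  the Langevin path, for sampler cross-validation and fitting recovery.
* **Toy data/noise ensembles** pair a known force field with a stated
  perturbation of it and record the ground truth for recovery tests.

What these fixtures do *not* emulate: sequence-dependent atomistic
statistics (all-atom ensembles of real DNA), solvent and ion structure, and
experimental noise models.  Passing the recovery tests therefore shows that
the estimators and optimizers are correct and well-conditioned at realistic
signal levels, not that the shipped parameters reproduce real DNA.

## Parameterization

**Stage 1 — marginal fitting.**  Each term is fitted independently by
Boltzmann inversion of its marginal: histogram, Jacobian correction (r² for
bonds, sin θ for angles, none for dihedrals), F = -k_BT ln p over bins with
≥10 counts, then a weighted quartic fit converted to Class-2 form by Taylor
expansion about the stationary point (dihedrals: linear fit of
c + A cos φ + B sin φ).  Warnings flag multimodal histograms and
statistically unconstrained curvature (free-energy relief < k_BT across the
sampled window).  Marginal fitting is exact for an isolated term; in a
coupled chain the neighbouring terms narrow each marginal, so marginal
stiffnesses are systematically high (measured ~65% for the intra-strand
bond of a 6-bp duplex) while equilibria are nearly unbiased.  This is the
standard bias that the contrasting stage exists to remove.

**Stage 2 — potential contrasting.**  Logistic noise-contrastive estimation:
with data configurations x_d and noise configurations x_n drawn from a
reference model, the logit is

    h(x) = -β [U_θ(x) - U_noise(x)] + c + ln(N_noise/N_data)

and the loss is the mean binary cross-entropy.  The scalar offset `c` is a
trainable log-normalizer, required for consistency: the optimal
discriminator is the true log-density *ratio*, whose normalization constant
an energy difference alone cannot represent (without it, stiffness recovery
on the two-Gaussian toy stalls ~30% short of truth).  Configurations are
featurized once (every internal coordinate of every frame in one vectorized
pass), so each loss/gradient evaluation is a parameter-array recombination;
all parameter gradients are analytic and verified against finite
differences to 1e-5 relative.  Optimization uses L-BFGS-B by default: the
raw coordinates mix stiffnesses (softplus-reparameterized, O(100) raw units
from a perturbed start) with equilibrium lengths that need ~1e-3 nm
resolution, an anisotropy on which first-order adaptive steps either stall
(small rate) or jitter (large rate); a quasi-Newton method with the same
analytic gradient converges in a few hundred iterations.  `method="adam"`
retains a first-order alternative with an optional geometric rate decay.

Two practical cautions established during development.  First, contrasting
recovers truth only when the trainable family can actually reach the data
distribution: training a restricted parameter subset against a noise model
whose *other* terms are biased (e.g. a marginal-fit model) lets the
discriminator abuse the trainable terms for separation instead of matching,
and training all ~116 active parameters of a 6-bp toy against ~1000-frame
ensembles overfits outright.  Second, identifiability: the cross-strand
bond's coordinate is also restrained by ten overlapping fan bonds carrying
several times its curvature, so its stiffness is barely constrained by
desk-scale ensembles (its equilibrium value, set by the distribution's
location, remains well determined).  The recovery experiment therefore
perturbs the identifiable intra-strand bond parameters, draws noise from
that perturbed model, and trains exactly the perturbed entries.

**Stage 3 — observable-matching fine-tuning.**  Observables under perturbed
parameters θ are estimated from a fixed reference ensemble by importance
reweighting, `w_i = exp(-β[U_1(x_i|θ) - U_0(x_i)])` (computed with a
max-shift; the estimator is invariant to additive energy constants), and

    l_OM(θ) = Σ_targets ( <O>_w - O_exp )² + R_ESS(θ),
    R_ESS = (1/α) ln(1 + exp(α (ESS₀ - ESS)/2)),  ESS = (Σw)²/Σw²

with α = 100 and ESS₀ = 750 by default.  Gradients flow through the weights
only (d<O>/dθ = -β cov_w(O, dU/dθ); dESS/dθ = 2 ESS β (<dU>_{w²} - <dU>_w)),
both verified against finite differences.  The reference ensemble is
regenerated whenever the minimum ESS falls below ESS₀/1.5; U₀ snapshots are
immutable within a round.  For persistence-length targets the per-sample
observable is the tangent-correlation statistic at fixed separations, so the
reweighted average remains a per-configuration expectation; the exponential
fit to extract L_p happens outside the gradient.

## Problem sizes used by the validation suite

Chosen so the full suite and the acceptance script each complete comfortably
on a single core: 8-bp duplexes for force/invariance checks; a 4-bp duplex,
800 ps of Langevin time and 3000 oracle samples for sampler
cross-validation; 500 worm-like chains of 600 beads for the estimator; 1000
data + 1000 noise frames of a 6-bp duplex for contrasting recovery; 2000
reference samples for the fine-tuning toy; 147 bp and 200 ps per fan-bond
mode for the kink experiment.

## Known limitations

* The shipped parameters are a plausibility set; sequence specificity is
  structural (per-trimer tables exist and are exercised by the fitting
  machinery) but not calibrated against real data.
* Fully base-paired linear duplexes only: no mismatches, bulges, nicks,
  single-stranded regions or circular topology.
* The scaffold is a geometric stand-in for the histone octamer; its charges
  and excluded-volume parameters are fixture choices, not fitted quantities.
* Marginal fitting of the fan-bond records identifies only the product
  depth·kb from the distance variance; depths are taken from the template.
* The kink experiment's cluster count depends on the thermal realization;
  the persistent-site statistic reduces but does not remove this.
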