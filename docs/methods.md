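# Methods

This note documents the models implemented in `kemplab`, the choices made
where the underlying procedures left room, and what the synthetic-data tests
do and do not establish.

## Kinetics

**Michaelis–Menten.** Observed rates v([S]) at a single temperature are
fitted, after subtracting the uncatalysed background rate, to
`v = kcat [S] / (KM + [S])` by nonlinear least squares (scipy
Levenberg–Marquardt) in a log-parameterisation that enforces `kcat, KM > 0`.
Initial guesses come from a double-reciprocal (Lineweaver–Burk)
linearisation; standard errors are transformed back to the natural scale by
the delta method using the full fit covariance. The catalytic efficiency
`kcat/KM` (s⁻¹ M⁻¹, with KM converted from mM) is computed from the
unrounded fitted values, never from rounded reports. At least five distinct
substrate concentrations are required; fits with no signal above background
are refused, and non-convergent fits are returned flagged rather than
raised.

**Arrhenius.** `ln k = ln A − Ea/(R·T)` with
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, fitted by ordinary least squares of ln k on
1/T (statsmodels OLS; optional per-point weights via WLS) — matching the
usual Arrhenius-plot analysis. Slope and intercept map to (Ea, ln A); their
covariance is transformed accordingly and carried on the results object.
Preconditions: ≥3 distinct temperatures, all rates positive.

**KIE decomposition.** Two independent Arrhenius fits (H and D) give

    kH/kD (T) = (A_H/A_D) · exp[(Ea_D − Ea_H)/(R·T)],

which holds exactly by construction on the returned object. Standard errors
are first-order (delta-method) propagated:

    Var ln(kH/kD) = Var lnA_H + Var lnA_D + (Var Ea_H + Var Ea_D)/(RT)²
                    − 2 Cov(Ea_H, lnA_H)/(RT) + 2 Cov(Ea_D, lnA_D)/(RT),

using each fit's full (lnA, Ea) covariance. The tabulation temperature
defaults to 303 K (the temperature at which saturation kinetic constants
are conventionally reported); it is always caller-specifiable, since the
Arrhenius fits themselves span 283–323 K. Delta-method SEs agree with a
1000-resample parametric bootstrap within 15 % on synthetic data (tested).

**Pipeline.** `kie_table` fits kcat(T) by a per-temperature
Michaelis–Menten fit (background-corrected) wherever several substrate
concentrations are present, then fits Arrhenius to kcat(T). Variants
missing an isotope series are skipped with a warning; output order follows
the evolutionary trajectory (B, R1, R4 … R7-2) regardless of input order.

## Two-state EVB engine

**Model.** The reaction (proton abstraction from a C–H donor by a
carboxylate-like base) is two diabatic states: state 1 has a Morse C–H bond
and substrate-like charges, state 2 a Morse O–H bond and the
proton-transferred charge set. Each diabatic energy is a plain force field:
Morse reacting bond, harmonic spectator bonds/angles, Lennard-Jones
(Lorentz–Berthelot) and Coulomb (332.06 kcal Å mol⁻¹ e⁻²) nonbonded terms
with a hard cutoff — reacting atoms exempt (effectively no cutoff), as is
standard for the reacting fragment. State 2 additionally carries the
gas-phase shift α. The ground surface is the lowest eigenvalue of the 2×2
matrix, `Eg = (ε₁+ε₂′)/2 − √((ε₁−ε₂′)² + 4H₁₂²)/2`. H₁₂ is constant by
default (the calibration then determines it uniquely together with α); an
exponential form A·exp(−μr) in the donor–acceptor distance is available.

The pairs donor–H and acceptor–H are excluded from nonbonded interactions
in *both* states: one of them is the Morse bond in each state, and
evaluating LJ/Coulomb across the other at bonded distances would swamp the
energy gap with an unphysical clash. The transferring hydrogen carries a
small LJ core (σ = 1.6 Å, ε = 0.02 kcal/mol) so that partial bonds at
intermediate λ cannot collapse it onto a water oxygen.

**Dynamics.** Leapfrog integration on the mapping potential
`Em = (1−λ)ε₁ + λε₂′`; Berendsen weak-coupling thermostat (τ = 50 fs)
measuring the temperature on the constraint-consistent velocities of the
previous step (measuring before SHAKE's kinetic-energy removal would bias
the mean temperature low — observed at ~8 % before the fix). SHAKE
(tolerance 10⁻⁸ Å, ≤500 sweeps, over-relaxation 1.3) constrains water
internal geometry; the transferring hydrogen is never constrained, by
construction. Default time step 1 fs with SHAKE, 0.5 fs without. Energy
blow-up (|E| > 10⁶) and SHAKE failure abort with the last coordinates
attached. NVE drift on the gas-phase complex is < 10⁻⁴ kcal/mol/ps at
0.5 fs (tested); equipartition under the thermostat holds to < 1 %.

**Droplet.** The production-scale setup (protein force field, SCAAS
boundary, long-range electrostatics) is replaced at desk scale by the toy
complex in a droplet of flexible 3-site waters (SPC/Fw-like geometry and
charges) bounded by a harmonic radial wall (10 kcal/mol/Å² beyond the
radius, default 7 Å, ~30 waters); a weak distance restraint
(1 kcal/mol/Å²) keeps donor and acceptor assembled, mirroring the restraint
used on reacting atoms in solution reference simulations. The staged
equilibration schedule mirrors the usual droplet protocol at desk scale:
minimisation, dynamics from 1 K under a 200 kcal/mol/Å² solute restraint,
heating to 300 K while the restraint tapers to 0.5 kcal/mol/Å².

**FEP/US.** The λ ladder defaults to 51 evenly spaced frames (0→1), run
sequentially with chained coordinates; frame lengths are configurable and
default to desk scale (hundreds of fs rather than the production
100 ps/frame). Free energies between adjacent frames use the forward
exponential-average (Zwanzig) formula (bidirectional averaging available);
each window reports an effective sample size and warns below 10. The
profile along the gap coordinate X = ε₁ − ε₂′ is assembled per frame as

    Δg_m(X) = ΔG(λ_m) − kT ln ⟨δ(X − X′) e^(−β(Eg − Em))⟩_m,

bins combined across frames weighted by their counts (default bin width
2 kcal/mol, ≥10 samples per reported bin). ΔG‡ is the maximum between the
two basin minima; monotone profiles are flagged, empty barrier regions
refused. On exhaustively sampled two-parabola models the estimator matches
direct Boltzmann integration to < 0.05 kcal/mol and the Marcus closed forms
λr/4 and (λr+ΔG0)²/(4λr) to < 0.1 (tested).

**Calibration.** (H₁₂, α) are adjusted until the reference profile
reproduces a target ΔG‡ (21.2 kcal/mol for the aqueous Kemp elimination
reference) and ΔG0. Candidates are screened *exactly* on existing samples —
the sampled mapping potential contains neither H₁₂ nor (as a force) the
constant α, so re-forming Eg per candidate is a re-analysis, not an
approximation — by alternating 1D Brent solves (α ↦ ΔG0 has slope ≈ +1;
barrier is monotone decreasing in H₁₂, with H₁₂ ≥ 0 enforced; an
unreachable target raises with the trace attached). The outer loop
re-simulates at the updated α and verifies the screened parameters on the
fresh ensemble. By default re-simulations reuse the sampling seed, making
the ensemble bit-identical and convergence deterministic (2 outer
iterations; 1 when started from converged parameters). `reseed=True` draws
fresh trajectories per iteration; at desk-scale frame lengths the
profile-to-profile noise (several kcal/mol) exceeds any reasonable outer
tolerance, so that mode is only meaningful at production sampling lengths.

The ΔG0 target is not a published quantity; it is a required input
defaulting to 0.0 kcal/mol (a near-thermoneutral reference transfer — any
value in a broad band is reachable through α and does not affect how the
machinery is exercised).

## Conformational substates

χ dihedrals are signed IUPAC angles in (−180°, 180°] computed with the
standard atan2 formulation (vectorised over frames). A substate library
maps state labels to per-dihedral centers with one circular tolerance;
frames are assigned to the nearest center under the *worst-coordinate*
circular distance, or to the disordered/unassigned label (D) outside all
tolerances. Exact ties break to the lexicographically smaller label.
The shipped Trp/Glu library encodes coarse estimates of the three
well-defined active-site configurations (A designed; B with the indole χ2
rotated ~100°; C flipped to hydrogen-bond the catalytic glutamate) and is
explicitly editable: the published state boundaries are graphical, not
numerical, so every assignment records the library used. Populations carry
Goodman 95 % multinomial confidence intervals (statsmodels).

HREX scaling ladders are geometric: factor[i] = λ_min^(i/(n−1)), which
reproduces the canonical six-replica solute-tempering sequence
1.000 … 0.667 at λ_min = 0.667. Exchange bookkeeping is analysis of
attempt logs, not an MD driver. Hot-region selection returns residues with
any atom within a radius of the center residue (scipy KD-tree). RMSD uses
Kabsch superposition (scipy `Rotation.align_vectors`); Daura (greedy
RMSD-neighbour) clustering takes the frame with the most neighbours within
the cutoff as each cluster centroid, ties to the lowest frame index, and is
verified against a brute-force re-implementation. Ring-plane angles use
SVD plane normals folded to [0°, 90°].

## Tunneling

A deliberate 1D stand-in for multidimensional variational-TST tunneling:
κ(T) from the closed-form asymmetric Eckart transmission probability
(matched to forward barrier V₁, reverse barrier V₂ and the imaginary
frequency) thermally averaged by adaptive quadrature — split at the barrier
top with the classical step subtracted above it, so the estimate stays
accurate when kT dwarfs the barrier region — plus the leading-order Wigner
correction 1 + u²/24, u = 1.43877·ν̃/T. Deuterium barriers derive from
hydrogen ones by frequency mass-scaling (ν_D = ν_H·√(m_H/m_D)). The
corrected KIE is (κ_H/κ_D)·KIE_classical, refusing κ_H < κ_D as a
mass-scaling violation. κ values beyond 10³ are flagged as outside the
validity of a parabolic-top 1D treatment. The module makes no claim to
reproduce published multidimensional tunneling coefficients or the
tunneling-corrected KIE of the real reaction — those require electronic-
structure surfaces that are out of scope.

## Synthetic data

Generators are pure functions of (seed, parameters) and serialise their
truth next to the data. Noise models: multiplicative lognormal on rates
(kinetic assays report positive rates with roughly constant relative
error), von Mises on angles, isotropic Gaussian on coordinates. The rate
generator defaults plant Arrhenius parameters representative of an early
and a late evolution round plus a buffer background series over 283–323 K
and 9 concentrations in 0.01–1.1 mM, three replicates. What a green test
establishes: the estimators recover parameters from data generated by the
model they assume, at the stated noise. What it does not: robustness to
model misspecification (substrate depletion, instrument drift, non-lognormal
error), protein-scale EVB energetics, or real conformational kinetics —
the rotamer chain has a single persistence time and no inter-state
correlations.

## Known limitations

- The droplet force field is a stand-in: no protein, no polarisable
  boundary, plain cutoff electrostatics. Calibrated (H₁₂, α) values are
  meaningful only within this toy world.
- Desk-scale mapping frames (sub-ps) undersample solvent reorganisation;
  profiles are reproducible only through the fixed-seed convention above.
- Berendsen weak coupling does not generate a canonical ensemble; it is
  used here (as in the original workflow) for equilibration-quality
  temperature control, with equipartition verified on means only.
- The 1D Eckart κ ignores corner-cutting and multidimensional effects and
  diverges from reality precisely in the deep-tunneling regime it flags.
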