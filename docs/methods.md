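# Methods

## The model

A disordered peptide is represented as a bead necklace: one hard sphere of
radius R = 2 Å per amino acid, adjacent beads joined by harmonic bonds
U_bond(r) = (k/2)(r − r₀)² with equilibrium separation r₀ = 4.1 Å and force
constant k = 0.4 N/m (≈ 0.97 kT/Å² at 298 K). Each bead carries the charge
of its residue; the amino and carboxy termini are explicit charge sites.
Polyvalent anions (citrate³⁻, pyrophosphate⁴⁻, tripolyphosphate⁵⁻ at
pH 8.4, valences configurable) are explicit hard spheres of the same radius
carrying their full charge.

The potential energy is pairwise additive over four terms, all evaluated in
kT at the force-field temperature:

1. **Hard sphere**: ∞ for r < Rᵢ + Rⱼ, else 0. Contact (r = Rᵢ + Rⱼ
   exactly) is allowed, which makes the quoted contact energies attainable.
2. **Extended Debye–Hückel**:
   U = zᵢzⱼ λ_B/r · e^{κ(Rᵢ+Rⱼ)}/[(1+κRᵢ)(1+κRⱼ)] · e^{−κr},
   with Bjerrum length λ_B = e²/(4πε₀ε_r k_BT) (≈ 7.15 Å at 298 K,
   ε_r = 78.4). The hard-core factors are the finite-ion-size ("extended")
   correction of DLVO theory; the expression reduces to bare Coulomb at
   κ = 0. κ is computed from the *implicit* background electrolyte only
   (buffer plus 1:1 salt, I = ½Σcᵢzᵢ²); explicit ions are excluded from κ,
   since counting them both explicitly and in the screening cloud would
   double-screen.
3. **Short-ranged dispersion**: U = −ε/r⁶, with the pair strength the
   arithmetic mean of the two sites' ε. Amino-acid beads default to
   ε = 6.1 × 10³ kJ Å⁶/mol, calibrated so the bead–bead contact attraction
   is 0.6 kT at 298 K; ions have site ε = 0. Arginine/polyvalent-anion
   pairs override the mean with ε = 8.0 × 10⁴ kJ Å⁶/mol — an ≈ 8 kT contact
   attraction representing the multimodal guanidinium–phosphate
   interaction that lysine cannot form. A boolean force-field switch
   disables this override to produce the electrostatics-only reference
   model; the arithmetic-mean combining rule (rather than a mean over √ε)
   is exposed implicitly through the per-site ε arrays.
4. **Bonds**, as above. The conventional ½ factor is included.

Distances use the minimum image convention in a periodic cubic box
(default 250 Å); long-ranged interactions are truncated by minimum image
rather than Ewald-summed, consistent with the granularity of the model.

**Temperature.** The default is 293.15 K (ambient room temperature): the
stated ε ↔ 8.0 kT contact equivalence implies RT ≈ 2.44 kJ/mol, i.e.
≈ 293–294 K; at 298 K the same ε gives 7.88 kT. Every unit conversion
(kJ/mol → kT, N/m → kT/Å², Debye length) lives in `constants.py`, pinned to
CODATA 2018 values.

**Termini.** The terminal charges are zero-radius point charges co-located
with the first/last bead: geometry is not specified by charge bookkeeping,
only the charge is. When a simulation system is assembled, each terminal
charge is added to its host bead's charge. This is exactly equivalent to
carrying separate co-located sites with the degenerate zero-distance
self-pair excluded, and avoids singular pair distances.

## Monte Carlo sampling

Metropolis sampling in the canonical ensemble. One "step" is one proposed
move. Four move classes: single-particle translation (uniform in a cube;
amino-acid beads and explicit ions share this class), pivot rotation
(random hinge bead, shorter arm rotated by a uniform angle about a random
axis), rigid whole-chain translation, and a slithering (reptation) move
that removes one terminal bead and regrows it at the opposite end at
exactly r₀ with a uniform random direction. Default weights propose
single-particle moves 20× as often as each of the other three. All
proposals are symmetric, with one caveat: the fixed-r₀ reinsertion of the
slither move is only exactly symmetric when bonds sit at r₀; the residual
asymmetry is second order in the bond fluctuation and the move is rarely
accepted in strongly coupled systems. Sampling-correctness tests therefore
run on move sets excluding it, and it can be disabled by weight.

Move amplitudes are not physically meaningful and are auto-tuned toward
30–50 % acceptance during equilibration only, then frozen for production
(tuning during production would violate detailed balance); the frozen
values are reported in the trajectory.

Energy bookkeeping is incremental — ΔU of the moved site against all
others for single-particle moves, subset-vs-rest recomputation for chain
moves — and revalidated against a full recomputation every 10⁴ steps with
an absolute tolerance of 10⁻⁶ kT; drift beyond tolerance raises an error.
Runs are pure functions of (initial state, force field, config, seed).

Initial configurations grow chains as self-avoiding random walks with bond
length r₀ and place ions uniformly, rejecting overlaps with bounded
retries.

## Observables

Chains are unwrapped across periodic images by bond-walking (each bead
placed at the minimum-image position relative to its predecessor;
unambiguous since bonds ≈ 4 Å ≪ box/2). R_g uses uniform bead masses, as
appropriate for comparing the bead model directly with SAXS-derived R_g.
Ensemble means carry block-averaged standard errors (default ~20 blocks) to
absorb Markov-chain autocorrelation. Model scattering uses the Debye
formula over identical point scatterers, normalized to I(0) = 1 per chain.
Chain clusters connect two chains when any inter-chain bead pair is within
the contact cutoff (4.5 Å = contact + 0.5 Å skin) or when an ion bridges
both.

## SAXS analysis

Guinier fits regress ln I on q² (weights 1/σ_lnI², σ_lnI = σ/I, when
uncertainties are present) on the largest low-q window satisfying
q·R_g < 0.8. Since the admissible window depends on R_g, it is found by
fixed-point iteration from a deterministic 10-point start; if a short noisy
start window yields an indeterminate (non-negative) slope the window is
grown before the curve is declared un-fittable, two-cycle ties are broken
toward the larger window, and the final window is shrunk if needed so
max(q)·R_g ≤ 0.8 holds exactly. A genuinely increasing curve raises an
error (imaginary R_g is a failure, never a NaN). A Wald–Wolfowitz runs test
on the residual signs flags the low-q drift characteristic of aggregation
as a warning, without rejecting the fit. Association numbers follow from
forward scattering normalized by mass concentration and calibrated against
a standard of known molecular weight (the standard's MW is a required
argument; no default is asserted). The Kratky transform is the plain
(q, q²I) — dimensionless rescaling is out of scope.

## Phase analysis

A titration point is *condensed* when the supernatant falls below 95 % of
the initial protein concentration (threshold configurable). The
condensation window is the contiguous condensed run containing the
minimum-supernatant point — anchoring to the well makes detection robust to
isolated sub-threshold noise on the soluble plateau while leaving noiseless
behaviour unchanged. C\* and C\*\* are linear interpolations of the
threshold crossings at the window's edges; a side the series never
recrosses is reported as missing, not zero. The phase line
c\* = m\*·c_p + c^f is fitted by unweighted ordinary least squares, with
standard errors from the regression covariance. The anion valence is an
explicit argument throughout (charge contribution = m\*·|z|); it is data,
not a constant. The Hst5 monomer mass defaults to 3036.3 Da, computed from
the wild-type sequence, and is overridable.

## Synthetic data

The generators define the study conditions for validation and are pure
functions of their parameters and a seed:

- **SAXS**: exact Guinier curves I = I₀e^{−q²R_g²/3} times mean-one
  lognormal noise with a given coefficient of variation (default scenarios:
  R_g 13 Å, 5 % noise); σ column = CV·I.
- **Precipitation**: for each protein concentration (defaults 2.6, 5.2,
  7.8, 10.4 mg/mL around the experimental 5.2 mg/mL), boundaries
  C\* = m\*·c_p + c^f and C\*\* = C\*·window ratio (default 6) shape a
  smooth well of two logistic shoulders in log-concentration, normalized so
  the minimum supernatant equals the well depth (default 1 mg/mL) and
  offset-calibrated so the supernatant equals the 95 % threshold *exactly*
  at C\* and C\*\*; both boundary concentrations are included in the anion
  grid, so noiseless detection recovers them to machine precision. Additive
  Gaussian noise (default scenario 0.1 mg/mL) is truncated to the physical
  range [0, 1.05·c_p].
- **Systems**: overlap-free chains + ions as described above. The default
  comparison axis places one chain with TPP at anion-per-protein ratios
  {0, 2, 5, 10} in the 250 Å box over a 10 mM implicit buffer background.

What the generators do *not* emulate: instrument-specific beamline noise
and smearing, absolute intensity units, interparticle structure factors at
high concentration, slow condensation kinetics, and polydispersity of the
condensed phase. Passing the recovery tests therefore demonstrates the
correctness and statistical soundness of the estimators on well-posed
inputs, not robustness to every experimental artefact.

## Validation strategy and problem sizes

- Pair terms and conversions check against closed forms (Coulomb at the
  Bjerrum length, κ⁻¹ = 9.6 Å at 0.1 M, the r⁻⁶ scaling, 0.4 N/m →
  2.41 kJ mol⁻¹ Å⁻²).
- The vectorized total energy is verified against an independent
  brute-force double loop over the scalar pair functions (50 random
  20-site mixed states, 10⁻⁹ relative tolerance).
- Boltzmann sampling is verified on a two-bead chain against 1-D
  quadrature of P(r) ∝ r²e^{−U(r)} (χ² on decorrelated samples from a
  10⁵-step run, thinned 10×, since χ² presumes independent draws), and in
  the phantom-chain limit (bead radius → 0.01 Å, dispersion off) against
  ⟨R_ee²⟩ = (N−1)⟨b²⟩ at N = 10 over 10⁶ steps.
- The salt-condition comparison uses one wild-type chain with 10 explicit
  TPP⁵⁻ ions over a 10 mM background, 10⁵ equilibration + 2×10⁵ production
  steps per condition: mean R_g orders TPP+Arg < TPP electrostatics-only <
  100 mM implicit NaCl with gaps well beyond the combined block-averaged
  SEMs (≈ 8.8, 11.1, 12.7 Å under the default seed). These step counts
  resolve the ordering cleanly; production-quality ensemble averages would
  use the full 5×10⁵ + 10⁶ schedule of the model's standard protocol.

## Known limitations

- No explicit solvent, no polarizability, no Ewald electrostatics; the
  dielectric is uniform and temperature-independent.
- Integer charges ignore charge regulation; the Henderson–Hasselbalch
  "average" scheme provides fractional charges but still no site–site
  coupling.
- The slither move's fixed-length reinsertion is approximately, not
  exactly, symmetric (see above).
- Cluster analysis treats an ion as a bridge regardless of its valence or
  binding strength.
- The phase-line fit is unweighted; heteroscedastic boundary uncertainties
  would call for weighted regression, but per-point boundary errors are
  not generally available from a single titration.
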