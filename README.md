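# necklace

Coarse-grained Monte Carlo modelling and solution-scattering / phase-behaviour
analysis of re-entrant condensation (RC) of intrinsically disordered proteins
by polyvalent anions.

Cationic proteins titrated with oppositely charged multivalent ions such as
tripolyphosphate (TPP⁵⁻) can pass through a condensed regime bounded by two
critical anion concentrations: C\* (condensation) and C\*\* (redissolution).
For the disordered saliva peptide histatin 5 (Hst5, 24 residues, net charge
+5 at pH 8.4) this behaviour is governed not only by electrostatics but by a
specific arginine–phosphate attraction. `necklace` provides the pieces needed
to study this computationally:

- **`sequence`** — Hst5-like chains as bead necklaces: one 2 Å bead per
  residue plus explicit terminal charges, integer or Henderson–Hasselbalch
  charge assignment, and the Arg/Lys substitution variants (0R, 1R, 2R,
  Ra/Rb/Rc, 0K, shuffles) that vary arginine content at constant linear
  charge density.
- **`energy`** — the pairwise force field: hard spheres, an extended
  (finite-ion-size) Debye–Hückel potential

  *U*<sub>el</sub>(r) = *z*<sub>i</sub>*z*<sub>j</sub>λ<sub>B</sub>/r ·
  e^{κ(R<sub>i</sub>+R<sub>j</sub>)} / [(1+κR<sub>i</sub>)(1+κR<sub>j</sub>)] ·
  e^{−κr},

  a short-ranged −ε/r⁶ attraction (ε = 8.0 × 10⁴ kJ Å⁶/mol for
  arginine–polyvalent-anion pairs, ≈ 8 kT at contact), and harmonic bonds
  (r₀ = 4.1 Å, k = 0.4 N/m). Polyvalent anions are explicit charged hard
  spheres; κ carries only the implicit background electrolyte.
- **`mc`** — Metropolis Monte Carlo in the canonical ensemble with
  single-particle, pivot, whole-chain and slithering moves (20:1 weighting
  of single-particle moves), incremental energies with periodic
  revalidation, and fully reproducible seeded trajectories.
- **`observables`** — radius of gyration with block-averaged errors,
  arginine–ion contacts, ion-bridged chain clusters, and Debye-formula
  scattering curves.
- **`saxs`** — Guinier analysis (R<sub>g</sub>, I₀ on the q·R<sub>g</sub> < 0.8
  window found by fixed-point iteration), association numbers from
  calibrated forward scattering, and Kratky transforms.
- **`phase`** — ionic strength I = ½Σc<sub>i</sub>z<sub>i</sub>²,
  condensation-boundary detection at the 95 % retention threshold, the
  empirical phase line c\* = m\*·c<sub>p</sub> + c<sup>f</sup> (m\*: ions
  bound per protein at C\*; c<sup>f</sup>: free-ion concentration), charge
  contributions m\*·|z|, and NaCl-equivalent ionic strengths.
- **`synth`** — generators for initial configurations, Guinier-regime SAXS
  curves and precipitation series with known ground truth.

## Worked example

```sh
$ necklace generate variant --spec 0R
Hst5 WT 0R: DSHAKKHHGYKKKFHEKHHSHKGY
net charge +5.00  arginines 0
```

All three arginines are replaced by lysine; the net charge is unchanged, so
any difference in behaviour against TPP isolates the Arg-specific
interaction.

```sh
$ necklace generate saxs --rg 13 --i0 7.3 --noise-cv 0.05 --seed 2 --out hst5.dat
$ necklace analyze-saxs hst5.dat
Rg = 13.199 ± 0.608 Å
I0 = 7.316 ± 0.066
window q ∈ [0.005, 0.06003] Å⁻¹ (76 points, R² = 0.6072)
```

A synthetic curve with true R<sub>g</sub> = 13 Å and 5 % noise is recovered
within one standard error; the fit window respects q·R<sub>g</sub> < 0.8.

```sh
$ necklace generate precip --noise-sd 0.1 --seed 7 --out-dir precip
$ necklace fit-phase precip/*.csv
precip/precip_2.6mgml.csv: C* = 0.93 mM, C** = 12.00 mM, C_max = 2.47 mM
...
m* = 0.781 ± 0.024 ions/protein, c^f = 0.270 ± 0.055 mM  (n = 4)
```

Four titrations at 2.6–10.4 mg/mL protein (ground truth m\* = 0.762,
c<sup>f</sup> = 0.355 mM, noise 0.1 mg/mL) yield boundaries whose linear fit
recovers the bound-ion number per protein within the regression error.

Simulations run from a YAML config:

```sh
necklace simulate --config run.yaml --seed 1 --out-dir run/
```

writing an XYZ trajectory, a final-frame PDB, energy and R<sub>g</sub> series
as CSV, and a JSON summary (mean R<sub>g</sub> ± SEM, acceptance rates,
tuned move amplitudes).

As a library:

```python
import necklace as nk

wt = nk.hst5_wild_type()                       # +5 at pH 8.4, 3 Arg
ff = nk.ForceField().with_ionic_strength(0.010)
state = nk.gen_system([wt], {"TPP": 10}, seed=1, ff=ff)
traj = nk.run_mc(state, ff, nk.MCConfig(n_equilibration=100_000,
                                        n_production=200_000, seed=1,
                                        sample_interval=100))
rg = nk.rg_series(traj)
print(f"Rg = {rg.mean:.1f} ± {rg.sem:.1f} Å")  # compacted by bound TPP
```

With the Arg–TPP term on, a single wild-type chain with 10 explicit TPP⁵⁻
ions compacts to R<sub>g</sub> ≈ 9 Å, versus ≈ 11 Å with electrostatics
alone and ≈ 13 Å in 100 mM implicit NaCl.

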