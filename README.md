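# kemplab

Computational companion toolkit for studying how a designed Kemp eliminase
(an enzyme catalysing base-mediated ring opening of 5-nitrobenzisoxazole via
rate-limiting C–H proton abstraction) improves over rounds of laboratory
evolution. It serves researchers who want to reanalyse or emulate four
strands of such a study on their own data, or on synthetic data with known
ground truth:

1. **Kinetics** — Michaelis–Menten fits, Arrhenius fits
   (`ln k = ln A − Ea/RT`, R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹), and the
   decomposition of H/D kinetic isotope effects into an activation-energy
   part and a pre-exponential part,
   `kH/kD = (A_H/A_D)·exp[(Ea_D−Ea_H)/RT]`, with delta-method error
   propagation.
2. **EVB free energies** — a two-state empirical valence bond engine:
   diabatic force fields mixed through a 2×2 Hamiltonian
   (`Eg = (ε₁+ε₂′)/2 − √((ε₁−ε₂′)²+4H₁₂²)/2`), mapping-potential molecular
   dynamics (leapfrog, Berendsen, SHAKE), free-energy perturbation /
   umbrella sampling along the energy-gap coordinate X = ε₁−ε₂′, and
   calibration of (H₁₂, α) against a solution reference barrier
   (21.2 kcal/mol for the aqueous Kemp elimination).
3. **Conformational substates** — classification of active-site rotamer
   configurations (A/B/C + disordered D) from χ-dihedral time series,
   geometric HREX solute-tempering ladders, Daura RMSD clustering, and
   active-site geometry metrics.
4. **Tunneling** — 1D Eckart/Wigner transmission coefficients κ(T) for H
   and D and tunneling-corrected KIEs (an explicit desk-scale stand-in for
   multidimensional treatments).

A synthetic-data module generates every input with planted truth, so the
whole pipeline is testable offline.

## Worked example

Fit saturation kinetics and decompose a kinetic isotope effect on a
synthetic rate table with known truth (planted: Ea_H = 10.8, Ea_D = 15.1
kcal/mol, lnA_H = 14.0, lnA_D = 19.6, KM = 0.96 mM, 2 % lognormal noise):

```python
from kemplab.synthetic import gen_rate_data
from kemplab.kinetics import MichaelisMenten, fit_arrhenius_from_table, kie_decomposition

table, truth = gen_rate_data(seed=7, noise=0.02)
df = table.select(variant="R1", isotope="H", temp_K=303.0)
print(MichaelisMenten(df["conc_mM"], df["rate_per_s"], background=2e-4).fit().summary())

fit_H = fit_arrhenius_from_table(table, "R1", "H")
fit_D = fit_arrhenius_from_table(table, "R1", "D")
print(kie_decomposition(fit_H, fit_D, 303.0, variant="R1").summary())
```

prints

```
Michaelis-Menten fit
  n obs        : 27
  background   : 2.000e-04 s^-1
  kcat         : 0.02012 +/- 0.00043 s^-1
  KM           : 1.062 +/- 0.038 mM
  kcat/KM      : 18.94 +/- 0.29 s^-1 M^-1
  converged    : True
KIE decomposition (R1 at 303 K)
  Ea(D)-Ea(H) : 4.18 +/- 0.22 kcal/mol
  A_H/A_D     : 0.00452 +/- 0.0016
  kH/kD       : 4.66 +/- 0.07
```

kcat ≈ 0.020 s⁻¹ and KM ≈ 1.06 mM recover the planted saturation curve; the
KIE of ~4.7 splits into a 4.2 kcal/mol activation-energy difference
(deuterium abstraction costs more enthalpy) against a strongly compensating
pre-exponential ratio of ~0.005 — the signature pattern this decomposition
exists to expose.

The same stages run from the shell:

```sh
kemplab synth rates --seed 7 --out data/
kemplab kinetics kie --rates data/rates.csv --temp 303 --out kie.tsv
kemplab substates ladder --n 6 --min 0.667   # 1.000, 0.922, ..., 0.667
kemplab evb calibrate --target-barrier 21.2 --seed 0 --out calib.json
kemplab tunneling kappa --method eckart --v1 14 --v2 14 --freq 1100
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computations from
scratch on inputs generated from the given seed — the kinetics pipeline and
KIE table, the HREX ladder, equilibration plus the full 51-frame EVB-FEP/US
calibration of the toy solution reference to a 21.2 kcal/mol barrier,
substate population recovery, and Eckart κ(T) — logging a summary to stderr
and writing its results JSON to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/kemplab/kinetics.py` — model/results classes for MM and Arrhenius
  fits, KIE decomposition and the per-variant table
- `src/kemplab/evb/` — topology, diabatic energies/forces, dynamics,
  FEP/US estimators, calibration, and exactly solvable surrogates
- `src/kemplab/substates.py` — dihedrals, substate libraries and
  classification, HREX ladders, Daura clustering, geometry metrics
- `src/kemplab/tunneling.py` — Eckart/Wigner κ(T), corrected KIEs
- `src/kemplab/synthetic.py` — generators with planted ground truth
- `src/kemplab/io.py`, `src/kemplab/cli.py` — PDB/XYZ/YAML/JSON I/O, run
  manifests, the `kemplab` umbrella CLI
- `docs/methods.md` — model assumptions, defaults, numerical choices and
  limitations
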