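# corona-thermo

Thermodynamic and structural characterization of the protein corona that
human serum albumin (HSA) forms on self-assembled amphiphilic-dendrimer (AD)
nanomicelles. The package bundles the four analysis stages such a study
needs — fluorescence quenching, isothermal titration calorimetry (ITC),
circular dichroism (CD), and molecular-dynamics trajectory fingerprinting —
as one tested library with a synthetic-data module, so every stage can be
exercised and validated end to end without instrument files.

It is written for biophysicists and formulation scientists who quantify
protein–nanocarrier binding: each module accepts plain CSV/PDB inputs and
returns fitted parameters with standard errors.

## Models at the core

**Fluorescence quenching.** Tryptophan fluorescence quenched by the titrant
follows the Stern–Volmer law F₀/F = 1 + K_SV·[Q]; the modified (double-log)
Stern–Volmer plot log₁₀((F₀−F)/F) vs log₁₀([AD] − (F₀−F)[HSA]/F₀) yields the
dissociation constant K_D = 10^(−intercept), with the slope reported as a
diagnostic (≈ 1 for a single class of sites).

**ITC with micelle mass conservation.** The amphiphile self-assembles above
its critical micellar concentration (CMC), so total titrant partitions as
[AD_tot] = [AD_mon] + N_agg·[AD_mic] with N_agg = 17. The micelle is the
macromolecule, carrying n independent identical protein sites; per-injection
heats follow the Wiseman one-set-of-sites isotherm under the overflow-cell
dilution convention, and the fit returns K_d, ΔH, n with
ΔG = RT·ln K_d and −TΔS = ΔG − ΔH.

**Circular dichroism.** Observed ellipticity is normalized to mean residue
ellipticity MRE = θ_obs/(10·C_p·n·l), and helicity follows from the 208 nm
band: α-helix % = (−MRE₂₀₈ − 4000)/29000 × 100. Thermal melts at 222 nm are
fitted with a two-state sigmoid to extract the melting temperature T_M.

**Trajectory analysis.** Per-residue contact fingerprints (minimum
protein–micelle atom distance < 6.5 Å), salt-bridge occupancies (4 Å
charged-atom criterion, stable at ≥ 50 % persistence), radius of gyration
and gyration-tensor semi-axes (a_i = √(5λ_i), so R_g = √((a²+b²+c²)/5)),
radial distribution functions around the micelle centre of mass,
Shrake–Rupley SASA with the 6:1 area-ratio stoichiometry estimate, and a
Kabsch–Sander (DSSP-style) H/E/T/C secondary-structure subset.

## Worked example

```python
import numpy as np
from corona_thermo import itc, fluorescence as fl
from corona_thermo.synthetic import GeneratorSpec, gen_itc, gen_quenching

# one noisy titration at the documented reference parameters
t = gen_quenching(GeneratorSpec(seed=7), model="modified_sv")
msv = fl.fit_modified_stern_volmer(t, f0=100.0)
print(f"K_D = {msv.k_d * 1e6:.1f} uM  (slope {msv.slope:.3f})")

# one noisy calorimetric isotherm under the reference design
table = gen_itc(GeneratorSpec(seed=7), baseline_sd_ucal=0.0)
fit = itc.fit_one_site(table)
print(f"K_d = {fit.params.k_d * 1e6:.1f} uM  dH = {fit.params.delta_h:.2f} "
      f"kcal/mol  n = {fit.params.n_sites:.1f}")
print(f"dG = {fit.thermo.delta_g:.2f}  -TdS = {fit.thermo.minus_t_delta_s:.2f}")
```

prints

```
K_D = 21.8 uM  (slope 1.003)
K_d = 13.5 uM  dH = -4.02 kcal/mol  n = 6.0
dG = -6.64  -TdS = -2.63
```

i.e. the moderate (tens of micromolar) protein–micelle affinity, the
exothermic enthalpy, the ~6 proteins per micelle, and the enthalpy-dominated
but entropy-assisted free energy split, all recovered from a single noisy
replicate.

The same operations are available from the shell:

```sh
corona-thermo simulate itc --seed 5 --out itc.csv
corona-thermo itc fit --input itc.csv
corona-thermo simulate complex --seed 2 --out complex.pdb
corona-thermo traj contacts --input complex.pdb --protein-chains A,B,C,D,E,F
```

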