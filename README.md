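# cueshift

How does falling seawater pH change the potency of an ionisable olfactory
cue?  `cueshift` implements the full quantitative chain for an amine
chemoattractant such as 2-phenylethylamine (PEA), the cue that attracts
intertidal hermit crabs and whose effect strengthens as the ocean
acidifies from pH 8.1 toward the end-of-century 7.7:

1. **Speciation** — the protonated fraction of the cue from the
   Henderson–Hasselbalch relation, f(pH) = 1/(1 + 10^(pH − pKa)).
2. **Conformer thermodynamics** — minima and barriers of a periodic
   torsion-angle energy scan E(τ), and Boltzmann populations
   p_i ∝ g_i·exp(−ΔE_i/RT) turning energy gaps into extended:folded
   conformer ratios at ocean temperature.
3. **Structure metrics** — XYZ / Gaussian-cube readers and the geometry
   observables of the ligand and its receptor-pocket complex: side-chain
   dihedrals, donor–H⋯acceptor hydrogen-bond distances and angles,
   positional RMSD, centre of mass and point-charge dipole moments.
4. **NMR validation** — ordinary least squares of measured chemical
   shifts δ on computed isotropic shieldings σ (δ ≈ σ_ref − σ), ranking
   candidate conformers by fit quality.
5. **Assay statistics** — paired three-zone choice-assay analysis: a
   random-intercept mixed model of % time near the cue on the 4-level
   treatment factor, Tukey-style post-hoc contrasts, and a one-sided
   Welch test of the between-pH effect difference.
6. **Synthetic data** — seeded generators that plant known torsion
   wells, H-bond geometries, shift maps and behavioural effects, so the
   whole pipeline runs and is testable with no external data.

It is written for chemical ecologists and computational chemists who
want the *analysis* layer — the quantum-chemistry and video-tracking
steps that produce its inputs are out of scope by design.

## Worked example

```python
from cueshift.speciation import AcidBaseSpec, fraction_protonated
from cueshift.conformers import pea_table_ensemble, extended_to_folded_ratio
from cueshift.assay import fit_dose_response, posthoc_pairwise, between_ph_effect
from cueshift.synthdata import GeneratorConfig, gen_assay_trials

pea = AcidBaseSpec("PEA", pKa=9.83)
for ph in (8.1, 7.7):
    print(f"pH {ph}: {100*fraction_protonated(ph, pea):.1f} % protonated")

for state in ("neutral", "protonated"):
    r = extended_to_folded_ratio(pea_table_ensemble(state))
    print(f"{state}: extended:folded = {r.text} (unrounded 1:{r.n_unrounded:.2f})")

trials, truth = gen_assay_trials(GeneratorConfig(seed=20181101))
fit = fit_dose_response(trials, ph=7.7)
posthoc_pairwise(fit)
print(fit.summary())
```

prints

```
pH 8.1: 98.2 % protonated
pH 7.7: 99.3 % protonated
neutral: extended:folded = 1:9 (unrounded 1:8.53)
protonated: extended:folded = 1:13 (unrounded 1:12.92)
Dose-response fit (mixed (REML); posthoc=tukey-single-step), zone=near, pH=7.7, n=20 animals
random intercept SD: 14.04 % time
omnibus treatment test: F(3, 57) = 3.659, p = 0.0175; LRT chi2(3) = 10.567, p = 0.0143
treatment means (% time):
   control:   30.2
      3e-6:   34.2
      3e-5:   49.4
      3e-4:   58.7
  control - 3e-6: -4.08 pp, p_adj = 0.9755
  control - 3e-5: -19.25 pp, p_adj = 0.2128
  control - 3e-4: -28.54 pp, p_adj = 0.0261
  3e-6 - 3e-5: -15.17 pp, p_adj = 0.4174
  3e-6 - 3e-4: -24.46 pp, p_adj = 0.0708
  3e-5 - 3e-4: -9.29 pp, p_adj = 0.7800
```

Reading the output: at the more acidic pH the cue is 1.1 percentage
points more protonated (99.3 vs 98.2 %) and the folded conformer pool
deepens from 1:9 to 1:13; on the synthetic cohort (20 animals, planted
dose-dependent attraction) the mixed model detects the treatment effect
and the Tukey-adjusted control-vs-top-dose contrast is significant.

The same stages are available from the shell:

```sh
cueshift speciate --pka 9.83 --ph 7.7 --ph 8.1
cueshift simulate assay --seed 1 --out demo/
cueshift assay fit demo/trials.csv --ph 7.7
cueshift assay compare demo/trials.csv
cueshift simulate scan --seed 1 --out demo/ && cueshift scan-analyze demo/scan.csv
```

## Layout

| Module                | Contents                                            |
| --------------------- | --------------------------------------------------- |
| `cueshift.speciation` | Henderson–Hasselbalch fractions and profiles         |
| `cueshift.conformers` | torsion scans, minima, barriers, Boltzmann ratios   |
| `cueshift.structures` | XYZ/cube IO, torsions, H-bonds, RMSD, dipole, COM   |
| `cueshift.nmr`        | shielding-vs-shift OLS and conformer ranking        |
| `cueshift.assay`      | mixed-model dose response, Tukey post-hoc, pH contrast |
| `cueshift.synthdata`  | seeded generators with planted, echoed ground truth |

See `docs/methods.md` for the models, conventions and their limitations.
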