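# Methods

This note records the models behind each `cueshift` stage, the defaults
and conventions that matter, and what the synthetic-data tests do and do
not demonstrate about real data.

## Speciation

For a monoprotic equilibrium HA ⇌ H⁺ + A⁻ the protonated fraction is
f(pH) = 1/(1 + 10^(pH − pKa)).  For an amine (`is_base=True`, the
default) HA is the charged ammonium species and A⁻ the neutral free
base; the flag changes which species is *charged*, not the arithmetic.
Fractions are kept at full precision; the one-decimal percentage is
formatting only.  With pKa 9.83 the closed form gives 99.3 % protonated
at pH 7.7, 98.2 % at pH 8.1 and 99.6 % at pH 7.4.  Secondary sources
sometimes quote 98.0 % and 99.4 % for the latter two conditions; those
figures are not reproducible from the closed form at this pKa and we
report the computed values.  The protonation-state difference between
pH 8.1 and 7.7 is accordingly 1.1 percentage points (the rounded
percentages would suggest 1.3).  Only a single ionisable group is
supported; polyprotic input is rejected.  Carbonate chemistry, activity
corrections and the temperature dependence of pKa are out of scope: the
assays this package analyses manipulate pH with a strong acid precisely
to decouple pH from the carbonate system.

## Conformer thermodynamics

A torsion scan is a periodic profile on (−180°, 180°] with at least 8
points; inputs on [0°, 360°) are remapped with a warning.  Minima are
grid points below both periodic neighbours; runs of equal energy
(plateaus) collapse to their central point.  Labels follow the angle
windows |τ| > 120° → *anti*, τ < 0 → *gauche 1*, τ ≥ 0 → *gauche 2*.
Barriers between adjacent minima are the maximum profile value on the
connecting arc minus the lower of the two minima, hence never negative.

Populations use p_i ∝ g_i·exp(−ΔE_i/RT) with R fixed at
8.31446×10⁻³ kJ·mol⁻¹·K⁻¹ for bit-level reproducibility.  The default
temperature is 290.15 K (17 °C, an annually averaged ocean surface
temperature); input in °C is accepted and stored as K.

The extended:folded ratio 1:n uses n = (g_f/g_a)·exp(ΔE_anti/RT) with
g_f = 2 by default: the amine side chain can lock into mirror-image
folded wells of identical energy, so the folded global minimum is
doubly degenerate while the extended well counts once.  Under this
bookkeeping the reference ensembles (hybrid-solvation energy gaps
ΔE_anti = 3.5 kJ/mol neutral, 4.5 kJ/mol protonated) give 1:9 and 1:13
after half-up integer rounding; the unrounded values (8.53, 12.92) are
always reported alongside.  This degeneracy convention is an inference —
an equally defensible `all_minima=True` mode weights every gauche well
by its full Boltzmann population and gives different numbers (e.g.
1:11.1 for the neutral ensemble); only the higher-lying *gauche 1* well
distinguishes the two conventions, and it is excluded from the default
ratio.  Entropic and other Gibbs contributions are deliberately
neglected: the inputs are electronic energy differences.

## Structure metrics

Coordinates are Å internally.  XYZ files are read as-is; Gaussian cube
files are converted from Bohr (factor 0.529177) and a negative atom
count (the oriented-data convention) is read via its absolute value,
with the volumetric grid ignored.  Parse errors name the offending line.
Element masses and covalent radii come from RDKit's periodic table.

Dihedrals use the standard signed atan2 construction, invariant under
reversing the atom order and sign-flipping under mirror reflection, with
range (−180°, 180°].  Hydrogen-bond geometry perceives donor hydrogens
by distance < 1.2 × (covalent-radius sum) — the factor is configurable —
selects the donor hydrogen closest to the acceptor and measures the
D–H⋯A angle *at the hydrogen*, the convention under which protein–ligand
hydrogen bonds concentrate in the 130–180° range.  RMSD defaults to the
raw shared frame (two ligands posed in one pocket are compared without
superposition; this choice is explicit and switchable to Kabsch least
squares), and atom correspondence across protonation states is given by
an explicit index mask rather than graph matching — simpler and
auditable.  Point-charge dipoles are μ = Σ qᵢ(rᵢ − origin) in e·Å,
converted at 1 e·Å = 4.80320 D; for net-charged species the result is
origin-dependent, so the origin (default: centre of mass) is reported
and flagged.  Point-charge dipoles are *not* comparable to dipoles
integrated from a DFT density and are never validated against them.

## NMR validation

Computed isotropic shieldings map onto TMS-referenced shifts roughly as
δ ≈ σ_ref − σ, so each candidate conformer is scored by OLS of δ on σ
(slope expected near −1, intercept estimating σ_ref).  Equivalent
protons are averaged on the computed side before fitting, mirroring
fast-rotation equivalence in solution; neutral and protonated samples
are fitted separately, never pooled.  Ranking uses RMSE as the primary
criterion with R² reported and used only to break exact RMSE ties
(< 10⁻⁹ ppm), then label order — "best linear fit" admits several
reasonable statistics, and this choice is recorded in the output rather
than hidden.  R² is defined as 0 for a zero-variance response.

## Assay statistics

A trial records the seconds an animal spent in the cue-side, middle and
far third of a tank over a nominal 120 s; zone fractions are
100·t_zone/total and must sum to 100 within the 1 s whole-second scoring
slack.  The response analysed is the cue-side percentage (the far-third
mirror analysis is available via `zone="far"`).

The dose–response model is `% near ~ treatment + (1 | animal)` with
treatment an unordered 4-level factor, fitted by REML.  The omnibus
treatment test is a Wald F on the three treatment coefficients with the
balanced-design denominator df (n−1)(t−1) = 57 at n = 20 — on a complete
paired design this reproduces the classical repeated-measures F and is
what the simulation calibration certifies (type-I error within
[0.02, 0.08] at α = 0.05 over 200 null cohorts).  A likelihood-ratio
chi-squared (ML full vs intercept-only, 3 df) is reported alongside.
When the random-intercept variance collapses to zero the model falls
back, with a warning, to OLS with animal as a fixed factor.

Post-hoc pairwise contrasts use the single-step adjustment: each |t| is
referred to the equicoordinate multivariate-t distribution of all six
contrasts (correlation from the fitted contrast covariance, df from the
omnibus denominator), the same family-wise logic as Tukey's test on a
fitted model; if that distribution cannot be evaluated the code falls
back to Holm, and the method used is recorded in the result metadata.
Adjusted p-values are floored at the unadjusted ones, which also absorbs
the small Monte-Carlo error of the multivariate-t quadrature.

The between-pH effect takes each animal's Δ = (% near at the top dose) −
(% near in control) and compares the low-pH Δs against the high-pH Δs
with a one-sided Welch two-sample t-test (alternative: the more acidic
condition shows the larger attraction gain).  Effects are in percentage
points of trial time throughout — a "+21 pp" gap corresponds to ~25 s of
a 120 s trial.  Preference counts use strict inequality; ties count as
non-preferring (conservative).

## Synthetic data

All generators derive independent streams from one integer seed via
`SeedSequence((seed, stream_id))`, so fixtures are byte-reproducible and
adding a generator never shifts another's stream.  Every generator
returns a metadata dict echoing its planted truth; recovery tests read
the truth only from that sidecar.

*Torsion scans* join planted wells with cosine half-waves: C¹-smooth,
periodic, attaining exactly the planted well energies and ridge-top
energies, so minima/barrier recovery is checked against construction
rather than against a second numerical method.  *Pocket complexes* place
the acceptor, donor and bridging hydrogen to realise the planted
d(D⋯A) and D–H⋯A angle exactly (triangle closure), then add random
clash-free decoration (> 1 Å pairwise) that cannot shadow the planted
contact.  *Shift tables* generate shared "experimental" shifts from the
true conformer's shieldings through the planted linear map plus noise;
decoys pair the same shifts with non-identity permutations of the
shieldings.

*Assay cohorts* default to the study conditions this package targets:
20 animals per pH, four treatments, 120 s trials.  Zone times are a
Dirichlet split with total concentration 1.2 — strongly over-dispersed,
matching the all-or-nothing zone occupancy of short choice trials and
implying a per-trial near-share SD of ≈ 32 pp, consistent with the
reported ±14 s standard errors at n = 20.  Planted near-zone biases are
0/+5/+12/+27 pp across doses at pH 7.7 and 0/+2/+4/+6 pp at pH 8.1,
reproducing in expectation the observed 27 pp top-dose effect, the
21 pp between-pH gap and the 14/20 vs 12/20 preference counts.  A
per-animal Gaussian intercept (SD 5 pp) induces the paired correlation.
Times are rounded to whole seconds by largest remainder, preserving the
total.

What passing these tests shows: the estimators are unbiased and
calibrated *under this noise model*.  What they do not show: robustness
to real animal movement, which is temporally autocorrelated, possibly
multimodal across animals, and bounded in ways a Dirichlet split only
approximates; nor anything about cue diffusion or water chemistry,
which are not modelled.

## Problem sizes and numerical choices

The simulation suites use 200 null cohorts (type-I calibration), 100
cohorts for effect recovery, 100 replicates for NMR ranking and 100
random curves for the minima-finder equivalence check; the full test
suite runs in under two minutes on one CPU and `scripts/acceptance.py`
in about one.  Degenerate inputs are first-class: all-equal torsion
scans, zero-variance regressions, missing design cells, donors without
hydrogens and charged dipole systems each raise a specific, named error
or warning rather than producing silent numbers.  Validation of the
pocket-geometry and behaviour-table code paths uses deterministic
synthetic stand-ins with planted observables at the magnitudes of the
real system (N⋯O 2.5/3.1 Å, angles 169.8°/147.2°, RMSD 2.1 Å, torsions
61.8°/66.5°/82.9°, 14/20 and 12/20 preference, 27/6 pp effects); these
verify metric recovery exactly but are not the original measured data.
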