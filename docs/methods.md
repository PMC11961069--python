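# Methods

## The double-Poisson assay model

The package models a sandwich immunoassay read out digitally in a droplet
array. A reaction volume V (default 50 μl) containing n_beads antibody-coated
silica beads is partitioned into monodisperse droplets of diameter d
(default 50 μm, volume πd³/6 = 65.45 pl, hence ≈7.6 × 10⁵ droplets). Two
independent Poisson processes generate the data:

1. **Beads over droplets.** Bead counts per droplet are Poisson(λ) with
   λ = n_beads/n_droplets. The fraction of droplets holding at least one
   bead is 1 − e^(−λ); the fraction of *beads* that sit alone in their
   droplet is e^(−λ) (identical to the empty-droplet fraction — a classical
   Poisson identity that the tests verify by brute-force placement).
2. **Molecules over beads.** At analyte concentration c (pg/ml) the total
   captured molecules are c·V/M·N_A·η with molar mass M (kDa) and capture
   efficiency η (default 0.422, the characterized maximum of the modeled
   chemistry), giving a per-bead Poisson mean μ = c·V·N_A·η/(M·n_beads).
   Binomial thinning by the label efficiency ℓ (fraction of captured
   molecules that end up enzyme-labeled) keeps the per-bead count Poisson
   with mean μ_eff = μ·ℓ, so the probability a bead is "off" is e^(−μ_eff)
   and the Poisson-corrected statistic AEB = −ln(1 − f_on) is a consistent
   estimator of the per-bead enzyme load.

Multi-bead droplets pool their enzymes into one droplet intensity
(physically, all beads in a droplet share one substrate pool) and are
counted as a single bead by the readout, matching the single-bead operating
assumption of a monodisperse design. Consequence: the per-gated-droplet AEB
estimates μ_eff · E[beads | occupied] = μ_eff · λ/(1 − e^(−λ)), a
concentration-independent multiplicative factor (≈1.45 at λ = 0.79) that
the log–log calibration absorbs into its intercept. The estimator-consistency
tests state this factor explicitly.

## Synthetic data generator

`simulate_droplet_table` draws, per droplet: a bead count ~ Poisson(λ); per
analyte channel, pooled enzyme counts ~ Poisson(μ_eff × bead count); an
intensity = Gaussian background + amplitude × enzymes × lognormal(mean 1,
cv); and a FITC gate intensity = Gaussian background + per-bead gate signal
× lognormal. False positives flip enzyme-free, bead-containing droplets to
a single-enzyme-equivalent signal at a configurable rate. Multiplicative
lognormal signal noise was chosen over additive-only noise so bright
droplets have proportional spread, as in fluorescence practice; blanks are
governed solely by the additive background.

Noise defaults (gate 2000 a.u./bead with cv 0.1, background 100 ± 10 a.u.,
50 a.u. per enzyme, signal cv 0.1, false-positive rate 2 × 10⁻⁴, label
efficiency 0.5) are synthetic fixture values chosen to behave like a clean
fluorescence readout; they are not measured constants of any instrument.
All randomness flows from one integer seed through counter-based
`SeedSequence(seed, spawn_key=...)` sub-streams, so extending a ladder or
adding replicates never perturbs earlier wells, and regeneration is
byte-identical.

What the generator does **not** emulate: photobleaching, droplet shrinkage
or coalescence, kinetic (time-lapse) substrate turnover, optical crosstalk
between channels, matrix effects of biological samples, and non-Poisson
bead aggregation. Passing tests therefore demonstrate correctness of the
statistical chain under the stated model, not robustness to every artifact
of real wet-lab data.

## Readout

The bead gate threshold is the midpoint between the background and
single-bead gate modes. The two populations are split by an Otsu threshold
on log intensity — on a linear scale the broad multi-bead tail at λ ≈ 0.8
dominates the between-class variance and the split lands between singlets
and multiplets — with the background mode taken as the lower-class median
and the single-bead mode as the upper-class histogram peak (robust to the
multi-bead tail). Droplets whose gate intensity exceeds 1.5× the single-bead
mode are flagged multi-bead but still count as one bead.

Positive cutoffs follow the blank rule: per channel, mean + k·SD over the
bead-containing droplets of the blank wells, k = 3 by default. Ties at a
cutoff are called positive (≥ rule) so integer fixtures are deterministic.
Threshold provenance (blank wells, means, SDs) is stored so any counts
object can be audited back to its blanks.

The image detector thresholds the channel sum against the dark canvas, takes
connected components, and filters by area ([0.5, 2]× the nominal disc area)
and circularity (≥ 0.7); per-droplet intensity is the component-interior
mean. It is scoped to the package's own monolayer renderings, not general
microscopy.

## Quantification

- **AEB.** Default mode is Poisson-corrected, −ln(1 − f_on); the naive mode
  f_on is retained for sensitivity analysis (the two agree within ~1% for
  f_on < 0.02 and ~5% at f_on = 0.1). A fully saturated well (f_on = 1)
  raises an error advising dilution; the calibration pipeline instead floors
  f_on at 1 − 0.5/n_beads and flags the value so the fit can exclude it.
- **Calibration** is ordinary least squares of log10 AEB on log10 c — a
  straight line, not a 4PL. The dynamic range is detected as the maximal
  contiguous ladder run whose mean AEB exceeds the LOD-AEB with pointwise
  log10 residuals < 0.15 (an artifact constant chosen so a clean ladder
  with ~10% signal cv retains its full linear span); saturated levels never
  enter. Out-of-tolerance levels are trimmed iteratively, worst first.
- **LOD.** lod_aeb = blank AEB mean + 3 × blank AEB SD, inverted through
  the fitted line. Blank wells with zero positive beads get a Jeffreys-style
  floor f_on ← 0.5/n_beads before the log so the LOD stays finite with
  finite bead counts.
- **Back-calculation** inverts the line and flags each value below_LOD /
  in_range / above_range; below-LOD values are reported with their flag,
  never censored to zero.
- **Unit conversion** pg/ml → fM divides by the molar mass in kDa and
  multiplies by 10³. Default molecular weights (OPN 33, IL-10 18.6, IL-6
  21.0, TNF-α 17.4 kDa) are standard literature monomer values and exist
  only to parameterize this conversion; they are configurable.
- **Dilution linearity** back-corrects each level (measured × dilution) and
  reports the largest dilution up to which recovery against the neat sample
  stays within ±20% — a conventional immunoassay validation tolerance —
  plus the r² of measured signal vs 1/dilution.

## Panel comparison

Cohort results are assembled in long format with flags preserved. Group
comparisons report the fold change of arithmetic group means and a Welch
two-sample t-test on log10 concentrations (immunoassay errors are
multiplicative), with Benjamini–Hochberg adjustment across the analytes of
each comparison pair. Below-LOD samples are excluded from testing with
their counts reported rather than imputed, since no principled substitution
rule exists for digital data near the floor.

## Problem sizes and numerical choices

The acceptance script and the full-scale linearity test run the reference
geometry (7.6 × 10⁵ droplets, 6 × 10⁵ beads). The rest of the suite runs
1/10- or 1/100-linear-scale designs that hold both λ and V/n_beads fixed,
so every closed-form expectation (occupancy fractions, μ(c), f_on(c))
carries over exactly and only counting noise grows. Monte-Carlo checks use
3 binomial standard errors; χ² goodness-of-fit uses α = 0.01 with sparse
tail bins merged. Counts are floored with a 10⁻⁹ slack so ratios that are
integral up to float representation do not round down. Oracle tests that
verify the encapsulation formula f_on = 1 − e^(−μ_eff) run with false
positives off and near-noiseless background, because with the default
background SD the 3-SD cutoff miscalls a few percent of single-enzyme
droplets — an intensity-discrimination property, deliberately separated
from the counting statistics under test.

## Known limitations

- The log–log line cannot represent the additive blank floor, so the bottom
  of the dynamic range carries a small positive bias that the range
  detection may trim; a 4PL would model it but is out of scope.
- The bead-count estimate per gated droplet is binary (0/1); quantized
  multi-bead counting from gate intensity is not attempted because no
  standard procedure exists for it.
- Absolute fM detection limits depend on instrument blanks and molecular
  weights and are not asserted; the package reproduces the rules that
  generate them, not wet-lab numbers.
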