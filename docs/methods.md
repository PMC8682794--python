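# Methods

This note records the models behind each stage of the package, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data generators do and do not emulate.

## Window grid and counting

Coverage is tabulated on sliding windows of 200 bp advanced by 100 bp.
Windows start at 0 and only full-length windows are emitted: a trailing
stub shorter than the window is dropped rather than truncated, so the GC
fraction and expected count of every window are directly comparable. This
is a deliberate, documented divergence from counting tools that emit
trailing stubs; the grid is identical for every sample, which the paired
tests require. A read increments every window its aligned span overlaps
by at least one base — a read no longer than the step that does not
straddle a window boundary lands in at most two windows, but a boundary-
straddling read can land in three. Because of the overlap, the sum of
window counts exceeds the number of reads; the library size
(`total_mapped`) is therefore tracked independently. Unmapped, secondary
and duplicate-flagged alignments are skipped by default. GC fractions
exclude ambiguous bases from numerator and denominator; an all-N window
gets NaN and unit correction factor, and is excluded from the bias fit.

## GC-bias correction

Depth depends on window GC in a smooth, unimodal way for Illumina-type
libraries. The model is a robust linear regression of count on GC (Huber
M-estimation, tuning constant 1.345, iterated to relative coefficient
change < 1e-8 or 50 iterations). Robustness matters because true CNVs are
exactly the outliers the fit must ignore. Correction factors are
tabulated per 0.01-wide GC bin as (mean fitted value)/(fitted value at
the bin centre), floored at 0.1 and capped at 10 so a handful of
extreme-GC windows cannot explode. If the fitted line goes non-positive
at any observed GC the model refits on log(count + 0.5) with a warning.
A straight line removes the dominant (monotone) component of a quadratic
bias; the residual curvature after correction is small relative to the
pre-correction trend, which is what the regression tests check. Each
sample is normalised independently, before testing — the conservative
ordering when the pipeline description leaves it open.

## Paired CNV tests

For each window the mutant is compared with the control by a Pearson
chi-squared test (1 df, no continuity correction) on the 2x2 table
window-vs-rest-of-library. This layout uses both library sizes and is
correctly calibrated when counts are near-Poisson; a goodness-of-fit
variant (mutant count against the depth-scaled control count) is offered
behind `layout="gof"` but is anticonservative under overdispersion and is
not the default. Windows with zero counts in both samples are excluded.
BH correction runs across all tested windows of one control/mutant pair
(the comparisons are pairwise per strain; pooling across strains would
mix families). Significant windows of the same direction with
overlapping or adjoining spans are merged; an interval is a call iff its
span strictly exceeds 500 bp and it contains >= 3 significant windows.
"More than 500 bp" is treated as strict and "three or more" as >= 3,
exactly as the filter is usually stated. Direction is the sign of the
mutant/control coverage ratio minus one.

Whole-chromosome duplications: per chromosome, the median window count of
each sample is rescaled by that sample's genome-wide median (cancelling
global depth differences), and the mutant/control ratio is flagged as a
duplication at >= 1.75 — midway between 1 and 2 on a haploid baseline
with margin for noise. The median rescaling assumes most of the genome is
euploid; when a large fraction of the genome is duplicated the genome
median shifts and ratios compress toward 1 (a ~30% duplicated fraction
reads out near 1.9 rather than 2.0). Chromosomes with fewer than 10
windows report a ratio but suppress the flag.

Mitochondrial copy number: RPKM = reads/(length_kb x mapped_millions) per
feature; copy number = mt RPKM over the mean RPKM of single-copy nuclear
genes, oriented so more mitochondria gives a larger number (an `invert`
flag provides the reciprocal convention). Quantile normalisation across
samples is available as an optional pre-step on per-gene RPKM vectors.
Relative copy number across samples divides by the control.

## G4 motifs and association

The scanner chains maximal G-runs (>= 3 Gs by default) left to right
while consecutive runs are separated by 1–25 nt; every maximal chain of
>= 4 runs is one motif, and overlapping motifs (including across strands;
C-runs on the forward strand are G-runs on the reverse) merge into one
locus so nested matches are not double-counted. The defaults are
calibrated so that both G4 cassettes used in the rearrangement assay
match while their G->C point mutants do not; the scanner is not intended
to reproduce any published genome-wide prediction catalogue.

Overlap enrichment classifies every window of a genome-wide universe by
overlap with the query and with the G4 set, so the 2x2 margins are well
defined; Fisher's exact two-sided p (tie convention: tables with pmf <=
observed x (1 + 1e-7)) and the one-sided hypergeometric upper tail are
both reported, because either may be quoted for such intersections. The
hypergeometric pmf is evaluated from log-gamma functions; the odds ratio
takes a Haldane +0.5 correction when a cell is zero; degenerate margins
return p = 1 with a warning.

The distance null draws, per replicate, one interval per observed query
interval with the identical length, placed uniformly at random
genome-wide — chromosome chosen with probability proportional to its
placeable start positions, intervals allowed to overlap each other.
The summary statistic is the mean nearest-G4 distance (median via flag);
the empirical p uses the add-one rule (1 + #{replicate <= observed}) /
(n_reps + 1), lower tail = closer than expected. 1000 replicates is the
default. Resampling is genome-wide; per-chromosome stratification was
considered and left out as the unstated default, since the chromosome-
weighting already matches the marginal placement distribution.

## Fluctuation analysis (MSS maximum likelihood)

The Luria–Delbrück mutant-count distribution is parameterised by m, the
expected number of mutation events per culture, through the
Ma–Sandri–Sarkar recursion (equivalently: a compound Poisson with
clone-size law P(K >= k) = 1/k). Two numerical facts shape the
implementation:

* the distribution's tail is p_r ~ m/r², so the mass beyond any feasible
  truncation point r_max is ~m/r_max — the pmf cannot be summed to within
  1e-9 of unity at desk scale, and estimators must not depend on the deep
  tail. Counts above a cap (default 10 000) are therefore right-censored
  in the likelihood, contributing log P(R >= cap); the exact value of a
  jackpot carries essentially no information about m.
* sampling uses the compound-Poisson representation directly
  (N ~ Poisson(m) clones of size floor(1/U)), which is exact in
  distribution with no truncation error and costs O(m) per culture.

The MLE maximises the summed log-pmf by bounded scalar optimisation on
[1e-9, m_hi], with m_hi set from the p₀-method pilot estimate
(-ln(fraction of zero cultures), floored to avoid log 0) as
2 x (pilot + 5). The 95% CI comes from the profile-likelihood drop of
1.92 log-units (deterministic, matching standard fluctuation-analysis
practice; no bootstrap). All-zero counts give the boundary MLE m = 0 with
a one-sided upper CI. Partial plating (fraction f of each culture plated)
is handled by binomial thinning of the pmf — the exact likelihood for
that design — rather than by rescaling counts. Rates are m/Nt with Nt the
viable cells per culture, measured once per strain in the usual design;
fold enrichment between strains is the rate ratio, reported per replicate
pair and as the mean when independent tests exist (with common Nt the
fold on rates equals the fold on m).

## qPCR (Pfaffl)

ΔCt for each locus is input Ct minus IP Ct, after subtracting
log_E(dilution factor) from the measured input Ct (a 1:d diluted input
crosses threshold log_E(d) cycles late). Fold enrichment is
E_target^ΔCt_target / E_ref^ΔCt_ref with a reference locus as internal
standard. Efficiencies are accepted in [1.95, 2.05] (95–105%) by default;
out-of-band values raise unless explicitly overridden.

## Thermal difference spectra

TDS = (A_high − A_low)/max(A_low), computed on the low-temperature grid
(linear interpolation if the grids differ). The G4 signature requires a
positive median over 260 nm to pivot−5, a negative median over pivot+5 to
320 nm, and a zero crossing within pivot ± 3 nm (pivot 290 nm). Band
medians rather than single wavelengths make the lobes robust to grid
placement and noise. The crossing is located by a local quadratic fit
over pivot ± 15 nm (root nearest the pivot); the quadratic term absorbs
the lobe curvature that biases a straight-line fit by over 1 nm, and on
noise-free generator spectra the located crossing is within 0.25 nm of
the true 290 nm. On sparse grids (< 6 points in the band) the locator
falls back to interpolating the sign flip nearest the pivot.

## Langmuir kinetics

Under single-site Langmuir binding, each concentration step relaxes as
sigma(t) = sigma_inf + (sigma_start − sigma_inf) e^(−k_obs t) with
k_obs = k_on c + k_off and plateau sigma_inf = sigma_max c/(c + K_d).
Stage one fits the exponential per step (initialised from log-linearised
residuals against a provisional plateau; >= 10 points per step); stage
two regresses k_obs on c, weighted by inverse squared standard errors
when the per-step fits provide them, giving k_on (slope) and k_off
(intercept); K_d = k_off/k_on by definition, and sigma_max comes from a
one-parameter least-squares fit of the plateaus to the isotherm with K_d
fixed. The two-stage scheme is the standard reading of "fit an
exponential growth per curve" that still yields k_on and k_off
separately. Steps with non-positive fitted k_obs are excluded with a
warning (at the highest concentration the step can be entirely plateau,
leaving no decay to fit); fewer than two usable steps is an error. Units
are fixed: concentrations nM, time s, k_on in 1/(nM s).

## Synthetic data: what is and is not emulated

The generators are pure functions of (configuration, seed) and return
machine-readable ground truth alongside the data.

* **Genome**: chromosomes with a sinusoidal GC landscape (default mean
  0.42, amplitude 0.08, period 50 kb — yeast-like composition with
  enough spread to make GC bias identifiable), planted canonical G4
  motifs at one per 25 kb on nuclear chromosomes, 1–2 kb single-copy
  gene intervals, and one 30 kb mitochondrial chromosome. Background
  sequence can contain accidental G-runs; an optional masking mode breaks
  them when scanner silence is required.
* **Coverage**: expected count per window = depth x copy x bias(GC);
  default depth 100 reads/window; the default bias curve is a unimodal
  quadratic peaking at GC 0.40 with multiplier range [0.5, 1.0] — a
  typical Illumina-like curve, strong enough that calling without
  normalisation visibly degrades. Noise is Poisson or negative binomial;
  **the negative-binomial "dispersion" d is the fractional excess of the
  variance over Poisson (Var = (1+d)mu, NB size = mu/d)**, so the default
  d = 0.1 means 10% extra variance — mild technical overdispersion under
  which the chi-squared pair test stays essentially calibrated. Counts
  are drawn independently per window; read sharing between overlapping
  windows (which correlates neighbours) is not emulated, nor are
  mappability holes, repeats, or alignment artefacts. Windows partially
  covered by a CNV get a proportionally blended copy number. The
  mitochondrial chromosome carries an independent depth multiplier
  (default 20x, a yeast-like mtDNA copy number).
* **Planted CNVs**: default 20 disjoint events of 800–2000 bp (the sub-
  2 kb scale of interest; large enough that the >500 bp / >=3-window
  filter is meaningful) with copy multipliers cycling through 0, 0.5, 2,
  separated by >= 2 kb, never on the mitochondrial chromosome.
* **Fluctuation counts**: exact Luria–Delbrück draws (see above); no
  phenotypic lag, post-plating growth, or death.
* **Spectra**: Gaussian low-temperature absorbance peaking near 258 nm;
  the G4 thermal difference is an odd-shaped lobe pair crossing zero at
  exactly 290 nm with amplitude ~0.27 A_max at 260 nm; duplex and
  single-strand differences are broad positive humps. Additive Gaussian
  noise per spectrum. Real spectra have correlated baseline drift and
  instrument-specific lineshapes that are not emulated.
* **Binding curves**: piecewise-exponential Langmuir response to the
  default five-step spike series (0.08, 0.4, 2, 10, 50 nM, 600 s per
  step, 2 s sampling) with multiplicative Gaussian noise. Mass-transport
  limitation, drift and spot-to-spot variability are not emulated.

Passing the recovery and calibration tests on these generators shows the
statistics and estimators are implemented correctly under their stated
assumptions; it does not show robustness to the real-data artefacts
listed above, which is why GC correction and duplicate filtering remain
configurable at the interfaces.

## Problem sizes used by the test suite and acceptance script

Chosen as desk-scale study conditions: a ~5.1 Mb two-chromosome genome
(~51 000 windows) for calibration and recovery checks; 20 null pairs for
the type-I check; one pair with 20 planted CNVs for recovery; 200 seeds
x 199 replicates for the resampling-null uniformity check and 1000
replicates for the planted-overlap p; 1000 cultures for MSS parameter
recovery and 3 replicate pairs of 100 cultures (m = 7.5 vs 0.5) for the
15:1 fold-recovery check — at the 5-culture scale of a wet-lab
fluctuation test the ratio of two MLEs is unstable for any estimator, so
the simulation uses enough cultures that estimator error, not culture
count, is measured; 100 seeds for the noisy-K_d recovery and the
classification robustness sweep (noise levels 1–5% of A_max, 20 seeds
each).

## Known limitations

* The chi-squared pair test assumes near-Poisson window counts; strong
  biological overdispersion inflates its type-I error, and the merge
  filter is then the only guard. A dispersion-aware test (e.g. negative-
  binomial GLM) is out of scope here.
* Breakpoints are window-resolution (±100 bp); no sub-window refinement.
* The copy-0.5 state at depth 100 sits near the power boundary of the
  prescribed per-window test: single-pair recall of a 20-event mix of
  copy 0/0.5/2 fluctuates around 0.9, driven almost entirely by
  heterozygous-like losses whose significant-window runs fragment.
* The MSS likelihood censors extreme jackpots (see above); m estimates
  are unaffected in practice but the reported log-likelihood depends on
  the censoring cap when jackpots are present.
* `scan_g4` reports loop lengths from the first chained match at a
  merged locus; alternative chainings through the same locus are not
  enumerated.
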