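# Methods

## Segregation model

An F2 population arises from selfing a fully heterozygous interspecific F1,
so each locus segregates 1:2:1 (wild homozygote : heterozygote : cultivar
homozygote) and unlinked loci assort independently. A gene model is an
ordered set of locus requirements; the "high terpene" phenotype requires
*every* locus to be satisfied (an AND-combination): a recessive locus needs
the wild homozygote (probability 1/4), a dominant locus at least one wild
allele (probability 3/4). The expected high fraction is the product of these
per-locus probabilities; `enumerate_f2_genotype_classes` provides the
brute-force joint-table oracle (up to 8 loci, 3^L rows) against which the
closed form is verified to 1e-12 for every recessive/dominant assignment up
to six loci.

Assumptions: no linkage, no epistasis beyond the AND-combination, no
segregation distortion, phenotype determined by genotype alone. Backcross
designs, recombination fractions and QTL mapping are out of scope.

### Goodness of fit and ranking

Observed high/low counts are compared to each candidate model with the
two-cell Pearson χ² (df = 1: two cells, no estimated parameters), upper-tail
p from the χ²₁ distribution (`scipy.stats.chi2.sf`; the df = 1 tail equals
`erfc(sqrt(x/2))`, which the tests use as an independent cross-check). No
Yates continuity correction by default — the corrected variant is available
behind a flag but changes the reproduced reference statistics. Models are
ranked by descending p (equivalently ascending χ² at fixed df); ties break
by fewer loci, then lexicographic name, then input order. No AIC-style
penalty is applied: all candidate models have the same df and published
segregation tables rank by fit alone.

**Expected-fraction basis.** Published segregation tables print rounded
ratios (1:15, 1:20, 1:27, ...) whose exact odds can be non-integer (a
two-recessive + one-dominant model has exact odds 61:3 ≈ 20.3). The χ²
statistic therefore depends on whether the expected fraction is the exact
product (3/64) or the fraction implied by the printed ratio (1/21). Both are
supported; `printed_ratio` is the default because it reproduces reference
statistics computed from printed ratios (12:380 vs 1:15 → χ² = 6.80; vs the
printed 1:20 → χ² = 2.50), `exact` is the right choice for simulation work.

**Known discrepancy.** For the observed 12:380 counts, only the 1:15 and
1:20 rows of the published six-model comparison are recoverable (6.80 and
2.50); the published statistics for the 1:63, 1:27, 1:84 and 1:255 rows
(2.54, 1.15, 6.46, 47.35) do not follow from 12:380 under either basis. The
package reproduces the recoverable rows and the full χ²→p mapping at df = 1
and makes no attempt to reverse-engineer the remaining inputs. Note the
ranking is unaffected: the two-recessive + two-dominant model fits best
under both the published statistics and the recomputed ones.

**Display.** Ratios round half away from zero; a model with f > 1/2 prints
the degenerate ratio "1:0" rather than failing. χ² prints at 2 dp and p
thresholded ("< 0.01", "< 0.05") in reports only — stored values are full
precision, and CSVs are re-read with the exact round-trip float parser so
report regeneration is byte-identical.

## GC-MS quantification

Integrated peak areas are normalised as

    normalized = (peak_area / IS_area) · dilution · (V_extraction / V_injection) / D

with D = mg fresh weight (leaf washes) or number of glands (trichome-head
extracts). The internal standard is benzyl acetate spiked at 0.5 ng/µL; all
steps are linear in peak area, so the order of the volume and IS corrections
does not affect the result (the combining convention above is fixed so that
intermediate columns are reproducible). Normalised areas become ng via a
calibration slope per compound (authentic standards; β-caryophyllene serves
for 7-epizingiberene and its derivatives). Compounds without a response
factor are flagged `semi-quantitative` and carried as IS-ratio areas, never
silently dropped.

The parental reference is mean ± 1.96·sd/√n of the wild-parent replicates
(default n = 4, sample sd). "Parental levels or higher" is operationalised
as value ≥ lower 95% CI bound (`rule="ci_low"`), configurable to the
parental mean; the CI is the only threshold object the normalisation
procedure defines, so its lower bound is the least arbitrary cut.

Histogram binning isolates exact zeros in bin 0 (an optional detection
limit zeroes values below it first); a positive value v falls in bin
⌈v/sd⌉ where sd is the parental standard deviation (left-open, right-closed
bins of width sd). Fold changes report a/b (integer display at ≥10, else
1 dp); percent reductions report 100·(control − treated)/control rounded
half away from zero (this convention, not banker's rounding, reproduces a
62.5% reduction printing as 63%). An increase (treated > control) yields a
negative reduction and is flagged, not raised. Per-sample plastidial vs
cytosolic totals sum quantities by the sub-cellular localisation of the
corresponding synthase; unmapped compounds are listed separately.

## Trichome and cavity phenotyping

Leaf-disc counts (default disc radius 2 mm, two discs per surface) are
averaged per surface, then summed over abaxial + adaxial to give the
two-sided per-disc total; the per-mm² density divides that total by one
disc area π·r² (both columns are emitted, since the summed and per-area
conventions are used in different figures of typical studies). Density
classes are K equal-width bins (default 10) on the summed counts,
right-closed, with the bin edges emitted for audit; the degenerate
all-equal case collapses to one class with a warning.

Storage cavities are prolate spheroids with semi-axes a = width/2
(transverse plane) and b = height/2 (medial plane). The default volume is
(4/3)·a²·b — the π-free convention of the source field protocol — with the
geometric volume (4/3)·π·a²·b behind `include_pi`. Which convention a given
published picolitre value uses cannot generally be determined, so both are
supported; every ratio-based summary (fold change, percent reduction) is
invariant to the choice. 1 picolitre = 1000 µm³.

The density–terpene association is ordinary least squares of leaf terpene
total on type-VI density, via statsmodels: r² (squared Pearson
correlation), two-sided p for slope = 0, and a 95% confidence band for the
mean response. A constant predictor or n < 3 raises.

## Synthetic populations

`SimulationConfig` defaults define the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| model | a-b-C-D | generating gene model (two recessive + two dominant loci) |
| n_plants | 392 | F2 subpopulation size |
| high_level_mean | 70 ng/mg FW | parental leaf 7-epizingiberene level |
| low_level_mean | 1.1 ng/mg FW | F1-like leaf level of low plants |
| high_cv / low_cv | 0.3 / 0.8 | lognormal CVs (declared assumptions — within-class variance components are not published) |
| zero_fraction_low | 0.8 | probability a low plant has zero detectable signal (reproduces a dominant zero bin in the level histogram) |
| density_mean / dispersion | 50 / 8 | negative-binomial two-sided trichome count per disc |
| active_gland_ng | 17.7 | per-gland terpene total of active plants |
| lazy_gland_ng | 17.7/150 | per-gland total of lazy plants (~150-fold spread) |
| active_fraction | 0.5 | share of plants with active glands |
| parental_n | 4 | parental replicates behind the reference CI |

Leaf levels are lognormal conditional on the phenotype class (strictly
positive and right-skewed, as observed), zero-inflated in the low class.
Trichome density is negative binomial and independent of the phenotype
loci. Gland productivity is a latent active/lazy class drawn independently
of both (a correlation knob exists for sensitivity analysis), reflecting
the finding that density and per-gland productivity segregate
independently; the leaf terpene *total* is density·(per-gland content)·
(leaf area per mg, 1.26 mm²/mg), so it correlates with density only when
per-gland content is near-constant. Cavity volume is proportional to gland
content at 25.0/12.3 ≈ 2.03 pl per ng, anchoring the volume scale to the
measured control pairing. All draws come from one seeded generator;
identical seeds give bit-identical tables.

Measurement-table writers invert the normalisation pipeline, so running the
quantification stage on the emitted CSVs recovers the simulated ng values
exactly — a round-trip property the tests assert. What the simulator does
**not** emulate: chromatographic noise, co-elution or integration error,
batch effects, environmental covariates, linkage, genotyping error. Passing
tests therefore validate the statistical logic of the pipeline, not its
robustness to raw-data artefacts.

### Calibration and recovery

The type-I error of the GOF test is checked by genotype-level forward
simulation: 10,000 populations of n = 392 under the best-fitting four-locus
model, tested with the true exact fraction at α = 0.05; the empirical
rejection rate must be 0.05 ± 0.01. (Exact binomial enumeration puts the
true rate at 0.054 for this model — the small excess over the nominal level
is binomial discreteness, not a defect.) Generator unbiasedness is checked
per model via 95%-interval coverage of simulated high counts, and by
3-standard-error law-of-large-numbers checks at n = 10⁵.

`recovery_experiment` runs the full loop — simulate, build a simulated
parental reference, classify high/low, rank models. Because the high-class
lognormal (CV 0.3) overlaps the reference CI cut, a noticeable share of
true-high plants classify low; the observed high fraction is therefore
biased slightly below the true f and the full-pipeline rejection rate of
the true model exceeds the nominal α at large n. This is a real property
of CI-threshold classification under measurement spread, reported honestly
by the experiment rather than calibrated away; the genetics-stage
calibration above bypasses classification by construction.

## Problem sizes

The default test suite simulates at n = 392–5,000 plants with up to 10,000
replicate populations for calibration and 1,000 for coverage, chosen to
keep the whole suite around a few seconds while leaving Monte Carlo noise
at least three standard errors inside every asserted band. Law-of-large-
numbers checks use n = 10⁵ draws.

## Known limitations

- The AND-combination of locus requirements cannot express heterozygote
  advantage, incomplete penetrance or additive thresholds.
- `printed_ratio` reproduces published tables but is a rounding artefact;
  use `exact` for anything downstream of simulation.
- The classification rule's misclassification rate depends on the unknown
  true within-class CV; with four parental replicates the reference CI is
  itself noisy.
- The per-mm² density convention (two-sided count over one disc area) and
  the π-free cavity volume are field conventions, not physical necessities;
  both are documented and the alternatives exposed.
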