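# trichoterp

Analysis toolkit for interspecific tomato F2 studies of glandular-trichome
terpene production. Wild tomato (*Solanum habrochaites*) type-VI trichomes
accumulate high levels of the sesquiterpene 7-epizingiberene; in an F2
population from a cross with cultivated tomato, the "high terpene" phenotype
reappears in only a few percent of plants, pointing at several unlinked loci.
`trichoterp` implements the quantitative stages of such a study as a tested,
reusable pipeline:

- **genetics** — enumerate multi-locus Mendelian models (each locus recessive
  or dominant), compute expected F2 segregation, and rank models against
  observed high/low counts with the Pearson χ² goodness-of-fit test;
- **quantification** — turn integrated GC-MS peak tables into normalized
  terpene quantities (ng per mg fresh weight or ng per gland), classify
  plants against a parental reference, bin levels for histograms, and compute
  fold-change / percent-reduction summaries;
- **phenotype** — trichome densities from leaf-disc counts, density classes,
  prolate-spheroid storage-cavity volumes in picolitres, and the
  density-vs-terpene OLS correlation;
- **synthetic** — a forward simulator of selfed-F1 (F2) populations with the
  statistical structure the analysis assumes, so every stage is testable
  end-to-end without raw data;
- **cli** — a `trichoterp` command tying the stages into a reproducible
  pipeline with JSON configs and deterministic reports.

## The model

For a gene model $M$ with loci $\ell = 1..L$, each either recessive or
dominant, the expected F2 fraction of high plants under independent
assortment from a fully heterozygous F1 is

$$f_M \;=\; \prod_{\ell=1}^{L} p_\ell, \qquad
p_\ell = \tfrac14 \text{ (recessive)},\quad p_\ell = \tfrac34 \text{ (dominant)},$$

displayed as a segregation ratio $1{:}k$ with $k = \mathrm{round}\!\big((1-f_M)/f_M\big)$.
Observed counts $(n_\mathrm{high}, n_\mathrm{low})$, $n = n_\mathrm{high}+n_\mathrm{low}$,
are tested against each model with the two-cell Pearson statistic

$$\chi^2 = \frac{(n_\mathrm{high}-nf)^2}{nf} + \frac{(n_\mathrm{low}-n(1-f))^2}{n(1-f)},
\qquad p = P(\chi^2_1 \ge \chi^2),$$

with no continuity correction and df = 1. The expected fraction $f$ can be
the exact product above (`basis="exact"`) or reconstructed from the rounded
printed ratio as $1/(k{+}1)$ (`basis="printed_ratio"`, the default, which
matches published segregation tables). Models are ranked by descending $p$.

## Worked example

Rank the six candidate gene models against an observed segregation of 12
high vs 380 low F2 plants:

```python
from trichoterp import SegregationModelSelection

res = SegregationModelSelection(n_high=12, n_low=380).fit(basis="printed_ratio")
print(res.summary())
```

```
Segregation model selection (Pearson GOF, df=1, basis=printed_ratio)
observed high:low = 12:380 (1:32), n = 392

model           segregation      chi2  p-value
a - b - C - D   1:27             0.30  0.59
a - b - C       1:20             2.50  0.11
a - b - c       1:63             5.72  < 0.05
a - b           1:15             6.80  < 0.01
a - b - c - D   1:84            11.98  < 0.01
a - b - c - d   1:255           71.85  < 0.01
```

Lower-case loci are recessive, upper-case dominant. The two-recessive +
two-dominant model (`a - b - C - D`, expected segregation 1:27) is the only
model not rejected at α = 0.05 together with `a - b - C`: the observed 1:32
segregation is consistent with roughly four unlinked loci being required for
the high phenotype. A two-locus recessive model (1:15, χ² = 6.80) and the
four-recessive model (1:255, χ² = 71.85) are clearly rejected.

Derived reporting metrics use the same conventions throughout:

```python
from trichoterp import fold_change, percent_reduction
from trichoterp.quantification import format_fold, round_half_away

round_half_away(percent_reduction(12.3, 0.21))   # 98  (% reduction, ng/gland)
format_fold(fold_change(17.7, 0.51))             # '~35' (parent vs cultivar glands)
```

The same analysis from the shell, end-to-end on synthetic data:

```
trichoterp simulate --seed 1 --out out/          # F2 population + measurement CSVs
trichoterp run --seed 1 --out out/               # quantify → classify → segregate → phenotype
trichoterp segregate --obs observations.csv      # tabular model ranking
```

See `docs/methods.md` for the statistical details, the simulator's
assumptions and known limitations.

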