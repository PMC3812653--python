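# metabeq

Statistical equivalence assessment of a crop line against the **natural
variation of the seed metabolome** across a germplasm pool.

Regulatory evaluation of a new (e.g. genetically modified) crop line asks
whether its composition deviates from what conventional breeding already
produces. `metabeq` operationalises that question for untargeted metabolomics
panels — tens of lines, a handful of seed replicates each, a few hundred
metabolites of integrated peak ion counts: it profiles the dynamic range of
every metabolite across the conventional pool, tests whether a candidate
line's per-metabolite means fall inside prediction intervals for a new line
drawn from that pool, and projects the candidate onto a PCA of the pool with
a prediction interval on component scores.

## The model

For metabolite *j*, seed *s* of line *i* is modelled with one-way random
effects on the (median-scaled) intensity scale:

```
y_is = mu + L_i + e_is,      L_i ~ N(0, sigma^2_line),   e_is ~ N(0, sigma^2_error)
```

with **line as the experimental unit**. Variance components come from the
method of moments (one-way ANOVA mean squares). With k baseline lines of m
seeds each, the mean of a new line of m seeds is predicted by

```
center ± t(1 - alpha/2, k-1) · sqrt( s²_lm · (1 + 1/k) )
```

where `center` is the grand mean of the k line means and `s²_lm` their
sample variance — equal, by the method-of-moments identity, to
`sigma²_line + sigma²_error / m`. Inverting the interval gives a two-sided
p-value per metabolite (p > alpha exactly when the candidate mean is inside
the 1 − alpha interval); the panel-wide screen is corrected with
Storey–Tibshirani q-values. The multivariate view standardises log2 line
means per metabolite, fits a PCA to the baseline pool by SVD, projects
held-out lines, and asks whether their scores fall inside a t prediction
interval whose scale is calibrated on leave-one-out held-out scores (see
`docs/methods.md` for why in-sample scores would over-cover when metabolites
far outnumber lines).

Before any testing: missing cells (below-detection) are imputed with the
metabolite's minimum detected value, each metabolite is scaled to median 1.0
over its detected values, and metabolites with a high null fraction are
flagged as unreliable rather than corrected.

A synthetic-panel generator (`metabeq.simulate`) realises exactly this model
on the log2 scale — 49 lines × 8 seeds × 169 metabolites by default, with
between-line SDs spanning tightly regulated to >100-fold-variable compounds,
per-metabolite detection-limit censoring, and optional targeted spikes — and
returns the generating truth, so calibration, coverage, power and parameter
recovery are all testable end to end.

## Worked example

Simulate a panel, then screen line `L49` against the other conventional
lines with `L48` treated as its parent:

```sh
$ metabeq simulate --seed 3 --out simdir
wrote 392 samples x 169 metabolites to simdir

$ metabeq test simdir/intensity.csv --test-line L49 --parent-line L48 \
      --annotations simdir/annotations.csv --out testdir
169 metabolites screened; outside the 95% interval: ['M024', 'M036', 'M039',
'M048', 'M058', 'M067', 'M083', 'M099', 'M106', 'M126']
q < 0.1: ['M036', 'M067', 'M083']

$ metabeq pca simdir/intensity.csv --test-line L49 --parent-line L48 --out pcadir
PC1 (4.9% var): L49 score 0.38, PI (-2.53, 2.53) -> inside
PC1 (4.9% var): L48 score -0.74, PI (-2.53, 2.53) -> inside

$ metabeq profile simdir/intensity.csv --annotations simdir/annotations.csv --out profdir
169 metabolites; 66.3% vary less than 10-fold
```

Reading the output: `L49` is an unmodified draw from the pool here, so the
~10 of 169 metabolites outside the 95% interval are what the nominal 5%
error rate predicts, and its PC1 score sits well inside the score interval.
The per-metabolite detail (interval bounds, p, q, missingness flags), the
p-value histogram, the dynamic-range profile by pathway class, detection
frequencies and box-plot summaries are written as TSV tables in the output
directories. The same analyses are available as library calls
(`test_all_metabolites`, `assess_multivariate`, `dynamic_range`, ...) on a
`RunConfig` + `IntensityMatrix`.

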