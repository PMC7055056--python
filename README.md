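# microcensus

Tools for stress-testing global microbial richness arguments from
sample-by-taxon count tables:

1. **Estimator-bias simulation** (`landscape_sim`, `estimators`) — place
   N individuals of S species on a gridded 2-D landscape under four
   scenarios (even/uneven abundances × uniform/aggregated space), census
   increasing numbers of sites, and track incidence-based nonparametric
   richness estimators (bias-corrected Chao2, ICE) against the true pool
   richness. Under even+uniform conditions the estimators converge on the
   truth; with uneven, aggregated communities they underestimate it even at
   full census.
2. **Diversity–abundance relationships** (`metrics`, `dar_scaling`) —
   per-sample SAD summaries (N, S, N_max, Simpson evenness, log-skewness
   rarity) and power-law fits of each summary against N via bootstrapped,
   stratified log10–log10 OLS regressions with percentile CIs and 95%
   prediction intervals, plus an N_max predictor from the dominance fit.
3. **Two-input lognormal richness model** (`lognormal_model`) — solve a
   lognormal species curve anchored on (N, N_max, N_min) for total
   richness, at the same scale as its inputs; closed-form error-function
   integrals, bracketed root solve, a seeded/quantile SAD sampler, and a
   report combining the empirical-N_max and dominance-DAR pathways.

`corpus_io` reads/writes wide and long delimited count tables (plus a
minimal BIOM 1.0 JSON reader), converts counts to incidence, tallies
incidence classes, and pools a corpus into one ranked SAD.
`synthetic_corpus` generates ground-truthed corpora (log-uniform N spanning
decades, known richness/dominance exponents, lognormal SADs, shared taxon
pool) so the whole chain is testable offline.

## Command line

```sh
microcensus synth-corpus --n-samples 1000 --seed 1 --out-prefix out/corpus
microcensus summarize --table out/corpus.counts.tsv --out out/summaries.tsv
microcensus fit-dar --summaries out/summaries.tsv --response richness \
    --n-boot 10000 --n-per-boot 500 --out out/fit_richness.tsv
microcensus predict-lognormal --n 1e9 --nmax 1e6
microcensus estimate --table out/corpus.counts.tsv
microcensus simulate-landscape --scenario d --n-individuals 1e7 \
    --pool-richness 1e5 --replicates 3 --out out/accumulation_d.tsv
microcensus run-fig1 --out-dir out/fig1          # all four scenarios
microcensus run-census --table out/corpus.counts.tsv --out-dir out/census
```

All outputs are UTF-8 TSV with a commented header block embedding the
parameters, a config hash and the seeds, so identical invocations are
byte-stable.

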