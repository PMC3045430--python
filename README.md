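# mrnaturnover

Inference of mRNA decay-rate kinetics from genome-wide transcription-rate
(TR) and mRNA-amount (RA) time courses measured after an environmental
shift — the situation created by a genomic run-on (GRO) experiment during
a yeast heat shock, where neither TR nor RA is at steady state.

The mRNA pool of every gene obeys the first-order balance

```
dRA/dt = TR(t) − k_D · RA(t),        t½ = ln 2 / k_D
```

At the pre-shift sample the culture is in steady state, so
`k_D(0) = TR(0)/RA(0)`. After the shift, assuming TR varies linearly
between consecutive sampling times and `k_D` is constant within each
interval, the balance has a closed-form solution for `RA(t₂)` given
`RA(t₁)`; because that prediction is strictly decreasing in `k_D`, the
interval-mean decay constant is recovered uniquely by bisection and
assigned to the interval midpoint. Running the same forward solution with
the time-0 `k_D` frozen yields the *theoretical* RA trajectory implied by
transcription alone; a gene whose measured RA runs above it has been
stabilized, below it destabilized. The package bundles everything around
that computation:

- **kinetics_core** — steady-state `k_D`, interval inversion, theoretical
  RA, Arrhenius temperature correction of TR (elongation roughly doubles
  for a 25→37 °C shift), stability classification.
- **profile_clustering** — ten-point log₂ relative TR‖RA profiles and a
  self-organizing tree (SOTA) clustering with per-cluster mean relative
  `k_D` and RA curves.
- **set_enrichment** — binomial and hypergeometric over-representation of
  TF/RBP target sets in clusters, with a Monte-Carlo family-wise adjusted
  p-value.
- **decay_fitting** — half-life estimation from promoter-shutoff
  (Northern-style) decay series: background subtraction, loading-control
  normalization, log-linear fit over the initial linear window, and
  Kruskal-Wallis comparison across conditions (exact permutation p for
  small samples).
- **synthetic_data** — a generator of GRO-like datasets with known
  ground truth (16 gene-class archetypes, steady-state initial
  conditions, multiplicative lognormal noise, triplicates), so every
  stage is testable without downloads.
- **io_formats / pipeline / cli** — TSV/GMT/JSON I/O and a `mrnaturnover`
  command-line front end.

## Worked example

Simulate a 400-gene dataset (16 archetypes × 25 genes, triplicate, 15%
observation noise) and run the full analysis. The simulator emits true
synthesis rates, so the run-on temperature correction is switched off:

```
mrnaturnover simulate --seed 1 --n-genes 25 --noise-cv 0.15 --out-dir sim
mrnaturnover run --seed 1 --no-tr-correction --out-dir out \
    --tr sim/tr_rep1.tsv --ra sim/ra_rep1.tsv \
    --tr sim/tr_rep2.tsv --ra sim/ra_rep2.tsv \
    --tr sim/tr_rep3.tsv --ra sim/ra_rep3.tsv
```

which prints

```
wrote 400 genes x 3 replicates to sim
400/400 genes inverted; stabilized 30.8%, destabilized 54.2%, unchanged 15.0%
```

The generative design is 31.25% stabilized / 56.25% destabilized /
12.5% unchanged classes, so at this noise level the per-gene calls land
within a few percent of the truth. `out/` then contains
`decay_profiles.tsv` (per-gene, per-interval `k_D` at the interval
midpoints, absolute and relative to `k_D(0)`, with solver flags),
`stability_calls.tsv`, cluster assignments, per-cluster mean `k_D`/RA
curves, a Newick cluster dendrogram, and `run_summary.json` with the
stability and homodirectional/antagonistic tallies (a gene is
homodirectional when its TR change and its stability change push RA the
same way).

The library surface mirrors the CLI; e.g.

```python
from mrnaturnover import solve_kd_interval
solve_kd_interval(ra1=10.0, ra2=10.0, tr1=1.0, tr2=1.0, dt=7.0).kd  # 0.1
```

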