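# elevbeta

**Elevational beta-diversity analysis of assemblage count data.**

`elevbeta` is for community ecologists who sample species assemblages (moths,
ants, beetles, plants…) in replicate plots along elevational transects and
want to quantify *how sensitive the assemblage is to elevation*.  The package
implements a complete, reproducible analysis protocol for plot × species
abundance matrices:

1. **Abundance-standardized richness** — exact individual-based (Hurlbert)
   rarefaction: `E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)]`, evaluated in
   log-space, one expected richness per plot at a common depth `n`.
2. **Common-species filtering** — the detection model
   `P = 1 − (1 − 1/n)^N` gives the smallest total abundance `N` at which a
   species is detected with probability ≥ P in one of `n` equally likely
   plots (for `n = 5`, `P = 0.95` the threshold is **14** individuals).
3. **Four similarity indices** — Sørensen (presence/absence, common
   species), Bray–Curtis (proportional abundances of common species),
   Chao–Sørensen estimated (all species, corrects for unseen shared
   species), and Raup–Crick (probabilistic, insensitive to richness
   differences; closed-form hypergeometric null).
4. **PERMANOVA** — one-way pseudo-F on `d = 1 − s` with unrestricted
   label permutations (exact enumeration for small designs) plus pairwise
   post hoc `t = √F` comparisons.
5. **Distance decay** — OLS of pairwise similarity on pairwise Δelevation;
   the slope is the headline sensitivity statistic.
6. **Indicator species** — Dufrêne–Legendre `IndVal = A·B·100` over every
   contiguous band range short of the whole gradient (nine candidate
   groupings for four bands), permutation significance, and a
   **null-model standardized effect size** of the significant-indicator
   count: `ES = (observed − mean(null)) / sd(null)` over re-analysed
   shuffled datasets, which makes indicator counts comparable across
   transects of very different richness.

A synthetic-assemblage generator (Gaussian elevational niches, log-normal
abundances, negative-binomial detection) reproduces the statistical
structure of hyper-diverse transect surveys so the entire pipeline is
testable without field data, including parameter-recovery experiments.

## Worked example

Two synthetic transects — T1 with narrow (120 m) elevational niches, T2 with
broad (300 m) niches — analysed end to end:

```python
from elevbeta import PipelineConfig, run_all

cfg = PipelineConfig(
    synthetic=[{"n_species": 800, "niche_width_sigma": 120.0},
               {"n_species": 800, "niche_width_sigma": 300.0}],
    n_standard=200, permutations=999, indicator_permutations=199,
    null_reps=49, inner_permutations=99, seed=7, out_dir="demo_out")
summary = run_all(cfg)
```

which prints (via the summary dict):

```
T1 | common: 83  | PERMANOVA F=30.36 p=0.001 | slope=-0.00126 R2=0.92 | indicators: 70 | ES=21.24
T2 | common: 134 | PERMANOVA F=2.07  p=0.001 | slope=-0.00016 R2=0.35 | indicators: 23 | ES=6.48
rank by slope: ['T1', 'T2']
rank by ES:    ['T1', 'T2']
```

Read: both transects are significantly stratified by elevation (PERMANOVA
p = 0.001, the permutation floor at 999 permutations), but the
narrow-niche transect T1 loses Sørensen similarity ~8× faster per metre of
elevation (slope −0.00126 vs −0.00016), hosts far more significantly
elevation-restricted species (70 vs 23 of the common species), and its
indicator count stands 21 null standard deviations above chance (ES 21.2 vs
6.5).  Both sensitivity measures rank the transects identically — the
protocol's core cross-check.  Every stage also writes CSV/JSON artefacts
under `out_dir`.

The same pipeline runs from the shell:

```bash
elevbeta simulate --sigma 120 --transect T1 --seed 7 --out-dir data/
elevbeta richness data/T1_community.csv --n-standard 364
elevbeta permanova data/T1_community.csv data/T1_metadata.csv --index sorensen
elevbeta effectsize data/T1_community.csv data/T1_metadata.csv --null-reps 99
elevbeta run-all --seed 7 --out-dir full_run/
```

## Layout

```
src/elevbeta/
  community.py    plot × species matrices, metadata, CSV I/O, stratum pooling
  synthetic.py    Gaussian-niche assemblage generator with stored ground truth
  richness.py     Hurlbert rarefaction, common-species threshold and filter
  similarity.py   Sørensen, Bray–Curtis, Chao–Sørensen, Raup–Crick
  inference.py    PERMANOVA (+ pairwise), distance-decay regression
  indicators.py   IndVal over band ranges, permutation p, null-model effect size
  pipeline.py     run_all orchestration, seeded and fully serializable
  cli.py          `elevbeta` command-line interface
  plotting.py     decay scatter, effect-size box plot, NMDS hook
```

See `docs/methods.md` for the statistical methods, model assumptions and
parameter choices.
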