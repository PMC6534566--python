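# fct — behavioral variance explained by static vs dynamic functional connectivity

`fct` implements a complete analysis chain for a question in resting-state
neuroimaging: **how much inter-subject behavioral variability is explained
by static functional connectivity (FC) versus its fast temporal dynamics?**
Static FC is the Pearson correlation matrix of parcellated fMRI time
series; dynamic FC is the coefficient matrix `A` of a first-order
autoregressive model

    x_t = A x_{t-1} + eps_t,       R^2 = 1 - ||Cov(eps)||_F / ||Cov(x)||_F

fit to the concatenated uncensored sections of each subject's runs.
Each FC type yields a subjects-by-subjects similarity kernel `F`
(correlation between subjects' vectorized FC patterns), which enters a
multivariate variance-component model for the subjects-by-measures
behavioral matrix `Y`:

    Y = C + E,   Vec(C) ~ N(0, Sigma_c ⊗ F),   Vec(E) ~ N(0, Sigma_e ⊗ I)

    M = Tr(Sigma_c) / (Tr(Sigma_c) + Tr(Sigma_e)),
    M_i = Sigma_c(i,i) / (Sigma_c(i,i) + Sigma_e(i,i))

`M` is the fraction of behavioral variance explained; a multi-kernel
variant fits several kernels jointly. Differences in `M` between model
variants are tested with the delete-1 jackknife

    M_jack = (1/N) Σ_i M_{-i},    V_jack = ((N-1)/N) Σ_i (M_{-i} - M_jack)^2

with a standard-normal reference for `z = M_jack / sqrt(V_jack)`, and
per-measure `T` statistics rank which measures dynamics explain better.
Multiple testing is controlled with Benjamini–Hochberg FDR.

Because the motivating cohort data are access-restricted, the package
ships a **synthetic-cohort generator with known ground truth**: stable
subject-specific AR dynamics sharing low-dimensional connectivity modes,
motion traces calibrated to realistic censoring fractions under the
standard scrubbing rules (FD > 0.2 mm or DVARS > 75, one frame before /
two after, segments < 5 frames removed, runs > 50% censored discarded),
and behavior drawn *exactly* from the matrix-normal model conditional on
the cohort's own empirical kernels — so the true `M` is known by
construction and every stage of the chain can be validated.

## Who this is for

Researchers studying brain–behavior association at the cohort level
(connectome predictive modeling, morphometricity/heritability-style
variance decomposition) who want a tested, self-contained implementation
of the AR-1 dynamic-FC + variance-component + jackknife chain, with a
generator for method validation.

## Layout

- `src/fct/` — the library: `synthdata` (cohort generator),
  `timeseries` (censoring, nuisance regression, static/dynamic FC),
  `behavior` (residualization + inverse-normal transform),
  `similarity` (kernels and the additive block decomposition),
  `vcm` (variance-component moment estimator), `inference`
  (jackknife, ranking, FDR), `pipeline` (orchestration), `io`, `cli`.
- `analysis/01..06_*.py` — numbered drivers running the study end to
  end, writing tables under `results/` (large intermediates go to
  `scratch/`).
- `fct` console command — the same stages as a CLI
  (`fct simulate/fc/kernels/fit/infer/run`).

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_estimate_fc.py
python analysis/03_build_kernels.py
python analysis/04_fit_variance_components.py
python analysis/05_jackknife_inference.py
python analysis/06_block_analysis.py
```

prints (abridged):

```
true M = 0.417; mean AR R^2 = 0.654
120 subjects; AR R^2 = 0.654 +- 0.076
overall variance explained: {'static': 0.248, 'dynamic': 0.366, 'combined': 0.443, 'true': 0.417}
dynamic - static: +0.116 (z=7.87, p=3.66e-15)
mean T task 1.86 | self 0.88 | interaction p=0.088
block-restricted M: max static 0.145, max dynamic 0.351
```

Reading: the AR model captures ~65% of the frame-to-frame variance
(`R^2`). Dynamic FC explains more behavioral variance than static FC
overall (0.37 vs 0.25, jackknife z = 7.9), the gap concentrates on
task-performance measures (mean T 1.86 vs 0.88 for self-reported ones),
and FC restricted to single network pairs explains less than the
whole-brain pattern — the qualitative signature the cohort was designed
to carry (its ground-truth loadings put task measures on the dynamic
kernel and self-reported measures equally on both).

The same chain runs in one call:

```bash
fct run --seed 1 --out out/
```

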