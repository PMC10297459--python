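# clockhsc

Regulome inference and circadian/cohort analyses for hepatic stellate
cells (HSCs).

HSCs are the liver's fibrogenic cells: quiescent, vitamin-A-storing cells
(qHSCs) that transdifferentiate into matrix-depositing myofibroblasts
(aHSCs) during fibrosis. The circadian transcription factor CLOCK (with
BMAL1) binds E-box motifs (CACGTG), and its dominant-negative mutant
CLOCKΔ19 binds but cannot transactivate — so genes de-repressed in the
mutant are candidates for direct repression by WT CLOCK, and vice versa.
`clockhsc` turns that reasoning into a tested pipeline:

- **regulome** — the core inference. A gene *g* is called a CLOCK target
  when (i) an ATAC peak with concentration ratio c_q/c_a > 2 (or the
  inverse) lies nearest to its TSS, (ii) that peak carries a CACGTG
  PWM match (log2-odds score ≥ 80% of the maximum), and (iii) *g* is
  >1.5-fold up (→ *repressed* by CLOCK) or down (→ *activated* by CLOCK)
  in mutant vs WT cells of the matching state.
- **expression** — pairwise contrasts (log2FC, t-test p, BH FDR), a 3×3
  direction-pattern clustering of (mutant-vs-WT) × (activation response),
  and primed-gene selection (>1.5-fold, p < 0.1).
- **motif** — double-strand PWM scanning and Fisher-exact motif
  enrichment of foreground vs background peak sets.
- **enrichment** — exact hypergeometric over-representation analysis of
  any gene list against a GMT collection.
- **rhythm** — 24 h moving-average detrending and damped-cosine fitting
  A·e^(−λt)·cos(2πt/T + φ) of PER2::LUC-style bioluminescence traces.
- **cohort** — FIB-4 scoring ((age × AST)/(platelets × √ALT)), LSM/FIB-4
  stratification, and Kruskal–Wallis + Dunn comparison of a serum
  biomarker across severity groups.
- **simulate** — synthetic inputs for every stage with planted ground
  truth (motif-bearing differential peaks, expression effects, damped
  cosines, shifted cohorts), so the whole pipeline is testable offline.

See `docs/methods.md` for models, parameter defaults and numerical
choices.

## Worked example

```python
from clockhsc import SimulationConfig, simulate_all, estimate_rhythm, compare_groups
from clockhsc.pipeline import run_regulome

res = simulate_all(SimulationConfig(seed=1))          # planted ground truth
calls = run_regulome(res.genes, res.peaks, res.sequences, res.expression)
print(calls["mode"].value_counts().to_string())
```

```
repressed    28
activated    25
```

At the default noise level (per-replicate SD 0.2 against a planted
log2 1.8 effect) 53 of the 60 planted genes survive the strict 1.5-fold
expression filter for this seed; none of the engineered decoys (no
motif / no accessibility fold / no expression change) is called. Each
call carries its evidence:

```
gene_id      mode peak_id   peak_state  expression_fold    log2fc  distance_bp
  g0005 activated   p0001 open-in-qHSC         0.634545 -0.656205            0
  g0010 repressed   p0002 open-in-qHSC         1.810899  0.856706            0
```

`g0010` sits nearest a qHSC-open, E-box-bearing peak and is 1.81-fold up
in the mutant, so it is modelled as repressed by WT CLOCK.

```python
est = estimate_rhythm(res.trace["time_h"], res.trace["value"])
print(f"period {est.period_h:.2f} h, damping {est.damping_rate:.4f}/h, "
      f"r2 {est.r_squared:.3f}, rhythmic {est.rhythmic}")
```

```
period 23.47 h, damping 0.0100/h, r2 0.928, rhythmic True
```

The fitted period recovers the generator's 23.5 h circadian rhythm and
the damping rate its population-desynchronisation constant.

```python
cmp_ = compare_groups(res.cohort["biomarker"], res.cohort["severity"])
print(f"H = {cmp_.h_statistic:.2f}, p = {cmp_.p:.3g}")
```

```
H = 99.79, p = 2.15e-22
```

Dunn post-hoc tests separate the cirrhotic group from both others
(adjusted p < 1e−15) while non-fibrotic vs fibrotic is not significant —
the early-marker pattern the biomarker analysis looks for.

## Command line

Every stage is also a `clockhsc` subcommand:

```sh
clockhsc simulate --outdir data --seed 1
clockhsc regulome --genes data/genes.tsv --peaks data/peaks.tsv \
    --fasta data/peaks.fasta --expression data/expression.csv --out regulome.tsv
clockhsc rhythm --trace data/trace.csv
clockhsc cohort --cohort data/cohort.csv --by lsm
```

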