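# persistsig

Analysis toolkit for **treatment-persistent tumor-cell signatures**: score
gene signatures in bulk samples, single cells, and spatial transcriptomics
spots; calibrate "high-score" calls against housekeeping-gene nulls;
classify cell clusters across treatment conditions; profile read
distributions around genomic sites; run enrichment statistics; and
stratify patient survival by signature score.

The motivating setting is drug resistance in prostate cancer: a small
subpopulation of cells persists through androgen-receptor-targeted
treatment, and its transcriptional signature — scored in bulk RNA-seq of
patient tumors — stratifies survival.  `persistsig` provides every
computational step of that workflow as a tested, reusable library with a
thin CLI, together with synthetic-data generators (negative-binomial count
matrices, spatial spot grids, read pileups, survival cohorts — each with
planted, recoverable ground truth) so the whole pipeline can be validated
without any external data.

## The core statistic

For sample *j* and gene set *k*, expression values are passed through a
per-gene kernel CDF transform (Poisson kernels for counts after
75th-percentile scale normalization, Gaussian kernels for log-normalized
data), ranked within each sample, and centered so ranks sum to zero.
Walking through the genes from most to least expressed, an in-set gene
advances the in-set running sum S₁ by its |r|^τ share and an out-of-set
gene advances S₂ by 1/(p−m).  With

&nbsp;&nbsp;ES⁺ⱼₖ = max(0, max (S₁−S₂)),&nbsp;&nbsp;ES⁻ⱼₖ = min(0, min (S₁−S₂)),

the enrichment score is **|ES⁺ⱼₖ| − |ES⁻ⱼₖ|** ∈ [−1, 1]: positive when the
set is concordantly up, negative when concordantly down, near zero when
its genes pull in both directions.

Per-cell/per-spot scoring uses control-subtracted module scores (mean
signature expression minus mean of expression-bin-matched control genes),
with high calls at the 90th percentile and a housekeeping-null
calibration that accepts the threshold only if length-matched random
stable-gene sets exceed it at most 5% of the time.  Survival
stratification uses a median score split (or a two-branch hierarchical
clustering cut), Kaplan–Meier curves, and a two-group log-rank test.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a 300-gene × 40-sample count matrix in which a 50-gene signature
is doubled (log2 effect 1) in 10% of samples, then score the planted
signature in every sample:

```bash
persistsig simulate --kind expression --seed 11 --n-genes 300 --n-units 40 \
    --log2-effect 1.0 --out-prefix demo
persistsig gsva --expr demo.expr.tsv --gmt demo.planted.gmt \
    --kernel poisson --out scores.tsv
```

The score matrix has one row per signature and one column per sample.
For this run the first few samples score

```
u00000   -0.031
u00001    0.084
u00002   -0.000
u00003    0.082
u00004    0.547
```

and sample `u00004` is one of the planted samples: planted samples
average **0.449** while background samples average **−0.074**, so the
planted up-regulation is cleanly separated on the −1…1 score scale.

The end-to-end pipeline (simulate → score → median split → log-rank on a
cohort whose hazard follows the planted group) runs from one YAML config:

```bash
persistsig pipeline --config cfg.yaml --out pipeline.json
```

with `cfg.yaml` setting 60 samples, a half-and-half planted split, and a
hazard ratio of 2.5.  Output for seed 7:

```json
{
  "group_agreement": 1.0,
  "logrank_statistic": 12.635161571615646,
  "logrank_p": 0.0003785584915448346
}
```

The median split of the enrichment scores recovered the planted group
perfectly (agreement 1.0), and the log-rank test detects the planted
2.5-fold hazard difference at p ≈ 4 × 10⁻⁴.

Other subcommands: `score` (per-cell/per-spot module scores and 90th
percentile high flags), `calibrate` (housekeeping-null threshold report),
`taxonomy` (initial / induced / persistent cluster calls), `profile`
(flank-normalized read distributions), `enrich` / `degfilter` /
`attribute` (hypergeometric enrichment, differential filters, TF-target
attribution), and `stratify` (KM + log-rank from a score matrix and
clinical table).

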