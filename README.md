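# histoadi

Quantify the tissue composition of H&E-stained colorectal whole-slide
images and test whether the **adipose fraction (ADI score)** of a
patient's slide predicts overall survival.

The package is aimed at computational-pathology and cancer-genomics
analysts. It implements the full analysis chain:

1. **Tiling** — a slide is resampled to 0.5 microns per pixel and cut
   into non-overlapping 224 × 224 px tiles; a tile is discarded as
   background when its global-average-pooled gray value (mean of the
   three pooled RGB channel means) exceeds 200.
2. **Classification** — every kept tile is assigned one of nine
   canonical tissue classes (ADI, BACK, DEB, LYM, MUC, MUS, NORM, STR,
   TUM) as the argmax of a model's probability vector. A desk-scale
   reference classifier (multinomial logistic regression on image
   features) ships with the package; externally trained CNNs plug into
   the same interface.
3. **Scoring** — per-patient tile counts give tissue proportions and
   the ADI score

   ```
   ADI = n_ADI / N_classified
   ```

   so a patient with 1,000 classified tiles, 200 labeled adipose, has
   ADI = 0.2.
4. **Survival** — patients are split into high- and low-ADI groups by a
   maximally selected log-rank cutpoint (survminer-style `surv_cutpoint`)
   or by the median; groups are compared with Kaplan–Meier curves, the
   log-rank test and a univariate Cox model (Newton–Raphson on the
   partial likelihood, Efron ties, Wald CIs) — all implemented from
   first principles and cross-checked against independent oracles.
5. **Enrichment** — ssGSEA (weighted rank-ECDF difference, α = 0.25)
   scores pathway activity per sample; preranked GSEA with permutation
   p-values and Benjamini–Hochberg correction compares high- vs low-ADI
   groups.

A `synthetic` subpackage generates textured tiles, mosaic slides,
survival cohorts and expression matrices with **known ground truth**
(label grids, true adipose fractions, true hazard ratios, planted
gene-set shifts), so the whole pipeline is testable end to end without
clinical data.

## Worked example

Simulate a 40-patient study (one 8 × 8-tile slide per patient, hazard
doubled above the true ADI cutpoint, one gene set shifted +2 in the
high-ADI group) and run every stage:

```sh
histoadi simulate --out demo --n-patients 40 --grid 8 --seed 1
histoadi run-all --config demo/config.yaml     # paths as written by simulate
```

On this synthetic study the pipeline prints, in about half a minute on
one CPU:

```
pipeline finished in 34.1s
```

and `demo/out/survival_summary.json` contains

```json
{
 "method": "cutpoint", "threshold": 0.352,
 "n_high": 18, "n_low": 22,
 "logrank_p": 5.9e-05,
 "hr": 4.53, "hr_ci_low": 2.05, "hr_ci_high": 10.0
}
```

— the high-ADI group has significantly shorter overall survival. The
hazard ratio (4.53) overshoots the simulated truth (2.0): selecting the
cutpoint that maximizes the log-rank statistic optimistically biases the
effect estimate at small n, which is exactly why the synthetic ground
truth is generated alongside the data. `demo/out/group_comparison.tsv`
flags the planted gene set (and only it) as significant:

```
feature  difference  p            q            stars
SET_0    138.5       3.4e-11      1.7e-10      ***
SET_1    -2.7        0.71         0.71         ns
```

Per-stage subcommands (`tile`, `train-model`, `classify`, `score`,
`survive`, `enrich`) expose the same operations on individual files; the
library API in `histoadi.*` is documented in the module docstrings and
`docs/methods.md`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's reportable reference quantity — the ADI score
of the documented worked example (1,000 classified tiles, 200 adipose)
— by building the prediction stream, running the composition and
scoring operations, and writing the resulting value with the problem
size as JSON.
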