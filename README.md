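# scpi — Self-Care Preparedness Index toolkit

Chronic-disease care in general practice leans heavily on patients' own
self-care, and clinicians need a quick way to spot who will struggle with it.
The Self-Care Preparedness Index (SCPI) is a six-checkbox screening score:
three options describe good self-care (knowledge, wanting to treat oneself,
monitoring/following a care plan) and three describe deficits (needing more
information, insufficient inner resources, measurements off-target without
knowing how to improve). Each endorsed option contributes a fixed integer
weight,

```
SCPI = 2·x1a + 1·x1b + 2·x1c − 1·x2a − 2·x2b − 2·x2c ,   x ∈ {0,1}
```

so the score runs from −5 to +5 and is classified as **low** (−5…0),
**moderate** (1…3) or **high** (4…5) preparedness.

This package implements, as a tested pipeline, everything needed to study
such an index when individual-level patient data cannot be shared:

* **`scpi.scoring`** — the scoring scheme, classification, and cohort-table
  scoring (with missing-answer and none-endorsed flagging).
* **`scpi.generator`** — a calibrated synthetic-cohort generator. The six
  items arise from a latent threshold (probit) model with three correlated
  factors (capability/activation, depleted inner resources, health
  literacy); probit thresholds are fitted by simulation so the score
  distribution matches published cohort summaries (level shares
  27.0/39.2/33.8 %, mean 2.22, SD 2.31), and outcomes (15D HRQoL, BDI, PAM,
  BMI, …) are linked through a Gaussian copula whose coefficients are
  bisected until the Spearman correlations with the score hit their targets
  (0.31, −0.27, 0.24 for the three headline outcomes).
* **`scpi.association`** — Cochran–Armitage trend tests for binary outcomes
  across the three levels, ANOVA linear contrasts for continuous ones,
  Spearman correlations with Fisher-z confidence intervals, and the Sidak
  multiplicity adjustment (p-values and widened per-comparison CI levels).
* **`scpi.efa`** — construct validity: pairwise tetrachoric correlations of
  the six binary items (two-step maximum likelihood with a deterministic
  bivariate-normal CDF), iterated principal-factor extraction, Kaiser/scree
  retention, promax rotation, communalities and variance explained, plus the
  report-style masking of loadings below 0.50.
* **`scpi.pipeline` / `scpi.cli`** — reproducible end-to-end runs with YAML
  configuration and provenance (seed, config hash) written next to every
  report.

## Worked example

```bash
scpi simulate --n 293 --seed 1 --out cohort.csv     # calibrates, then draws
scpi analyze --input cohort.csv --out report --seed 1
```

or the same through the API:

```python
from scpi import RunConfig, run_simulate, run_analyze, render_report
cfg = RunConfig(seed=1, n=293)
cohort, profile, cal = run_simulate(cfg, out_path="cohort.csv")
render_report(run_analyze(cohort, cfg), "report")
```

`report/report.txt` then begins (actual output):

```
SCPI analysis report
====================
seed=1  config=824f78a8fec1  version=0.1.0

cohort: n=293 (293 complete, 0 with no option endorsed)
SCPI mean (SD): 2.12 (2.39)
levels: low 89 (30.4%), moderate 107 (36.5%), high 97 (33.1%)

Outcomes by preparedness level (trend p-values)
------------------------------------------------
hrqol_15d                    0.84 (0.10)     0.88 (0.08)     0.89 (0.09)  p<0.001
bdi                          9.08 (6.14)     7.09 (6.23)     5.20 (4.35)  p<0.001
...
```

Reading it: a 293-person draw lands near the calibration targets (mean 2.12
vs 2.22; shares 30/37/33 % vs 27/39/34 % — sampling noise at this n), the
health-related quality of life (15D, 0–1 scale) rises monotonically across
preparedness levels while depressive symptoms (BDI) fall, both with
significant linear trends, and the correlation block shows e.g.
`hrqol_15d r=+0.26 [+0.15, +0.36]` — a Spearman correlation with its
Fisher-z 95 % interval. The EFA block retains 3 factors by the Kaiser rule
and prints the promax pattern matrix with loadings below 0.50 masked
(machine-readable CSVs keep full precision).

At n = 50 000 the same pipeline reproduces the calibration targets tightly;
at n = 293 expect the wobble the example shows — that is the point of
simulating at the study's size.

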