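# immunomark

Pathway-activation scoring, survival/response biomarker screening and
risk-score signature construction for immunotherapy cohorts.

The package implements an end-to-end analysis pipeline for tumor RNA-seq
profiles annotated with treatment response (RECIST-style categories) and
progression-free survival (PFS):

* **expression** — median-of-ratios size-factor normalization with a
  post-division pseudo-count, TPM, and per-gene case-vs-control statistics:
  CNR (sample over geometric mean of a control panel) and BTIF (significant
  deviation flag at level alpha).
* **pathways** — pathway collections with activator/repressor roles (ARR in
  {-1, -0.5, 0, 0.5, 1}), merging typed interactions into a connected
  interactome, algorithmic construction of gene-centric pathways around a
  center gene, and the pathway activation level
  `PAL = sum ARR * BTIF * ln(CNR)`.
* **screening** — per-biomarker response statistics (rank AUC, Mann-Whitney,
  Fisher) and survival statistics (Cox PH with Efron ties by Newton
  iteration; numeric markers dichotomized at the threshold maximizing
  |ln HR| with both groups holding >= 30% of samples), the selection filters
  (HR > 2.5 or < 0.4 with p < 0.05; response p < 0.05 with AUC > 0.62) and
  their intersection; Kaplan-Meier curves and log-rank tests.
* **features** — TMB per megabase (high when strictly > 10), per-gene
  mutation flags, HLA presence/homozygosity/superfamily features, the
  housekeeping-normalized GEP score and the TMB+GEP categorical marker.
* **signature** — min-max scaling with a stored scaler, ridge-stabilized
  logistic coefficients, the coefficient-weighted risk score, backward
  elimination driven by the thresholded score's |ln HR|, and evaluation
  (AUC / HR / KM) on arbitrary cohorts.
* **synthetic** — seed-reproducible cohort generator (expression + control
  panel + clinical + pathways + interactome + variants + HLA) with planted
  proportional-hazards and logistic response effects and a truth record for
  recovery experiments.
* **pipeline / cli** — seven-stage orchestration with a machine-readable
  manifest, plus the `immunomark` command line tool.

## Tests

```
python -m pytest -q tests/
```

The suite contains unit tests per module, property tests for the stated
invariants, and `tests/test_acceptance.py` with one test per acceptance
criterion (exact/oracle checks of the statistical engines and fixed-seed
Monte-Carlo parameter-recovery / null-calibration experiments). Brute-force
oracles (pairwise AUC enumeration, grid-search partial-likelihood
maximization, exhaustive threshold scans, BFS pathway enumeration) live in
`tests/oracles.py` and are independent of the implementation.

## CLI

```
immunomark simulate --seed 7 --out cohort/          # synthetic cohort
immunomark run --input cohort/ --out run/           # full 7-stage pipeline
immunomark normalize counts.tsv --out norm.tsv
immunomark tpm counts.tsv --lengths lengths.tsv --out tpm.tsv
immunomark cnr norm.tsv --controls ctrl.tsv --out activity.tsv
immunomark pal --pathways pathways.json --matrix norm.tsv --controls ctrl.tsv --out pal.tsv
immunomark screen --clinical clinical.csv --markers markers.tsv --out results.tsv
immunomark signature build --markers markers.tsv --clinical clinical.csv --out model.json
immunomark signature apply --model model.json --markers markers.tsv --clinical clinical.csv --out report.json
```

A pipeline run writes `results.tsv`, `selected.json`, `model.json`,
`trace.json`, `evaluation.json`, `scores.tsv` and `manifest.json` under the
output directory; reruns with the same inputs are byte-identical.

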