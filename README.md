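# asymadstrat

Risk stratification of progression from asymptomatic to symptomatic
Alzheimer's disease from a targeted CSF peptide panel. The package
implements the full analysis pipeline on subject-by-peptide abundance
tables:

- **biomarker gating** — two-component Gaussian-mixture cut-off on the
  tTau:Aβ42 ratio (positivity where the upper-component posterior crosses
  0.5), Youden-index ROC cut-offs for PET SUVR scores, diagnostic group
  assignment (Control / AsymAD / AD) and greedy demographically matched
  1:1:1 triplets;
- **panel selection** — recursive feature elimination run independently
  under a linear SVM and an L2 logistic regression on an 80% training
  split, with the final panel being the intersection of the two survivor
  sets; held-out evaluation, a permutation null over random same-size
  peptide subsets, Kendall tau-b ranking of peptides against MoCA, and
  volcano statistics (log2 fold change + Mann–Whitney);
- **AsymAD stratification** — t-SNE embedding of the panel to 2-D, k-NN
  (k = 5) majority vote against the Control/AD reference points, repeated
  over re-initializations to yield per-subject assignment probabilities;
  APOE ε4 allele enrichment by Fisher's exact test; subgroup classifiers
  (held-out split or pooled stratified 6-fold CV);
- **event-based staging** — scaled event-based model: per-biomarker
  normal/abnormal Gaussian mixtures anchored on labelled Control/AD rows,
  joint Metropolis MCMC over the cluster-level event ordering and the
  balanced biomarker-to-cluster assignment, greedy multi-start
  initialization, probabilistic patient staging under the modal state,
  positional-variance summaries, external-cohort recalibration and
  chi-square stage-distribution comparisons;
- **synthetic cohorts** — generators that emulate the assumed data
  structure (three diagnostic groups on a latent severity continuum,
  informative peptides with monotone effects, bimodal biomarker ratio,
  group-specific APOE ε4 frequencies) plus an event-cascade generator with
  a planted ordering used as a recovery oracle.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: the proportion
worked examples, exact oracle equivalences (Youden scan, permutation
p-values, k-NN labels, AUC pair enumeration, EBM likelihood enumeration,
chi-square/Kendall hand formulas), seeded synthetic recovery checks and
pipeline determinism. The stochastic recovery tests use reduced cohort
sizes and the fast MCMC profile to stay inside a CI budget.

## CLI

```bash
asymadstrat simulate --n-control 134 --n-asymad 134 --n-ad 134 --seed 1 --out cohort.csv
asymadstrat gate     --input cohort.csv --mode ratio --out labels.csv
asymadstrat select   --input cohort.csv --stop 14 --seed 1 --out panel.json
asymadstrat permute  --input cohort.csv --panel panel.json --n 100000 --out perm.json
asymadstrat stratify --input cohort.csv --panel panel.json --repeats 100 --k 5 --out strat.csv
asymadstrat ebm-fit  --input cohort.csv --panel panel.json --fast --out fit.json
asymadstrat ebm-stage --fit fit.json --input cohort.csv --panel panel.json --out stages.csv
asymadstrat report   --seed 1 --out-dir results/run1
```

`report` runs the whole pipeline (gate → select → permute → stratify →
ebm-fit → ebm-stage → report) on a simulated cohort, or on a CSV when the
config JSON sets `input_csv`, and writes a deterministic report hash.

## Data formats

Cohorts are wide CSV (UTF-8, header row, empty cell = missing):
`subject_id,group_label,age,sex,race,education,moca,apoe,abeta42,ttau,ptau,
av45_suvr,fdg_suvr,pep_0001,…`. Model objects (cut-offs, panels, EBM fits)
are serialized as JSON; all tabular outputs are CSV.
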