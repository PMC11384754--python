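# alleleprime

Allele-aware analysis of germline-targeting vaccine priming.

Germline-targeting immunogens aim to activate the rare naive B cells whose
receptors can mature into broadly neutralizing antibodies. For VRC01-class
HIV bnAb precursors the heavy chain must come from IGHV1-2 allele *02 or
*04 — so a participant's immunoglobulin genotype sets both the frequency of
targetable precursors in their naive repertoire and, potentially, the
strength of their vaccine response. When allele content is unevenly
distributed between dose groups of a trial, an apparent dose effect can in
fact be a genotype effect. This package implements the statistical toolkit
for detecting and quantifying such effects, for immunologists and trial
statisticians analyzing UMI-tagged IgM repertoires, sorted B cell counts,
BCR sequences, and antibody affinities.

## What it computes

- **`synthetic_trial`** — a generator of complete synthetic trials:
  Hardy–Weinberg genotypes over {*02, *02_S4953, *04, *05, *06} (with an
  optional dose-imbalance mode), UMI-level IgM libraries with per-allele
  usage proportional to zygosity, over-dispersed VRC01-class counts with
  additive allele means, and BCR reads from personal germline templates.
- **`repertoire_quant`** — per-allele mRNA (unique-UMI) and unique-HCDR3
  counts and frequencies from AIRR-style rearrangement tables, primer-set
  combination, *02_S4953 collapse, HCDR3-to-mRNA ratio diagnostics, and
  zygosity-stratified summaries.
- **`response_model`** — the four competing quasi-Poisson mean structures
  for the VRC01-class count V given N sampled IgG B cells, fitted by
  identity-link quasi-likelihood (IRLS with step-halving):

      Null    E(V) = β_Intercept · N
      Dose    E(V) = β_Dose20 · N + β_DoseΔ · 1[high] · N
      Allele  E(V) = β_*02 · n02 · N + β_*04 · n04 · N
      Full    E(V) = Allele terms + β_DoseΔ · 1[high] · N

  ranked by QAICc = −2 lnL/ĉ + 2K + 2K(K+1)/(n−K−1), with genotype means,
  delta-method *02:*04 ratios, and allele differences from the fit.
- **`bcr_allele_assign`** — nearest-germline (Hamming) allele calls with
  exact ties reported ambiguous and *02/*04 ties counted 0.5/0.5, plus
  per-participant usage ratios.
- **`association_stats`** — Fisher exact allele-by-dose tests, exact
  Wilcoxon rank-sum comparisons, ratio t-intervals, a seeded bootstrap
  ratio of means, Spearman/Pearson correlations with permutation p-values,
  genotype favourability ranking, and Holm adjustment.
- **`affinity_lme`** — K_D summaries and random-intercept linear mixed
  models (profile REML, Satterthwaite degrees of freedom) for
  between-allele and paired original-vs-variant affinity comparisons on
  the log10 molar scale.

## Worked example

```python
from alleleprime.synthetic_trial import (
    TrialConfig, simulate_genotypes, simulate_trial_responses)
from alleleprime.response_model import fit_all_models, rank_models, allele_ratio

cfg = TrialConfig(seed=3)          # beta_02 = 8e-4, beta_04 = 2e-4, phi = 2
participants = simulate_genotypes(cfg)
responses = simulate_trial_responses(participants, cfg, timepoints=[("MBC", 4)])
fits = fit_all_models(responses)
print(rank_models(fits))
print(allele_ratio(fits["Allele"]))
```

prints (seed 3)

```
    model  K       qaicc     c_hat  rank
0  Allele  3  165.550562  1.353443     1
1    Full  4  165.686387  1.353443     2
2    Dose  3  381.584427  1.353443     3
3    Null  2  382.054874  1.353443     4
{'ratio': 4.837, 'se': 0.645, 'ci_low': 3.574, 'ci_high': 6.101, 'defined': True}
```

The Allele model (one mean-frequency coefficient per *02/*04 allele copy)
ranks above the Full, Dose and Null structures — allele content, not dose,
explains the counts — and the fitted *02 contribution is about 4–5× the
*04 contribution, matching the 4:1 ratio the trial was simulated with.
The `examples/` directory has one short script per capability
(simulation, repertoire quantification, model ranking, BCR assignment,
association tests, affinity comparison).

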