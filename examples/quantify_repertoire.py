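"""Quantify per-allele mRNA usage and unique-HCDR3 frequencies.

Simulates paired IgM libraries for a small roster, counts unique UMIs and
HCDR3s per IGHV1-2 allele, combines the two primer sets, folds the
non-coding *02_S4953 variant into *02, and summarizes usage by zygosity.
"""

import pandas as pd

from alleleprime.repertoire_quant import (
    allele_usage,
    collapse_s4953,
    combine_primer_sets,
    ratio_diagnostics,
    zygosity_stratified_means,
)
from alleleprime.synthetic_trial import (
    TrialConfig,
    simulate_genotypes,
    simulate_repertoire_pair,
)

cfg = TrialConfig(seed=2)
rng = cfg.rng()
participants = simulate_genotypes(cfg, rng)

usages = []
for p in participants:
    rep = simulate_repertoire_pair(p, cfg, rng)
    leader = allele_usage(rep, primer_set="leader")
    utr = allele_usage(rep, primer_set="5utr")
    usages.append(collapse_s4953(combine_primer_sets(leader, utr)))
usage = pd.concat(usages, ignore_index=True)

strata = zygosity_stratified_means(usage, participants)
print(strata[["allele", "n_homo", "n_het", "mean_homo", "mean_het"]].round(4))
print("-> mean library fraction using each allele; homozygotes carry twice "
      "the per-copy usage of heterozygotes\n")

rows, summary = ratio_diagnostics(usage)
print(summary[["allele", "n", "median_count_ratio"]].round(3))
print("-> unique-HCDR3 to mRNA count ratio (~0.23), a proxy for 1/(BCR "
      "surface density): similar across alleles")
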