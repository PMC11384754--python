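"""Repeated-measures affinity comparisons with participant random effects.

Simulates log-normal K_D values for inferred-germline antibodies where
affinities cluster within participants, then runs the between-allele and
paired original-vs-variant mixed models with Satterthwaite tests.
"""

import numpy as np
import pandas as pd

from alleleprime.affinity_lme import (
    fit_between_group_lme,
    fit_paired_variant_lme,
    summarize_affinities,
)

rng = np.random.default_rng(6)

rows = []
for i in range(12):
    participant_effect = rng.normal(0.0, 0.8)
    group = "*02" if i < 6 else "*04"
    for j in range(4):
        log_kd = -6.8 + participant_effect + rng.normal(0.0, 0.6)
        rows.append({"antibody_id": f"ab{i}_{j}", "participant_id": f"p{i}",
                     "group": group, "kd_molar": 10.0 ** log_kd,
                     "censored": False})
df = pd.DataFrame(rows)

print(summarize_affinities(df)[["group", "n", "median_kd", "q1_kd", "q3_kd"]]
      .to_string(index=False))
between = fit_between_group_lme(df)
print(f"\nbetween-allele log10 K_D difference {between['estimate']:.2f} "
      f"(SE {between['se']:.2f}, Satterthwaite df {between['df']:.1f}, "
      f"p = {between['p_value']:.2f})")
print("-> no true allele effect was simulated; the random intercept absorbs "
      "the within-participant correlation\n")

paired_rows = []
for i in range(10):
    base = rng.normal(-6.5, 1.0)
    shift = rng.normal(0.1, 0.3)  # small variant effect
    paired_rows += [
        {"antibody_id": f"v{i}", "participant_id": f"q{i % 4}",
         "group": "original", "kd_molar": 10.0 ** base, "censored": False},
        {"antibody_id": f"v{i}", "participant_id": f"q{i % 4}",
         "group": "variant", "kd_molar": 10.0 ** (base + shift),
         "censored": False},
    ]
paired = fit_paired_variant_lme(pd.DataFrame(paired_rows))
print(f"paired variant-minus-original difference {paired['estimate']:.2f} "
      f"log10 units (df {paired['df']:.1f}, p = {paired['p_value']:.2f})")
print("-> positive values mean the variant binds more weakly (higher K_D)")
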