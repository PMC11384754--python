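"""Assign BCR reads to germline alleles and compute usage ratios.

Simulates mutated BCR reads for *02/*04 heterozygotes, assigns each read to
the nearest personal germline template (Hamming distance; exact ties are
ambiguous and split 0.5/0.5), and summarizes the per-participant *02:*04
usage ratio.
"""

from alleleprime.bcr_allele_assign import (
    assign_reads,
    per_participant_ratio,
    tally_assignments,
)
from alleleprime.synthetic_trial import (
    TrialConfig,
    germline_templates,
    simulate_bcr_reads,
    simulate_genotypes,
)

cfg = TrialConfig(seed=4, mutation_rate=0.005)
rng = cfg.rng()
participants = simulate_genotypes(cfg, rng)
templates = germline_templates()

hets = [p for p in participants if p.n02 == 1 and p.n04 == 1][:8]
tallies = {}
for p in hets:
    reads = simulate_bcr_reads(p, cfg, 110, rng)
    calls = assign_reads(reads, {p.id: (p.allele_1, p.allele_2)}, templates)
    tallies[p.id] = tally_assignments(calls)
    accuracy = sum(
        c.assigned == t for c, t in zip(calls, reads["true_allele"])
    ) / len(calls)
    print(f"{p.id}: counts {tallies[p.id]['counts']}, "
          f"{tallies[p.id]['ambiguous_fraction_pct']:.2f}% ambiguous, "
          f"accuracy {accuracy:.3f}")

summary = per_participant_ratio(tallies)["summary"]
print(f"\nmean *02:*04 usage ratio {summary.mean:.2f} "
      f"(95% CI {summary.ci_low:.2f}-{summary.ci_high:.2f}, "
      f"p vs 1 = {summary.p_value:.2g})")
print("-> reads were simulated with equal origin per chromosome, so the "
      "ratio should be near 1; ambiguity arises only when a mutation hits "
      "the single diagnostic nucleotide")
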