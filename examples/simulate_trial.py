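"""Generate a complete synthetic vaccine trial and write it to disk.

Creates a genotyped roster (three dose groups), paired IgM repertoire
libraries, VRC01-class response counts, and BCR reads for one heterozygous
participant, then writes TSV/FASTA files under ./trial_output.
"""

from pathlib import Path

from alleleprime.synthetic_trial import (
    TrialConfig,
    simulate_bcr_reads,
    simulate_genotypes,
    simulate_repertoire_pair,
    simulate_trial_responses,
    write_germlines_fasta,
    write_participants_tsv,
    write_reads_fasta,
    write_repertoire_tsv,
    write_responses_tsv,
)

out = Path("trial_output")
out.mkdir(exist_ok=True)

cfg = TrialConfig(seed=1)
rng = cfg.rng()
participants = simulate_genotypes(cfg, rng)
write_participants_tsv(participants, out / "participants.tsv")
print(f"{len(participants)} participants in 3 dose groups")
print("genotype of first participant:", participants[0].genotype)

repertoire = simulate_repertoire_pair(participants[0], cfg, rng)
write_repertoire_tsv(repertoire, out / f"{participants[0].id}_repertoire.tsv")
print(f"repertoire for {participants[0].id}: {len(repertoire)} UMI records "
      "across two primer sets (leader + 5'UTR)")

responses = simulate_trial_responses(participants, cfg, rng)
write_responses_tsv(responses, out / "responses.tsv")
print(f"responses: {len(responses)} (participant x timepoint) count samples; "
      "V is over-dispersed with additive per-allele means")

het = next(p for p in participants if p.n02 == 1 and p.n04 == 1)
reads = simulate_bcr_reads(het, cfg, 100, rng)
write_reads_fasta(reads, out / f"{het.id}_reads.fasta")
write_germlines_fasta(out / "germlines.fasta")
print(f"wrote 100 BCR reads for heterozygote {het.id} plus germline "
      f"templates; files under {out}/")
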