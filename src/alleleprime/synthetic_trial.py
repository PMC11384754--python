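"""Synthetic trial generator for allele-aware germline-targeting analyses.

Generates complete synthetic vaccine trials with the statistical structure
the downstream analysis assumes: two-allele IGHV1-2 genotypes drawn under
Hardy-Weinberg independence, UMI-tagged IgM repertoire libraries with
per-allele mRNA usage proportional to zygosity, over-dispersed VRC01-class
response counts with additive per-allele means, and BCR reads copied from
personal germline templates that differ at a single diagnostic nucleotide
(*02 vs *04).

Every generator takes an explicit :class:`numpy.random.Generator` or derives
one from ``TrialConfig.seed``, and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALLELES",
    "ALLELE_SYNONYMS",
    "DOSE_GROUPS",
    "TIMEPOINTS",
    "BACKGROUND_ALLELE",
    "TrialConfig",
    "Participant",
    "germline_templates",
    "simulate_genotypes",
    "simulate_repertoire",
    "simulate_repertoire_pair",
    "simulate_responses",
    "simulate_trial_responses",
    "simulate_bcr_reads",
    "participants_to_frame",
    "write_participants_tsv",
    "write_repertoire_tsv",
    "write_responses_tsv",
    "write_reads_fasta",
    "write_germlines_fasta",
]

#: IGHV1-2 alleles tracked by the generator. ``*02_S4953`` is a non-coding
#: variant of ``*02`` (same amino-acid sequence) and is collapsed into *02
#: for analysis.
ALLELES = ("*02", "*02_S4953", "*04", "*05", "*06")

#: Synonym map applied when collapsing non-coding allelic variants.
ALLELE_SYNONYMS = {"*02_S4953": "*02"}

DOSE_GROUPS = ("low", "high", "placebo")

#: The seven sampling points of the trial design: lymph-node germinal-center
#: (GC) B cells at weeks 3 and 11, blood IgG memory B cells (MBC) at weeks
#: 4, 8, 10 and 16, and plasmablasts (PB) at week 9.
TIMEPOINTS = (
    ("GC", 3),
    ("MBC", 4),
    ("MBC", 8),
    ("PB", 9),
    ("MBC", 10),
    ("GC", 11),
    ("MBC", 16),
)

#: Label used for the pooled "all other IGHV genes" class in repertoires.
BACKGROUND_ALLELE = "IGHVother"

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _count_02(a1: str, a2: str) -> int:
    return sum(ALLELE_SYNONYMS.get(a, a) == "*02" for a in (a1, a2))


def _count_04(a1: str, a2: str) -> int:
    return sum(a == "*04" for a in (a1, a2))


@dataclass(frozen=True)
class TrialConfig:
    """Study conditions for one synthetic trial.

    Defaults reproduce the trial-scale conditions the analysis targets:
    18 participants per dose group, per-allele mRNA usage of 3.1% (*02) and
    0.9% (*04), a unique-HCDR3-to-mRNA thinning ratio of 0.23, additive
    per-allele VRC01-class response frequencies with a 4:1 *02:*04 ratio,
    and quasi-Poisson over-dispersion phi = 2.

    Parameters
    ----------
    n_per_group
        Participants per dose group (low / high / placebo).
    allele_freqs
        Population allele frequencies, ordered as :data:`ALLELES`; must sum
        to 1. The default makes *04 the most common allele followed by *02.
    expr_rate_per_allele
        Per-allele-copy fraction of library mRNA (UMIs) using that allele.
    hcdr3_ratio
        Expected unique-HCDR3-to-UMI count ratio (binomial thinning rate),
        a proxy for 1/(BCR surface density).
    beta_02, beta_04
        Per-allele-copy VRC01-class response frequency (VRC01-class cells
        per sampled IgG B cell).
    dose_delta
        Additive high-dose effect on the response frequency.
    dispersion
        Variance inflation phi >= 1; response counts have variance phi*mu
        (NB1; exact Poisson when phi == 1).
    n_total_umis
        Unique UMIs per IgM library.
    n_igg_sampled
        Total IgG B cells sampled per response measurement (N). The source
        study does not report per-sample totals; this default is a
        configurable stand-in.
    mutation_rate
        Per-base substitution probability applied to simulated BCR reads.
    seed
        Root RNG seed; all generators are deterministic given it.
    """

    n_per_group: int = 18
    allele_freqs: tuple[float, ...] = (0.29, 0.02, 0.48, 0.05, 0.16)
    expr_rate_per_allele: Mapping[str, float] = field(
        default_factory=lambda: {
            "*02": 0.031,
            "*02_S4953": 0.031,
            "*04": 0.009,
            "*05": 0.0009,
            "*06": 0.024,
        }
    )
    hcdr3_ratio: float = 0.23
    beta_02: float = 8.0e-4
    beta_04: float = 2.0e-4
    dose_delta: float = 0.0
    dispersion: float = 2.0
    n_total_umis: int = 20_000
    n_igg_sampled: int = 30_000
    mutation_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        freqs = np.asarray(self.allele_freqs, dtype=float)
        if freqs.shape != (len(ALLELES),):
            raise ValueError(
                f"allele_freqs must have {len(ALLELES)} entries "
                f"(order {ALLELES})"
            )
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("allele_freqs must be non-negative and sum to 1")
        for allele in ALLELES:
            rate = self.expr_rate_per_allele.get(allele)
            if rate is None or not 0.0 <= rate <= 1.0:
                raise ValueError(f"expression rate for {allele} must be in [0,1]")
            # a homozygote expresses 2 * rate of its library
            if 2.0 * rate > 1.0:
                raise ValueError(f"2 x expression rate for {allele} exceeds 1")
        if not 0.0 <= self.hcdr3_ratio <= 1.0:
            raise ValueError("hcdr3_ratio must be in [0,1]")
        if self.beta_02 < 0 or self.beta_04 < 0:
            raise ValueError("beta parameters must be non-negative")
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0,1]")
        if self.n_total_umis <= 0 or self.n_igg_sampled <= 0:
            raise ValueError("library and sample sizes must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def replace(self, **changes) -> "TrialConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Participant:
    """One trial participant: dose group and two-allele IGHV1-2 genotype.

    ``n02`` counts alleles in {*02, *02_S4953}; ``n04`` counts *04 alleles.
    """

    id: str
    dose_group: str
    allele_1: str
    allele_2: str
    n02: int = field(init=False)
    n04: int = field(init=False)

    def __post_init__(self) -> None:
        if self.dose_group not in DOSE_GROUPS:
            raise ValueError(f"unknown dose group {self.dose_group!r}")
        for a in (self.allele_1, self.allele_2):
            if a not in ALLELES:
                raise ValueError(f"unknown allele {a!r}")
        object.__setattr__(self, "n02", _count_02(self.allele_1, self.allele_2))
        object.__setattr__(self, "n04", _count_04(self.allele_1, self.allele_2))

    @property
    def genotype(self) -> tuple[str, str]:
        return tuple(sorted((self.allele_1, self.allele_2)))

    @property
    def dose_high(self) -> int:
        return int(self.dose_group == "high")

    def zygosity(self, allele: str) -> int:
        """Copies of ``allele`` carried (synonyms collapsed), in {0, 1, 2}."""
        target = ALLELE_SYNONYMS.get(allele, allele)
        return sum(
            ALLELE_SYNONYMS.get(a, a) == target
            for a in (self.allele_1, self.allele_2)
        )


# ---------------------------------------------------------------------------
# germline templates

# Synthetic 294-nt V-region scaffold (not a database sequence). The allele
# templates below differ only at a handful of fixed positions, mimicking the
# real situation where *02 and *04 differ by a single nucleotide
# (A in *04 / T in *02 at the codon-66 position) and *05/*06 share a
# substitution in codon 50.
_BASE_V = (
    "GGATGGGACCTTAGCTACCTACAGGTCTGGGTAACGGATTTGTACAGTGGCTAGTAACCAGCAATGTT"
    "CCTCCCAGAGAATCCGCTATCCGTCCCAAGTGTGCCGTGGTACGTCCGGTGGCGCACAGCTTATGGAT"
    "CTTGCTCGGGCCCAGAGGTGACAAATAGGCCATGTTCGTGTCAAGCACACCCGCATCCTACCTTACAA"
    "GCATTCCGGGGTATACGACACCTCGGGCAGAGTACCCTGGCAACGTGCGTGATACAATTTTAAACTAG"
    "TAAATGTAGTCAGCGTTCGGGG"
)

#: 0-based position of the single nucleotide separating *02 (T) from *04 (A),
#: the codon-66 diagnostic site.
DIAGNOSTIC_POS = 196

# codon-50 site shared by *05 and *06, plus allele-private positions
_POS50 = 148


def _substitute(seq: str, edits: Mapping[int, str]) -> str:
    chars = list(seq)
    for pos, base in edits.items():
        chars[pos] = base
    return "".join(chars)


def germline_templates() -> dict[str, str]:
    """Personalized germline V-region templates per allele (synthetic).

    ``*02`` and ``*04`` are identical except at :data:`DIAGNOSTIC_POS`;
    ``*02_S4953`` is coding-identical to ``*02`` (its defining polymorphism
    lies outside the compared V window); ``*05``/``*06`` share a codon-50
    substitution and carry private differences.
    """
    base04 = _substitute(_BASE_V, {DIAGNOSTIC_POS: "A"})
    base02 = _substitute(_BASE_V, {DIAGNOSTIC_POS: "T"})
    return {
        "*02": base02,
        "*02_S4953": base02,
        "*04": base04,
        "*05": _substitute(base04, {_POS50: "G", 30: "C", 250: "A"}),
        "*06": _substitute(base04, {_POS50: "G", 60: "A", 270: "C"}),
    }


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(
    config: TrialConfig,
    rng: np.random.Generator | None = None,
    dose_imbalance: bool = False,
) -> list[Participant]:
    """Draw a trial roster of genotyped participants.

    Each participant's two alleles are drawn independently from
    ``config.allele_freqs`` (Hardy-Weinberg independence); dose groups are
    assigned in blocks of ``n_per_group`` (low, high, placebo).

    With ``dose_imbalance=True`` the vaccine groups are stratified so that
    13 of 18 high-dose and 5 of 18 low-dose participants carry at least one
    *02-type allele (scaled proportionally for other group sizes),
    regenerating the confounding scenario in which dose and allele content
    are entangled.
    """
    if rng is None:
        rng = config.rng()
    freqs = np.asarray(config.allele_freqs, dtype=float)
    n = config.n_per_group

    def draw_pair() -> tuple[str, str]:
        i, j = rng.choice(len(ALLELES), size=2, p=freqs)
        return ALLELES[i], ALLELES[j]

    participants: list[Participant] = []
    if not dose_imbalance:
        idx = rng.choice(len(ALLELES), size=(3 * n, 2), p=freqs)
        for k in range(3 * n):
            participants.append(
                Participant(
                    id=f"P{k + 1:03d}",
                    dose_group=DOSE_GROUPS[k // n],
                    allele_1=ALLELES[idx[k, 0]],
                    allele_2=ALLELES[idx[k, 1]],
                )
            )
        return participants

    # stratified mode: fixed numbers of *02 carriers per vaccine group
    carriers_per_group = {
        "low": int(round(5 / 18 * n)),
        "high": int(round(13 / 18 * n)),
        "placebo": int(round(n * freqs[0] + n * freqs[1])),  # unstratified-ish
    }
    pool_carrier: list[tuple[str, str]] = []
    pool_noncarrier: list[tuple[str, str]] = []
    # rejection-fill both pools; bounded because both genotype classes have
    # positive probability under any valid frequency vector with *02 mass
    for _ in range(200_000):
        if len(pool_carrier) >= 3 * n and len(pool_noncarrier) >= 3 * n:
            break
        pair = draw_pair()
        (pool_carrier if _count_02(*pair) > 0 else pool_noncarrier).append(pair)
    k = 0
    for group in DOSE_GROUPS:
        n_c = carriers_per_group[group]
        for i in range(n):
            take_carrier = i < n_c
            pool = pool_carrier if take_carrier else pool_noncarrier
            if not pool:
                raise ValueError(
                    "could not fill stratified genotype pools; check allele_freqs"
                )
            a1, a2 = pool.pop(0)
            participants.append(
                Participant(
                    id=f"P{k + 1:03d}", dose_group=group, allele_1=a1, allele_2=a2
                )
            )
            k += 1
    return participants


# ---------------------------------------------------------------------------
# repertoires

def _hcdr3_string(index: int) -> str:
    """Deterministic, globally unique HCDR3-like amino-acid string."""
    body = []
    i = index
    for _ in range(9):
        body.append(_AA20[i % 20])
        i //= 20
    return "CAR" + "".join(body) + "DYW"


def simulate_repertoire(
    participant: Participant,
    config: TrialConfig,
    primer_set: str,
    rng: np.random.Generator | None = None,
    _hcdr3_offset: int = 0,
) -> pd.DataFrame:
    """Simulate one UMI-deduplicated IgM library for one primer set.

    Per carried allele the UMI count is marginally
    Binomial(n_total_umis, zygosity * expr_rate); remaining UMIs form a
    pooled other-IGHV background class, so per-library allele frequencies
    plus the background frequency sum to one exactly. The number of distinct
    HCDR3 strings per allele is a Binomial(umi_count, hcdr3_ratio) thinning
    (floored at 1 when the allele has any UMIs).

    Returns an AIRR-style table with columns ``sequence_id, umi, v_call,
    v_mismatches, cdr3_aa, primer_set, participant_id``.
    """
    if rng is None:
        rng = config.rng()
    alleles = sorted(set((participant.allele_1, participant.allele_2)))
    zyg = {a: (participant.allele_1 == a) + (participant.allele_2 == a) for a in alleles}
    probs = np.array(
        [zyg[a] * config.expr_rate_per_allele[a] for a in alleles], dtype=float
    )
    if probs.sum() > 1.0:
        raise ValueError("total zygosity-weighted expression rate exceeds 1")
    counts = rng.multinomial(
        config.n_total_umis, np.append(probs, 1.0 - probs.sum())
    )
    allele_counts = dict(zip(alleles, counts[:-1]))
    allele_counts[BACKGROUND_ALLELE] = int(counts[-1])

    rows_seq, rows_umi, rows_call, rows_cdr3 = [], [], [], []
    umi_counter = 0
    hcdr3_counter = _hcdr3_offset
    for allele, n_umi in allele_counts.items():
        n_umi = int(n_umi)
        if n_umi == 0:
            continue
        k = int(rng.binomial(n_umi, config.hcdr3_ratio))
        k = max(k, 1)
        strings = [_hcdr3_string(hcdr3_counter + i) for i in range(k)]
        hcdr3_counter += k
        # first k UMIs realize each distinct HCDR3 once; the rest re-draw
        assignment = list(range(k)) + list(rng.integers(0, k, size=n_umi - k))
        call = (
            f"IGHV1-2{allele}" if allele != BACKGROUND_ALLELE else f"{BACKGROUND_ALLELE}*01"
        )
        for idx in assignment:
            umi_counter += 1
            rows_seq.append(f"{participant.id}_{primer_set}_{umi_counter:06d}")
            rows_umi.append(f"UMI{umi_counter:06d}")
            rows_call.append(call)
            rows_cdr3.append(strings[idx])
    return pd.DataFrame(
        {
            "sequence_id": rows_seq,
            "umi": rows_umi,
            "v_call": rows_call,
            "v_mismatches": 0,
            "cdr3_aa": rows_cdr3,
            "primer_set": primer_set,
            "participant_id": participant.id,
        }
    )


def simulate_repertoire_pair(
    participant: Participant,
    config: TrialConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two independently generated libraries (leader and 5'UTR primer sets)."""
    if rng is None:
        rng = config.rng()
    leader = simulate_repertoire(participant, config, "leader", rng)
    utr = simulate_repertoire(
        participant, config, "5utr", rng, _hcdr3_offset=10_000_000
    )
    return pd.concat([leader, utr], ignore_index=True)


# ---------------------------------------------------------------------------
# responses

def _draw_nb1(rng: np.random.Generator, mu: float, phi: float) -> int:
    """Count draw with mean mu and variance phi*mu (NB1; Poisson if phi=1)."""
    if mu == 0.0:
        return 0
    if phi == 1.0:
        return int(rng.poisson(mu))
    size = mu / (phi - 1.0)
    prob = 1.0 / phi
    return int(rng.negative_binomial(size, prob))


def response_mean(participant: Participant, config: TrialConfig) -> float:
    """Additive-allele expected VRC01-class count for one sample.

    mu = (beta_02 * n02 + beta_04 * n04 + dose_delta * 1[high]) * N for
    vaccine recipients; structurally zero for placebo recipients.
    """
    if participant.dose_group == "placebo":
        return 0.0
    mu = (
        config.beta_02 * participant.n02
        + config.beta_04 * participant.n04
        + config.dose_delta * participant.dose_high
    ) * config.n_igg_sampled
    if mu < 0:
        raise ValueError(
            f"negative response mean for {participant.id}: "
            "dose_delta more negative than the allele terms"
        )
    return mu


def simulate_responses(
    participant: Participant,
    config: TrialConfig,
    rng: np.random.Generator | None = None,
    timepoints: Sequence[tuple[str, int]] = TIMEPOINTS,
) -> pd.DataFrame:
    """VRC01-class count samples (V, N) for one participant across timepoints."""
    if rng is None:
        rng = config.rng()
    mu = response_mean(participant, config)
    rows = []
    for compartment, week in timepoints:
        v = _draw_nb1(rng, mu, config.dispersion)
        rows.append(
            {
                "participant_id": participant.id,
                "compartment": compartment,
                "week": week,
                "V": v,
                "N": config.n_igg_sampled,
                "dose_group": participant.dose_group,
                "dose_high": participant.dose_high,
                "n02": participant.n02,
                "n04": participant.n04,
            }
        )
    return pd.DataFrame(rows)


def simulate_trial_responses(
    participants: Iterable[Participant],
    config: TrialConfig,
    rng: np.random.Generator | None = None,
    timepoints: Sequence[tuple[str, int]] = TIMEPOINTS,
) -> pd.DataFrame:
    """Response table for a whole roster (one row per participant x timepoint).

    Vectorized across all participant x timepoint cells (one NB1/Poisson
    draw per cell), so large rosters simulate quickly.
    """
    if rng is None:
        rng = config.rng()
    participants = list(participants)
    mu_p = np.array([response_mean(p, config) for p in participants])
    n_t = len(timepoints)
    mu = np.repeat(mu_p, n_t)
    v = np.zeros(mu.size, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        if config.dispersion == 1.0:
            v[pos] = rng.poisson(mu[pos])
        else:
            size = mu[pos] / (config.dispersion - 1.0)
            v[pos] = rng.negative_binomial(size, 1.0 / config.dispersion)
    return pd.DataFrame(
        {
            "participant_id": np.repeat([p.id for p in participants], n_t),
            "compartment": [tp[0] for tp in timepoints] * len(participants),
            "week": [tp[1] for tp in timepoints] * len(participants),
            "V": v,
            "N": config.n_igg_sampled,
            "dose_group": np.repeat([p.dose_group for p in participants], n_t),
            "dose_high": np.repeat([p.dose_high for p in participants], n_t),
            "n02": np.repeat([p.n02 for p in participants], n_t),
            "n04": np.repeat([p.n04 for p in participants], n_t),
        }
    )


# ---------------------------------------------------------------------------
# BCR reads

def simulate_bcr_reads(
    participant: Participant,
    config: TrialConfig,
    n_reads: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate BCR reads copied from the participant's germline templates.

    Each read picks one of the participant's two chromosomes uniformly
    (origin proportional to zygosity) and substitutes each base
    independently with probability ``mutation_rate`` (uniform over the three
    alternatives). The true origin allele is recorded for truth-set
    evaluation.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if participant.n02 + participant.n04 == 0:
        raise ValueError(
            f"{participant.id} carries neither *02 nor *04; no VRC01-class reads"
        )
    if rng is None:
        rng = config.rng()
    templates = germline_templates()
    chromosomes = (participant.allele_1, participant.allele_2)
    origins = rng.integers(0, 2, size=n_reads)
    bases = np.array(list("ACGT"))
    base_index = {b: i for i, b in enumerate("ACGT")}
    rows = []
    for i in range(n_reads):
        allele = chromosomes[origins[i]]
        tmpl = np.array(list(templates[allele]))
        hit = rng.random(tmpl.size) < config.mutation_rate
        if hit.any():
            idx = np.flatnonzero(hit)
            # substitute with one of the three non-identical bases
            offsets = rng.integers(1, 4, size=idx.size)
            cur = np.array([base_index[b] for b in tmpl[idx]])
            tmpl[idx] = bases[(cur + offsets) % 4]
        rows.append(
            {
                "read_id": f"{participant.id}_read{i + 1:05d}",
                "participant_id": participant.id,
                "true_allele": allele,
                "sequence": "".join(tmpl),
            }
        )
    return pd.DataFrame(
        rows, columns=["read_id", "participant_id", "true_allele", "sequence"]
    )


# ---------------------------------------------------------------------------
# I/O

def participants_to_frame(participants: Iterable[Participant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [p.id for p in participants],
            "dose_group": [p.dose_group for p in participants],
            "allele_1": [p.allele_1 for p in participants],
            "allele_2": [p.allele_2 for p in participants],
            "n02": [p.n02 for p in participants],
            "n04": [p.n04 for p in participants],
        }
    )


def write_participants_tsv(participants: Iterable[Participant], path) -> None:
    participants_to_frame(participants).to_csv(path, sep="\t", index=False)


def write_repertoire_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def write_responses_tsv(responses: pd.DataFrame, path) -> None:
    responses.to_csv(path, sep="\t", index=False)


def write_reads_fasta(reads: pd.DataFrame, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(
            Seq(row.sequence),
            id=row.read_id,
            description=f"participant={row.participant_id} true_allele={row.true_allele}",
        )
        for row in reads.itertuples()
    ]
    SeqIO.write(records, path, "fasta")


def write_germlines_fasta(path, alleles: Sequence[str] | None = None) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    templates = germline_templates()
    names = alleles if alleles is not None else list(templates)
    records = [
        SeqRecord(Seq(templates[a]), id=f"IGHV1-2{a}", description="synthetic template")
        for a in names
    ]
    SeqIO.write(records, path, "fasta")
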