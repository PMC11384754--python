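"""Germline IGHV1-2 allele assignment for BCR reads.

Each read is compared against the participant's personal germline templates
over a fixed-length V-region window and assigned to the allele with the
fewest mismatches (Hamming distance). Because the candidate templates are
equal-length and ungapped, fewest-mismatches ordering coincides with a
lowest-e-value ranking; reads equidistant from two or more templates are
"ambiguous", and *02/*04-ambiguous reads are equiprobable for either allele
so contribute 0.5 to each in tallies. Indels are assumed corrected upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association_stats import ratio_t_ci
from .synthetic_trial import ALLELE_SYNONYMS

__all__ = [
    "BCRCall",
    "hamming",
    "assign_allele",
    "assign_reads",
    "tally_assignments",
    "per_participant_ratio",
]

AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BCRCall:
    """Germline allele call for one BCR read.

    ``weights`` sums to 1 across the participant's candidate alleles:
    1.0 on the winner for a unique minimum, 1/k over k tied alleles.
    """

    sequence_id: str
    participant_id: str | None
    assigned: str  # allele label or "ambiguous"
    tied: tuple[str, ...]
    weights: Mapping[str, float]
    distances: Mapping[str, int]

    @property
    def is_ambiguous(self) -> bool:
        return self.assigned == AMBIGUOUS


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def _collapse(allele: str) -> str:
    return ALLELE_SYNONYMS.get(allele, allele)


def assign_allele(
    read: str,
    personal_germlines: Mapping[str, str],
    sequence_id: str = "",
    participant_id: str | None = None,
    window: tuple[int, int] | None = None,
) -> BCRCall:
    """Assign one read to the closest personal germline allele.

    ``personal_germlines`` maps allele labels to template sequences (the
    participant's genotype); synonymous labels (e.g. *02_S4953) are
    collapsed to their coding allele before tie detection, so a coding-
    identical pair does not produce spurious ambiguity. ``window`` is a
    half-open (start, end) slice over which mismatches are counted; by
    default the full common template length is used.

    A read shorter than the window is an error naming the read.
    """
    if not personal_germlines:
        raise ValueError("personal germline set is empty")
    lengths = {len(s) for s in personal_germlines.values()}
    if len(lengths) != 1:
        raise ValueError("germline templates must have equal length")
    start, end = window if window is not None else (0, lengths.pop())
    if len(read) < end:
        raise ValueError(
            f"read {sequence_id or '<unnamed>'!r} shorter than comparison window"
        )
    segment = read[start:end]
    distances: dict[str, int] = {}
    for allele, template in personal_germlines.items():
        d = hamming(segment, template[start:end])
        label = _collapse(allele)
        distances[label] = min(d, distances.get(label, d))
    dmin = min(distances.values())
    winners = tuple(sorted(a for a, d in distances.items() if d == dmin))
    if len(winners) == 1:
        assigned = winners[0]
        weights = {winners[0]: 1.0}
    else:
        assigned = AMBIGUOUS
        weights = {a: 1.0 / len(winners) for a in winners}
    return BCRCall(
        sequence_id=sequence_id,
        participant_id=participant_id,
        assigned=assigned,
        tied=winners,
        weights=weights,
        distances=distances,
    )


def assign_reads(
    reads: pd.DataFrame,
    genotypes: Mapping[str, Sequence[str]],
    germlines: Mapping[str, str],
    window: tuple[int, int] | None = None,
) -> list[BCRCall]:
    """Assign a table of reads, using each participant's own genotype.

    ``reads`` needs columns ``read_id, participant_id, sequence``;
    ``genotypes`` maps participant id to its allele labels.
    """
    calls = []
    for row in reads.itertuples():
        alleles = genotypes[row.participant_id]
        personal = {a: germlines[a] for a in set(alleles)}
        calls.append(
            assign_allele(
                row.sequence,
                personal,
                sequence_id=row.read_id,
                participant_id=row.participant_id,
                window=window,
            )
        )
    return calls


def tally_assignments(calls: Iterable[BCRCall]) -> dict:
    """Weighted per-allele counts and the ambiguous fraction.

    Reads ambiguous between *02 and *04 contribute 0.5 to each allele;
    ambiguity involving any other allele goes to an ``ambiguous_other``
    bucket (excluded from per-allele counts, included in the total).
    The ambiguous fraction is a percentage of all calls.
    """
    counts: dict[str, float] = {}
    n_calls = 0
    n_ambiguous = 0
    ambiguous_other = 0
    for call in calls:
        n_calls += 1
        if not call.is_ambiguous:
            counts[call.assigned] = counts.get(call.assigned, 0.0) + 1.0
            continue
        n_ambiguous += 1
        if set(call.tied) == {"*02", "*04"}:
            counts["*02"] = counts.get("*02", 0.0) + 0.5
            counts["*04"] = counts.get("*04", 0.0) + 0.5
        else:
            ambiguous_other += 1
    return {
        "counts": counts,
        "n_calls": n_calls,
        "n_ambiguous": n_ambiguous,
        "ambiguous_fraction_pct": 100.0 * n_ambiguous / n_calls if n_calls else 0.0,
        "ambiguous_other": ambiguous_other,
    }


def per_participant_ratio(
    tallies: Mapping[str, Mapping],
    null_ratio: float = 1.0,
) -> dict:
    """*02:*04 weighted-count ratio per participant, with t CI and test vs 1.

    ``tallies`` maps participant id to a :func:`tally_assignments` result.
    Zero *04 counts give infinite ratios and zero *02 counts give zero
    ratios; both are reported but excluded (flagged) from the mean/CI/test,
    which use the finite positive ratios across participants.
    """
    per_participant = {}
    finite: list[float] = []
    for pid, tally in tallies.items():
        c02 = tally["counts"].get("*02", 0.0)
        c04 = tally["counts"].get("*04", 0.0)
        ratio = np.inf if c04 == 0 else c02 / c04
        flagged = not np.isfinite(ratio) or ratio == 0.0
        per_participant[pid] = {"ratio": ratio, "excluded": flagged}
        if not flagged:
            finite.append(ratio)
    result = ratio_t_ci(np.array(finite), null=null_ratio) if finite else None
    return {
        "per_participant": per_participant,
        "n_finite": len(finite),
        "summary": result,
    }
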