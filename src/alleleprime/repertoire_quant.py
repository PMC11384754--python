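"""Per-allele mRNA (UMI) usage and unique-HCDR3 quantification of IgM libraries.

Works on AIRR-style rearrangement tables (columns ``sequence_id, umi,
v_call, v_mismatches, cdr3_aa, primer_set``). Only unmutated records
(zero germline mismatches) contribute; mRNA molecules are counted as unique
UMIs per allele, B cell clones as unique HCDR3 strings per allele, and
frequencies use the whole library (all IGHV genes) as denominator by
default. Primer-set libraries are combined by averaging frequencies, and
the non-coding *02_S4953 variant is folded into *02.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_trial import ALLELE_SYNONYMS, Participant

logger = logging.getLogger(__name__)

__all__ = [
    "count_umis_per_allele",
    "count_unique_hcdr3",
    "allele_usage",
    "combine_primer_sets",
    "collapse_s4953",
    "ratio_diagnostics",
    "zygosity_stratified_means",
    "read_airr_tsv",
]

USAGE_COLUMNS = [
    "participant_id",
    "allele",
    "umi_count",
    "umi_frequency",
    "hcdr3_count",
    "hcdr3_frequency",
    "primer_set",
]


def read_airr_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"umi": str, "cdr3_aa": str})


def _unmutated(records: pd.DataFrame) -> pd.DataFrame:
    """Records with zero germline mismatches; missing annotation is treated
    as mutated (excluded), conservatively."""
    mism = pd.to_numeric(records["v_mismatches"], errors="coerce")
    return records[mism == 0]


def count_umis_per_allele(records: pd.DataFrame) -> tuple[pd.Series, int]:
    """Unique-UMI counts per allele over unmutated records.

    Duplicate (allele, UMI) pairs count once. Records missing a UMI are
    skipped (logged). Returns ``(per-allele counts, library total)`` where
    the total is the number of unique UMIs over all alleles in the library.
    """
    kept = _unmutated(records)
    missing = kept["umi"].isna() | (kept["umi"].astype(str).str.len() == 0)
    if missing.any():
        logger.warning("skipping %d records with missing UMI", int(missing.sum()))
        kept = kept[~missing]
    dedup = kept.drop_duplicates(subset=["v_call", "umi"])
    counts = dedup.groupby("v_call").size().sort_index()
    return counts, int(counts.sum())


def count_unique_hcdr3(records: pd.DataFrame) -> tuple[pd.Series, int]:
    """Unique-HCDR3 counts per allele over unmutated records.

    Matching is exact string equality on the amino-acid field; empty HCDR3s
    are excluded (logged). The total is the number of unique HCDR3s in the
    whole library.
    """
    kept = _unmutated(records)
    empty = kept["cdr3_aa"].isna() | (kept["cdr3_aa"].astype(str).str.len() == 0)
    if empty.any():
        logger.warning("excluding %d records with empty HCDR3", int(empty.sum()))
        kept = kept[~empty]
    counts = kept.groupby("v_call")["cdr3_aa"].nunique().sort_index()
    total = int(kept["cdr3_aa"].nunique())
    return counts, total


def allele_usage(
    records: pd.DataFrame,
    participant_id: str | None = None,
    primer_set: str | None = None,
) -> pd.DataFrame:
    """Per-allele usage table for one library.

    Frequencies divide by the library totals (all IGHV genes): UMI frequency
    = allele unique-UMI count / total unique UMIs, and analogously for
    unique HCDR3s.
    """
    if primer_set is not None:
        records = records[records["primer_set"] == primer_set]
    if participant_id is None and "participant_id" in records.columns:
        ids = records["participant_id"].unique()
        if len(ids) == 1:
            participant_id = ids[0]
    umi_counts, umi_total = count_umis_per_allele(records)
    cdr_counts, cdr_total = count_unique_hcdr3(records)
    alleles = sorted(set(umi_counts.index) | set(cdr_counts.index))
    out = pd.DataFrame(
        {
            "participant_id": participant_id,
            "allele": alleles,
            "umi_count": [int(umi_counts.get(a, 0)) for a in alleles],
            "hcdr3_count": [int(cdr_counts.get(a, 0)) for a in alleles],
        }
    )
    out["umi_frequency"] = out["umi_count"] / umi_total if umi_total else 0.0
    out["hcdr3_frequency"] = (
        out["hcdr3_count"] / cdr_total if cdr_total else 0.0
    )
    out["primer_set"] = primer_set if primer_set is not None else "all"
    return out[USAGE_COLUMNS]


def combine_primer_sets(
    usage_leader: pd.DataFrame, usage_5utr: pd.DataFrame
) -> pd.DataFrame:
    """Combine the two primer-set libraries of one participant.

    The combined relative usage of an allele is the arithmetic mean of its
    frequencies in the two libraries (an allele absent from one library
    contributes frequency zero there). Counts are summed for reference.
    """
    key = ["participant_id", "allele"]
    merged = usage_leader.merge(
        usage_5utr, on=key, how="outer", suffixes=("_a", "_b")
    )
    num_cols = [
        "umi_count",
        "umi_frequency",
        "hcdr3_count",
        "hcdr3_frequency",
    ]
    for col in num_cols:
        merged[f"{col}_a"] = merged[f"{col}_a"].fillna(0)
        merged[f"{col}_b"] = merged[f"{col}_b"].fillna(0)
    out = merged[key].copy()
    out["umi_count"] = (merged["umi_count_a"] + merged["umi_count_b"]).astype(int)
    out["hcdr3_count"] = (
        merged["hcdr3_count_a"] + merged["hcdr3_count_b"]
    ).astype(int)
    out["umi_frequency"] = (
        merged["umi_frequency_a"] + merged["umi_frequency_b"]
    ) / 2.0
    out["hcdr3_frequency"] = (
        merged["hcdr3_frequency_a"] + merged["hcdr3_frequency_b"]
    ) / 2.0
    out["primer_set"] = "combined"
    return out[USAGE_COLUMNS]


def collapse_s4953(usage: pd.DataFrame) -> pd.DataFrame:
    """Fold the non-coding *02_S4953 variant into *02 (frequencies add)."""
    out = usage.copy()
    out["allele"] = out["allele"].map(
        lambda a: a.replace("*02_S4953", "*02") if isinstance(a, str) else a
    )
    grouped = (
        out.groupby(["participant_id", "allele", "primer_set"], dropna=False)
        .agg(
            umi_count=("umi_count", "sum"),
            umi_frequency=("umi_frequency", "sum"),
            hcdr3_count=("hcdr3_count", "sum"),
            hcdr3_frequency=("hcdr3_frequency", "sum"),
        )
        .reset_index()
    )
    return grouped[USAGE_COLUMNS]


def ratio_diagnostics(usage: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unique-HCDR3-to-mRNA ratio diagnostics per allele per participant.

    ``count_ratio`` = hcdr3_count / umi_count (a measure of 1/BCR surface
    density) and ``frequency_ratio`` = hcdr3_frequency / umi_frequency.
    Zero denominators yield undefined ratios, which are excluded from the
    summary (logged). Returns ``(per-row ratios, per-allele median/IQR)``.
    """
    rows = usage.copy()
    zero = (rows["umi_count"] == 0) | (rows["umi_frequency"] == 0)
    if zero.any():
        logger.warning("excluding %d rows with zero denominators", int(zero.sum()))
    rows["count_ratio"] = np.where(
        rows["umi_count"] > 0, rows["hcdr3_count"] / rows["umi_count"], np.nan
    )
    rows["frequency_ratio"] = np.where(
        rows["umi_frequency"] > 0,
        rows["hcdr3_frequency"] / rows["umi_frequency"],
        np.nan,
    )
    summary = (
        rows.dropna(subset=["count_ratio"])
        .groupby("allele")
        .agg(
            n=("count_ratio", "size"),
            median_count_ratio=("count_ratio", "median"),
            q1_count_ratio=("count_ratio", lambda s: s.quantile(0.25)),
            q3_count_ratio=("count_ratio", lambda s: s.quantile(0.75)),
            median_frequency_ratio=("frequency_ratio", "median"),
        )
        .reset_index()
    )
    return rows, summary


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and t-distribution CI; zero-width for degenerate variance."""
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(values.mean())
    if n < 2 or np.allclose(values, mean):
        return mean, mean, mean
    se = values.std(ddof=1) / np.sqrt(n)
    tq = stats.t.ppf(0.5 + level / 2, df=n - 1)
    return mean, mean - tq * se, mean + tq * se


def zygosity_stratified_means(
    usage: pd.DataFrame,
    participants: Iterable[Participant],
    value: str = "umi_frequency",
    per_copy: bool = False,
) -> pd.DataFrame:
    """Mean allele usage for homozygotes vs heterozygotes, with t CIs.

    For each allele, participants are stratified by zygosity (2 copies vs
    1); group means carry 95% t-distribution CIs and the homozygote minus
    heterozygote difference is tested with a two-sided Welch t-test of zero
    difference. With ``per_copy=True`` usage is divided by zygosity first
    (per-allele-copy expression, expected equal across strata when usage is
    proportional to zygosity).
    """
    zyg_lookup: dict[tuple[str, str], int] = {}
    for p in participants:
        for allele in set(
            ALLELE_SYNONYMS.get(a, a) for a in (p.allele_1, p.allele_2)
        ):
            zyg_lookup[(p.id, allele)] = p.zygosity(allele)

    def suffix(label: str) -> str:
        # usage tables carry full V calls like "IGHV1-2*02"; genotype tables
        # carry bare allele labels like "*02"
        star = label.find("*")
        return label[star:] if star >= 0 else label

    rows = usage.copy()
    # report genotype-level allele labels (e.g. "*02") in the output
    rows["allele"] = rows["allele"].map(suffix)
    rows["zygosity"] = [
        zyg_lookup.get((pid, allele), 0)
        for pid, allele in zip(rows["participant_id"], rows["allele"])
    ]
    rows = rows[rows["zygosity"] > 0]
    out = []
    for allele, sub in rows.groupby("allele"):
        vals = sub[value].to_numpy(dtype=float)
        if per_copy:
            vals = vals / sub["zygosity"].to_numpy()
        homo = vals[sub["zygosity"] == 2]
        het = vals[sub["zygosity"] == 1]
        rec: dict[str, object] = {"allele": allele, "n_homo": homo.size, "n_het": het.size}
        for name, grp in (("homo", homo), ("het", het)):
            if grp.size:
                m, lo, hi = _t_ci(grp)
                rec[f"mean_{name}"], rec[f"ci_low_{name}"], rec[f"ci_high_{name}"] = m, lo, hi
            else:
                rec[f"mean_{name}"] = rec[f"ci_low_{name}"] = rec[f"ci_high_{name}"] = np.nan
        if homo.size >= 2 and het.size >= 2:
            if np.allclose(homo, homo.mean()) and np.allclose(het, het.mean()):
                rec["difference"] = float(homo.mean() - het.mean())
                rec["p_difference"] = 1.0 if rec["difference"] == 0 else np.nan
                rec["degenerate_variance"] = True
            else:
                res = stats.ttest_ind(homo, het, equal_var=False)
                rec["difference"] = float(homo.mean() - het.mean())
                rec["p_difference"] = float(res.pvalue)
                rec["degenerate_variance"] = False
        else:
            rec["difference"] = (
                float(homo.mean() - het.mean()) if homo.size and het.size else np.nan
            )
            rec["p_difference"] = np.nan
            rec["degenerate_variance"] = False
        out.append(rec)
    return pd.DataFrame(out)
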