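"""UMI/HCDR3 counting, primer-set combination, synonym collapse, ratio
diagnostics, and zygosity-stratified summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from alleleprime.repertoire_quant import (
    allele_usage,
    collapse_s4953,
    combine_primer_sets,
    count_umis_per_allele,
    count_unique_hcdr3,
    ratio_diagnostics,
    zygosity_stratified_means,
)
from alleleprime.synthetic_trial import (
    Participant,
    TrialConfig,
    simulate_repertoire,
    simulate_repertoire_pair,
)


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "umi", "v_call", "v_mismatches", "cdr3_aa",
                 "primer_set"],
    )


class TestCounting:
    def test_duplicate_allele_umi_pairs_count_once(self):
        rec = _records([
            ("s1", "U1", "IGHV1-2*02", 0, "CARX", "leader"),
            ("s2", "U1", "IGHV1-2*02", 0, "CARY", "leader"),
        ])
        counts, total = count_umis_per_allele(rec)
        assert counts["IGHV1-2*02"] == 1 and total == 1

    def test_mutated_records_excluded(self):
        rec = _records([
            ("s1", "U1", "IGHV1-2*02", 2, "CARX", "leader"),
            ("s2", "U2", "IGHV1-2*02", 0, "CARX", "leader"),
        ])
        counts, total = count_umis_per_allele(rec)
        assert counts["IGHV1-2*02"] == 1 and total == 1

    def test_missing_mismatch_annotation_treated_as_mutated(self):
        rec = _records([
            ("s1", "U1", "IGHV1-2*02", None, "CARX", "leader"),
            ("s2", "U2", "IGHV1-2*04", 0, "CARY", "leader"),
        ])
        counts, _ = count_umis_per_allele(rec)
        assert "IGHV1-2*02" not in counts.index

    def test_missing_umi_skipped(self):
        rec = _records([
            ("s1", "", "IGHV1-2*02", 0, "CARX", "leader"),
            ("s2", "U2", "IGHV1-2*02", 0, "CARX", "leader"),
        ])
        counts, total = count_umis_per_allele(rec)
        assert counts["IGHV1-2*02"] == 1

    def test_shared_hcdr3_counts_once_per_allele(self):
        rec = _records(
            [(f"s{i}", f"U{i}", "IGHV1-2*02", 0, "CARSAME", "leader")
             for i in range(5)]
        )
        cdr, _ = count_unique_hcdr3(rec)
        umi, _ = count_umis_per_allele(rec)
        assert cdr["IGHV1-2*02"] == 1 and umi["IGHV1-2*02"] == 5

    def test_empty_hcdr3_excluded(self):
        rec = _records([
            ("s1", "U1", "IGHV1-2*02", 0, "", "leader"),
            ("s2", "U2", "IGHV1-2*02", 0, "CARX", "leader"),
        ])
        cdr, total = count_unique_hcdr3(rec)
        assert cdr["IGHV1-2*02"] == 1 and total == 1

    def test_disjoint_hcdr3_sets_are_additive(self):
        rec = _records([
            ("s1", "U1", "IGHV1-2*02", 0, "CARA", "leader"),
            ("s2", "U2", "IGHV1-2*02", 0, "CARB", "leader"),
            ("s3", "U3", "IGHV1-2*04", 0, "CARC", "leader"),
        ])
        cdr, total = count_unique_hcdr3(rec)
        assert total == cdr.sum() == 3

    def test_counts_match_generator_truth(self, config, het_participant):
        """Synthetic library with known composition: counts equal the
        generator's own bookkeeping."""
        rep = simulate_repertoire(het_participant, config, "leader")
        counts, total = count_umis_per_allele(rep)
        truth = rep.groupby("v_call")["umi"].nunique()
        assert total == config.n_total_umis
        for allele in truth.index:
            assert counts[allele] == truth[allele]


class TestUsageAndCombination:
    def test_frequency_is_count_over_library_total(self):
        rec = _records(
            [(f"s{i}", f"U{i}", "IGHV1-2*02", 0, f"C{i}", "leader")
             for i in range(3)]
            + [(f"t{i}", f"W{i}", "IGHVother*01", 0, f"D{i}", "leader")
               for i in range(97)]
        )
        usage = allele_usage(rec, participant_id="P1", primer_set="leader")
        row = usage.set_index("allele").loc["IGHV1-2*02"]
        assert row["umi_frequency"] == pytest.approx(0.03)

    def test_combined_frequency_is_mean_of_primer_sets(self):
        a = pd.DataFrame({
            "participant_id": ["P1"], "allele": ["IGHV1-2*02"],
            "umi_count": [20], "umi_frequency": [0.02],
            "hcdr3_count": [5], "hcdr3_frequency": [0.02],
            "primer_set": ["leader"],
        })
        b = a.assign(umi_frequency=0.04, hcdr3_frequency=0.04,
                     primer_set="5utr")
        comb = combine_primer_sets(a, b)
        assert comb["umi_frequency"].iloc[0] == pytest.approx(0.03)
        assert comb["hcdr3_frequency"].iloc[0] == pytest.approx(0.03)

    @given(
        fa=st.floats(0, 0.5), fb=st.floats(0, 0.5),
        fs=st.floats(0, 0.2), ft=st.floats(0, 0.2),
    )
    @settings(max_examples=50, deadline=None)
    def test_combine_and_collapse_commute(self, fa, fb, fs, ft):
        """Sum of means equals mean of sums: collapsing *02_S4953 into *02
        before or after combining primer sets gives the same usage."""
        def usage(f02, fs49, pset):
            return pd.DataFrame({
                "participant_id": ["P1", "P1"],
                "allele": ["IGHV1-2*02", "IGHV1-2*02_S4953"],
                "umi_count": [10, 10], "umi_frequency": [f02, fs49],
                "hcdr3_count": [2, 2], "hcdr3_frequency": [f02, fs49],
                "primer_set": [pset, pset],
            })
        a, b = usage(fa, fs, "leader"), usage(fb, ft, "5utr")
        path1 = collapse_s4953(combine_primer_sets(a, b))
        path2 = combine_primer_sets(collapse_s4953(a), collapse_s4953(b))
        v1 = path1.set_index("allele")["umi_frequency"]
        v2 = path2.set_index("allele")["umi_frequency"]
        assert v1["IGHV1-2*02"] == pytest.approx(v2["IGHV1-2*02"], abs=1e-12)

    def test_collapse_is_identity_without_s4953(self):
        a = pd.DataFrame({
            "participant_id": ["P1"], "allele": ["IGHV1-2*04"],
            "umi_count": [7], "umi_frequency": [0.007],
            "hcdr3_count": [2], "hcdr3_frequency": [0.008],
            "primer_set": ["combined"],
        })
        out = collapse_s4953(a)
        assert out["umi_frequency"].iloc[0] == pytest.approx(0.007)
        assert list(out["allele"]) == ["IGHV1-2*04"]

    def test_collapse_conserves_totals(self):
        a = pd.DataFrame({
            "participant_id": ["P1"] * 2,
            "allele": ["IGHV1-2*02", "IGHV1-2*02_S4953"],
            "umi_count": [20, 10], "umi_frequency": [0.02, 0.01],
            "hcdr3_count": [4, 2], "hcdr3_frequency": [0.02, 0.01],
            "primer_set": ["combined"] * 2,
        })
        out = collapse_s4953(a)
        assert out["umi_frequency"].sum() == pytest.approx(0.03)
        assert set(out["allele"]) == {"IGHV1-2*02"}


class TestRatios:
    def test_count_ratio_direct(self):
        usage = pd.DataFrame({
            "participant_id": ["P1"], "allele": ["IGHV1-2*02"],
            "umi_count": [100], "umi_frequency": [0.03],
            "hcdr3_count": [23], "hcdr3_frequency": [0.03],
            "primer_set": ["combined"],
        })
        rows, _ = ratio_diagnostics(usage)
        assert rows["count_ratio"].iloc[0] == pytest.approx(0.23)
        assert rows["frequency_ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_excluded(self):
        usage = pd.DataFrame({
            "participant_id": ["P1"], "allele": ["IGHV1-2*05"],
            "umi_count": [0], "umi_frequency": [0.0],
            "hcdr3_count": [0], "hcdr3_frequency": [0.0],
            "primer_set": ["combined"],
        })
        rows, summary = ratio_diagnostics(usage)
        assert np.isnan(rows["count_ratio"].iloc[0])
        assert summary.empty

    def test_median_ratio_recovers_thinning_parameter(self):
        """Across simulated participants the median unique-HCDR3-to-mRNA
        count ratio recovers the configured thinning rate 0.23."""
        cfg = TrialConfig(seed=13, n_total_umis=5_000)
        rows = []
        for i in range(12):
            p = Participant(f"P{i}", "low", "*02", "*04")
            rep = simulate_repertoire(p, cfg, "leader",
                                      rng=np.random.default_rng(100 + i))
            rows.append(allele_usage(rep, primer_set="leader"))
        usage = pd.concat(rows, ignore_index=True)
        ratios, summary = ratio_diagnostics(usage)
        med = summary.set_index("allele").loc["IGHV1-2*02",
                                              "median_count_ratio"]
        assert med == pytest.approx(cfg.hcdr3_ratio, abs=0.02)


class TestZygosityStrata:
    @staticmethod
    def _usage_frame(values):
        rows = []
        for pid, freq in values.items():
            rows.append({
                "participant_id": pid, "allele": "IGHV1-2*02",
                "umi_count": 100, "umi_frequency": freq,
                "hcdr3_count": 23, "hcdr3_frequency": freq,
                "primer_set": "combined",
            })
        return pd.DataFrame(rows)

    def test_identical_values_give_zero_width_ci_and_difference(self):
        participants = [
            Participant("A", "low", "*02", "*02"),
            Participant("B", "low", "*02", "*02"),
            Participant("C", "low", "*02", "*04"),
            Participant("D", "low", "*02", "*04"),
        ]
        usage = self._usage_frame({"A": 0.06, "B": 0.06, "C": 0.06, "D": 0.06})
        out = zygosity_stratified_means(usage, participants)
        row = out.set_index("allele").loc["*02"]
        assert row["ci_low_homo"] == row["ci_high_homo"] == 0.06
        assert row["difference"] == 0.0
        assert row["degenerate_variance"]

    def test_ci_matches_textbook_t_formula(self):
        """Hand-computed three-value t interval oracle."""
        participants = [
            Participant(p, "low", "*02", "*02") for p in ("A", "B", "C")
        ]
        vals = {"A": 0.05, "B": 0.06, "C": 0.07}
        usage = self._usage_frame(vals)
        out = zygosity_stratified_means(usage, participants)
        row = out.set_index("allele").loc["*02"]
        x = np.array([0.05, 0.06, 0.07])
        half = stats.t.ppf(0.975, 2) * x.std(ddof=1) / np.sqrt(3)
        assert row["mean_homo"] == pytest.approx(0.06)
        assert row["ci_low_homo"] == pytest.approx(0.06 - half)
        assert row["ci_high_homo"] == pytest.approx(0.06 + half)

    def test_simulated_two_to_one_homo_het_usage_recovered(self):
        """Generator truth: homozygote usage is about twice heterozygote
        usage, and per-copy usage is equal across strata."""
        cfg = TrialConfig(seed=19, n_total_umis=5_000)
        participants = [
            Participant(f"HO{i}", "low", "*02", "*02") for i in range(6)
        ] + [Participant(f"HE{i}", "low", "*02", "*04") for i in range(6)]
        frames = []
        rng = np.random.default_rng(19)
        for p in participants:
            rep = simulate_repertoire(p, cfg, "leader", rng)
            frames.append(allele_usage(rep, primer_set="leader"))
        usage = pd.concat(frames, ignore_index=True)
        out = zygosity_stratified_means(usage, participants).set_index("allele")
        row = out.loc["*02"]
        assert row["mean_homo"] / row["mean_het"] == pytest.approx(2.0, rel=0.15)
        per_copy = zygosity_stratified_means(
            usage, participants, per_copy=True
        ).set_index("allele").loc["*02"]
        assert per_copy["mean_homo"] == pytest.approx(
            per_copy["mean_het"], rel=0.15
        )
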