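"""TPM normalization, diversity, rarefaction, DTE and the DTU rules."""

import numpy as np
import pandas as pd
import pytest

from isokit import expression_dtu as ed
from isokit import synthetic_data as sd
from isokit.models import ValidationError

from _oracles import oracle_ranksum_p


class TestTpm:
    def test_simple_proportions(self):
        counts = pd.DataFrame({"s1": [1, 1, 2]}, index=["a", "b", "c"])
        tpm = ed.tpm_normalize(counts)
        assert list(tpm["s1"]) == [250000.0, 250000.0, 500000.0]

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(80, 6)) + 1)
        tpm = ed.tpm_normalize(counts)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, size=(20, 3)))
        assert np.allclose(ed.tpm_normalize(counts), ed.tpm_normalize(counts * 7))

    def test_zero_total_column_names_the_sample(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValidationError, match="empty"):
            ed.tpm_normalize(counts)


class TestGeneAggregate:
    def classification(self):
        return pd.DataFrame(
            {
                "transcript_id": ["t1", "t2", "t3", "t4"],
                "category": ["FSM", "NIC", "genic_genomic", "fusion"],
                "associated_genes": ["G1", "G1", "G1", "G1;G2"],
                "n_exons": [3, 2, 1, 5],
            }
        )

    def test_multiexonic_sum(self):
        counts = pd.DataFrame({"s": [5, 7, 7, 9]}, index=["t1", "t2", "t3", "t4"])
        out = ed.gene_aggregate(counts, self.classification())
        assert out.loc["G1", "s"] == 12  # mono-exonic t3 and fusion t4 excluded

    def test_monoexonic_kept_when_flag_off(self):
        counts = pd.DataFrame({"s": [5, 7, 7, 9]}, index=["t1", "t2", "t3", "t4"])
        out = ed.gene_aggregate(counts, self.classification(), drop_monoexonic=False)
        assert out.loc["G1", "s"] == 19

    def test_unclassified_transcript_is_an_error(self):
        counts = pd.DataFrame({"s": [1]}, index=["unknown"])
        with pytest.raises(ValidationError):
            ed.gene_aggregate(counts, self.classification())


class TestDiversity:
    def test_correlations_match_textbook_formula(self):
        rng = np.random.default_rng(2)
        rows = []
        for g in range(100):
            n_iso = int(rng.integers(1, 12))
            length = int(rng.integers(500, 50000))
            n_ex = int(rng.integers(2, 30))
            for i in range(n_iso):
                rows.append(
                    {
                        "transcript_id": f"g{g}.t{i}",
                        "category": "FSM",
                        "associated_genes": f"G{g}",
                        "length": length - i,  # longest is the first
                        "n_exons": n_ex,
                    }
                )
        cls = pd.DataFrame(rows)
        out = ed.diversity_stats(cls)
        per_gene = out["per_gene"]
        x = per_gene["n_isoforms"].to_numpy(float)
        y = np.log10(per_gene["length"].to_numpy(float))
        r_manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out["corr_length"] == pytest.approx(r_manual, abs=1e-12)

    def test_constant_vector_gives_absent_correlation(self):
        cls = pd.DataFrame(
            {
                "transcript_id": ["a", "b", "c"],
                "category": ["FSM"] * 3,
                "associated_genes": ["G1", "G2", "G3"],
                "length": [100, 200, 300],
                "n_exons": [2, 3, 4],
            }
        )
        out = ed.diversity_stats(cls)  # isoform count constant at 1
        assert out["corr_length"] is None

    def test_isoform_count_rows(self):
        cls = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(15)],
                "category": ["FSM"] * 15,
                "associated_genes": ["G1"] * 12 + ["G2", "G2", "G3"],
                "length": range(100, 1600, 100),
                "n_exons": [2] * 15,
            }
        )
        out = ed.diversity_stats(cls)
        assert out["genes_gt1_isoform"] == 2
        assert out["genes_gt10_isoforms"] == 1


class TestRarefaction:
    def test_full_depth_returns_all_features_and_zero_depth_none(self):
        labels = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        curve = ed.rarefaction(labels, [0, 10], reps=5, seed=0)
        assert curve.mean_unique[0] == 0.0
        assert curve.mean_unique[1] == 3.0

    def test_mean_curve_non_decreasing(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in rng.integers(0, 50, size=400)]
        depths = [0, 50, 100, 200, 400]
        curve = ed.rarefaction(labels, depths, reps=30, seed=1)
        assert all(a <= b + 1e-9 for a, b in zip(curve.mean_unique, curve.mean_unique[1:]))

    def test_matches_hypergeometric_closed_form(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 30, size=40)
        labels = np.repeat([f"t{i}" for i in range(len(counts))], counts)
        total = int(counts.sum())
        reps = 300
        depths = [total // 10, total // 3, total // 2, total]
        curve = ed.rarefaction(labels, depths, reps=reps, seed=2)
        for d, mean, sdev in zip(curve.depths, curve.mean_unique, curve.sd_unique):
            expect = ed.rarefaction_expectation(counts, d)
            se = sdev / np.sqrt(reps)
            assert abs(mean - expect) <= max(3 * se, 1e-9), (d, mean, expect)

    def test_depth_beyond_total_is_an_error(self):
        with pytest.raises(ValidationError):
            ed.rarefaction(["a", "b"], [3], reps=2, seed=0)


class TestWilcoxon:
    def test_complete_separation_small_n_exact(self):
        p = ed.wilcoxon_rank_sum([1, 2, 3, 4], [10, 11, 12])
        assert p == pytest.approx(2 / 35, abs=1e-15)

    def test_identical_groups_give_p_one(self):
        counts = pd.DataFrame(
            {"a1": [5.0], "a2": [7.0], "b1": [5.0], "b2": [7.0]}, index=["t"]
        )
        dte = ed.dte_wilcoxon(counts, ["a1", "a2"], ["b1", "b2"])
        assert dte.loc["t", "p_value"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            vals = rng.permutation(1000)[: n + m].astype(float)
            a, b = vals[:n], vals[n:]
            assert ed.wilcoxon_rank_sum(a, b) == pytest.approx(
                oracle_ranksum_p(a, b), abs=1e-12
            )

    def test_degenerate_group_size_is_an_error(self):
        with pytest.raises(ValidationError):
            ed.wilcoxon_rank_sum([1.0], [2.0, 3.0])


class TestDtuRules:
    def dte_frame(self, rows):
        return pd.DataFrame(rows).set_index("transcript_id")

    def test_opposite_switch_called(self):
        dte = self.dte_frame(
            [
                {"transcript_id": "t1", "mean_a": 50.0, "mean_b": 0.0, "p_value": 0.01, "direction": 1},
                {"transcript_id": "t2", "mean_a": 0.0, "mean_b": 60.0, "p_value": 0.01, "direction": -1},
            ]
        )
        calls = ed.dtu_fetal_adult(dte, {"t1": "G", "t2": "G"})
        assert [c.gene_id for c in calls] == ["G"]

    def test_single_significant_transcript_not_called(self):
        dte = self.dte_frame(
            [
                {"transcript_id": "t1", "mean_a": 50.0, "mean_b": 0.0, "p_value": 0.01, "direction": 1},
                {"transcript_id": "t2", "mean_a": 0.0, "mean_b": 60.0, "p_value": 0.5, "direction": -1},
            ]
        )
        assert ed.dtu_fetal_adult(dte, {"t1": "G", "t2": "G"}) == []

    def test_delta_tpm_threshold_is_strict(self):
        dte = self.dte_frame(
            [
                {"transcript_id": "t1", "mean_a": 10.0, "mean_b": 0.0, "p_value": 0.01, "direction": 1},
                {"transcript_id": "t2", "mean_a": 0.0, "mean_b": 60.0, "p_value": 0.01, "direction": -1},
            ]
        )
        # t1's difference of 10 <= 20 TPM: no call
        assert ed.dtu_fetal_adult(dte, {"t1": "G", "t2": "G"}) == []

    def test_region_pair_flag_thresholds(self):
        tpm = pd.DataFrame(
            {"ra": [100.0, 30.0, 28.0], "rb": [20.0, 10.0, 1.0]},
            index=["t1", "t2", "t3"],
        )
        flags = ed.region_pair_flags(tpm, ["ra"], ["rb"])
        # (100+1)/(20+1) = 4.81, delta 80 -> flagged
        assert bool(flags.loc["t1", "flagged"])
        # (30+1)/(10+1) = 2.8 -> not flagged
        assert not bool(flags.loc["t2", "flagged"])
        # (28+1)/(1+1) = 14.5, delta 27 -> flagged
        assert bool(flags.loc["t3", "flagged"])

    def test_region_pair_gene_call_needs_opposite_directions(self):
        tpm = pd.DataFrame(
            {"ra": [100.0, 1.0], "rb": [2.0, 90.0]}, index=["t1", "t2"]
        )
        _, calls = ed.dtu_region_pair(tpm, {"t1": "G", "t2": "G"}, ["ra"], ["rb"])
        assert [c.gene_id for c in calls] == ["G"]


class TestGroupSpecific:
    def test_detection_mode(self):
        counts = pd.DataFrame(
            {
                "f1": [3, 0, 0],
                "f2": [2, 0, 0],
                "a1": [0, 5, 1],
                "a2": [0, 6, 0],
                "a3": [0, 7, 2],
            },
            index=["fetal_only", "adult_only", "mixed"],
        )
        out = ed.group_specific_transcripts(
            counts, {"fetal": ["f1", "f2"], "adult": ["a1", "a2", "a3"]}
        )
        assert out["fetal"] == ["fetal_only"]
        assert out["adult"] == ["adult_only"]

    def test_tpm_threshold_mode(self):
        counts = pd.DataFrame(
            {"c1": [900, 50, 50], "h1": [30, 940, 30], "s1": [20, 30, 950]},
            index=["cortex_t", "hippo_t", "striatum_t"],
        )
        out = ed.group_specific_transcripts(
            counts,
            {"cortex": ["c1"], "hippocampus": ["h1"], "striatum": ["s1"]},
            mode="tpm_threshold",
            tpm_min=500000,
        )
        assert out["cortex"] == ["cortex_t"]
        assert out["striatum"] == ["striatum_t"]


class TestCrossDataset:
    def test_identity_comparison(self):
        a = {"G1": 3, "G2": 7, "G3": 1}
        out = ed.cross_dataset_compare(a, dict(a))
        assert out["correlation"] == pytest.approx(1.0)
        assert out["table"]["absolute_diff"].sum() == 0

    def test_relative_and_absolute_differences(self):
        # 12 vs 1 isoforms: relative 12; 5 vs 86: absolute 81
        a = {"LPAR2": 12, "SORBS1": 5, "X": 4}
        b = {"Lpar2": 1, "Sorbs1": 86, "Xm": 4}
        out = ed.cross_dataset_compare(
            a, b, homolog_map={"Lpar2": "LPAR2", "Sorbs1": "SORBS1", "Xm": "X"}
        )
        tbl = out["table"]
        assert tbl.loc["LPAR2", "relative_diff"] == pytest.approx(12.0)
        assert tbl.loc["SORBS1", "absolute_diff"] == pytest.approx(81.0)
        assert out["top_relative"].index[0] == "SORBS1" or tbl.loc["SORBS1", "relative_diff"] > 12

    def test_non_unique_homologs_dropped_and_empty_join_errors(self):
        a = {"G1": 2}
        b = {"m1": 3, "m2": 4}
        with pytest.raises(ValidationError):
            ed.cross_dataset_compare(a, b, homolog_map={"m1": "G1", "m2": "G1"})
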