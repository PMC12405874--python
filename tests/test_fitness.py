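"""Normalization, FD scoring, robust CV, best-tag selection, combination."""

import numpy as np
import pandas as pd
import pytest

import barseqkit as bk
from barseqkit.fitness import write_fd_table

from conftest import toy_counts


class TestNormalize:
    def test_equal_counts_give_quarter_million(self):
        counts = pd.DataFrame(
            {"S1": [5, 5, 5, 5]},
            index=pd.MultiIndex.from_tuples(
                [(f"s{i}", "uptag") for i in range(4)],
                names=["strain_id", "tag_class"],
            ),
        )
        norm = bk.normalize(counts, pseudocount=2.0)
        assert (norm.values["S1"] == 250_000 + 2.0).all()

    def test_scale_invariance(self):
        counts = toy_counts({"S1": [3, 9, 1, 7]})
        a = bk.normalize(counts, 0.5).values
        b = bk.normalize(counts * 10, 0.5).values
        pd.testing.assert_frame_equal(a, b)

    def test_mixed_column_hand_computed(self):
        counts = toy_counts({"S1": [10, 30, 20, 40]})
        norm = bk.normalize(counts, 1.0).values["S1"]
        total = 100
        for (sid, cls), count in counts["S1"].items():
            assert norm[(sid, cls)] == pytest.approx(count / total * 1e6 + 1.0)

    def test_zero_depth_column_rejected(self):
        counts = toy_counts({"S1": [0, 0, 0, 0]})
        with pytest.raises(ValueError):
            bk.normalize(counts)


class TestFdScores:
    def test_treatment_equal_control_gives_zero(self, small_sheet):
        counts = toy_counts(
            {s: [10, 20, 30, 40] for s in ("T1", "T2", "C1", "C2")}
        )
        prof = bk.fd_scores(bk.normalize(counts, 0.0), small_sheet, "drug")
        assert np.allclose(prof.fd[["fd_uptag", "fd_downtag"]], 0.0)

    def test_fourfold_depletion_is_fd_two(self, small_sheet):
        # equal depth; strain s0's uptag has 400 in control, 100 treated
        counts = toy_counts(
            {
                "T1": [100, 700, 100, 100],
                "T2": [100, 700, 100, 100],
                "C1": [400, 400, 100, 100],
                "C2": [400, 400, 100, 100],
            }
        )
        prof = bk.fd_scores(bk.normalize(counts, 0.0), small_sheet, "drug")
        assert prof.fd.loc["s0", "fd_uptag"] == pytest.approx(2.0)

    def test_replicates_with_unequal_depth_hand_computed(self, small_sheet):
        counts = toy_counts(
            {
                "T1": [10, 30, 20, 40],
                "T2": [30, 50, 10, 110],  # double depth
                "C1": [40, 20, 30, 10],
                "C2": [50, 70, 40, 40],  # double depth
            }
        )
        norm = bk.normalize(counts, 1.0)
        prof = bk.fd_scores(norm, small_sheet, "drug")
        v = norm.values
        for key in counts.index:
            expected = np.log2(v.loc[key, ["C1", "C2"]].mean()) - np.log2(
                v.loc[key, ["T1", "T2"]].mean()
            )
            cls = key[1]
            assert prof.fd.loc[key[0], f"fd_{cls}"] == pytest.approx(expected)

    def test_unknown_condition_raises(self, small_sheet):
        counts = toy_counts({s: [1, 2, 3, 4] for s in ("T1", "T2", "C1", "C2")})
        with pytest.raises(KeyError):
            bk.fd_scores(bk.normalize(counts), small_sheet, "nonexistent")

    def test_antisymmetry_under_label_swap(self, small_sheet):
        rng = np.random.default_rng(3)
        counts = toy_counts(
            {s: rng.integers(10, 1000, 8).tolist()
             for s in ("T1", "T2", "C1", "C2")}
        )
        norm = bk.normalize(counts, 1.0)
        fwd = bk.fd_scores(norm, small_sheet, "drug")
        swapped_sheet = bk.SampleSheet(
            small_sheet.table.assign(
                role=small_sheet.table["role"].map(
                    {"treatment": "control", "control": "treatment"}
                ),
                condition=small_sheet.table["role"].map(
                    {"treatment": "ctrl", "control": "drug"}
                ),
            )
        )
        rev = bk.fd_scores(norm, swapped_sheet, "drug")
        assert np.allclose(
            fwd.fd[["fd_uptag", "fd_downtag"]],
            -rev.fd[["fd_uptag", "fd_downtag"]],
        )

    def test_depth_invariance_at_zero_pseudocount(self, small_sheet):
        rng = np.random.default_rng(4)
        counts = toy_counts(
            {s: rng.integers(10, 1000, 8).tolist()
             for s in ("T1", "T2", "C1", "C2")}
        )
        scaled = counts.copy()
        scaled["T1"] *= 7
        scaled["C2"] *= 3
        a = bk.fd_scores(bk.normalize(counts, 0.0), small_sheet, "drug")
        b = bk.fd_scores(bk.normalize(scaled, 0.0), small_sheet, "drug")
        assert np.allclose(a.fd["fd_uptag"], b.fd["fd_uptag"])
        assert np.allclose(a.fd["fd_downtag"], b.fd["fd_downtag"])


class TestRobustCv:
    def test_constant_vector_is_zero(self):
        assert bk.robust_cv([7.0, 7.0, 7.0]) == 0.0

    def test_single_outlier_has_zero_mad(self):
        # MAD of {0, 0, 0, 90} is 0, so the outlier vanishes
        assert bk.robust_cv([10, 10, 10, 100]) == 0.0

    def test_hand_computed_example(self):
        # median 11, |dev| = [3, 1, 1, 3], MAD 2 -> 1.4826*2/11
        assert bk.robust_cv([8, 10, 12, 14]) == pytest.approx(1.4826 * 2 / 11)

    def test_errors(self):
        with pytest.raises(ValueError):
            bk.robust_cv([5.0])
        with pytest.raises(ValueError):
            bk.robust_cv([-2.0, -1.0, 0.0])


class TestBestTag:
    def test_steady_uptag_beats_noisy_downtag(self, small_sheet):
        counts = toy_counts(
            {
                "T1": [100, 100, 100, 100],
                "T2": [100, 100, 100, 100],
                "C1": [100, 100, 10, 100],
                "C2": [100, 100, 400, 100],
            }
        )
        best = bk.select_best_tag(bk.normalize(counts, 1.0), small_sheet)
        assert best.loc["s0", "chosen_class"] == "uptag"
        assert best.loc["s0", "rcv_uptag"] < best.loc["s0", "rcv_downtag"]

    def test_uptag_only_strain_chooses_uptag(self, small_sheet):
        idx = pd.MultiIndex.from_tuples(
            [("s0", "uptag"), ("s1", "uptag"), ("s1", "downtag")],
            names=["strain_id", "tag_class"],
        )
        counts = pd.DataFrame(
            {s: [50, 100, 100] for s in ("T1", "T2", "C1", "C2")}, index=idx
        )
        best = bk.select_best_tag(bk.normalize(counts, 1.0), small_sheet)
        assert best.loc["s0", "chosen_class"] == "uptag"
        assert pd.isna(best.loc["s0", "rcv_downtag"])

    def test_tie_breaks_to_uptag(self, small_sheet):
        counts = toy_counts({s: [100, 100, 100, 100] for s in
                             ("T1", "T2", "C1", "C2")})
        best = bk.select_best_tag(bk.normalize(counts, 1.0), small_sheet)
        assert (best["chosen_class"] == "uptag").all()

    def test_needs_two_controls(self, small_sheet):
        counts = toy_counts({s: [1, 2, 3, 4] for s in ("T1", "T2", "C1", "C2")})
        one_ctrl = bk.SampleSheet(
            small_sheet.table[small_sheet.table["sample_id"] != "C2"]
        )
        with pytest.raises(ValueError):
            bk.select_best_tag(bk.normalize(counts), one_ctrl)


class TestCombine:
    def _profile(self, small_sheet, counts):
        norm = bk.normalize(counts, 1.0)
        return norm, bk.fd_scores(norm, small_sheet, "drug")

    def test_agreeing_tags_agree_under_all_modes(self, small_sheet):
        counts = toy_counts(
            {
                "T1": [100, 300, 100, 300],
                "T2": [100, 300, 100, 300],
                "C1": [283, 300, 283, 300],  # ~FD 1.5 for s0 both tags
                "C2": [283, 300, 283, 300],
            }
        )
        norm, prof = self._profile(small_sheet, counts)
        best = bk.select_best_tag(norm, small_sheet)
        for mode in ("best_tag", "mean", "sum"):
            combined = bk.combine_tags(
                prof, mode=mode, best=best, counts=counts, sheet=small_sheet,
                pseudocount=1.0,
            ).combined
            up = prof.fd.loc["s0", "fd_uptag"]
            assert combined["s0"] == pytest.approx(up, abs=0.02)

    def test_best_vs_mean_arithmetic(self, small_sheet):
        fd = pd.DataFrame(
            {"fd_uptag": [2.0], "fd_downtag": [0.0]}, index=["s0"]
        )
        prof = bk.FitnessProfile("drug", fd)
        best = pd.DataFrame(
            {"chosen_class": ["uptag"], "rcv_uptag": [0.1], "rcv_downtag": [0.5]},
            index=["s0"],
        )
        assert bk.combine_tags(prof, "best_tag", best=best).combined["s0"] == 2.0
        assert bk.combine_tags(prof, "mean").combined["s0"] == 1.0

    def test_sum_mode_equals_pseudo_strain_oracle(self, small_sheet):
        rng = np.random.default_rng(9)
        counts = toy_counts(
            {s: rng.integers(50, 500, 8).tolist()
             for s in ("T1", "T2", "C1", "C2")}
        )
        norm, prof = self._profile(small_sheet, counts)
        combined = bk.combine_tags(
            prof, mode="sum", counts=counts, sheet=small_sheet, pseudocount=1.0
        ).combined
        # oracle: build the summed pseudo-strain matrix by hand, rescore
        summed = counts.groupby(level="strain_id").sum()
        summed.index = pd.MultiIndex.from_product(
            [summed.index, ["uptag"]], names=["strain_id", "tag_class"]
        )
        oracle = bk.fd_scores(
            bk.normalize(summed, 1.0), small_sheet, "drug"
        ).fd["fd_uptag"]
        assert np.allclose(combined.sort_index(), oracle.sort_index())

    def test_single_tag_passes_through_mean(self):
        fd = pd.DataFrame(
            {"fd_uptag": [1.5], "fd_downtag": [np.nan]}, index=["s0"]
        )
        assert bk.combine_tags(
            bk.FitnessProfile("d", fd), "mean"
        ).combined["s0"] == 1.5

    def test_best_tag_requires_table(self):
        fd = pd.DataFrame({"fd_uptag": [1.0], "fd_downtag": [2.0]}, index=["s0"])
        with pytest.raises(ValueError):
            bk.combine_tags(bk.FitnessProfile("d", fd), "best_tag")

    def test_best_tag_null_noise_not_worse_than_mean(self):
        """With one noisy tag class, best-tag FDs on null (control vs
        control) comparisons should be no noisier than mean-combined."""
        cfg = bk.SimConfig(
            n_strains=400, fraction_affected=0.0,
            replicate_efficiency_sigma=(0.0, 0.6),
            depth_per_sample=400_000, fraction_uptag_only=0.0, seed=21,
        )
        truth = bk.simulate_abundances(cfg)
        samples = [(f"C{i}", "control") for i in range(1, 5)]
        counts = bk.simulate_counts(truth, cfg, samples)
        sheet = bk.SampleSheet(pd.DataFrame([
            {"sample_id": f"C{i}", "condition": "null_a" if i <= 2 else "ctrl",
             "role": "treatment" if i <= 2 else "control",
             "replicate": i, "assay": "HOP", "generations": 5.0}
            for i in range(1, 5)
        ]))
        norm = bk.normalize(counts, 1.0)
        prof = bk.fd_scores(norm, sheet, "null_a")
        best = bk.select_best_tag(norm, sheet)
        fd_best = bk.combine_tags(prof, "best_tag", best=best).combined
        fd_mean = bk.combine_tags(prof, "mean").combined
        mad = lambda x: float(np.median(np.abs(x - np.median(x))))
        assert mad(fd_best.dropna()) <= mad(fd_mean.dropna()) * 1.05


def test_fd_table_round_trip(tmp_path, small_sheet):
    counts = toy_counts({s: [10, 20, 30, 40] for s in ("T1", "T2", "C1", "C2")})
    norm = bk.normalize(counts, 1.0)
    prof = bk.combine_tags(bk.fd_scores(norm, small_sheet, "drug"), "mean")
    path = tmp_path / "fd.tsv"
    write_fd_table(prof, path)
    loaded = pd.read_csv(path, sep="\t", index_col=0)
    assert list(loaded.columns) == ["fd_uptag", "fd_downtag", "fd_combined"]
    assert np.allclose(loaded["fd_combined"], prof.combined)
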