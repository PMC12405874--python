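"""Simulator determinism, conservation laws, and closed-form agreement."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import barseqkit as bk
from barseqkit.simulate import expected_shares


class TestAbundances:
    def test_neutral_pool_identical_arms(self):
        cfg = bk.SimConfig(n_strains=50, fraction_affected=0.0, seed=1)
        truth = bk.simulate_abundances(cfg)
        assert np.allclose(truth.abundance_control, truth.abundance_treated)
        assert np.allclose(truth.true_fd, 0.0)

    def test_abundances_sum_to_one(self):
        cfg = bk.SimConfig(n_strains=200, fraction_affected=0.2, seed=2)
        truth = bk.simulate_abundances(cfg)
        assert truth.abundance_control.sum() == pytest.approx(1.0, abs=1e-9)
        assert truth.abundance_treated.sum() == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_fd_for_rare_affected_strain(self):
        """One strain at s=0.03 over g=20 in a large neutral pool: its
        FD approaches the closed form g*s = 0.6 as the affected
        fraction shrinks (renormalization correction -> 0)."""
        n = 2000
        s = np.zeros(n)
        s[0] = 0.03
        cfg = bk.SimConfig(
            n_strains=n, assay="HIP", fitness_coefficients=tuple(s),
            initial_abundance_sigma=0.0, seed=3,
        )
        truth = bk.simulate_abundances(cfg)
        assert truth.true_fd[0] == pytest.approx(0.6, abs=2e-3)
        # and the exact identity: fd_i - fd_j = g*(s_i - s_j) for any pair
        assert truth.true_fd[0] - truth.true_fd[1] == pytest.approx(0.6)

    def test_fd_differences_exact_in_general(self):
        cfg = bk.SimConfig(n_strains=100, fraction_affected=0.3, seed=4)
        truth = bk.simulate_abundances(cfg)
        diff = truth.true_fd - cfg.g * truth.s
        assert np.allclose(diff, diff[0])  # common renormalization shift

    def test_super_unity_coefficient_rejected(self):
        cfg = bk.SimConfig(
            n_strains=3, fitness_coefficients=(0.0, 0.5, 1.2), seed=5
        )
        with pytest.raises(ValueError):
            bk.simulate_abundances(cfg)


class TestCounts:
    def test_depth_conservation_exact(self):
        cfg = bk.SimConfig(n_strains=100, depth_per_sample=10_001, seed=6)
        truth = bk.simulate_abundances(cfg)
        counts = bk.simulate_counts(truth, cfg, [("A", "control"), ("B", "treatment")])
        assert (counts.sum(axis=0) == 10_001).all()

    def test_uniform_expectation_with_zero_sigmas(self):
        cfg = bk.SimConfig(
            n_strains=10, fraction_affected=0.0, initial_abundance_sigma=0.0,
            tag_efficiency_sigma=0.0, fraction_uptag_only=0.0,
            depth_per_sample=100_000, seed=7,
        )
        truth = bk.simulate_abundances(cfg)
        shares = expected_shares(truth, "control", "uptag")
        assert np.allclose(shares, 0.1)
        counts = bk.simulate_counts(truth, cfg, [("A", "control")])
        up = counts["A"].xs("uptag", level="tag_class")
        assert up.sum() == 50_000
        assert (abs(up - 5000) < 5 * np.sqrt(5000)).all()

    def test_uptag_only_strains_emit_no_downtag(self):
        cfg = bk.SimConfig(n_strains=50, fraction_uptag_only=0.2, seed=8)
        truth = bk.simulate_abundances(cfg)
        counts = bk.simulate_counts(truth, cfg, [("A", "control")])
        down = counts["A"].xs("downtag", level="tag_class")
        only = {s for s, o in zip(truth.strain_ids, truth.uptag_only) if o}
        assert only.isdisjoint(down.index)
        assert len(down) == 50 - len(only)

    def test_determinism_bitwise(self):
        cfg = bk.SimConfig(n_strains=60, seed=9)
        a = bk.simulate_counts(bk.simulate_abundances(cfg), cfg, [("A", "control")])
        b = bk.simulate_counts(bk.simulate_abundances(cfg), cfg, [("A", "control")])
        pd.testing.assert_frame_equal(a, b)

    def test_infinite_depth_limit_recovers_g_s(self, small_sheet):
        """Using expected shares directly (no sampling) with all sigmas
        zero, the pipeline FD equals the planted true FD to 1e-9."""
        n = 500
        s = np.zeros(n)
        s[:10] = 0.03
        cfg = bk.SimConfig(
            n_strains=n, assay="HIP", fitness_coefficients=tuple(s),
            initial_abundance_sigma=0.0, tag_efficiency_sigma=0.0,
            fraction_uptag_only=0.0, seed=10,
        )
        truth = bk.simulate_abundances(cfg)
        idx = pd.MultiIndex.from_tuples(
            [(sid, cls) for cls in ("uptag", "downtag")
             for sid in truth.strain_ids],
            names=["strain_id", "tag_class"],
        )
        cols = {}
        for sample, role in [("T1", "treatment"), ("T2", "treatment"),
                             ("C1", "control"), ("C2", "control")]:
            p = expected_shares(truth, role, "uptag")
            cols[sample] = np.concatenate([p, p]) * 1e6  # expected counts
        counts = pd.DataFrame(cols, index=idx).sort_index()
        prof = bk.fd_scores(bk.normalize(counts, 0.0), small_sheet, "drug")
        est = prof.fd["fd_uptag"].reindex(truth.strain_ids).to_numpy()
        assert np.allclose(est, truth.true_fd, atol=1e-9)


class TestSynthReads:
    def test_zero_error_round_trip_all_presets(self, random_catalog):
        cfg = bk.SimConfig(
            n_strains=50, depth_per_sample=300, error_rate_substitution=0.0,
            error_rates_indel=(0.0, 0.0), fraction_uptag_only=0.1,
            tag_linkage="cis", stuffer_len=120, seed=42,
        )
        truth = bk.simulate_abundances(cfg)
        truth.uptag_only = np.array(
            [r.downtag is None for r in random_catalog]
        )
        counts = bk.simulate_counts(truth, cfg, [("A", "control")])["A"]
        index = bk.build_index(random_catalog)
        for platform in ("illumina_uptag", "mgi_downtag", "element_uptag",
                         "nanopore_long"):
            layout = bk.preset_layout(platform)
            params = (
                bk.MatchParams(max_dist=3, metric="levenshtein")
                if layout.error_model == "with_indels"
                else bk.MatchParams()
            )
            si = "ACGTACGTAC" if platform == "nanopore_long" else None
            for rid, seq, strain in bk.synth_reads(
                counts, random_catalog, layout, cfg,
                np.random.default_rng(1), sample_index_seq=si,
            ):
                observations = bk.extract_tags((rid, seq), layout)
                assert observations, (platform, seq)
                for obs in observations:
                    a = bk.assign_tag(obs.observed_seq, obs.tag_class, index, params)
                    if a.reason == "no_hit":
                        # uptag-only strain: planted random downtag
                        assert obs.tag_class == "downtag"
                    else:
                        assert a.strain_id == strain

    def test_mgi_stagger_prefix_lengths(self, random_catalog):
        cfg = bk.SimConfig(n_strains=50, depth_per_sample=200,
                           error_rate_substitution=0.0, seed=11)
        truth = bk.simulate_abundances(cfg)
        truth.uptag_only = np.array([r.downtag is None for r in random_catalog])
        counts = bk.simulate_counts(truth, cfg, [("A", "control")])["A"]
        layout = bk.preset_layout("mgi_uptag")
        left = "GATGTCCACGAGGTCTCT"
        lengths = set()
        for rid, seq, _ in bk.synth_reads(
            counts, random_catalog, layout, cfg, np.random.default_rng(2)
        ):
            assert left in seq
            lengths.add(seq.index(left))
        assert lengths == {0, 1, 2, 3}

    def test_fastq_determinism_byte_identical(self, tmp_path):
        a = bk.make_fixture("platform_panel", 5, tmp_path / "a")
        b = bk.make_fixture("platform_panel", 5, tmp_path / "b")
        for platform, path_a in a["fastqs"].items():
            bytes_a = Path(path_a).read_bytes()
            bytes_b = Path(b["fastqs"][platform]).read_bytes()
            assert bytes_a == bytes_b, platform
        assert (tmp_path / "a" / "catalog.tsv").read_bytes() == (
            tmp_path / "b" / "catalog.tsv"
        ).read_bytes()

    def test_platform_panel_counts_agree_across_presets(self, tmp_path):
        fixture = bk.make_fixture("platform_panel", 3, tmp_path)
        catalog = bk.load_catalog(fixture["catalog"])
        index = bk.build_index(catalog)
        true_counts = pd.read_csv(
            fixture["counts_true"], sep="\t", index_col=[0, 1]
        )["S1"]
        from barseqkit._fastq import read_fastq

        per_class = {}
        for platform, path in fixture["fastqs"].items():
            layout = bk.preset_layout(platform)
            params = (
                bk.MatchParams(max_dist=3, metric="levenshtein")
                if layout.error_model == "with_indels"
                else bk.MatchParams()
            )
            col, stats = bk.quantify_sample(read_fastq(path), layout, index, params)
            assert stats["extraction_failed"] == 0
            assert stats["assigned"] == stats["n_reads"]
            for cls in layout.tag_classes:
                got = col.xs(cls, level="tag_class")
                expected = true_counts.xs(cls, level="tag_class")
                pd.testing.assert_series_equal(
                    got.sort_index(), expected.sort_index(),
                    check_names=False,
                )

    def test_unknown_scenario_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            bk.make_fixture("nope", 1, tmp_path)
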