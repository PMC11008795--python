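import numpy as np
import pandas as pd
import pytest

from wormclock import cycling as cyc
from wormclock import synthetic as syn


def tiny_design(zts=(0, 6, 12, 18), reps=2, phenotype="rhythmic"):
    rows = [{"sample_id": f"{phenotype}_ZT{z}_r{r}", "phenotype": phenotype,
             "zt_h": float(z), "replicate": r}
            for z in zts for r in range(1, reps + 1)]
    return pd.DataFrame(rows)


class TestFilter:
    def _setup(self):
        design = pd.concat([tiny_design(phenotype="rhythmic"),
                            tiny_design(phenotype="arrhythmic")],
                           ignore_index=True)
        counts = pd.DataFrame(
            10, index=["tx1", "tx2", "tx3"], columns=design["sample_id"])
        lengths = pd.Series([800, 499, 900], index=counts.index)
        return counts, design, lengths

    def test_short_transcript_removed_despite_high_counts(self):
        counts, design, lengths = self._setup()
        log = {}
        kept = cyc.filter_transcripts(counts, design, lengths, log=log)
        assert "tx2" not in kept.index
        assert "length" in log["tx2"]

    def test_expressed_in_one_phenotype_only_removed(self):
        counts, design, lengths = self._setup()
        ar = design.loc[design["phenotype"] == "arrhythmic", "sample_id"]
        counts.loc["tx1", ar] = 0
        kept = cyc.filter_transcripts(counts, design, lengths)
        assert "tx1" not in kept.index and "tx3" in kept.index

    def test_remove_rule_keeps_one_sided_expression(self):
        counts, design, lengths = self._setup()
        ar = design.loc[design["phenotype"] == "arrhythmic", "sample_id"]
        counts.loc["tx1", ar] = 0
        kept = cyc.filter_transcripts(counts, design, lengths, rule="remove")
        assert "tx1" in kept.index

    def test_ubiquitous_transcript_kept(self):
        counts, design, lengths = self._setup()
        assert "tx3" in cyc.filter_transcripts(counts, design, lengths).index

    def test_design_mismatch_rejected(self):
        counts, design, lengths = self._setup()
        with pytest.raises(ValueError):
            cyc.filter_transcripts(counts.iloc[:, :-1], design, lengths)


class TestNormalize:
    def test_identical_samples_give_unit_size_factors(self):
        counts = pd.DataFrame({"s1": [4, 8, 16], "s2": [4, 8, 16]},
                              index=["a", "b", "c"])
        norm = cyc.normalize(counts)
        np.testing.assert_allclose(norm["s1"], np.log2(np.array([4, 8, 16]) + 1))
        np.testing.assert_allclose(norm["s1"], norm["s2"])

    def test_doubled_sample_gets_size_factor_two(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=50)
        counts = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base})
        norm = cyc.normalize(counts)
        np.testing.assert_allclose(norm["s3"], norm["s1"], rtol=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cyc.normalize(pd.DataFrame())

    def test_all_zero_row_falls_back_with_warning(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 7]}, index=["a", "b"])
        counts.loc["a"] = 0
        counts.loc["b", "s1"] = 0  # no all-nonzero transcript
        with pytest.warns(UserWarning, match="size factors"):
            cyc.normalize(counts)


class TestUmbrellaShapes:
    def test_six_even_timepoints_give_18_shapes(self):
        shapes = cyc.umbrella_shapes(np.array([0, 4, 8, 12, 16, 20.0]), 24.0)
        assert len(shapes) == 18  # 6 peaks x 3 admissible rise lengths

    def test_four_even_timepoints_give_half_period_rises_only(self):
        shapes = cyc.umbrella_shapes(np.array([0, 6, 12, 18.0]), 24.0)
        assert len(shapes) == 4
        for j, k in shapes:
            assert (k - j) % 4 == 2

    def test_no_admissible_shape_is_an_error(self):
        with pytest.raises(ValueError):
            cyc.umbrella_shapes(np.array([0, 1, 2, 3.0]), 24.0, (0.45, 0.55))


class TestDetectCycling:
    def _planted(self, n_sig=20, n_null=60, seed=5):
        cfg = syn.CountSimConfig(
            n_transcripts_per_category={"rhythmic_only": n_sig, "none": n_null},
            seed=seed)
        counts, lengths, design, truth = syn.simulate_count_matrix(cfg)
        sub = design[design["phenotype"] == "rhythmic"]
        norm = cyc.normalize(counts)
        return norm[sub["sample_id"]], sub, truth

    def test_planted_cosines_score_lower_p_than_nulls(self):
        norm, design, truth = self._planted()
        p = cyc.detect_cycling(norm, design, n_perm=999, seed=1)
        sig = p[truth["category"] == "rhythmic_only"]
        null = p[truth["category"] == "none"]
        assert sig.median() < 0.01
        assert null.median() > 0.2

    def test_deterministic_given_seed(self):
        norm, design, _ = self._planted(n_sig=5, n_null=5)
        p1 = cyc.detect_cycling(norm, design, n_perm=499, seed=3)
        p2 = cyc.detect_cycling(norm, design, n_perm=499, seed=3)
        pd.testing.assert_series_equal(p1, p2)

    def test_invariant_under_monotone_transform(self):
        """Rank statistic: p identical after any strictly increasing
        transform of a transcript's values."""
        norm, design, _ = self._planted(n_sig=5, n_null=5)
        p1 = cyc.detect_cycling(norm, design, n_perm=499, seed=3)
        p2 = cyc.detect_cycling(np.exp(norm / 4.0), design, n_perm=499, seed=3)
        pd.testing.assert_series_equal(p1, p2)

    def test_mixed_phenotype_design_rejected(self):
        norm, design, _ = self._planted(n_sig=2, n_null=2)
        bad = design.copy()
        bad.loc[bad.index[0], "phenotype"] = "arrhythmic"
        with pytest.raises(ValueError, match="one phenotype"):
            cyc.detect_cycling(norm, bad)

    def test_too_few_timepoints_rejected(self):
        design = tiny_design(zts=(0, 8, 16), reps=3)
        norm = pd.DataFrame(
            np.random.default_rng(0).normal(8, 1, (3, len(design))),
            index=["a", "b", "c"], columns=design["sample_id"])
        with pytest.raises(ValueError, match="4 distinct"):
            cyc.detect_cycling(norm, design)

    def test_single_replicate_rejected(self):
        design = tiny_design(zts=(0, 6, 12, 18), reps=1)
        norm = pd.DataFrame(
            np.random.default_rng(0).normal(8, 1, (2, len(design))),
            index=["a", "b"], columns=design["sample_id"])
        with pytest.raises(ValueError, match="2 replicates"):
            cyc.detect_cycling(norm, design)


class TestCategorize:
    def test_partition_identity(self):
        rng = np.random.default_rng(0)
        idx = [f"t{i}" for i in range(300)]
        p_rh = pd.Series(rng.uniform(0, 1, 300) ** 3, index=idx)
        p_ar = pd.Series(rng.uniform(0, 1, 300) ** 3, index=idx)
        table, summary = cyc.adjust_and_categorize(p_rh, p_ar, alpha=0.05)
        n_sig_rh = int((table["q_rhythmic"] < 0.05).sum())
        n_sig_ar = int((table["q_arrhythmic"] < 0.05).sum())
        assert summary.n_rhythmic_only + summary.n_both == n_sig_rh
        assert summary.n_arrhythmic_only + summary.n_both == n_sig_ar
        assert summary.union == (summary.n_rhythmic_only
                                 + summary.n_arrhythmic_only + summary.n_both)
        assert (table["q_rhythmic"] >= table["p_rhythmic"] - 1e-12).all()

    def test_mismatched_universes_rejected(self):
        p_rh = pd.Series([0.1, 0.2], index=["a", "b"])
        p_ar = pd.Series([0.1], index=["a"])
        with pytest.raises(ValueError):
            cyc.adjust_and_categorize(p_rh, p_ar)


class TestPeakPhase:
    def test_constant_transcript_takes_earliest_zt(self):
        design = tiny_design(zts=(0, 6, 12, 18), reps=2)
        norm = pd.DataFrame(np.ones((1, len(design))), index=["a"],
                            columns=design["sample_id"])
        assert cyc.peak_phase(norm, design).loc["a"] == 0.0

    def test_single_timepoint_rejected(self):
        design = tiny_design(zts=(0,), reps=3)
        norm = pd.DataFrame(np.ones((1, len(design))), index=["a"],
                            columns=design["sample_id"])
        with pytest.raises(ValueError):
            cyc.peak_phase(norm, design)


class TestHeatmapNormalize:
    def _data(self):
        cfg = syn.CountSimConfig(
            n_transcripts_per_category={"rhythmic_only": 10, "both": 10},
            seed=9)
        counts, lengths, design, truth = syn.simulate_count_matrix(cfg)
        return cyc.normalize(counts), design

    def test_range_and_endpoints(self):
        norm, design = self._data()
        h = cyc.heatmap_normalize(norm, design)
        x = h.to_numpy()
        assert x.min() >= -1.0 - 1e-12 and x.max() <= 1.0 + 1e-12
        np.testing.assert_allclose(x.min(axis=1), -1.0)
        np.testing.assert_allclose(x.max(axis=1), 1.0)

    def test_positive_scaling_leaves_output_unchanged(self):
        norm, design = self._data()
        h1 = cyc.heatmap_normalize(norm, design)
        h2 = cyc.heatmap_normalize(norm * 3.7, design)
        np.testing.assert_allclose(h1.to_numpy(), h2.to_numpy(), atol=1e-10)

    def test_lower_amplitude_phenotype_occupies_subinterval(self):
        """rhythmic_only transcripts are flat in the arrhythmic phenotype, so
        that phenotype's joint-normalized values span a narrower range."""
        cfg = syn.CountSimConfig(
            n_transcripts_per_category={"rhythmic_only": 12}, seed=10)
        counts, lengths, design, truth = syn.simulate_count_matrix(cfg)
        h = cyc.heatmap_normalize(cyc.normalize(counts), design)
        rh = h.loc[:, "rhythmic"]
        ar = h.loc[:, "arrhythmic"]
        span_rh = (rh.max(axis=1) - rh.min(axis=1)).to_numpy()
        span_ar = (ar.max(axis=1) - ar.min(axis=1)).to_numpy()
        assert (span_ar < span_rh).mean() > 0.9

    def test_constant_row_flagged_as_zeros(self):
        design = tiny_design(zts=(0, 6, 12, 18), reps=2)
        norm = pd.DataFrame(np.ones((1, len(design))), index=["flat"],
                            columns=design["sample_id"])
        with pytest.warns(UserWarning, match="constant"):
            h = cyc.heatmap_normalize(norm, design)
        np.testing.assert_allclose(h.to_numpy(), 0.0)


class TestVarianceScenarios:
    def test_hand_computable_mean_sd(self):
        design = pd.concat([tiny_design(zts=(0, 6, 12, 18), reps=2),
                            tiny_design(zts=(0, 6, 12, 18), reps=2,
                                        phenotype="arrhythmic")],
                           ignore_index=True)
        # replicate pairs differ by 2 everywhere -> SD = sqrt(2) per timepoint
        vals = {}
        for s in design.itertuples():
            vals[s.sample_id] = 1.0 if s.replicate == 1 else 3.0
        norm = pd.DataFrame([vals, vals], index=["a", "b"])
        per, p = cyc.variance_scenarios(norm, design)
        np.testing.assert_allclose(per["mean_sd_rhythmic"], np.sqrt(2.0))
        np.testing.assert_allclose(per["mean_sd_arrhythmic"], np.sqrt(2.0))

    def test_identical_replicates_degenerate_flagged(self):
        design = pd.concat([tiny_design(zts=(0, 6, 12, 18), reps=2),
                            tiny_design(zts=(0, 6, 12, 18), reps=2,
                                        phenotype="arrhythmic")],
                           ignore_index=True)
        norm = pd.DataFrame(np.tile(np.arange(len(design), dtype=float) // 2,
                                    (4, 1)),
                            index=list("abcd"), columns=design["sample_id"])
        norm.loc[:] = 5.0
        with pytest.warns(UserWarning, match="degenerate"):
            per, p = cyc.variance_scenarios(norm, design)
        assert p is None
        np.testing.assert_allclose(per.to_numpy(), 0.0)

    def test_small_set_returns_descriptives_only(self):
        design = pd.concat([tiny_design(zts=(0, 6, 12, 18), reps=2),
                            tiny_design(zts=(0, 6, 12, 18), reps=2,
                                        phenotype="arrhythmic")],
                           ignore_index=True)
        rng = np.random.default_rng(0)
        norm = pd.DataFrame(rng.normal(8, 1, (2, len(design))),
                            index=["a", "b"], columns=design["sample_id"])
        with pytest.warns(UserWarning, match="fewer than 3"):
            per, p = cyc.variance_scenarios(norm, design)
        assert p is None and len(per) == 2
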