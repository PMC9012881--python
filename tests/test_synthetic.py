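import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import nfomics as nf
from nfomics.synthetic import ConfigurationError, apply_detection_floor


class TestSkeleton:
    def test_never_nf_count_matches_cohort_fraction(self):
        sk = nf.generate_cohort_skeleton(nf.CohortConfig(n_patients=36, frac_never_nf=3 / 36, seed=0))
        assert sk.patients["nf_day"].isna().sum() == 3

    def test_all_patients_febrile_when_fraction_zero(self):
        sk = nf.generate_cohort_skeleton(nf.CohortConfig(n_patients=10, frac_never_nf=0.0, seed=0))
        assert sk.patients["nf_day"].notna().all()

    def test_same_seed_reproduces_schedule(self):
        cfg = nf.CohortConfig(n_patients=8, seed=99)
        a, b = nf.generate_cohort_skeleton(cfg), nf.generate_cohort_skeleton(cfg)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.patients, b.patients)

    def test_sample_days_stay_in_window_and_near_grid(self, small_skeleton):
        days = small_skeleton.samples["day"]
        assert days.between(0, small_skeleton.config.followup_days).all()
        # every day within 1 of a Mon/Thu grid point
        grid = {7 * w + o for w in range(5) for o in (0, 3)}
        assert all(min(abs(d - g) for g in grid) <= 1 for d in days)

    def test_nf_days_within_configured_range(self, small_skeleton):
        lo, hi = small_skeleton.config.nf_day_range
        nf_days = small_skeleton.patients["nf_day"].dropna()
        assert nf_days.between(lo, hi).all()

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigurationError):
            nf.generate_cohort_skeleton(nf.CohortConfig(n_patients=1))
        with pytest.raises(ConfigurationError):
            nf.generate_cohort_skeleton(nf.CohortConfig(nf_day_range=(5, -5)))


class TestMetabolome:
    def test_null_shift_leaves_groups_identical(self, small_skeleton):
        truth = nf.MetabolomeTruth(n_metabolites=200, signature_ids=(), shift_log2fc=0.0,
                                   detection_floor_quantile=0.0)
        values, _ = nf.generate_metabolome(small_skeleton, truth, seed=3)
        groups = nf.assign_nf_groups(small_skeleton.serum_samples,
                                     small_skeleton.patients["nf_day"])
        logv = np.log(values)
        diff = (logv[groups == "post-NF"].mean() - logv[groups == "pre-NF"].mean())
        assert abs(diff.mean()) < 0.05  # averages ~200 metabolites

    def test_planted_log2fc_recovered(self):
        # many samples so the empirical fold change concentrates near truth
        sk = nf.generate_cohort_skeleton(nf.CohortConfig(n_patients=48, seed=7))
        truth = nf.MetabolomeTruth(n_metabolites=5, signature_ids=(0,), shift_log2fc=2.0,
                                   detection_floor_quantile=0.0)
        values, _ = nf.generate_metabolome(sk, truth, seed=7)
        groups = nf.assign_nf_groups(sk.serum_samples, sk.patients["nf_day"])
        logv = np.log(values.iloc[:, 0])
        est = (logv[(groups == "post-NF").to_numpy()].mean()
               - logv[(groups == "pre-NF").to_numpy()].mean()) / math.log(2)
        assert abs(est - 2.0) < 0.3

    def test_zero_floor_means_no_missingness(self, small_skeleton):
        truth = nf.MetabolomeTruth(n_metabolites=20, detection_floor_quantile=0.0)
        values, _ = nf.generate_metabolome(small_skeleton, truth, seed=1)
        assert not values.isna().any().any()

    def test_missing_fraction_tracks_floor_quantile(self, small_skeleton):
        truth = nf.MetabolomeTruth(n_metabolites=30, detection_floor_quantile=0.2)
        values, _ = nf.generate_metabolome(small_skeleton, truth, seed=1)
        frac = values.isna().mean()
        n = values.shape[0]
        tol = 3 * math.sqrt(0.2 * 0.8 / n)
        assert ((frac - 0.2).abs() < tol + 1 / n).all()

    def test_floor_helper_noop_at_zero(self, small_skeleton):
        truth = nf.MetabolomeTruth(n_metabolites=5, detection_floor_quantile=0.0)
        values, _ = nf.generate_metabolome(small_skeleton, truth, seed=2, apply_floor=False)
        pd.testing.assert_frame_equal(apply_detection_floor(values, 0.0), values)


class TestMicrobiome:
    def test_count_rows_sum_to_drawn_depth_in_range(self, small_skeleton):
        truth = nf.MicrobiomeTruth(n_genera=8, depth_range=(2000, 4000))
        vals = pd.DataFrame(
            1.0, index=small_skeleton.serum_samples["sample_id"], columns=["M0000"]
        )
        counts, _, _ = nf.generate_microbiome(small_skeleton, truth, vals, seed=5)
        depths = counts.sum(axis=1)
        assert depths.between(2000, 4000).all()
        assert (counts >= 0).all().all()
        assert counts.to_numpy().dtype.kind == "i"

    def test_fixed_depth_range_is_exact(self, small_skeleton):
        truth = nf.MicrobiomeTruth(n_genera=5, depth_range=(5000, 5000))
        vals = pd.DataFrame(
            1.0, index=small_skeleton.serum_samples["sample_id"], columns=["M0000"]
        )
        counts, _, _ = nf.generate_microbiome(small_skeleton, truth, vals, seed=5)
        assert (counts.sum(axis=1) == 5000).all()

    def test_zero_association_matrix_leaves_metabolome_untouched(self, small_skeleton):
        truth = nf.MicrobiomeTruth(n_genera=5)
        met = nf.MetabolomeTruth(n_metabolites=10, detection_floor_quantile=0.0)
        values, _ = nf.generate_metabolome(small_skeleton, met, seed=9)
        _, _, adjusted = nf.generate_microbiome(small_skeleton, truth, values, seed=9)
        pd.testing.assert_frame_equal(adjusted, values)

    def test_noiseless_forward_model_is_exact_log_contrast(self, small_skeleton):
        # coefficients (+1, -1, 0, ...) with zero noise: the adjustment is
        # exactly log(rel_0 / rel_1) of the paired stool sample
        B = {0: np.array([1.0, -1.0, 0.0, 0.0, 0.0])}
        truth = nf.MicrobiomeTruth(n_genera=5, association_matrix=B, noise_sd=0.0)
        met = nf.MetabolomeTruth(n_metabolites=3, detection_floor_quantile=0.0)
        baseline, _ = nf.generate_metabolome(small_skeleton, met, seed=21)
        from nfomics.synthetic import sample_compositions

        rel = sample_compositions(truth, len(small_skeleton.stool_samples),
                                  np.random.default_rng(13))
        counts, _, adjusted = nf.generate_microbiome(small_skeleton, truth, baseline, seed=13)
        pairs = nf.pair_samples(small_skeleton.serum_samples, small_skeleton.stool_samples)
        stool_pos = {s: i for i, s in enumerate(small_skeleton.stool_samples["sample_id"])}
        col = baseline.columns[0]
        for _, p in pairs.head(20).iterrows():
            delta = (np.log(adjusted.at[p["serum_id"], col])
                     - np.log(baseline.at[p["serum_id"], col]))
            r = rel[stool_pos[p["stool_id"]]]
            assert delta == pytest.approx(math.log(r[0] / r[1]), abs=1e-9)

    def test_single_nonzero_association_column_rejected(self):
        B = {0: np.array([1.0, 0.0, 0.0])}
        with pytest.raises(ConfigurationError):
            nf.MicrobiomeTruth(n_genera=3, association_matrix=B).validate()
        B = {0: np.array([1.0, -0.5, 0.0])}
        with pytest.raises(ConfigurationError):
            nf.MicrobiomeTruth(n_genera=3, association_matrix=B).validate()


class TestFullCohortAndIO:
    def test_full_cohort_reproducible_and_writable(self, tmp_path):
        cfg = nf.CohortConfig(n_patients=6, seed=17)
        met = nf.MetabolomeTruth(n_metabolites=12)
        mic = nf.MicrobiomeTruth(n_genera=6)
        a = nf.generate_cohort(cfg, met, mic)
        b = nf.generate_cohort(cfg, met, mic)
        pd.testing.assert_frame_equal(a.metabolome, b.metabolome)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        paths = nf.write_cohort(a, tmp_path)
        from nfomics.metabolome import read_metabolite_tsv
        from nfomics.microbiome import read_count_table, read_taxonomy

        rt = read_metabolite_tsv(paths["metabolome"])
        pd.testing.assert_frame_equal(rt, a.metabolome)
        pd.testing.assert_frame_equal(read_count_table(paths["counts"]), a.counts)
        assert read_taxonomy(paths["taxonomy"]).equals(a.taxonomy.rename("genus"))

    def test_benchmark_responses_follow_declared_model(self):
        B = {0: np.array([1.0, -1.0, 0.0, 0.0])}
        truth = nf.MicrobiomeTruth(n_genera=4, association_matrix=B, noise_sd=0.0)
        counts, tax, ys = nf.simulate_log_contrast_dataset(40, truth, seed=2)
        assert ys.shape == (40, 1)
        assert len(counts) == 40
        # noise-free response has the variance of the planted log contrast
        assert ys.iloc[:, 0].std() > 0
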