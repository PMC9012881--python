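import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import nfomics as nf
from nfomics import integration as integ
from oracles import constrained_lasso_oracle, p2_soft_threshold


def _meta(rows, kind):
    df = pd.DataFrame(rows, columns=["sample_id", "patient_id", "day"])
    df["type"] = kind
    return df


# the twelve constructed lag scenarios: (stool days, serum day, expected
# (stool_day, lag) or None when unpaired)
LAG_SCENARIOS = [
    ([9], 9, (9, 0)),          # same day: lag 0 allowed
    ([8], 9, (8, 1)),
    ([7], 9, (7, 2)),
    ([6], 9, (6, 3)),          # lag 3 still within the window
    ([5], 9, None),            # lag 4: too old
    ([10], 9, None),           # stool after serum: lag -1 ineligible
    ([], 9, None),             # no stool at all
    ([5, 8], 9, (8, 1)),       # nearest preceding wins
    ([8, 10], 9, (8, 1)),      # future stool ignored
    ([2, 5], 9, None),         # all too old
    ([9, 6], 9, (9, 0)),       # same-day beats older
    ([6, 7, 8], 9, (8, 1)),    # nearest of several
]


class TestPairing:
    @pytest.mark.parametrize("stool_days,serum_day,expected", LAG_SCENARIOS)
    def test_lag_truth_table(self, stool_days, serum_day, expected):
        serum = _meta([["se0", "p1", serum_day]], "serum")
        stool = _meta(
            [[f"st{d}", "p1", d] for d in stool_days], "stool"
        )
        pairs = integ.pair_samples(serum, stool, max_lag_days=3)
        if expected is None:
            assert pairs.empty
        else:
            day, lag = expected
            assert len(pairs) == 1
            assert pairs.loc[0, "stool_id"] == f"st{day}"
            assert pairs.loc[0, "lag_days"] == lag

    def test_other_patients_stools_ineligible(self):
        serum = _meta([["se0", "p1", 9]], "serum")
        stool = _meta([["st8", "p2", 8]], "stool")
        assert integ.pair_samples(serum, stool).empty

    def test_one_stool_may_serve_multiple_serum_samples(self):
        serum = _meta([["se0", "p1", 8], ["se1", "p1", 9]], "serum")
        stool = _meta([["st7", "p1", 7]], "stool")
        pairs = integ.pair_samples(serum, stool)
        assert (pairs["stool_id"] == "st7").all() and len(pairs) == 2


class TestRankINT:
    def test_three_distinct_values(self):
        out = integ.rank_int([5.0, 1.0, 3.0])
        expected = norm.ppf([5 / 6, 1 / 6, 3 / 6])
        assert out == pytest.approx(expected)

    def test_median_of_odd_n_maps_to_zero(self):
        out = integ.rank_int([10.0, 20.0, 30.0, 40.0, 50.0])
        assert out[2] == pytest.approx(0.0)

    def test_invariant_to_monotone_pretransform(self, rng):
        x = rng.lognormal(size=30)
        assert integ.rank_int(np.log(x)) == pytest.approx(integ.rank_int(x))

    def test_ties_get_average_ranks(self):
        out = integ.rank_int([1.0, 1.0, 2.0])
        assert out[0] == out[1]


class TestPrevalenceFilter:
    def test_boundary_exactly_twenty_percent_kept(self):
        t = pd.DataFrame({
            "rare": [1] + [0] * 9,       # 10%
            "edge": [1, 1] + [0] * 8,    # 20% kept
            "common": [1] * 10,
        })
        out = integ.prevalence_filter_genera(t, 0.20)
        assert list(out.columns) == ["edge", "common"]

    def test_zero_threshold_is_identity(self, toy_counts):
        pd.testing.assert_frame_equal(
            integ.prevalence_filter_genera(toy_counts, 0.0), toy_counts
        )


class TestDesign:
    def test_equal_counts_give_constant_row_before_centering(self):
        t = pd.DataFrame([[5, 5, 5], [1, 2, 3]])
        Z = integ.log_contrast_design(t, center=False)
        assert Z.iloc[0].nunique() == 1

    def test_depth_scaling_leaves_row_unchanged(self, toy_counts):
        doubled = toy_counts.copy()
        doubled.iloc[1] *= 7
        a = integ.log_contrast_design(toy_counts, center=False)
        b = integ.log_contrast_design(doubled, center=False)
        assert np.allclose(a.iloc[1], b.iloc[1], atol=1e-12)

    def test_pseudocount_prevents_infinities(self, toy_counts):
        Z = integ.log_contrast_design(toy_counts)
        assert np.isfinite(Z.to_numpy()).all()


class TestConstrainedLasso:
    def test_full_shrinkage_at_large_lambda(self, rng):
        Z = pd.DataFrame(rng.normal(size=(30, 5)))
        y = rng.normal(size=30)
        fit = integ.fit_constrained_lasso(Z, y, lam=1e6)
        assert (fit.beta == 0).all()
        assert fit.intercept == pytest.approx(y.mean())

    def test_p2_closed_form_across_lambda_grid(self, rng):
        Z = rng.normal(size=(25, 2))
        beta_true = np.array([1.5, -1.5])
        y = Z @ beta_true + 0.2 * rng.normal(size=25)
        lmax = integ.lambda_max(Z, y)
        for lam in lmax * np.logspace(0, -3, 20):
            fit = integ.fit_constrained_lasso(pd.DataFrame(Z), y, lam)
            expected = p2_soft_threshold(Z, y, lam)
            assert np.abs(fit.beta.to_numpy() - expected).max() <= 1e-8

    def test_matches_sign_pattern_oracle_on_small_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 31))
            p = int(rng.integers(2, 5))
            Z = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            lam = float(rng.uniform(0.01, 1.2) * max(integ.lambda_max(Z, y), 1e-3))
            fit = integ.fit_constrained_lasso(pd.DataFrame(Z), y, lam)
            _, obj_oracle = constrained_lasso_oracle(Z, y, lam)
            assert fit.objective(Z, y) <= obj_oracle + 1e-4
            assert abs(fit.sum_beta) <= 1e-8
            assert fit.kkt_residual <= 1e-7

    def test_support_size_monotone_along_lambda_path(self, rng):
        Z = pd.DataFrame(rng.normal(size=(60, 8)))
        y = Z.iloc[:, 0] - Z.iloc[:, 1] + 0.3 * rng.normal(size=60)
        grid = integ.default_lambda_grid(Z, y)
        sizes = [len(integ.fit_constrained_lasso(Z, y, lam).support) for lam in grid]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_invalid_inputs_rejected(self, rng):
        Z = pd.DataFrame(rng.normal(size=(10, 3)))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            integ.fit_constrained_lasso(Z, y, lam=-0.1)
        y[0] = np.nan
        with pytest.raises(ValueError):
            integ.fit_constrained_lasso(Z, y, lam=0.1)


class TestLambdaSelection:
    def test_pure_noise_selects_near_lambda_max(self, rng):
        Z = pd.DataFrame(rng.normal(size=(80, 6)))
        y = rng.normal(size=80)
        lam, _ = integ.cv_select_lambda(Z, y, seed=0)
        assert lam >= 0.3 * integ.lambda_max(Z, y)

    def test_strong_signal_selects_interior_lambda_with_nonzero_fit(self, rng):
        Z = pd.DataFrame(rng.normal(size=(100, 6)))
        y = 2 * (Z.iloc[:, 0] - Z.iloc[:, 1]).to_numpy() + 0.1 * rng.normal(size=100)
        lam, _ = integ.cv_select_lambda(Z, y, seed=0)
        lmax = integ.lambda_max(Z, y)
        assert lam < lmax
        fit = integ.fit_constrained_lasso(Z, y, lam)
        assert len(fit.support) >= 2

    def test_grid_of_one_returns_that_value(self, rng):
        Z = pd.DataFrame(rng.normal(size=(30, 4)))
        y = rng.normal(size=30)
        lam, _ = integ.cv_select_lambda(Z, y, lam_grid=[0.123], seed=0)
        assert lam == 0.123

    def test_min_rule_breaks_ties_toward_larger_lambda(self, rng):
        Z = pd.DataFrame(rng.normal(size=(40, 4)))
        y = rng.normal(size=40)
        lmax = integ.lambda_max(Z, y)
        # above lambda_max every fit is the null model: identical CV error
        lam, _ = integ.cv_select_lambda(
            Z, y, lam_grid=[2 * lmax, 3 * lmax, 4 * lmax], seed=0, rule="min"
        )
        assert lam == 4 * lmax


class TestBootstrapStability:
    def test_single_bootstrap_frequencies_are_binary(self, rng):
        Z = pd.DataFrame(rng.normal(size=(40, 4)))
        y = (Z.iloc[:, 0] - Z.iloc[:, 1]).to_numpy() + 0.1 * rng.normal(size=40)
        rep = integ.bootstrap_stability(Z, y, lam=0.05, B=1, seed=0)
        assert set(rep["frequency"]).issubset({0.0, 1.0})

    def test_planted_pair_is_stable_with_correct_signs(self, rng):
        Z = pd.DataFrame(rng.normal(size=(200, 6)))
        y = (Z.iloc[:, 0] - Z.iloc[:, 1]).to_numpy() + 0.1 * rng.normal(size=200)
        lam, _ = integ.cv_select_lambda(Z, y, seed=1)
        rep = integ.bootstrap_stability(Z, y, lam, B=50, seed=1)
        assert rep["frequency"].iloc[0] > 0.9 and rep["sign"].iloc[0] == "+"
        assert rep["frequency"].iloc[1] > 0.9 and rep["sign"].iloc[1] == "-"

    def test_noise_genera_rarely_selected(self, rng):
        Z = pd.DataFrame(rng.normal(size=(200, 6)))
        y = (Z.iloc[:, 0] - Z.iloc[:, 1]).to_numpy() + 0.1 * rng.normal(size=200)
        lam, _ = integ.cv_select_lambda(Z, y, seed=1)
        rep = integ.bootstrap_stability(Z, y, lam, B=50, seed=1)
        assert (rep["frequency"].iloc[2:] < 0.5).all()


class TestAssociationTable:
    def test_empty_when_nothing_stable(self):
        stab = pd.DataFrame(
            {"frequency": [0.5], "sign": ["+"], "stable": [False]}, index=["g0"]
        )
        table = integ.build_association_table({"m": stab})
        assert table.empty
        assert integ.association_summary(table) == {
            "n_associations": 0, "n_genera": 0, "n_metabolites": 0,
        }

    def test_two_stable_genera_give_two_records(self):
        stab = pd.DataFrame(
            {"frequency": [0.95, 0.99, 0.2], "sign": ["+", "-", "0"],
             "stable": [True, True, False]},
            index=["g0", "g1", "g2"],
        )
        table = integ.build_association_table({"m": stab})
        assert len(table) == 2
        assert integ.association_summary(table)["n_genera"] == 2


class TestEndToEndInvariances:
    def test_count_scaling_changes_no_downstream_fit(self, rng):
        B = {0: np.array([1.0, -1.0, 0.0, 0.0, 0.0, 0.0])}
        truth = nf.MicrobiomeTruth(n_genera=6, association_matrix=B, noise_sd=0.2)
        counts, tax, ys = nf.simulate_log_contrast_dataset(60, truth, seed=4)
        genus = nf.aggregate_genera(counts, tax)
        scaled = genus.copy()
        scaled.iloc[0] *= 13  # rescale one sample's counts
        y = integ.rank_int(ys.iloc[:, 0].to_numpy())
        for g in (genus, scaled):
            Z = integ.log_contrast_design(g)
            fit = integ.fit_constrained_lasso(Z, y, lam=0.05)
            if g is genus:
                ref = fit.beta.copy()
        assert np.allclose(ref.to_numpy(), fit.beta.to_numpy(), atol=1e-10)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_zero_sum_holds_for_any_fit(self, seed):
        rng = np.random.default_rng(seed)
        Z = pd.DataFrame(rng.normal(size=(25, 5)))
        y = rng.normal(size=25)
        lam = float(rng.uniform(0.01, 1.0))
        fit = integ.fit_constrained_lasso(Z, y, lam)
        assert abs(fit.beta.sum()) <= 1e-8
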