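"""Paired NB-GLM machinery: design, fits, dispersions, LRT, BH, classing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from hervex import dediff, synthdata
from hervex.dediff import (
    adjust_bh,
    adjusted_profile_loglik,
    build_design,
    classify,
    estimate_dispersions,
    fit_nb_glm,
    lfc_to_fold,
    lrt,
    nb_loglik,
    summarize_families,
)


def paired_table(n_donors, conditions=("untreated", "treated")):
    rows = []
    for d in range(1, n_donors + 1):
        for c in conditions:
            rows.append({"sample": f"D{d}_{c}", "donor": f"D{d}", "condition": c,
                         "dose_um": 10.0 if c == "treated" else 0.0})
    return pd.DataFrame(rows).set_index("sample")


class TestDesign:
    def test_four_donors_eight_samples(self):
        dm = build_design(paired_table(4))
        assert dm.matrix.shape == (8, 5)
        assert np.linalg.matrix_rank(dm.matrix) == 5
        assert dm.residual_df == 3
        assert dm.columns[-1] == "treatment"
        assert set(dm.matrix[:, -1]) == {0.0, 1.0}

    def test_two_donors(self):
        dm = build_design(paired_table(2))
        assert dm.matrix.shape == (4, 3)
        assert dm.residual_df == 1

    def test_unpaired_donor_rejected(self):
        tbl = paired_table(3).drop(index="D3_treated")
        with pytest.raises(ValueError, match="D3"):
            build_design(tbl)


class TestGlmFit:
    def test_poisson_intercept_only_fits_arithmetic_mean(self):
        y = np.array([[3.0, 7.0, 5.0, 9.0]])
        X = np.ones((4, 1))
        fit = fit_nb_glm(y, X, np.zeros(4), phi=0.0)
        assert np.exp(fit["beta"][0, 0]) == pytest.approx(6.0, rel=1e-6)

    def test_saturated_design_zero_deviance(self):
        y = np.array([[3.0, 7.0, 5.0, 9.0]])
        X = np.eye(4)
        fit = fit_nb_glm(y, X, np.zeros(4), phi=0.1)
        assert fit["deviance"][0] == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_row_flagged(self):
        y = np.zeros((1, 4))
        fit = fit_nb_glm(y, np.ones((4, 1)), np.zeros(4), phi=0.1)
        assert fit["all_zero"][0]
        assert fit["deviance"][0] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("phi", [0.05, 0.2])
    def test_matches_numeric_optimizer_oracle(self, phi, rng):
        # brute-force likelihood maximization over beta via Nelder-Mead
        dm = build_design(paired_table(2))
        X = dm.matrix
        offs = np.log(rng.uniform(0.5e4, 2e4, size=4))
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * 50), size=(5, 4)).astype(float)

        fit = fit_nb_glm(y, X, offs, phi)
        for g in range(y.shape[0]):
            def negll(beta, g=g):
                mu = np.exp(np.clip(X @ beta + offs, -30, 30))
                return -nb_loglik(y[g], mu, phi)[0]

            best = optimize.minimize(negll, x0=fit["beta"][g], method="Nelder-Mead",
                                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
            start = optimize.minimize(negll, x0=np.zeros(X.shape[1]), method="Nelder-Mead",
                                      options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
            oracle = min(best.fun, start.fun)
            assert -nb_loglik(y[g], fit["mu"][g], phi)[0] == pytest.approx(oracle, abs=1e-4)


class TestDispersions:
    def _null_data(self, m, phi, seed, n_donors=4, mean_log2=(7.0, 1.0)):
        cfg = synthdata.SimulationConfig(
            n_families=2, elements_per_family=m // 2, duplication_rate=0,
            fragment_rate=0, n_donors=n_donors, treatment_lfc_map={},
            dispersion_trend={"asymptote": phi, "amplitude": 0.0},
            baseline_mean_log2=mean_log2, seed=seed,
        )
        lib, _ = synthdata.generate_library(cfg)
        counts, truth = synthdata.simulate_counts(lib, cfg)
        dm = build_design(truth.design)
        offsets = np.log(counts.sum(axis=0).to_numpy().astype(float))
        return counts, dm, offsets

    def test_common_dispersion_recovery(self):
        counts, dm, offsets = self._null_data(2000, phi=0.1, seed=15)
        disp = estimate_dispersions(counts, dm, offsets)
        assert 0.07 <= disp.common <= 0.13

    def test_prior_df_limits(self):
        counts, dm, offsets = self._null_data(300, phi=0.15, seed=6)
        loose = estimate_dispersions(counts, dm, offsets, prior_df=0.0)
        tight = estimate_dispersions(counts, dm, offsets, prior_df=1e9)
        assert np.allclose(loose.tagwise, loose.genewise)
        assert np.allclose(tight.tagwise, tight.trended)

    def test_tagwise_between_genewise_and_trend(self):
        counts, dm, offsets = self._null_data(400, phi=0.1, seed=77)
        disp = estimate_dispersions(counts, dm, offsets)
        lo = np.minimum(disp.genewise, disp.trended)
        hi = np.maximum(disp.genewise, disp.trended)
        assert ((disp.tagwise >= lo - 1e-12) & (disp.tagwise <= hi + 1e-12)).all()

    def test_residual_df_zero_rejected(self):
        counts, dm, offsets = self._null_data(50, phi=0.1, seed=2, n_donors=1)
        with pytest.raises(ValueError, match="residual df"):
            estimate_dispersions(counts, dm, offsets)

    def test_apl_increases_information_penalty(self):
        counts, dm, offsets = self._null_data(20, phi=0.1, seed=3)
        y = counts.to_numpy()[:5]
        apl = adjusted_profile_loglik(y, dm.matrix, offsets, 0.1)
        ll_at_fit = None
        fit = fit_nb_glm(y, dm.matrix, offsets, 0.1)
        ll_at_fit = nb_loglik(y, fit["mu"], 0.1)
        assert (apl < ll_at_fit).all()  # the Cox-Reid penalty is positive


class TestLrt:
    def test_identical_conditions_give_null_result(self):
        tbl = paired_table(4)
        dm = build_design(tbl)
        row = np.array([50.0, 50.0, 80.0, 80.0, 40.0, 40.0, 66.0, 66.0])
        counts = pd.DataFrame([row], index=["e1"], columns=tbl.index)
        res = lrt(counts, dm, np.zeros(8), 0.1)
        assert res["LR"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert res["PValue"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_chi2_reference(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=1e-3)

    def test_null_pvalues_approximately_uniform(self):
        # many donors, known dispersion: LRT p-values should pass a KS test
        cfg = synthdata.SimulationConfig(
            n_families=2, elements_per_family=250, duplication_rate=0,
            fragment_rate=0, n_donors=10, treatment_lfc_map={},
            baseline_mean_log2=(8.0, 0.5), seed=42,
        )
        lib, _ = synthdata.generate_library(cfg)
        counts, truth = synthdata.simulate_counts(lib, cfg)
        dm = build_design(truth.design)
        offsets = np.log(counts.sum(axis=0).to_numpy().astype(float))
        res = lrt(counts, dm, offsets, 0.1)
        ks = stats.kstest(res["PValue"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_invariant_to_consistent_sample_reordering(self):
        tbl = paired_table(4)
        dm = build_design(tbl)
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(60, size=(20, 8)), columns=tbl.index
        )
        offsets = np.log(np.full(8, 1e4))
        res1 = lrt(counts, dm, offsets, 0.1)
        perm = list(tbl.index[::-1])
        tbl2 = tbl.loc[perm]
        dm2 = build_design(tbl2)
        res2 = lrt(counts[perm], dm2, offsets, 0.1)
        assert np.allclose(res1["LR"], res2["LR"], atol=1e-6)


class TestBH:
    def test_hand_worked_example(self):
        adj = adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_all_ones(self):
        assert np.allclose(adjust_bh(np.ones(5)), 1.0)

    def test_single_p_unchanged(self):
        assert adjust_bh(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_adjusted_at_least_raw_and_rejections_nested(self, rng):
        p = rng.uniform(size=40)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-15).all()
        # re-adjustment can only grow values (BH is a step-up envelope, not a
        # projection), preserving the sorted order
        adj2 = adjust_bh(adj)
        assert (adj2 >= adj - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj2[order]) >= -1e-15).all()

    def test_nans_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.02])
        adj = adjust_bh(p)
        assert np.isnan(adj[1])
        # m = 2, so adj = (2*0.01/1 capped by step-up, 2*0.02/2)
        assert adj[2] == pytest.approx(0.02)
        assert adj[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.5]))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_properties_hold_for_arbitrary_pvalues(self, pvals):
        p = np.array(pvals)
        adj = adjust_bh(p)
        assert ((adj >= p - 1e-12) & (adj <= 1.0 + 1e-12)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()
        # the smallest adjusted value equals the minimal step-up bound
        m = len(p)
        expect_min = min((m * q / r) for r, q in enumerate(sorted(p), start=1))
        assert adj.min() == pytest.approx(min(1.0, expect_min), abs=1e-12)

    def test_order_preserving(self, rng):
        p = rng.uniform(size=25)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestClassify:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (11.985, 1e-6, "up"),
            (2.9, 1e-6, "ns"),
            (-3.5, 0.2, "ns"),
            (-3.5, 0.01, "down"),
            (3.0, 1e-6, "ns"),  # strict inequality at the threshold
        ],
    )
    def test_classes(self, lfc, fdr, expected):
        res = pd.DataFrame({"logFC": [lfc], "FDR": [fdr]})
        assert classify(res).iloc[0] == expected

    @pytest.mark.parametrize("lfc,fold", [(11.985, 4054), (0.0, 1), (3.0, 8), (-3.0, 0)])
    def test_fold_change_reporting(self, lfc, fold):
        assert lfc_to_fold(lfc) == fold


class TestFamilySummary:
    def test_all_ns_empty(self):
        res = pd.DataFrame({"family": ["A", "B"], "class": ["ns", "ns"]})
        assert summarize_families(res).empty

    def test_directional_tallies_and_conservation(self):
        res = pd.DataFrame(
            {
                "family": ["LTR12"] * 3 + ["LTR33"] * 2 + ["X"],
                "class": ["up", "up", "ns", "down", "down", "up"],
            }
        )
        s = summarize_families(res)
        assert s.loc["LTR12", "n_up"] == 2 and s.loc["LTR12", "n_down"] == 0
        assert s.loc["LTR33", "n_down"] == 2 and s.loc["LTR33", "n_up"] == 0
        total_called = (res["class"] != "ns").sum()
        assert s["n_up"].sum() + s["n_down"].sum() == total_called


class TestWilcoxonComparison:
    def test_minimum_pvalue_with_four_donors_is_large(self):
        # with n=4 pairs the exact signed-rank test cannot reach 0.05
        tbl = paired_table(4)
        log_cpm = pd.DataFrame(
            [[1.0, 9.0, 1.1, 9.2, 0.9, 8.8, 1.2, 9.1]], index=["e1"], columns=tbl.index
        )
        res = dediff.wilcoxon_signed_rank(log_cpm, tbl)
        assert res["PValue"].iloc[0] == pytest.approx(0.125)
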