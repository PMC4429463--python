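"""Nonparametric estimators and model-adequacy diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import parfrail as pf
from parfrail.diagnostics import km_quantile
from parfrail.simulate import SimulationDesign
from conftest import two_covariate_design


def brute_force_km_na(times, events):
    """Risk-set enumeration oracle for the product-limit and Nelson–Aalen
    estimators (tiny inputs only)."""
    uniq = sorted(set(times))
    surv, cumhaz, s, H = [], [], 1.0, 0.0
    for u in uniq:
        n_risk = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        s *= 1.0 - d / n_risk
        H += d / n_risk
        surv.append(s)
        cumhaz.append(H)
    return np.array(uniq), np.array(surv), np.array(cumhaz)


class TestStepEstimators:
    def test_km_all_events(self):
        km = pf.kaplan_meier([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])

    def test_km_all_censored_flat(self):
        km = pf.kaplan_meier([4, 9], [0, 0])
        np.testing.assert_allclose(km["survival"], [1.0, 1.0])

    def test_km_with_censoring_by_hand(self):
        # events at 1 and 3, censored at 2: S(3) = (1-1/3)(1-1/1) = 0
        km = pf.kaplan_meier([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(km["survival"], [2 / 3, 2 / 3, 0.0])

    def test_na_increments_by_hand(self):
        na = pf.nelson_aalen([1, 2], [1, 1])
        np.testing.assert_allclose(na["cumhaz"], [0.5, 1.5])

    def test_na_no_events_flat_zero(self):
        na = pf.nelson_aalen([1, 2], [0, 0])
        np.testing.assert_allclose(na["cumhaz"], [0.0, 0.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pf.kaplan_meier([], [])

    def test_exhaustive_small_instances_match_brute_force(self):
        """All event patterns on small tied/untied time vectors."""
        time_sets = ([1, 2, 3], [2, 2, 5, 7], [1, 1, 1, 4, 4, 9])
        for times in time_sets:
            for events in itertools.product([0, 1], repeat=len(times)):
                t, s, H = brute_force_km_na(times, list(events))
                km = pf.kaplan_meier(times, list(events))
                na = pf.nelson_aalen(times, list(events))
                np.testing.assert_allclose(km["survival"], s, atol=1e-12)
                np.testing.assert_allclose(na["cumhaz"], H, atol=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter, NelsonAalenFitter

        rng = np.random.default_rng(1)
        t = rng.exponential(10, 200).round(1) + 0.1
        e = rng.integers(0, 2, 200)
        km = pf.kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = km.set_index("time")["survival"]
        theirs = kmf.survival_function_["KM_estimate"].drop(index=0.0)
        np.testing.assert_allclose(ours.to_numpy(), theirs.to_numpy(), atol=1e-12)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(t, e)
        na = pf.nelson_aalen(t, e).set_index("time")["cumhaz"]
        np.testing.assert_allclose(
            na.to_numpy(),
            naf.cumulative_hazard_["NA_estimate"].drop(index=0.0).to_numpy(),
            atol=1e-12,
        )

    def test_na_approximates_neg_log_km_large_n(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 5000)
        e = np.ones(5000, dtype=int)
        km = pf.kaplan_meier(t, e)
        na = pf.nelson_aalen(t, e)
        keep = km["survival"].to_numpy() > 0.05
        np.testing.assert_allclose(
            na["cumhaz"].to_numpy()[keep],
            -np.log(km["survival"].to_numpy()[keep]),
            rtol=0.02,
        )


class TestCoxSnell:
    def test_unit_exponential_under_correct_model(self):
        des = two_covariate_design(n_clusters=250, size=4)
        ds, _ = pf.simulate_dataset(des, 1234)
        f = pf.fit(pf.ModelSpec("loglogistic", "invgauss", ("a", "b")), ds,
                   compute_se=False)
        res = pf.cox_snell(f, ds)
        assert np.all(res.residuals >= 0)
        assert 0.85 <= res.origin_slope <= 1.15

    def test_misspecified_model_leaves_band(self):
        # exponential fit to strongly log-logistic (rho = 3) data
        des = two_covariate_design(theta=0.0, n_clusters=250, size=4)
        out = []
        for seed in range(5):
            ds, _ = pf.simulate_dataset(des, 4500 + seed)
            f = pf.fit(pf.ModelSpec("exponential", None, ("a", "b"), "PH"), ds,
                       compute_se=False)
            out.append(pf.cox_snell(f, ds).origin_slope)
        assert sum(not (0.85 <= s <= 1.15) for s in out) >= 3

    def test_all_censored_dataset_flat(self, toy_ds):
        frame = toy_ds.frame.copy()
        frame["event"] = 0
        ds = pf.ClusteredSurvivalDataset(frame, toy_ds.schema)
        f = pf.fit(pf.ModelSpec("exponential", None, ("group",)), ds,
                   compute_se=False)
        res = pf.cox_snell(f, ds)
        assert len(res.residuals) == 4
        assert np.all(res.cumhaz["cumhaz"] == 0.0)

    def test_marginal_residuals_available(self, recovery_fit, recovery_ds):
        ds, _ = recovery_ds
        cond = pf.cox_snell(recovery_fit, ds, use_frailty=True)
        marg = pf.cox_snell(recovery_fit, ds, use_frailty=False)
        assert not np.allclose(cond.residuals, marg.residuals)


class TestBaselineAdequacy:
    def test_two_point_input_perfect_line(self):
        df = pd.DataFrame({"cluster": ["c", "c"], "time": [2.0, 5.0],
                           "event": [1, 1], "g": ["a", "a"]})
        ds = pf.load_dataset(df, {"g": ["a", "b"]})
        for fam in ("exponential", "weibull"):
            assert pf.baseline_adequacy_coords(ds, fam)["r_squared"] == 1.0

    def test_loglogistic_truth_wins_linearity(self):
        des = two_covariate_design(n_clusters=250, size=4)
        ds, _ = pf.simulate_dataset(des, 31)
        r2 = {fam: pf.baseline_adequacy_coords(ds, fam)["r_squared"]
              for fam in ("exponential", "weibull", "loglogistic")}
        assert max(r2, key=r2.get) == "loglogistic"

    def test_degenerate_survival_points_dropped(self):
        # every subject an event: the last KM point has S = 0 and must be
        # dropped from the log-odds transform
        df = pd.DataFrame({"cluster": ["c"] * 4, "time": [1.0, 2, 3, 4],
                           "event": [1] * 4, "g": ["a"] * 4})
        ds = pf.load_dataset(df, {"g": ["a", "b"]})
        out = pf.baseline_adequacy_coords(ds, "loglogistic")
        assert out["n_dropped"] == 1
        assert len(out["x"]) == 3


class TestQqAft:
    def test_identical_groups_slope_one(self, recovery_ds):
        ds, _ = recovery_ds
        out = pf.qq_aft(ds, "a", "yes", "yes")
        assert out["slope_origin"] == pytest.approx(1.0)

    def test_hand_built_quantiles(self):
        # 4 subjects per group, all events: KM quantiles are order statistics
        df = pd.DataFrame({
            "cluster": ["c"] * 8,
            "time": [1.0, 2, 3, 4, 2.0, 4, 6, 8],
            "event": [1] * 8,
            "g": ["a"] * 4 + ["b"] * 4,
        })
        ds = pf.load_dataset(df, {"g": ["a", "b"]})
        out = pf.qq_aft(ds, "g", "a", "b", probs=[0.25, 0.5, 0.75])
        np.testing.assert_allclose(out["quantiles_a"], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(out["quantiles_b"], [2.0, 4.0, 6.0])
        assert out["slope_origin"] == pytest.approx(2.0)

    def test_km_quantile_undefined_dropped(self):
        km = pf.kaplan_meier([1.0, 2.0], [1, 0])  # S never reaches 0.25
        q = km_quantile(km, [0.25, 0.9])
        assert q[0] == 1.0 and np.isnan(q[1])

    def test_group_without_events_rejected(self, toy_ds):
        frame = toy_ds.frame.copy()
        frame.loc[frame["group"] == "b", "event"] = 0
        ds = pf.ClusteredSurvivalDataset(frame, toy_ds.schema)
        with pytest.raises(ValueError, match="no events"):
            pf.qq_aft(ds, "group", "a", "b")


class TestConditionalHazardCurves:
    def test_unit_frailty_curve_is_conditional_hazard(self, recovery_fit):
        from parfrail.baselines import BaselineSpec, RegressionSpec, conditional_functions

        curves = pf.conditional_hazard_curves(recovery_fit, frailty_probs=(0.5,))
        spec = BaselineSpec("loglogistic", recovery_fit.lam, recovery_fit.rho)
        reg = RegressionSpec("AFT", np.array(list(recovery_fit.coef.values())))
        t = curves["t"].unique()
        base = conditional_functions(spec, reg, np.zeros((len(t), 2)), t)["h"]
        z = curves["z"].iloc[0]
        np.testing.assert_allclose(curves["hazard"].to_numpy(), z * base, rtol=1e-12)

    def test_multiplicative_ordering(self, recovery_fit):
        curves = pf.conditional_hazard_curves(
            recovery_fit, frailty_probs=(0.25, 0.75))
        lo = curves[curves["p"] == 0.25]
        hi = curves[curves["p"] == 0.75]
        ratio = hi["hazard"].to_numpy() / lo["hazard"].to_numpy()
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)
        assert np.all(hi["hazard"].to_numpy() > lo["hazard"].to_numpy())

    def test_unimodal_with_large_shape(self):
        des = two_covariate_design(rho=3.56, n_clusters=120, size=4)
        ds, _ = pf.simulate_dataset(des, 66)
        f = pf.fit(pf.ModelSpec("loglogistic", "invgauss", ("a", "b")), ds,
                   compute_se=False)
        curves = pf.conditional_hazard_curves(
            f, frailty_probs=(0.25, 0.5, 0.75), t_grid=np.linspace(0.5, 63, 200))
        for p, grp in curves.groupby("p"):
            h = grp["hazard"].to_numpy()
            peak = int(np.argmax(h))
            assert 0 < peak < len(h) - 1
            assert np.all(np.diff(h[: peak + 1]) > 0)
            assert np.all(np.diff(h[peak:]) < 0)
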