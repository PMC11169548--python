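"""Cox association battery: oracles, recovery, stratification mechanics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from pgsrisk.cox import (DEFAULT_GROUP_SPEC, AgeQuartiles, PgsGroupSpec,
                         assign_pgs_groups, compute_age_quartiles, cox_fit,
                         fit_cox_age_intervals, fit_cox_by_sex, fit_cox_full,
                         fit_cox_pgs_groups, fit_sex_interaction,
                         restrict_to_interval, standardize_pgs)
from pgsrisk.simulate import default_config, simulate_cohort

from conftest import naive_partial_loglik


class TestStandardize:
    def test_hand_arithmetic(self):
        df = pd.DataFrame({"study": "a", "pgs": [1.0, 2.0, 3.0]})
        out = standardize_pgs(df)
        np.testing.assert_allclose(out["pgs"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"study": "a", "pgs": rng.standard_normal(100)})
        once = standardize_pgs(df)
        twice = standardize_pgs(once)
        np.testing.assert_allclose(once["pgs"], twice["pgs"], atol=1e-12)

    def test_per_study_contract(self):
        df = pd.DataFrame({
            "study": ["a"] * 50 + ["b"] * 50,
            "pgs": np.r_[np.linspace(0, 1, 50), np.linspace(0, 100, 50)],
        })
        out = standardize_pgs(df)
        for study in ("a", "b"):
            vals = out.loc[out["study"] == study, "pgs"]
            assert abs(vals.mean()) < 1e-12
            assert abs(vals.std(ddof=1) - 1.0) < 1e-12

    def test_zero_variance_names_study(self):
        df = pd.DataFrame({"study": ["weird"] * 5, "pgs": [2.0] * 5})
        with pytest.raises(ValueError, match="weird"):
            standardize_pgs(df)


class TestCoxEngine:
    def test_toy_cohort_matches_bruteforce_partial_likelihood(self,
                                                              toy_cohort):
        est = fit_cox_full(toy_cohort, covariates=["pgs"])
        x = toy_cohort["pgs"].to_numpy()
        t = toy_cohort["exit_age"].to_numpy()
        e = (toy_cohort["status"] == "disease").to_numpy()
        res = minimize_scalar(
            lambda b: -naive_partial_loglik(b, x, t, e),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert abs(est.log_hr - res.x) < 1e-6

    def test_delayed_entry_matches_bruteforce(self, toy_cohort):
        entry = np.array([0.0, 5.0, 15.0, 0.0, 25.0, 35.0])
        x = toy_cohort["pgs"].to_numpy()
        t = toy_cohort["exit_age"].to_numpy()
        e = (toy_cohort["status"] == "disease").to_numpy()
        fit = cox_fit(x[:, None], t, e, entry=entry)
        res = minimize_scalar(
            lambda b: -naive_partial_loglik(b, x, t, e, entry),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10})
        assert abs(fit.params[0] - res.x) < 1e-6

    def test_agrees_with_lifelines(self):
        # independent implementation cross-check, with ties and two covariates
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(3)
        n = 3_000
        x1 = rng.standard_normal(n)
        x2 = rng.integers(0, 2, n).astype(float)
        t = np.ceil(rng.exponential(1 / (0.02 * np.exp(0.4 * x1 - 0.3 * x2))))
        e = t < 60
        t = np.minimum(t, 60)
        fit = cox_fit(np.column_stack([x1, x2]), t, e, names=["x1", "x2"])
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": t, "E": e, "x1": x1, "x2": x2}), "T", "E")
        np.testing.assert_allclose(fit.params, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values,
                                   atol=1e-6)

    def test_parameter_recovery(self):
        cfg = default_config(n_individuals=50_000, seed=21, beta0=0.3)
        est = fit_cox_full(standardize_pgs(simulate_cohort(cfg)))
        assert 0.25 < est.log_hr < 0.35

    def test_no_events_raises(self, toy_cohort):
        dead = toy_cohort.assign(status="censored")
        with pytest.raises(ValueError):
            fit_cox_full(dead, covariates=["pgs"])


class TestSexModels:
    def test_sex_difference_recovery(self):
        cfg = default_config(n_individuals=100_000, seed=8, beta0=0.2,
                             beta_sex=0.2)
        cohort = standardize_pgs(simulate_cohort(cfg))
        by_sex = fit_cox_by_sex(cohort)
        diff = by_sex["male"].log_hr - by_sex["female"].log_hr
        pooled_se = np.hypot(by_sex["male"].se, by_sex["female"].se)
        assert abs(diff - 0.2) < 3 * pooled_se

    def test_single_sex_cohort_raises(self):
        cfg = default_config(n_individuals=2_000, seed=1)
        cohort = simulate_cohort(cfg)
        with pytest.raises(ValueError, match="male"):
            fit_cox_by_sex(cohort[cohort["sex"] == "female"])

    def test_interaction_negated_when_sexes_relabeled(self):
        cfg = default_config(n_individuals=20_000, seed=13, beta_sex=0.15)
        cohort = standardize_pgs(simulate_cohort(cfg))
        inter = fit_sex_interaction(cohort)
        flipped = cohort.assign(
            sex=cohort["sex"].map({"female": "male", "male": "female"}))
        inter_f = fit_sex_interaction(flipped)
        assert abs(inter.log_hr + inter_f.log_hr) < 1e-6


class TestAgeQuartiles:
    def test_uniform_onsets_quantile_rule(self):
        df = pd.DataFrame({
            "study": "a", "sex": "female",
            "pgs": 0.0, "status": "disease",
            "exit_age": np.arange(1.0, 101.0),
        })
        q = compute_age_quartiles([df])
        np.testing.assert_allclose(q.boundaries, [25.75, 50.5, 75.25])

    def test_two_study_average(self):
        def study(label, quart):
            # onsets whose quartiles are exactly `quart`
            ages = [quart[0] - 5, quart[0], quart[1], quart[2],
                    quart[2] + 5]
            return pd.DataFrame({"study": label, "sex": "female",
                                 "pgs": 0.0, "status": "disease",
                                 "exit_age": np.asarray(ages, dtype=float)})

        a = study("a", (20.0, 30.0, 40.0))
        b = study("b", (30.0, 40.0, 50.0))
        q = compute_age_quartiles([a, b])
        np.testing.assert_allclose(q.boundaries, [25.0, 35.0, 45.0])

    def test_degenerate_onsets_rejected(self):
        df = pd.DataFrame({"study": "a", "sex": "female", "pgs": 0.0,
                           "status": "disease", "exit_age": [50.0] * 10})
        with pytest.raises(ValueError):
            compute_age_quartiles([df])


class TestAgeIntervals:
    QUARTILES = AgeQuartiles(boundaries=(25.0, 45.0, 60.0),
                             median_onset=(20.0, 35.0, 50.0, 70.0))

    def _cohort(self):
        return pd.DataFrame({
            "study": "s", "iid": list("ABCDE"),
            "sex": "female", "pgs": [0.1, -0.2, 0.3, 0.5, -0.1],
            "status": ["disease", "censored", "disease", "disease",
                       "other_death"],
            "exit_age": [30.0, 80.0, 50.0, 20.0, 40.0],
        })

    def test_hand_constructed_risk_sets(self):
        c = self._cohort()
        ivs = self.QUARTILES.intervals(80.0)
        # interval 1 [0,25): all five at risk, only D (onset 20) an event
        sub, _, ev, _ = restrict_to_interval(c, *ivs[0])
        assert set(sub["iid"]) == set("ABCDE")
        assert list(sub.loc[ev, "iid"]) == ["D"]
        # interval 2 [25,45): D excluded (prior onset); A is the event;
        # E contributes censored time to 40
        sub, ex, ev, ent = restrict_to_interval(c, *ivs[1])
        assert set(sub["iid"]) == set("ABCE")
        assert list(sub.loc[ev, "iid"]) == ["A"]
        assert ex[list(sub["iid"]).index("E")] == 40.0
        assert (ent == 25.0).all()
        # interval 3 [45,60): A and D excluded, E dead before entry;
        # C is the event
        sub, _, ev, _ = restrict_to_interval(c, *ivs[2])
        assert set(sub["iid"]) == {"B", "C"}
        assert list(sub.loc[ev, "iid"]) == ["C"]
        # interval 4 [60,80): only B remains, no events
        sub, _, ev, _ = restrict_to_interval(c, *ivs[3])
        assert set(sub["iid"]) == {"B"}
        assert ev.sum() == 0

    def test_interval_case_counts_partition_total(self):
        cfg = default_config(n_individuals=20_000, seed=17)
        cohort = standardize_pgs(simulate_cohort(cfg))
        q = compute_age_quartiles([cohort])
        ests = fit_cox_age_intervals(cohort, q)
        onset = cohort.loc[cohort["status"] == "disease", "exit_age"]
        assert sum(e.n_cases for e in ests) == len(onset)

    def test_declining_effect_yields_decreasing_estimates(self):
        cfg = default_config(n_individuals=150_000, seed=19, beta0=0.5,
                             beta_age=-0.012)
        cohort = standardize_pgs(simulate_cohort(cfg))
        q = compute_age_quartiles([cohort])
        ests = fit_cox_age_intervals(cohort, q)
        vals = [e.log_hr for e in ests]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestPgsGroups:
    def test_default_spec_counts_n100(self):
        df = pd.DataFrame({"study": "a", "pgs": np.random.default_rng(0)
                           .permutation(100).astype(float)})
        out = assign_pgs_groups(df)
        counts = out["pgs_group"].value_counts()
        expect = {"<20": 20, "20-40": 20, "40-60": 20, "60-80": 20,
                  "80-90": 10, "90-95": 5, ">95": 5}
        assert counts.to_dict() == expect

    def test_tail_resolution_n1000(self):
        spec = PgsGroupSpec(cut_points=(1, 20, 40, 60, 80, 90, 95, 99),
                            reference="40-60")
        df = pd.DataFrame({"study": "a",
                           "pgs": np.arange(1000, dtype=float)})
        out = assign_pgs_groups(df, spec)
        counts = out["pgs_group"].value_counts()
        assert counts["<1"] == 10
        assert counts[">99"] == 10

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "study": rng.choice(["a", "b"], 500),
            "pgs": rng.standard_normal(500)})
        out = assign_pgs_groups(df)
        assert out["pgs_group"].notna().all()
        assert len(out) == 500

    def test_constant_pgs_rejected(self):
        df = pd.DataFrame({"study": "a", "pgs": np.ones(50)})
        with pytest.raises(ValueError, match="ranks undefined"):
            assign_pgs_groups(df)


class TestGroupModels:
    def test_two_group_toy_matches_bruteforce(self):
        spec = PgsGroupSpec(cut_points=(50.0,), reference="<50")
        df = pd.DataFrame({
            "study": "s", "sex": "female",
            "pgs": [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0],
            "status": ["disease", "disease", "censored", "disease",
                       "disease", "censored"],
            "exit_age": [12.0, 33.0, 55.0, 20.0, 47.0, 61.0],
        })
        ests = fit_cox_pgs_groups(df, spec)
        x = (assign_pgs_groups(df, spec)["pgs_group"] == ">50").to_numpy(
            dtype=float)
        t = df["exit_age"].to_numpy()
        e = (df["status"] == "disease").to_numpy()
        res = minimize_scalar(
            lambda b: -naive_partial_loglik(b, x, t, e),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10})
        assert abs(ests[">50"].log_hr - res.x) < 1e-6
        assert ests["<50"].log_hr == 0.0

    def test_monotone_group_hrs_under_positive_effect(self):
        cfg = default_config(n_individuals=150_000, seed=23, beta0=0.3)
        cohort = assign_pgs_groups(standardize_pgs(simulate_cohort(cfg)))
        ests = fit_cox_pgs_groups(cohort)
        hrs = [ests[lab].log_hr for lab in DEFAULT_GROUP_SPEC.labels]
        assert all(a < b for a, b in zip(hrs, hrs[1:]))

    def test_null_effect_group_hrs_near_zero(self):
        cfg = default_config(n_individuals=40_000, seed=29, beta0=0.0)
        cohort = assign_pgs_groups(standardize_pgs(simulate_cohort(cfg)))
        ests = fit_cox_pgs_groups(cohort)
        for lab, e in ests.items():
            if lab == DEFAULT_GROUP_SPEC.reference:
                continue
            assert abs(e.log_hr) < 3.5 * e.se
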