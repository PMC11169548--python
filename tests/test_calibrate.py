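"""Incidence recalibration across PGS strata: conservation, monotonicity,
degeneracies and country transfer."""

import numpy as np
import pandas as pd
import pytest

from pgsrisk.calibrate import (POPULATION, GroupEffect, StrataHr,
                               group_incidences, pool_group_estimates,
                               predict_hr_by_age, reference_incidence,
                               stratified_cumulative_incidence,
                               transfer_with_meta_hrs)
from pgsrisk.cox import DEFAULT_GROUP_SPEC, HrEstimate
from pgsrisk.meta import AgeTrend
from pgsrisk.simulate import default_config, derive_population_rates


def flat_rate_table(inc=0.01, prev=0.0, mort=0.0, location="X",
                    bounds=True, rel_se=0.05):
    rows = []
    for sex in ("female", "male"):
        for m in range(0, 80, 5):
            rows.append({"location": location, "sex": sex,
                         "age_lower": float(m), "incidence": inc,
                         "prevalence": prev, "cause_mortality": 0.0,
                         "all_cause_mortality": mort})
    df = pd.DataFrame(rows)
    if bounds:
        from pgsrisk.simulate import _attach_bounds
        df = _attach_bounds(df, rel_se)
    return df


def scalar_strata(log_hrs, spec=DEFAULT_GROUP_SPEC):
    groups = []
    for lab, prop in zip(spec.labels, spec.proportions):
        lhr = 0.0 if lab == spec.reference else log_hrs[lab]
        groups.append(GroupEffect(lab, prop, lhr, 0.1))
    return StrataHr(groups=tuple(groups), reference=spec.reference)


class TestHrPrediction:
    def test_zero_slope_constant(self):
        t = AgeTrend(slope=0.0, intercept=0.4, cov=np.eye(2) * 1e-4,
                     age_range=(20, 60))
        np.testing.assert_allclose(predict_hr_by_age(t, [0, 30, 80]),
                                   np.exp(0.4))

    def test_clamped_below_range(self):
        t = AgeTrend(slope=-0.01, intercept=np.log(2),
                     cov=np.eye(2) * 1e-4, age_range=(20, 60))
        assert predict_hr_by_age(t, [5])[0] == pytest.approx(
            predict_hr_by_age(t, [20])[0])

    def test_closed_form_at_age_40(self):
        t = AgeTrend(slope=-0.01, intercept=np.log(2),
                     cov=np.eye(2) * 1e-4, age_range=(20, 60))
        assert predict_hr_by_age(t, [40])[0] == pytest.approx(
            2 * np.exp(-0.4), abs=1e-12)


class TestReferenceIncidence:
    def test_all_hr_one_identity(self):
        i0 = reference_incidence(0.02, [0.5, 0.5], np.ones(2))
        np.testing.assert_allclose(i0, 0.02, atol=1e-15)

    def test_two_group_hand_arithmetic(self):
        # equal halves, HR 3: I0 = 2*0.02/(1+3) = 0.01, I1 = 0.03
        i0 = reference_incidence(0.02, [0.5, 0.5], np.array([1.0, 3.0]))
        assert i0 == pytest.approx(0.01, abs=1e-15)
        i = group_incidences(i0, np.array([1.0, 3.0]))
        np.testing.assert_allclose(i, [0.01, 0.03], atol=1e-15)
        assert np.dot([0.5, 0.5], i) == pytest.approx(0.02, abs=1e-15)

    def test_conservation_over_random_configurations(self):
        # Sum_i (n_i/n) I_i must reproduce the population incidence exactly
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = rng.integers(2, 9)
            props = rng.dirichlet(np.ones(k))
            hrs = rng.uniform(0.2, 5.0, size=(k, 16))
            inc = rng.uniform(0.0, 0.05, 16)
            i0 = reference_incidence(inc, props, hrs)
            groups = group_incidences(i0, hrs)
            recovered = np.sum(props[:, None] * groups, axis=0)
            np.testing.assert_allclose(recovered, inc, atol=1e-12)

    def test_monotone_in_hr(self):
        i = group_incidences(0.01, np.array([0.5, 1.0, 2.0, 4.0]))
        assert (np.diff(i) > 0).all()


class TestStratifiedCurves:
    def test_unit_hrs_reduce_to_population(self):
        rates = flat_rate_table(inc=0.01, prev=0.02, mort=0.01)
        strata = scalar_strata({lab: 0.0 for lab in
                                DEFAULT_GROUP_SPEC.labels})
        curves = stratified_cumulative_incidence(rates, strata,
                                                 location="X", sex="female")
        pop = curves.curve(POPULATION)
        for lab in DEFAULT_GROUP_SPEC.labels:
            np.testing.assert_allclose(curves.curve(lab), pop, atol=1e-12)

    def test_constant_hazard_closed_form_per_stratum(self):
        # zero mortality, zero prevalence: each stratum is a pure
        # exponential with hazard h_i from the mixture identities
        rates = flat_rate_table(inc=0.01)
        log_hrs = {"<20": -0.6, "20-40": -0.2, "40-60": 0.0, "60-80": 0.2,
                   "80-90": 0.5, "90-95": 0.7, ">95": 1.0}
        strata = scalar_strata(log_hrs)
        curves = stratified_cumulative_incidence(rates, strata,
                                                 location="X", sex="male")
        hrs = np.exp([log_hrs[lab] for lab in strata.labels])
        i0 = 0.01 / np.dot(strata.proportions, hrs)
        for lab, hr in zip(strata.labels, hrs):
            expect = 1 - np.exp(-80 * i0 * hr)
            assert curves.curve(lab)[-1] == pytest.approx(expect, abs=1e-12)

    def test_generator_end_to_end_bracketing(self):
        cfg = default_config(n_individuals=100)
        rates = derive_population_rates(cfg)
        strata = scalar_strata({"<20": -0.5, "20-40": -0.2, "40-60": 0.0,
                                "60-80": 0.2, "80-90": 0.45, "90-95": 0.6,
                                ">95": 0.8})
        curves = stratified_cumulative_incidence(
            rates, strata, location=cfg.location, sex="female")
        pop = curves.curve(POPULATION)[1:]
        top = curves.curve(">95")[1:]
        bottom = curves.curve("<20")[1:]
        assert (top > pop).all() and (pop > bottom).all()

    def test_mismatched_keys_raise(self):
        rates = flat_rate_table()
        strata = scalar_strata({lab: 0.0 for lab in
                                DEFAULT_GROUP_SPEC.labels})
        with pytest.raises(KeyError):
            stratified_cumulative_incidence(rates, strata,
                                            location="nope", sex="female")


class TestStrataValidation:
    def test_reference_must_be_unit(self):
        groups = (GroupEffect("a", 0.5, 0.1, 0.1),
                  GroupEffect("b", 0.5, 0.2, 0.1))
        with pytest.raises(ValueError, match="HR exactly 1"):
            StrataHr(groups=groups, reference="a")

    def test_proportions_must_sum_to_one(self):
        groups = (GroupEffect("a", 0.5, 0.0), GroupEffect("b", 0.6, 0.2))
        with pytest.raises(ValueError, match="sum"):
            StrataHr(groups=groups, reference="a")


class TestTransfer:
    def _estimates(self, shift):
        out = {}
        for lab in DEFAULT_GROUP_SPEC.labels:
            lhr = 0.0 if lab == DEFAULT_GROUP_SPEC.reference else 0.3 + shift
            se = 0.0 if lab == DEFAULT_GROUP_SPEC.reference else 0.1
            out[lab] = HrEstimate(lab, lhr, se, 100, 1000, True)
        return out

    def test_meta_of_one_study_is_identity(self):
        rates = flat_rate_table()
        pooled = pool_group_estimates({"s1": self._estimates(0.0)})
        strata = StrataHr.from_estimates(pooled, DEFAULT_GROUP_SPEC)
        direct = StrataHr.from_estimates(self._estimates(0.0),
                                         DEFAULT_GROUP_SPEC)
        a = transfer_with_meta_hrs(rates, strata, location="X", sex="female")
        b = stratified_cumulative_incidence(rates, direct, location="X",
                                            sex="female")
        for lab in a.strata:
            np.testing.assert_allclose(a.curve(lab), b.curve(lab),
                                       atol=1e-12)

    def test_transfer_lies_between_heterogeneous_studies(self):
        rates = flat_rate_table()
        lo, hi = self._estimates(-0.15), self._estimates(0.15)
        pooled = pool_group_estimates({"s1": lo, "s2": hi})
        curves = {}
        for name, ests in (("lo", lo), ("hi", hi), ("meta", pooled)):
            strata = StrataHr.from_estimates(ests, DEFAULT_GROUP_SPEC)
            curves[name] = stratified_cumulative_incidence(
                rates, strata, location="X", sex="female")
        for lab in DEFAULT_GROUP_SPEC.labels:
            if lab == DEFAULT_GROUP_SPEC.reference:
                continue
            m = curves["meta"].curve(lab)[1:]
            a = curves["lo"].curve(lab)[1:]
            b = curves["hi"].curve(lab)[1:]
            assert ((m >= np.minimum(a, b) - 1e-12)
                    & (m <= np.maximum(a, b) + 1e-12)).all()
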