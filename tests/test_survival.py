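"""Endpoint construction, Kaplan-Meier (hand-computed oracle), log-rank
and the per-gene Cox screen cross-checked against lifelines."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from lymphpanel.models import ClinicalRecord
from lymphpanel.survival import (
    SurvivalDataset,
    _fit_cox_binary,
    build_endpoint,
    cox_per_gene,
    cox_univariable,
    km_estimate,
    logrank_test,
)


def clin(pid, fu, cause, tte=None, relapse=False):
    os_e = cause in ("lymphoma", "other")
    dss_e = cause == "lymphoma"
    return ClinicalRecord(
        patient_id=pid, treatment="systemic", response="CR",
        relapse_flag=relapse, time_to_event_months=tte if tte is not None else fu,
        follow_up_months=fu, os_event=os_e, dss_event=dss_e,
        pfs_event=relapse or dss_e, death_cause=cause,
    )


def dataset(times, events, **cov):
    df = pd.DataFrame({"time_months": times, "event": events, **cov},
                      index=[f"P{i}" for i in range(len(times))])
    return SurvivalDataset("OS", df)


class TestBuildEndpoint:
    def test_administrative_censoring_at_five_years(self):
        ds = build_endpoint([clin("A", 80.0, "alive")], "OS")
        row = ds.df.loc["A"]
        assert row.time_months == 60.0 and not row.event

    def test_lymphoma_death_events_all_endpoints(self):
        recs = [clin("A", 14.0, "lymphoma")]
        for ep in ("OS", "DSS", "PFS"):
            row = build_endpoint(recs, ep).df.loc["A"]
            assert row.event and row.time_months == 14.0

    def test_other_cause_death_censors_dss(self):
        recs = [clin("A", 45.0, "other")]
        os_row = build_endpoint(recs, "OS").df.loc["A"]
        dss_row = build_endpoint(recs, "DSS").df.loc["A"]
        assert os_row.event
        assert not dss_row.event and dss_row.time_months == 45.0

    def test_pfs_uses_relapse_time(self):
        recs = [clin("A", 40.0, "alive", tte=9.0, relapse=True)]
        row = build_endpoint(recs, "PFS").df.loc["A"]
        assert row.event and row.time_months == 9.0

    def test_event_at_sixty_one_censored(self):
        ds = build_endpoint([clin("A", 61.0, "lymphoma")], "OS")
        row = ds.df.loc["A"]
        assert row.time_months == 60.0 and not row.event

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="endpoint"):
            build_endpoint([], "TTF")


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        res = km_estimate(dataset([1, 2, 3, 4], [True] * 4))
        assert res.survival_at(1) == pytest.approx(0.75)
        assert res.survival_at(2) == pytest.approx(0.5)
        assert res.survival_at(3) == pytest.approx(0.25)
        assert res.survival_at(4) == pytest.approx(0.0)
        assert res.median_months == 2.0

    def test_all_censored(self):
        res = km_estimate(dataset([5, 10, 15], [False] * 3))
        assert np.all(res.survival == 1.0)
        assert res.median_months is None

    def test_hand_computed_product_limit(self):
        """Events at 3, 5, 9 with censoring at 4, 7, 10:
        S(3) = 5/6, S(5) = 5/6 * 3/4 = 0.625, S(9) = 0.625 * 1/2 = 0.3125."""
        res = km_estimate(dataset([3, 4, 5, 7, 9, 10],
                                  [True, False, True, False, True, False]))
        assert res.survival_at(3) == pytest.approx(5 / 6)
        assert res.survival_at(5) == pytest.approx(0.625)
        assert res.survival_at(9) == pytest.approx(0.3125)
        assert res.survival_at(60) == pytest.approx(0.3125)

    def test_matches_empirical_sf_without_censoring(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(20, 40).round(1) + 0.1
        res = km_estimate(dataset(times, [True] * 40))
        for t in (5.0, 10.0, 30.0):
            assert res.survival_at(t) == pytest.approx((times > t).mean())

    def test_nonincreasing(self):
        rng = np.random.default_rng(3)
        res = km_estimate(dataset(rng.exponential(20, 50) + 0.1,
                                  rng.random(50) < 0.6))
        assert np.all(np.diff(res.survival) <= 1e-12)


class TestLogRank:
    def test_identical_groups_null(self):
        g = dataset([2, 4, 6, 8], [True, True, False, True])
        stat, p = logrank_test([g, g])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        fast = dataset(rng.exponential(5, 200) + 0.01, [True] * 200)
        slow = dataset(rng.exponential(50, 200) + 0.01, [True] * 200)
        stat, p = logrank_test([fast, slow])
        assert p < 1e-10

    def test_empty_group_rejected(self):
        g = dataset([1.0], [True])
        with pytest.raises(ValueError, match="zero subjects"):
            logrank_test([g, dataset([], [])])


class TestCox:
    def test_matches_lifelines(self):
        """Dual-route check: the in-package Efron Newton solver against
        lifelines CoxPHFitter on data with and without ties."""
        rng = np.random.default_rng(6)
        for ties in (False, True):
            n = 250
            x = (rng.random(n) < 0.35).astype(float)
            t = rng.exponential(30 * np.exp(-0.9 * x))
            if ties:
                t = np.maximum(np.ceil(t), 1.0)
            t = t + 0.001
            e = rng.random(n) < 0.8
            beta, se, ok = _fit_cox_binary(t, e, x)
            assert ok
            cph = CoxPHFitter()
            cph.fit(pd.DataFrame({"T": t, "E": e, "x": x}), "T", "E", formula="x")
            assert beta == pytest.approx(cph.params_.iloc[0], abs=1e-4)
            assert se == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-4)

    def test_constant_flag_skipped(self):
        ds = dataset([1, 2, 3, 4], [True] * 4)
        flags = pd.DataFrame({"G1": [1, 1, 1, 1], "G2": [0, 1, 0, 1]},
                             index=ds.df.index)
        res = cox_per_gene(ds, flags)
        assert [r.covariate for r in res] == ["G2"]

    def test_bonferroni_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        n = 120
        ds = dataset(rng.exponential(30, n) + 0.01, rng.random(n) < 0.7)
        flags = pd.DataFrame(
            (rng.random((n, 10)) < 0.3).astype(float),
            index=ds.df.index, columns=[f"G{j}" for j in range(10)])
        res = cox_per_gene(ds, flags)
        est = [r for r in res if r.estimable]
        assert est, "at least one estimable gene expected"
        for r in est:
            assert r.p_adjusted >= r.p_raw
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * r.m_tests))
            assert r.ci95[0] <= r.hr <= r.ci95[1]
        ps = [r.p_adjusted for r in est]
        assert ps == sorted(ps)

    def test_separation_flagged_not_counted(self):
        # all events in carriers, no events elsewhere: likelihood unbounded
        t = np.array([1, 2, 3, 50, 60, 70], dtype=float)
        e = np.array([True, True, True, False, False, False])
        ds = dataset(t, e, G1=[1, 1, 1, 0, 0, 0.0], G2=[0, 1, 0, 1, 0, 1.0])
        res = {r.covariate: r for r in cox_per_gene(ds, ds.df[["G1", "G2"]])}
        assert not res["G1"].estimable
        assert res["G2"].estimable
        assert res["G2"].m_tests == 1  # non-estimable gene excluded from m

    def test_ci_coverage_nominal(self):
        """The Wald 95% CI covers the true HR in ~95% of simulations
        (n = 500 per replicate, 200 replicates)."""
        rng = np.random.default_rng(8)
        beta_true = np.log(2.0)
        hits = 0
        for _ in range(200):
            x = (rng.random(500) < 0.4).astype(float)
            t = rng.exponential(40 * np.exp(-beta_true * x)) + 0.001
            e = np.ones(500, dtype=bool)
            beta, se, ok = _fit_cox_binary(t, e, x)
            assert ok
            if abs(beta - beta_true) <= 1.959964 * se:
                hits += 1
        # binomial(200, .95): 3 sigma ~ 0.046
        assert 0.90 <= hits / 200 <= 0.995

    def test_recovers_true_hazard(self):
        rng = np.random.default_rng(9)
        x = np.tile([0.0, 1.0], 500)
        t = rng.exponential(40 * np.exp(-np.log(3.0) * x)) + 0.001
        ds = dataset(t, np.ones(1000, dtype=bool), flag=x)
        beta, se, p, ok = cox_univariable(ds, "flag")
        assert ok and abs(np.exp(beta) - 3.0) < 0.45
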