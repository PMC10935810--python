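"""Survival analysis (KM, log-rank, Cox) and drug-sensitivity association."""

import numpy as np
import pandas as pd
import pytest

import epimut as em


def _records(times, events):
    return pd.DataFrame({"time": times, "event": events})


class TestQuartileGroups:
    def test_one_to_eight(self):
        values = pd.Series([1, 2, 3, 4, 5, 6, 7, 8],
                           index=[f"s{i}" for i in range(8)])
        labels = em.quartile_groups(values)
        assert set(labels[labels == "high"].index) == {"s6", "s7"}
        assert set(labels[labels == "low"].index) == {"s0", "s1"}
        assert (labels == "excluded").sum() == 4

    def test_constant_values_all_excluded_degenerate(self):
        values = pd.Series([5.0] * 10, index=[f"s{i}" for i in range(10)])
        labels = em.quartile_groups(values)
        assert (labels == "excluded").all()
        assert labels.attrs["degenerate"]

    def test_hundred_uniform_values_split_25_25(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.random(100), index=[f"s{i:03d}" for i in range(100)])
        labels = em.quartile_groups(values)
        assert (labels == "high").sum() == 25
        assert (labels == "low").sum() == 25

    def test_ties_broken_by_sample_id_deterministically(self):
        values = pd.Series([1.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 3.0],
                           index=["b", "h", "g", "f", "e", "d", "c", "a"])
        labels = em.quartile_groups(values)
        # ties at 2.0 are ordered by sample id: c is the first tied sample
        assert set(labels[labels == "low"].index) == {"b", "c"}
        assert set(labels[labels == "high"].index) == {"a", "h"}

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            em.quartile_groups(pd.Series([1.0] * 7))


class TestKaplanMeier:
    def test_two_events_no_censoring(self):
        km = em.km_estimate(_records([1.0, 2.0], [1, 1])).set_index("time")
        assert km.at[0.0, "survival"] == 1.0
        assert km.at[1.0, "survival"] == pytest.approx(0.5)
        assert km.at[2.0, "survival"] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        km = em.km_estimate(_records([1.0, 2.0, 3.0], [0, 0, 0]))
        assert (km["survival"] == 1.0).all()

    def test_six_record_hand_worked_product_limit(self):
        """Events at 1,2,4,6 and censorings at 3,5: S = 5/6, 4/6, 4/9, 0."""
        km = em.km_estimate(_records([1, 2, 3, 4, 5, 6],
                                     [1, 1, 0, 1, 0, 1])).set_index("time")
        assert km.at[1.0, "survival"] == pytest.approx(5 / 6)
        assert km.at[2.0, "survival"] == pytest.approx(4 / 6)
        assert km.at[3.0, "survival"] == pytest.approx(4 / 6)  # censoring: no step
        assert km.at[4.0, "survival"] == pytest.approx(4 / 9)
        assert km.at[6.0, "survival"] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(6)
        times = np.round(rng.exponential(10, size=30), 3)
        km = em.km_estimate(_records(times, np.ones(30, dtype=int)))
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            em.km_estimate(_records([-1.0], [1]))


def logrank_oracle(time, event, group):
    """Observed-minus-expected log-rank statistic from per-event-time 2x2 tables."""
    time, event, group = (np.asarray(time, float), np.asarray(event, int),
                          np.asarray(group, int))
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        records = _records([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        labels = pd.Series([0, 0, 0, 1, 1, 1])
        chi2, p = em.logrank_test(records, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_per_event_time_table_oracle(self):
        rng = np.random.default_rng(13)
        times = np.round(rng.exponential(5, size=40), 2)
        events = rng.random(40) < 0.8
        group = np.repeat([0, 1], 20)
        records = _records(times, events.astype(int))
        chi2, _ = em.logrank_test(records, pd.Series(group))
        assert chi2 == pytest.approx(logrank_oracle(times, events, group), rel=1e-6)

    def test_label_swap_invariance(self):
        records = _records([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 1, 1])
        a, _ = em.logrank_test(records, pd.Series([0, 0, 0, 1, 1, 1]))
        b, _ = em.logrank_test(records, pd.Series([1, 1, 1, 0, 0, 0]))
        assert a == pytest.approx(b)

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError):
            em.logrank_test(_records([1, 2], [1, 1]), pd.Series([0, 0]))

    def test_power_under_hazard_ratio_two(self):
        """HR=2 at n=200 detected at 0.05 in >= 80/100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.concatenate([rng.exponential(1.0, 100),
                                rng.exponential(0.5, 100)])
            c = rng.exponential(2.0, 200)
            records = _records(np.minimum(t, c), (t <= c).astype(int))
            _, p = em.logrank_test(records, pd.Series(np.repeat([0, 1], 100)))
            if p < 0.05:
                hits += 1
        assert hits >= 80


def partial_loglik(coef, time, event, x, ties="efron"):
    """Hand-written Cox partial log-likelihood (Efron or Breslow ties)."""
    time, event, x = np.asarray(time, float), np.asarray(event, int), np.asarray(x, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        risk = time >= t
        d = int(dead.sum())
        theta_risk = np.exp(coef * x[risk]).sum()
        ll += coef * x[dead].sum()
        if ties == "breslow":
            ll -= d * np.log(theta_risk)
        else:
            theta_dead = np.exp(coef * x[dead]).sum()
            for ell in range(d):
                ll -= np.log(theta_risk - ell / d * theta_dead)
    return ll


def grid_search_mle(time, event, x, lo=-5.0, hi=5.0, ties="efron"):
    """Iterative grid refinement of the partial-likelihood maximum."""
    for _ in range(4):
        grid = np.linspace(lo, hi, 201)
        ll = [partial_loglik(b, time, event, x, ties) for b in grid]
        best = grid[int(np.argmax(ll))]
        span = (hi - lo) / 20
        lo, hi = best - span, best + span
    return best


class TestCox:
    def test_five_record_fit_matches_grid_search_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 1, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 0.0, 0.0]
        res = em.cox_univariate(_records(times, events), np.array(x))
        # no ties: Efron and Breslow likelihoods coincide
        oracle = grid_search_mle(times, events, x, ties="breslow")
        assert res.coef == pytest.approx(oracle, abs=1e-4)

    def test_tied_event_times_match_efron_oracle(self):
        times = [1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0]
        events = [1, 1, 1, 0, 1, 1, 1, 0]
        x = [1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0]
        res = em.cox_univariate(_records(times, events), np.array(x))
        oracle = grid_search_mle(times, events, x)
        assert res.coef == pytest.approx(oracle, abs=1e-4)

    def test_null_covariate_hr_near_one(self):
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(1_000 + seed)
            t = rng.exponential(1.0, 150)
            x = rng.normal(size=150)
            res = em.cox_univariate(_records(t, np.ones(150, int)), x)
            if res.ci_low <= 1.0 <= res.ci_high:
                covered += 1
        assert covered >= 93

    def test_recovers_true_hazard_ratio_two(self):
        """True HR 2.0 at n=200 inside the 95% CI in >= 90/100 seeds."""
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(2_000 + seed)
            x = np.repeat([0.0, 1.0], 100)
            t = rng.exponential(1.0 / (0.5 * np.exp(np.log(2.0) * x)))
            c = rng.exponential(4.0, 200)
            records = _records(np.minimum(t, c), (t <= c).astype(int))
            res = em.cox_univariate(records, x)
            if res.ci_low <= 2.0 <= res.ci_high:
                covered += 1
        assert covered >= 90

    def test_constant_covariate_and_few_events_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            em.cox_univariate(_records([1, 2, 3], [1, 1, 1]), np.ones(3))
        with pytest.raises(ValueError, match="events"):
            em.cox_univariate(_records([1, 2, 3], [1, 0, 0]),
                              np.array([0.0, 1.0, 2.0]))


class TestDrugAssociation:
    def _pm(self, values, lines):
        return em.PromoterMethylation(
            beta=pd.DataFrame({"G": values}, index=lines).T,
            n_probes=pd.DataFrame({"G": [5] * len(lines)}, index=lines).T)

    def test_perfectly_proportional_pairs(self):
        lines = [f"cl{i}" for i in range(6)]
        pm = self._pm([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], lines)
        drugs = pd.DataFrame({"cell_line": lines, "compound": "d1",
                              "ic50_z": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                              "pathway": "p"})
        res = em.drug_sensitivity_assoc(pm, drugs, "G", ["d1"])
        assert res.rho == pytest.approx(1.0)
        assert res.slope > 0

    def test_constant_methylation_flagged(self):
        lines = [f"cl{i}" for i in range(6)]
        pm = self._pm([0.3] * 6, lines)
        drugs = pd.DataFrame({"cell_line": lines, "compound": "d1",
                              "ic50_z": np.arange(6.0), "pathway": "p"})
        res = em.drug_sensitivity_assoc(pm, drugs, "G", ["d1"])
        assert res.flagged

    def test_too_few_pairs_rejected(self):
        lines = ["cl0", "cl1"]
        pm = self._pm([0.1, 0.9], lines)
        drugs = pd.DataFrame({"cell_line": lines, "compound": "d1",
                              "ic50_z": [0.0, 1.0], "pathway": "p"})
        with pytest.raises(ValueError, match="5"):
            em.drug_sensitivity_assoc(pm, drugs, "G", ["d1"])

    def test_pooled_compound_estimate_near_target(self, called_cohort):
        """rho estimated on the simulated 31-line table lands in [0.1, 0.5] in
        >= 90/100 regenerations of the drug noise."""
        import dataclasses
        truth = called_cohort["truth"]
        cfg = called_cohort["config"]
        pm = called_cohort["pm"]
        gene = truth.drug_gene
        in_band = 0
        for seed in range(100):
            _, drugs = em.simulate_clinical(
                truth, dataclasses.replace(cfg, seed=90_000 + seed))
            res = em.drug_sensitivity_assoc(pm, drugs, gene,
                                            list(cfg.drug_compounds))
            if 0.1 <= res.rho <= 0.5:
                in_band += 1
        assert in_band >= 90
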