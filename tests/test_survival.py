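"""Oracle and invariance checks for the survival primitives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from twinsurv.survival import (
    cumulative_incidence,
    fit_cox,
    fit_fine_gray,
    fit_stratified_cox,
    harrells_c,
    ph_test,
    time_varying_auc,
)
from twinsurv.synthetic import CohortConfig, simulate_event_times
from tests.conftest import make_outcomes


def _partial_loglik_no_ties(times, events, x, beta):
    """Hand-written Cox partial likelihood (untied data, any ties method)."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_coefficient_matches_likelihood_grid_oracle(self):
        """MLE agrees with a 1-D maximization of the written-out likelihood."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        oc = make_outcomes(times, events)
        fit = fit_cox(oc, pd.DataFrame({"x": x}, index=oc.index))
        res = minimize_scalar(
            lambda b: -_partial_loglik_no_ties(times, events.astype(bool), x, b),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-6)

    def test_monotone_likelihood_flagged_not_crashed(self):
        """Two subjects, the earlier failure carrying the covariate: no finite MLE."""
        oc = make_outcomes([1.0, 2.0], [1, 1])
        fit = fit_cox(oc, pd.DataFrame({"x": [1.0, 0.0]}, index=oc.index))
        assert not fit.converged
        assert np.isposinf(fit.coef[0])

    def test_constant_covariate_rejected(self):
        oc = make_outcomes([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="information"):
            fit_cox(oc, pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=oc.index))

    def test_no_events_rejected(self):
        oc = make_outcomes([1, 2], [0, 0])
        with pytest.raises(ValueError):
            fit_cox(oc, pd.DataFrame({"x": [1.0, 0.0]}, index=oc.index))

    def test_singleton_clusters_equal_unclustered_robust(self):
        rng = np.random.default_rng(0)
        n = 60
        oc = make_outcomes(rng.exponential(1, n), rng.integers(0, 2, n))
        X = pd.DataFrame({"x": rng.normal(size=n)}, index=oc.index)
        f1 = fit_cox(oc, X, cluster=np.arange(n))
        f2 = fit_cox(oc, X, cluster=None)
        assert f1.robust_se[0] == pytest.approx(f2.robust_se[0], rel=1e-10)


class TestStratifiedCox:
    def test_concordant_pairs_carry_no_information(self):
        oc = make_outcomes([1, 2, 3, 4], [1, 0, 1, 0])
        X = pd.DataFrame({"x": [1.0, 1.0, 0.0, 0.0]}, index=oc.index)
        with pytest.raises(ValueError, match="informative"):
            fit_stratified_cox(oc, X, strata=np.array(["a", "a", "b", "b"]))

    def test_within_pair_effect_recovered(self):
        """Planted within-pair log HR 0.7 recovered from discordant pairs."""
        rng = np.random.default_rng(1)
        n_pairs = 250
        x = rng.normal(size=2 * n_pairs)
        pair = np.repeat(np.arange(n_pairs), 2)
        frail = rng.normal(0, 1, n_pairs)[pair]  # shared baseline shift
        t = rng.exponential(1.0 / (0.1 * np.exp(0.7 * x + frail)))
        e = (t < 8.0).astype(int)
        t = np.minimum(t, 8.0)
        oc = make_outcomes(t, e)
        fit = fit_stratified_cox(
            oc, pd.DataFrame({"x": x}, index=oc.index), strata=pair
        )
        assert fit.coef[0] == pytest.approx(0.7, abs=3 * fit.robust_se[0])

    def test_pair_fast_path_matches_generic_stratified_solver(self):
        """Closed-form pair-conditional likelihood agrees with lifelines."""
        import warnings
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(12)
        n_pairs = 80
        pair = np.repeat(np.arange(n_pairs), 2)
        x = rng.normal(size=2 * n_pairs)
        t = rng.exponential(1.0 / (0.3 * np.exp(0.5 * x)))
        e = (t < 5.0).astype(int)
        t = np.minimum(t, 5.0)
        oc = make_outcomes(t, e)
        fit = fit_stratified_cox(
            oc, pd.DataFrame({"x": x}, index=oc.index), strata=pair
        )
        df = pd.DataFrame({"x": x, "t": t, "e": e, "s": pair})
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="t", event_col="e", strata="s",
                    fit_options={"precision": 1e-9})
        # agreement bounded by the generic solver's own convergence tolerance
        assert fit.coef[0] == pytest.approx(cph.params_.iloc[0], abs=1e-5)


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        rng = np.random.default_rng(2)
        n = 150
        t = rng.exponential(1, n)  # continuous: no ties, Efron == Breslow
        e = rng.integers(0, 2, n)
        e[0] = 1
        oc = make_outcomes(t, e)
        X = pd.DataFrame({"x": rng.normal(size=n)}, index=oc.index)
        fg = fit_fine_gray(oc, X)
        cx = fit_cox(oc, X)
        assert fg.coef[0] == pytest.approx(cx.coef[0], abs=1e-8)

    def test_all_competing_events_rejected(self):
        oc = make_outcomes([1, 2, 3], [2, 2, 2])
        with pytest.raises(ValueError):
            fit_fine_gray(oc, pd.DataFrame({"x": [1.0, 0.0, 1.0]}, index=oc.index))

    def test_bad_event_codes_rejected(self):
        oc = make_outcomes([1, 2], [1, 3])
        with pytest.raises(ValueError):
            fit_fine_gray(oc, pd.DataFrame({"x": [1.0, 0.0]}, index=oc.index))

    def test_competing_events_attenuate_cause_specific_fit(self):
        """Sanity: with heavy competing mortality, FG and cause-specific Cox
        answer different questions but both keep the planted sign."""
        rng = np.random.default_rng(3)
        n = 3000
        x = rng.normal(size=n)
        cfg = CohortConfig(base_rate_cause1=0.02, base_rate_death=0.05, seed=1)
        oc = simulate_event_times(0.5 * x, cfg, rng=rng)
        oc.index = pd.Index([f"s{i}" for i in range(n)])
        X = pd.DataFrame({"x": x}, index=oc.index)
        fg = fit_fine_gray(oc, X)
        assert fg.coef[0] == pytest.approx(0.5, abs=3 * fg.robust_se[0])


class TestPhTest:
    def test_single_event_rejected(self):
        oc = make_outcomes([1, 2, 3], [1, 0, 0])
        with pytest.raises(ValueError):
            ph_test(oc, pd.DataFrame({"x": [1.0, 0.0, 0.5]}, index=oc.index))

    def test_reversing_effect_detected(self):
        """A covariate whose effect flips sign at the median time is rejected."""
        rng = np.random.default_rng(4)
        hits = 0
        for rep in range(5):
            n = 1000
            x = rng.normal(size=n)
            # piecewise effect: +1 before t=1, -1 after
            t1 = rng.exponential(1.0 / (0.5 * np.exp(x)))
            t = np.where(
                t1 < 1.0, t1, 1.0 + rng.exponential(1.0 / (0.5 * np.exp(-x)))
            )
            e = (t < 4.0).astype(int)
            t = np.minimum(t, 4.0)
            oc = make_outcomes(t, e)
            res = ph_test(oc, pd.DataFrame({"x": x}, index=oc.index))
            hits += res.p_value[0] < 0.01
        assert hits >= 4


class TestCif:
    def test_hand_example_no_censoring(self):
        oc = make_outcomes([1.0, 2.0, 1.5, 3.0], [1, 1, 2, 0])
        cif1 = cumulative_incidence(oc, cause=1)
        assert cif1.at(np.inf) == pytest.approx(0.5)
        # step structure: 1/4 after t=1, 1/2 after t=2
        assert cif1.at(1.2) == pytest.approx(0.25)
        assert cif1.at(0.5) == 0.0

    def test_no_events_gives_zero_curve(self):
        oc = make_outcomes([1, 2, 3], [0, 0, 0])
        assert cumulative_incidence(oc, cause=1).at(10.0) == 0.0

    def test_cause_cifs_bounded_and_monotone(self):
        rng = np.random.default_rng(5)
        n = 300
        oc = make_outcomes(rng.exponential(2, n), rng.integers(0, 3, n))
        c1 = cumulative_incidence(oc, cause=1)
        c2 = cumulative_incidence(oc, cause=2)
        grid = np.linspace(0, oc["time"].max(), 50)
        v1, v2 = c1.at(grid), c2.at(grid)
        assert (np.diff(v1) >= -1e-12).all() and (np.diff(v2) >= -1e-12).all()
        assert ((v1 + v2) <= 1 + 1e-12).all()

    def test_matches_lifelines_aalen_johansen(self):
        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(6)
        n = 200
        t = rng.exponential(2, n)  # continuous, untied
        e = rng.integers(0, 3, n)
        oc = make_outcomes(t, e)
        mine = cumulative_incidence(oc, cause=1)
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(t, e, event_of_interest=1)
        grid = np.quantile(t, [0.2, 0.5, 0.8])
        theirs = (
            ajf.cumulative_density_.reindex(
                ajf.cumulative_density_.index.union(grid)
            )
            .ffill()
            .fillna(0.0)
            .loc[grid]
            .to_numpy()
            .ravel()
        )
        np.testing.assert_allclose(mine.at(grid), theirs, atol=1e-12)


class TestHarrellsC:
    def test_perfect_and_reversed_ranking(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 1]
        assert harrells_c(t, e, [3.0, 2.0, 1.0]).c_index == 1.0
        assert harrells_c(t, e, [1.0, 2.0, 3.0]).c_index == 0.0

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(7)
        n = 20
        t = rng.exponential(1, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        s = rng.normal(size=n)
        res = harrells_c(t, e, s)
        conc = disc = tied = 0
        for i in range(n):
            for j in range(n):
                if i == j or not e[i]:
                    continue
                # pair comparable if i fails before j's observed time
                if t[i] < t[j] or (t[i] == t[j] and not e[j]):
                    if s[i] > s[j]:
                        conc += 1
                    elif s[i] < s[j]:
                        disc += 1
                    else:
                        tied += 1
        expected = (conc + 0.5 * tied) / (conc + disc + tied)
        assert res.c_index == pytest.approx(expected, abs=1e-12)
        assert (res.n_concordant, res.n_discordant, res.n_tied) == (conc, disc, tied)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_to_monotone_score_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        t = rng.exponential(1, n)
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        s = rng.normal(size=n)
        c1 = harrells_c(t, e, s).c_index
        c2 = harrells_c(t, e, np.expm1(2.0 * s)).c_index
        assert c1 == pytest.approx(c2, abs=1e-12)


class TestTimeVaryingAuc:
    def test_perfect_score_no_censoring(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        oc = make_outcomes(t, e)
        curve = time_varying_auc(oc, -t, horizons=[2.5, 4.5])
        np.testing.assert_allclose(curve.auc, 1.0)

    def test_matches_direct_enumeration_without_censoring(self):
        rng = np.random.default_rng(8)
        n = 80
        t = rng.exponential(2, n)
        e = np.ones(n, int)
        e[rng.choice(n, 10, replace=False)] = 2  # competing events
        s = rng.normal(size=n)
        oc = make_outcomes(t, e)
        horizon = float(np.quantile(t, 0.5))
        curve = time_varying_auc(oc, s, horizons=[horizon])
        case = (e == 1) & (t <= horizon)
        ctrl = (t > horizon) | ((e == 2) & (t <= horizon))
        num = den = 0.0
        for i in np.flatnonzero(case):
            for j in np.flatnonzero(ctrl):
                num += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
                den += 1.0
        assert curve.auc[0] == pytest.approx(num / den, abs=1e-12)

    def test_horizon_beyond_follow_up_rejected(self):
        oc = make_outcomes([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError):
            time_varying_auc(oc, [1, 2, 3], horizons=[10.0])

    def test_auc_within_reported_ci(self):
        rng = np.random.default_rng(9)
        n = 400
        t = rng.exponential(2, n)
        e = rng.integers(0, 2, n)
        oc = make_outcomes(t, e)
        s = rng.normal(size=n)
        curve = time_varying_auc(oc, s, horizons=[1.0])
        assert curve.ci_lower[0] <= curve.auc[0] <= curve.ci_upper[0]
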