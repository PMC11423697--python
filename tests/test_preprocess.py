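"""Imputation, mixed-model residualization and dichotomization checks."""

import numpy as np
import pandas as pd
import pytest

from twinsurv.preprocess import (
    covariate_design,
    dichotomize,
    impute_missing,
    residualize,
)
from twinsurv._lmm import CrossedLMMDesign


def _tiny_cohort(n=40, n_plates=3, n_pos=4, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"s{i}" for i in range(n)], name="individual_id")
    return pd.DataFrame(
        {
            "pair_id": [f"p{i // 2}" for i in range(n)],
            "zygosity": rng.choice(["MZ", "DZ"], n),
            "sex": rng.choice(["F", "M"], n),
            "age_at_entry": rng.uniform(55, 80, n),
            "dataset": rng.choice(["A", "B"], n),
            "frac_monocytes": rng.uniform(0.05, 0.1, n),
            "frac_lymphocytes": rng.uniform(0.2, 0.4, n),
            "frac_eosinophils": rng.uniform(0.01, 0.05, n),
            "plate": rng.choice([f"pl{i}" for i in range(n_plates)], n),
            "position": rng.choice([f"po{i}" for i in range(n_pos)], n),
        },
        index=idx,
    )


class TestImpute:
    def test_no_missing_is_identity(self):
        cohort = _tiny_cohort()
        m = pd.DataFrame(
            np.random.default_rng(1).uniform(0.2, 0.8, (40, 5)),
            index=cohort.index,
            columns=[f"c{i}" for i in range(5)],
        )
        pd.testing.assert_frame_equal(impute_missing(m, cohort), m)

    def test_missing_value_equals_normal_equations_fit(self):
        """Imputed entry equals the OLS prediction from the normal equations."""
        cohort = _tiny_cohort()
        rng = np.random.default_rng(2)
        m = pd.DataFrame(
            rng.uniform(0.2, 0.8, (40, 3)),
            index=cohort.index,
            columns=["c0", "c1", "c2"],
        )
        m.iloc[7, 1] = np.nan
        out = impute_missing(m, cohort)
        X = covariate_design(cohort).to_numpy()
        obs = ~m["c1"].isna().to_numpy()
        beta = np.linalg.solve(X[obs].T @ X[obs], X[obs].T @ m.loc[obs, "c1"].to_numpy())
        expected = float(np.clip(X[7] @ beta, 0, 1))
        assert out.iloc[7, 1] == pytest.approx(expected, abs=1e-10)
        # observed cells untouched
        assert np.array_equal(out.to_numpy()[obs], m.to_numpy()[obs])

    def test_fully_missing_cpg_raises_with_name(self):
        cohort = _tiny_cohort()
        m = pd.DataFrame(
            np.full((40, 2), 0.5), index=cohort.index, columns=["good", "bad"]
        )
        m["bad"] = np.nan
        m["good"] += np.random.default_rng(0).normal(0, 0.01, 40)
        with pytest.raises(ValueError, match="bad"):
            impute_missing(m, cohort)


class TestResidualize:
    def test_orthogonal_input_single_batch_level_is_rescaled_identity(self):
        cohort = _tiny_cohort()
        cohort["plate"] = "pl0"
        cohort["position"] = "po0"
        X = covariate_design(cohort).to_numpy()
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        # project out the covariates so the input is exactly orthogonal
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]
        m = pd.DataFrame({"c0": y}, index=cohort.index)
        out = residualize(m, cohort)
        np.testing.assert_allclose(
            out["c0"].to_numpy(), y / y.std(ddof=1), atol=1e-10
        )

    def test_reml_matches_profile_grid_oracle(self):
        """Variance components match a dense 1-D profile-REML grid to 1e-4."""
        rng = np.random.default_rng(4)
        n_plate, per = 6, 8
        n = n_plate * per
        plate = np.repeat([f"pl{i}" for i in range(n_plate)], per)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        b_pl = rng.normal(0, 0.7, n_plate)
        y = X @ [1.0, 0.5] + np.repeat(b_pl, per) + rng.normal(0, 0.5, n)

        design = CrossedLMMDesign(X, plate, np.array(["po0"] * n))
        fit = design.fit(y)

        # independent dense-REML grid over the plate variance ratio
        Z = np.zeros((n, n_plate))
        Z[np.arange(n), np.repeat(np.arange(n_plate), per)] = 1.0

        def crit(gamma):
            W = np.eye(n) + gamma * Z @ Z.T
            Wi = np.linalg.inv(W)
            XtWX = X.T @ Wi @ X
            beta = np.linalg.solve(XtWX, X.T @ Wi @ y)
            r = y - X @ beta
            rss = r @ Wi @ r
            return (
                np.linalg.slogdet(W)[1]
                + np.linalg.slogdet(XtWX)[1]
                + (n - 2) * np.log(rss)
            ), rss

        grid = np.exp(np.linspace(-6, 4, 4001))
        crits = np.array([crit(g)[0] for g in grid])
        g_star = grid[crits.argmin()]
        rss = crit(g_star)[1]
        sigma2_star = rss / (n - 2)
        tau_star = g_star * sigma2_star
        assert fit.sigma2 == pytest.approx(sigma2_star, abs=1e-4)
        assert fit.tau[0] == pytest.approx(tau_star, abs=5e-3 * max(1.0, tau_star))

    def test_reml_matches_statsmodels_mixedlm(self):
        """Cross-check against MixedLM (crossed intercepts via vc_formula)."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        n = 120
        plate = rng.choice([f"pl{i}" for i in range(4)], n)
        pos = rng.choice([f"po{i}" for i in range(5)], n)
        x = rng.normal(size=n)
        eff_pl = dict(zip([f"pl{i}" for i in range(4)], rng.normal(0, 0.6, 4)))
        eff_po = dict(zip([f"po{i}" for i in range(5)], rng.normal(0, 0.4, 5)))
        y = (
            0.3 * x
            + np.array([eff_pl[p] for p in plate])
            + np.array([eff_po[p] for p in pos])
            + rng.normal(0, 0.5, n)
        )
        df = pd.DataFrame({"y": y, "x": x, "plate": plate, "pos": pos, "g": 1})
        md = smf.mixedlm(
            "y ~ x", df, groups="g",
            vc_formula={"plate": "0 + C(plate)", "pos": "0 + C(pos)"},
        )
        mf = md.fit(reml=True, method="lbfgs")

        design = CrossedLMMDesign(
            np.column_stack([np.ones(n), x]), plate, pos
        )
        fit = design.fit(y)
        np.testing.assert_allclose(fit.beta, mf.fe_params.to_numpy(), atol=1e-3)
        np.testing.assert_allclose(fit.sigma2, mf.scale, rtol=1e-2)
        np.testing.assert_allclose(
            fit.tau,
            [mf.vcomp[0], mf.vcomp[1]],
            rtol=5e-2, atol=1e-3,
        )

    def test_residuals_orthogonal_to_fixed_effects(self, demo_cohort, demo_residuals):
        _, cohort, _, _, _ = demo_cohort
        X = covariate_design(cohort)
        R = demo_residuals.to_numpy()
        for col in X.columns:
            v = X[col].to_numpy()
            if v.std() == 0:
                continue
            r = (v - v.mean()) @ R / len(v)
            assert np.abs(r).max() < 1e-8

    def test_residualize_idempotent_on_own_output(self):
        cohort = _tiny_cohort(n=60)
        cohort["plate"] = "pl0"
        cohort["position"] = "po0"
        m = pd.DataFrame(
            np.random.default_rng(6).uniform(0.2, 0.8, (60, 4)),
            index=cohort.index,
            columns=[f"c{i}" for i in range(4)],
        )
        r1 = residualize(m, cohort)
        r2 = residualize(r1, cohort)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-10)

    def test_unit_sd_and_no_missing(self, demo_residuals):
        sd = demo_residuals.std(ddof=1)
        np.testing.assert_allclose(sd.to_numpy(), 1.0, atol=1e-8)
        assert not demo_residuals.isna().any().any()

    def test_constant_cpg_raises(self):
        cohort = _tiny_cohort()
        m = pd.DataFrame(
            {"flat": np.full(40, 0.5)}, index=cohort.index
        )
        with pytest.raises(ValueError, match="flat"):
            residualize(m, cohort)


class TestDichotomize:
    def test_boundary_and_signs(self):
        r = pd.DataFrame({"c": [-0.01, 0.0, 0.7]})
        out = dichotomize(r)
        assert out["c"].tolist() == [0, 1, 1]

    def test_symmetric_residuals_split_near_half(self, demo_residuals):
        frac = dichotomize(demo_residuals).mean()
        n = len(demo_residuals)
        assert (np.abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)).all()
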