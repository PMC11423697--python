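"""Stability-selected LASSO-Cox predictor with forced sex/age, and validation.

The candidate CpGs (those passing the dual p-value rule in the screen) enter
an L1-penalised Cox model in which sex and age are penalty-free.  The
smoothing parameter comes from 10-fold cross-validated partial-likelihood
deviance with a "minimum plus half a standard error" rule; stability
selection repeats the whole procedure on random half-samples (drawn by twin
pair) and keeps CpGs chosen in more than 80% of replicates.  The final
predictor is an unpenalised multivariable Cox refit whose linear predictor
is the risk score, validated by pair-blocked cross-validated Harrell's C and
IPCW time-varying AUC, and by a refit protocol on an external cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from . import survival

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorModel",
    "fit_lasso_cox_path",
    "select_lambda_cv",
    "stability_selection",
    "build_predictor",
    "cross_validate",
    "external_validate",
]

FORCED = ("sex_F", "age")


def sex_age_design(cohort: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sex_F": (cohort["sex"].to_numpy() == "F").astype(float),
            "age": cohort["age_at_entry"].to_numpy(dtype=float),
        },
        index=cohort.index,
    )


def _surv_y(outcomes: pd.DataFrame) -> np.ndarray:
    return Surv.from_arrays(
        event=outcomes["event"].to_numpy() == 1,
        time=outcomes["time"].to_numpy(dtype=float),
    )


def breslow_partial_loglik(
    time: np.ndarray, delta: np.ndarray, eta: np.ndarray
) -> float:
    """Breslow-ties Cox log partial likelihood of a fixed linear predictor."""
    time = np.asarray(time, float)
    delta = np.asarray(delta, bool)
    eta = np.asarray(eta, float)
    order = np.argsort(time, kind="stable")
    t, dd, ee = time[order], delta[order], eta[order]
    ex = np.exp(ee)
    suffix = np.cumsum(ex[::-1])[::-1]  # sum over {time >= t_i}
    if not dd.any():
        return 0.0
    uniq, inv = np.unique(t[dd], return_inverse=True)
    d_k = np.bincount(inv).astype(float)
    i0 = np.searchsorted(t, uniq, side="left")
    return float(ee[dd].sum() - d_k @ np.log(suffix[i0]))


def fit_lasso_cox_path(
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    penalty_free: tuple[str, ...] = FORCED,
    alphas: np.ndarray | None = None,
    n_alphas: int = 50,
    tol: float = 1e-7,
) -> tuple[np.ndarray, pd.DataFrame]:
    """L1-penalised Cox path with zero penalty on the forced covariates.

    Returns (alphas, coefficients) with one coefficient column per alpha,
    alphas decreasing.
    """
    if not (outcomes["event"].to_numpy() == 1).any():
        raise ValueError("no events: penalised Cox path is not estimable")
    pf = np.array([0.0 if c in penalty_free else 1.0 for c in X.columns])
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=alphas,
        n_alphas=n_alphas,
        penalty_factor=pf,
        normalize=False,
        tol=tol,
        fit_baseline_model=False,
    )
    model.fit(X.to_numpy(dtype=float), _surv_y(outcomes))
    coefs = pd.DataFrame(
        model.coef_, index=X.columns, columns=np.asarray(model.alphas_)
    )
    return np.asarray(model.alphas_), coefs


def select_lambda_cv(
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    pair_ids: np.ndarray,
    k: int = 10,
    rule: str = "min_plus_half_se",
    seed: int = 0,
    alphas: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the LASSO penalty by pair-blocked k-fold CV deviance.

    Deviance per fold follows Verweij & van Houwelingen: with the fold held
    out, dev = -2 [ loglik(all data; beta_train) - loglik(train; beta_train) ].
    Rules: ``min`` (argmin of the mean CV deviance); ``min_plus_half_se``
    (largest penalty whose deviance is within half the SE of the minimum);
    ``literal_min_plus_half_se`` (the minimiser plus half the SE, read as a
    number on the penalty scale).
    """
    if alphas is None:
        alphas, _ = fit_lasso_cox_path(X, outcomes)
    pair_ids = np.asarray(pair_ids)
    time = outcomes["time"].to_numpy(dtype=float)
    delta = outcomes["event"].to_numpy() == 1
    rng = np.random.default_rng(seed)
    uniq = pd.unique(pair_ids)
    perm = rng.permutation(len(uniq))
    fold_of_pair = dict(zip(uniq[perm], np.arange(len(uniq)) % k))
    fold = np.array([fold_of_pair[p] for p in pair_ids])

    devs = np.full((k, len(alphas)), np.nan)
    Xa = X.to_numpy(dtype=float)
    for f in range(k):
        train = fold != f
        if delta[train].sum() == 0:
            continue
        try:
            _, coefs = fit_lasso_cox_path(
                X.loc[train], outcomes.loc[train], alphas=alphas
            )
        except (ValueError, ArithmeticError):
            continue
        # coxnet may truncate the path on a subset; align by nearest alpha
        avail = np.asarray(coefs.columns, dtype=float)
        for a_i in range(len(alphas)):
            beta = coefs.iloc[:, int(np.argmin(np.abs(avail - alphas[a_i])))].to_numpy()
            ll_all = breslow_partial_loglik(time, delta, Xa @ beta)
            ll_train = breslow_partial_loglik(
                time[train], delta[train], Xa[train] @ beta
            )
            devs[f, a_i] = -2.0 * (ll_all - ll_train)

    ok = ~np.all(np.isnan(devs), axis=1)
    if not ok.any():
        raise ValueError("cross-validation failed in every fold")
    mean_dev = np.nanmean(devs[ok], axis=0)
    se_dev = np.nanstd(devs[ok], axis=0, ddof=1) / np.sqrt(ok.sum())
    table = pd.DataFrame(
        {"alpha": alphas, "cv_deviance": mean_dev, "se": se_dev}
    )
    return apply_lambda_rule(alphas, mean_dev, se_dev, rule), table


def apply_lambda_rule(
    alphas: np.ndarray, mean_dev: np.ndarray, se_dev: np.ndarray, rule: str
) -> float:
    """Resolve a CV-deviance curve into one penalty value (see select_lambda_cv)."""
    alphas = np.asarray(alphas, float)
    i_min = int(np.nanargmin(mean_dev))
    if rule == "min":
        return float(alphas[i_min])
    if rule == "min_plus_half_se":
        thresh = mean_dev[i_min] + 0.5 * se_dev[i_min]
        # alphas decrease along the path; take the largest alpha within threshold
        within = np.flatnonzero(mean_dev <= thresh)
        return float(alphas[within.min()])
    if rule == "literal_min_plus_half_se":
        return float(
            np.clip(alphas[i_min] + 0.5 * se_dev[i_min], alphas.min(), alphas.max())
        )
    raise ValueError(f"unknown rule {rule!r}")


def _coefs_at(X, outcomes, lam, alphas) -> np.ndarray:
    """Coefficients of the penalised fit at one penalty value."""
    grid = np.unique(np.append(alphas, lam))[::-1]
    _, coefs = fit_lasso_cox_path(X, outcomes, alphas=grid)
    j = int(np.argmin(np.abs(np.asarray(coefs.columns, float) - lam)))
    return coefs.iloc[:, j].to_numpy()


def stability_selection(
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    pair_ids: np.ndarray,
    n_replicates: int = 1000,
    subsample: float = 0.5,
    threshold: float = 0.8,
    seed: int = 0,
    cv_folds: int = 10,
    rule: str = "min_plus_half_se",
) -> pd.DataFrame:
    """Half-sample (by pair) stability selection for the penalised Cox model.

    Returns a table (cpg_id, selection_frequency, selected) over the
    penalised columns; forced covariates are always in the model and are
    excluded from the frequencies.  ``selected`` is strict: frequency must
    exceed the threshold.
    """
    if not 0.0 < subsample < 1.0:
        raise ValueError("subsample must lie in (0, 1)")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pair_ids = np.asarray(pair_ids)
    uniq = pd.unique(pair_ids)
    n_take = max(2, int(round(subsample * len(uniq))))
    penalised = [c for c in X.columns if c not in FORCED]
    counts = pd.Series(0.0, index=penalised)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_replicates)
    done = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(child[rep])
        for attempt in range(100):
            take = set(rng.choice(uniq, size=n_take, replace=False))
            mask = np.array([p in take for p in pair_ids])
            if (outcomes.loc[mask, "event"].to_numpy() == 1).sum() >= 2:
                break
            logger.info("replicate %d: no events in subsample, redrawing", rep)
        else:
            continue
        Xs, ocs = X.loc[mask], outcomes.loc[mask]
        try:
            alphas, _ = fit_lasso_cox_path(Xs, ocs)
            lam, _ = select_lambda_cv(
                Xs, ocs, pair_ids[mask], k=cv_folds, rule=rule,
                seed=int(rng.integers(2**31)), alphas=alphas,
            )
            beta = _coefs_at(Xs, ocs, lam, alphas)
        except (ValueError, ArithmeticError):
            continue
        nz = pd.Series(beta, index=X.columns).loc[penalised] != 0
        counts[nz.index[nz]] += 1.0
        done += 1
    if done == 0:
        raise ValueError("stability selection failed in every replicate")
    freq = counts / done
    return pd.DataFrame(
        {
            "cpg_id": penalised,
            "selection_frequency": freq.to_numpy(),
            "selected": freq.to_numpy() > threshold,
        }
    )


@dataclass
class PredictorModel:
    cpg_ids: list[str]
    coef: pd.DataFrame  # rows: CpGs + sex_F + age; columns coef, hr, robust_se, p
    c_index: float
    auc_curve: survival.AucCurve | None = None
    lambda_rule: str = "min_plus_half_se"
    seed: int = 0

    def linear_predictor(
        self, residuals: pd.DataFrame, cohort: pd.DataFrame
    ) -> pd.Series:
        X = pd.concat([residuals[self.cpg_ids], sex_age_design(cohort)], axis=1)
        return pd.Series(
            X.to_numpy(dtype=float) @ self.coef["coef"].to_numpy(),
            index=X.index,
        )

    def to_json(self) -> str:
        d = {
            "cpg_ids": self.cpg_ids,
            "coef": {
                name: {k: float(v) for k, v in row.items()}
                for name, row in self.coef.iterrows()
            },
            "c_index": float(self.c_index),
            "lambda_rule": self.lambda_rule,
            "seed": int(self.seed),
        }
        if self.auc_curve is not None:
            d["auc"] = {
                "horizons": [float(v) for v in self.auc_curve.horizons],
                "auc": [float(v) for v in self.auc_curve.auc],
            }
        return json.dumps(d, indent=2, sort_keys=True)


def build_predictor(
    selected_cpgs: list[str],
    residuals: pd.DataFrame,
    outcomes: pd.DataFrame,
    cohort: pd.DataFrame,
    auc_horizons=None,
) -> PredictorModel:
    """Unpenalised multivariable Cox refit (selected CpGs + sex + age)."""
    if len(selected_cpgs) == 0:
        raise ValueError("empty CpG selection")
    X = pd.concat(
        [residuals[list(selected_cpgs)], sex_age_design(cohort)], axis=1
    )
    fit = survival.fit_cox(outcomes, X, cluster=cohort["pair_id"].to_numpy())
    score = X.to_numpy(dtype=float) @ fit.coef
    conc = survival.harrells_c(
        outcomes["time"].to_numpy(dtype=float),
        outcomes["event"].to_numpy() == 1,
        score,
    )
    auc = None
    if auc_horizons is not None:
        auc = survival.time_varying_auc(outcomes, score, auc_horizons)
    return PredictorModel(
        cpg_ids=list(selected_cpgs),
        coef=fit.summary(),
        c_index=conc.c_index,
        auc_curve=auc,
    )


def cross_validate(
    cpgs: list[str],
    residuals: pd.DataFrame,
    outcomes: pd.DataFrame,
    cohort: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    auc_horizons=None,
) -> dict:
    """Pair-blocked k-fold CV of the full (CpGs+sex+age) and basic (sex+age)
    models; Harrell's C and AUC(t) on the pooled out-of-fold risk scores."""
    base = sex_age_design(cohort)
    X_full = pd.concat([residuals[list(cpgs)], base], axis=1) if cpgs else base
    pair_ids = cohort["pair_id"].to_numpy()
    rng = np.random.default_rng(seed)
    uniq = pd.unique(pair_ids)
    perm = rng.permutation(len(uniq))
    fold_of_pair = dict(zip(uniq[perm], np.arange(len(uniq)) % k))
    fold = np.array([fold_of_pair[p] for p in pair_ids])

    scores_full = np.full(len(cohort), np.nan)
    scores_basic = np.full(len(cohort), np.nan)
    for f in range(k):
        train, test = fold != f, fold == f
        for X, out_arr in ((X_full, scores_full), (base, scores_basic)):
            fit = survival.fit_cox(
                outcomes.loc[train], X.loc[train],
                cluster=pair_ids[train],
            )
            # flagged infinite coefficients keep their sign at a large value
            coef = np.nan_to_num(fit.coef, nan=0.0, posinf=10.0, neginf=-10.0)
            out_arr[test] = X.loc[test].to_numpy(dtype=float) @ coef

    time = outcomes["time"].to_numpy(dtype=float)
    delta = outcomes["event"].to_numpy() == 1
    res = {
        "cv_c_full": survival.harrells_c(time, delta, scores_full).c_index,
        "cv_c_basic": survival.harrells_c(time, delta, scores_basic).c_index,
    }
    if auc_horizons is not None:
        res["auc_full"] = survival.time_varying_auc(
            outcomes, scores_full, auc_horizons
        )
        res["auc_basic"] = survival.time_varying_auc(
            outcomes, scores_basic, auc_horizons
        )
    return res


def external_validate(
    model: PredictorModel,
    ext_residuals: pd.DataFrame,
    ext_outcomes: pd.DataFrame,
    ext_cohort: pd.DataFrame,
) -> dict:
    """Refit-based validation of the predictor on an external cohort.

    Model CpGs absent from the external matrix are dropped (logged); the
    selection itself is never re-estimated.  Per available CpG, Harrell's C
    of a sex+age+CpG Cox refit on the external data; combined C for the
    sex+age+all-available-CpGs refit; basic C for sex+age only.  When the
    external event count is below the parameter count, the combined refit is
    ridge-stabilised (logged).
    """
    available = [c for c in model.cpg_ids if c in ext_residuals.columns]
    dropped = [c for c in model.cpg_ids if c not in available]
    if not available:
        raise ValueError("no model CpGs present in the external matrix")
    if dropped:
        logger.warning("external validation drops missing CpGs: %s", dropped)

    base = sex_age_design(ext_cohort)
    time = ext_outcomes["time"].to_numpy(dtype=float)
    delta = ext_outcomes["event"].to_numpy() == 1
    cluster = ext_cohort["pair_id"].to_numpy()

    def _c_of(X: pd.DataFrame, penalizer: float = 0.0) -> float:
        if penalizer > 0:
            from lifelines import CoxPHFitter
            import warnings

            df = X.copy()
            df["__t"], df["__e"] = time, delta.astype(int)
            cph = CoxPHFitter(penalizer=penalizer)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, "__t", "__e")
            score = X.to_numpy(dtype=float) @ cph.params_.to_numpy()
        else:
            fit = survival.fit_cox(ext_outcomes, X, cluster=cluster)
            coef = np.nan_to_num(fit.coef, nan=0.0, posinf=10.0, neginf=-10.0)
            score = X.to_numpy(dtype=float) @ coef
        return survival.harrells_c(time, delta, score).c_index

    per_cpg = {}
    for cpg in available:
        per_cpg[cpg] = _c_of(pd.concat([ext_residuals[[cpg]], base], axis=1))
    X_all = pd.concat([ext_residuals[available], base], axis=1)
    pen = 0.1 if delta.sum() < X_all.shape[1] else 0.0
    if pen:
        logger.warning(
            "combined refit ridge-stabilised (%d events < %d parameters)",
            int(delta.sum()), X_all.shape[1],
        )
    return {
        "available_cpgs": available,
        "dropped_cpgs": dropped,
        "per_cpg_c": per_cpg,
        "combined_c": _c_of(X_all, penalizer=pen),
        "basic_c": _c_of(base),
    }
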