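"""Preparation of model inputs: imputation, covariate adjustment, dichotomization.

Missing beta-values are imputed per CpG by ordinary least squares on sex, age
at entry, zygosity, data set and the three cell-type fractions.  The complete
matrix is then adjusted per CpG through a linear mixed model with those same
fixed effects and crossed random intercepts for sample plate and array
position; the residuals, standardised to SD one, are the inputs to all
downstream survival models.  Exposure status for the causal contrasts is the
sign of the standardised residual (residual >= 0 -> "high" methylation).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._lmm import CrossedLMMDesign

logger = logging.getLogger(__name__)

__all__ = ["impute_missing", "residualize", "dichotomize", "covariate_design"]


def covariate_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect design: intercept, sex, age, zygosity, data set, cell fractions.

    Categorical covariates are dummy-coded against a reference level; columns
    that are constant in the cohort (e.g. a single data set) are dropped so
    the design keeps full column rank.
    """
    cols = {"intercept": np.ones(len(cohort))}
    cols["sex_F"] = (cohort["sex"].to_numpy() == "F").astype(float)
    cols["age"] = cohort["age_at_entry"].to_numpy(dtype=float)
    cols["zygosity_MZ"] = (cohort["zygosity"].to_numpy() == "MZ").astype(float)
    for level in sorted(pd.unique(cohort["dataset"]))[1:]:
        cols[f"dataset_{level}"] = (cohort["dataset"].to_numpy() == level).astype(float)
    for c in ("frac_monocytes", "frac_lymphocytes", "frac_eosinophils"):
        cols[c] = cohort[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=cohort.index)
    keep = [c for c in X.columns if c == "intercept" or X[c].std() > 0]
    return X[keep]


def impute_missing(raw: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing beta-value by its OLS-predicted value.

    The per-CpG regression uses the covariate design above, fitted on the
    CpG's observed samples only.  Observed entries are never modified;
    imputed values are clamped to [0, 1].
    """
    raw = raw.loc[cohort.index]
    X = covariate_design(cohort).to_numpy()
    p = X.shape[1]
    values = raw.to_numpy(dtype=float, copy=True)
    missing = np.isnan(values)
    if not missing.any():
        return raw.copy()
    for j in np.flatnonzero(missing.any(axis=0)):
        obs = ~missing[:, j]
        n_obs = int(obs.sum())
        if n_obs < p + 2:
            raise ValueError(
                f"CpG {raw.columns[j]!r} has only {n_obs} observed values; "
                f"at least {p + 2} are required for imputation"
            )
        beta, *_ = np.linalg.lstsq(X[obs], values[obs, j], rcond=None)
        pred = X[~obs] @ beta
        values[~obs, j] = np.clip(pred, 0.0, 1.0)
    return pd.DataFrame(values, index=raw.index, columns=raw.columns)


def residualize(
    complete: pd.DataFrame,
    cohort: pd.DataFrame,
    method: str = "reml",
) -> pd.DataFrame:
    """Adjust each CpG for covariates and batch; return SD-1 residuals.

    ``method="reml"`` fits, per CpG, the linear mixed model with the fixed
    effects of :func:`covariate_design` and crossed random intercepts for
    plate and position, and subtracts both the fixed-effect fit and the
    predicted random effects.  CpGs whose REML optimisation fails fall back
    to a fixed-effects-only OLS fit (logged).  ``method="ols"`` skips the
    random effects entirely.  Residuals are standardised by their n-1 sample
    standard deviation.
    """
    if complete.shape[1] == 0:
        raise ValueError("empty methylation matrix")
    complete = complete.loc[cohort.index]
    values = complete.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("residualize requires a complete (imputed) matrix")
    sd0 = values.std(axis=0, ddof=1)
    if np.any(sd0 == 0):
        bad = complete.columns[np.flatnonzero(sd0 == 0)[0]]
        raise ValueError(f"CpG {bad!r} is constant; cannot residualize")

    X = covariate_design(cohort)
    Xa = X.to_numpy()
    plate = cohort["plate"].to_numpy()
    position = cohort["position"].to_numpy()
    design = CrossedLMMDesign(Xa, plate, position)
    use_reml = method == "reml" and design.has_random
    if method not in ("reml", "ols"):
        raise ValueError(f"unknown method {method!r}")

    resid = np.empty_like(values)
    n_fallback = 0
    for j in range(values.shape[1]):
        y = values[:, j]
        if use_reml:
            fit = design.fit(y)
            if fit.converged:
                resid[:, j] = fit.residual
                continue
            n_fallback += 1
        beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
        resid[:, j] = y - Xa @ beta
    if n_fallback:
        logger.warning(
            "REML did not converge for %d/%d CpGs; fixed-effects-only OLS used",
            n_fallback, values.shape[1],
        )
    sd = resid.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = complete.columns[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"CpG {bad!r} has zero residual variance")
    resid /= sd
    return pd.DataFrame(resid, index=complete.index, columns=complete.columns)


def dichotomize(residuals: pd.DataFrame) -> pd.DataFrame:
    """Binary exposure: 1 ("high") iff standardised residual >= 0."""
    return pd.DataFrame(
        (residuals.to_numpy(dtype=float) >= 0).astype(int),
        index=residuals.index,
        columns=residuals.columns,
    )
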